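import pytest

from mirtarget.align import DuplexAlignment, score_alignment
from mirtarget.ann import TrainingConfig, train_per_class
from mirtarget.seq_io import GAP, RnaSequence, pair_type
from mirtarget.simulate import GeneratorSpec, make_corpus

#: seeds used throughout the suite; fixed so every run exercises the same data
CORPUS_SEED = 1
TRAIN_SEED = 11


def duplex_from_strings(
    mirna_line: str,
    target_line: str,
    mirna_id: str = "mir",
    target_id: str = "utr",
    window_start: int = 0,
) -> DuplexAlignment:
    """Build a DuplexAlignment from two column-aligned strings.

    ``mirna_line`` runs 5'->3'; ``target_line`` holds the paired target bases
    3'->5' (the aligner's column convention). '-' marks a gap.
    """
    assert len(mirna_line) == len(target_line)
    cols = [(m, t, pair_type(m, t)) for m, t in zip(mirna_line, target_line)]
    used = sum(m != GAP for m in mirna_line)
    n_target = sum(t != GAP for t in target_line)
    return DuplexAlignment(
        mirna_id=mirna_id,
        target_id=target_id,
        window_start=window_start,
        columns=cols,
        score=score_alignment(cols),
        target_span=(window_start, window_start + n_target),
        mirna_span=(0, used),
    )


@pytest.fixture(scope="session")
def corpus():
    """Default-condition synthetic corpus (150/200 per split, 90-site fixture)."""
    return make_corpus(GeneratorSpec(seed=CORPUS_SEED))


@pytest.fixture(scope="session")
def models(corpus):
    """Per-class verifier networks trained on the session corpus."""
    return train_per_class(corpus.train_examples, TrainingConfig(seed=TRAIN_SEED))
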