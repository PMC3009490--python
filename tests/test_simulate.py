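import numpy as np
import pytest

from mirtarget.seq_io import PairType
from mirtarget.simulate import (
    GeneratorSpec,
    build_kinds,
    implant_site,
    make_corpus,
    make_mirna,
    read_examples_tsv,
    realize_duplex,
    synthesize_duplex,
    write_corpus,
    write_examples_tsv,
)
from mirtarget.site_classes import SeedDefinition, TargetClass, classify, region_counts

SPEC = GeneratorSpec(seed=3)


class TestMakeMirna:
    def test_seeded_determinism(self):
        a = make_mirna(np.random.default_rng(1), SPEC, "m")
        b = make_mirna(np.random.default_rng(1), SPEC, "m")
        assert a.seq == b.seq

    def test_lengths_within_range(self):
        rng = np.random.default_rng(0)
        lengths = {len(make_mirna(rng, SPEC, f"m{i}")) for i in range(500)}
        assert min(lengths) >= 18 and max(lengths) <= 24

    def test_composition_approaches_uniform(self):
        rng = np.random.default_rng(2)
        seq = "".join(make_mirna(rng, SPEC, f"m{i}").seq for i in range(800))
        for base in "ACGU":
            assert seq.count(base) / len(seq) == pytest.approx(0.25, abs=0.02)


class TestSynthesizeDuplex:
    @pytest.mark.parametrize(
        "cls", [TargetClass.SEED_ONLY, TargetClass.DOMINANT, TargetClass.CANONICAL]
    )
    def test_positive_duplex_classifies_as_requested(self, cls):
        rng = np.random.default_rng(17)
        for i in range(30):
            mirna = make_mirna(rng, SPEC, f"m{i}")
            aln, site = synthesize_duplex(mirna, cls, SPEC, rng)
            assert classify(*region_counts(aln, SPEC.seed_def)) is cls
            # site is the forward-strand reversal of the column target bases
            tbases = "".join(t for _m, t, _pt in aln.columns if t != "-")
            assert site == tbases[::-1]

    def test_decoy_fails_all_rules_but_keeps_seed_match_run(self):
        rng = np.random.default_rng(23)
        sd = SPEC.seed_def
        for i in range(60):
            mirna = make_mirna(rng, SPEC, f"m{i}")
            aln, _site = synthesize_duplex(mirna, None, SPEC, rng)
            assert classify(*region_counts(aln, sd)) is TargetClass.NONE
            # >4-mer consecutive matched stretch within the seed region
            run = best = 0
            for (_m, _t, pt), pos in zip(aln.columns, aln.mirna_positions()):
                if pos is not None and sd.contains(pos) and pt in (
                    PairType.WC, PairType.WOBBLE
                ):
                    run += 1
                    best = max(best, run)
                elif pos is not None and sd.contains(pos):
                    run = 0
            assert best > 4

    def test_none_request_rejected(self):
        rng = np.random.default_rng(1)
        with pytest.raises(ValueError):
            synthesize_duplex(make_mirna(rng, SPEC, "m"), TargetClass.NONE, SPEC, rng)

    def test_realize_handles_bulge_and_unpaired_kinds(self):
        rng = np.random.default_rng(5)
        mirna = make_mirna(rng, SPEC, "m")
        cols, site, used = realize_duplex(mirna, ["W", "B", "W", "D", "W"], rng)
        assert used == 4
        types = [pt for _m, _t, pt in cols]
        assert types[1] is PairType.GAP_MIRNA and types[3] is PairType.GAP_TARGET
        assert len(site) == 4  # three paired + one bulged target base


class TestImplantSite:
    def test_span_truth_and_site_content(self):
        rng = np.random.default_rng(9)
        mirna = make_mirna(rng, SPEC, "m")
        from mirtarget.simulate import _random_utr

        utr = _random_utr(rng, SPEC, "u")
        new, span, cls = implant_site(mirna, utr, TargetClass.SEED_ONLY, SPEC, rng)
        assert len(new.seq) == len(utr.seq)
        assert 0 <= span[0] < span[1] <= len(new.seq)
        # outside the span the UTR is untouched
        assert new.seq[: span[0]] == utr.seq[: span[0]]
        assert new.seq[span[1] :] == utr.seq[span[1] :]

    def test_unclassified_request_rejected(self):
        rng = np.random.default_rng(9)
        mirna = make_mirna(rng, SPEC, "m")
        from mirtarget.simulate import _random_utr

        utr = _random_utr(rng, SPEC, "u")
        with pytest.raises(ValueError):
            implant_site(mirna, utr, TargetClass.NONE, SPEC, rng)


class TestCorpus:
    def test_default_sizes_match_study_conditions(self, corpus):
        pos = {c: sum(e.label == 1 for e in ex) for c, ex in corpus.train_examples.items()}
        neg = {c: sum(e.label == -1 for e in ex) for c, ex in corpus.train_examples.items()}
        assert pos == {
            TargetClass.SEED_ONLY: 52,
            TargetClass.DOMINANT: 58,
            TargetClass.CANONICAL: 40,
        }
        assert neg == {
            TargetClass.SEED_ONLY: 70,
            TargetClass.DOMINANT: 74,
            TargetClass.CANONICAL: 56,
        }
        assert sum(pos.values()) == 150 and sum(neg.values()) == 200
        assert len(corpus.truth) == 90 and len(corpus.scan_utrs) == 60

    def test_every_positive_example_keeps_its_class_label(self, corpus):
        for cls, examples in corpus.train_examples.items():
            for e in examples:
                assert e.target_class is cls
                assert e.label in (+1, -1)

    def test_truth_spans_inside_utrs_and_pairs_consistent(self, corpus):
        utr_by_id = {u.id: u for u in corpus.scan_utrs}
        mirna_ids = {m.id for m in corpus.scan_mirnas}
        for t in corpus.truth:
            assert t.mirna_id in mirna_ids
            assert 0 <= t.start < t.end <= len(utr_by_id[t.target_id].seq)
            assert (t.mirna_id, t.target_id) in corpus.pairs

    def test_multiplicity_and_cooperation_present(self, corpus):
        from collections import Counter

        per_mirna = Counter(t.mirna_id for t in corpus.truth)
        per_utr = Counter(t.target_id for t in corpus.truth)
        assert max(per_mirna.values()) >= 2  # one miRNA targets several UTRs
        assert max(per_utr.values()) >= 2    # one UTR hosts several miRNAs
        multi = [u for u, n in per_utr.items() if n >= 2]
        for u in multi[:3]:
            mirs = {t.mirna_id for t in corpus.truth if t.target_id == u}
            assert len(mirs) >= 2

    def test_same_seed_reproduces_corpus_exactly(self):
        small = GeneratorSpec(
            seed=5,
            n_positives={c: 6 for c in list(TargetClass)[:3]},
            n_negatives={c: 6 for c in list(TargetClass)[:3]},
            n_utrs=4, n_sites=5, n_scan_mirnas=5,
        )
        a, b = make_corpus(small), make_corpus(small)
        assert [u.seq for u in a.scan_utrs] == [u.seq for u in b.scan_utrs]
        assert a.truth == b.truth
        for cls in a.train_examples:
            assert [e.features for e in a.train_examples[cls]] == [
                e.features for e in b.train_examples[cls]
            ]

    def test_corpus_files_roundtrip(self, tmp_path, corpus):
        write_corpus(corpus, tmp_path)
        assert (tmp_path / "mirnas.fasta").exists()
        assert (tmp_path / "truth.tsv").exists()
        back = read_examples_tsv(tmp_path / "train_dominant.tsv")
        orig = corpus.train_examples[TargetClass.DOMINANT]
        assert len(back) == len(orig)
        assert back[0].features == orig[0].features
        assert [e.label for e in back] == [e.label for e in orig]
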