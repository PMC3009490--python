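"""Seeded synthetic corpora of miRNA:target duplexes with known labels.

The generator emulates a curated training corpus of experimentally supported
target sites plus seed-matched decoys, at the scale used for the per-class
verifier networks: 150 positives (52 seed-only / 58 dominant / 40 canonical)
and 200 negatives (70 / 74 / 56 per class partition).

Positives are built by inverting the class rules: a per-class seed
composition (WC / G:U / mismatch counts over the 7 seed positions) and a
non-seed match count are sampled inside the class bounds, realised as a
gap-free duplex against a random miRNA, and re-checked with ``classify``.
Negatives are seed-matched decoys, not random sequence: each contains a
greater-than-4-mer consecutive WC run in its seed yet fails all three class
rules (chiefly by pairing too little outside the seed).

For positives, pair kinds are arranged so that every proper prefix and
suffix of the duplex scores positive under the alignment scheme (WC +5,
G:U +1, mismatch -3): position 1 and the miRNA 3' terminus are match
anchors and mismatches are only placed where the running score stays
positive. A scanning local alignment therefore recovers the implanted
duplex in full rather than trimming its ends.

The scan fixture implants sites into random-background UTRs, exercising
multiplicity (one miRNA, many UTRs) and cooperation (one UTR, several
miRNAs), and records ground truth plus the (miRNA, UTR) pairs to scan.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .align import DuplexAlignment, score_alignment
from .ann import LabeledExample
from .features import FEATURE_NAMES, FeatureVector, assemble_feature_vector
from .seq_io import RnaSequence, complement, pair_type, write_fasta
from .site_classes import SeedDefinition, TargetClass, classify, region_counts
from .thermo import FallbackBackend, compute_thermo_features

_BASES = "ACGU"
_WOBBLE_PARTNER = {"G": "U", "U": "G"}
_KIND_SCORE = {"W": 5, "G": 1, "M": -3}  # alignment-scheme score per kind

#: per-class seed compositions (wc, gu, mismatch) over the 7 seed positions;
#: each satisfies exactly its own class rule (given the non-seed match ranges
#: below) and fails all higher-precedence rules
SEED_COMPOSITIONS = {
    TargetClass.SEED_ONLY: [(7, 0, 0)],
    TargetClass.DOMINANT: [(6, 1, 0), (6, 0, 1), (5, 2, 0), (5, 1, 1)],
    # canonical compositions keep at least 5 paired seed positions; the
    # rule admits sparser seeds (down to 3 WC with 4 mismatches), but such
    # duplexes score so poorly that a local alignment of their own site
    # prefers a shifted, gapped arrangement and the intended register is lost
    # (5,0,2) is canonical, not dominant: two seed mismatches overrun the
    # dominant budget; it is also the wobble-free option for miRNAs whose
    # seed cannot form G:U pairs
    TargetClass.CANONICAL: [(4, 3, 0), (4, 2, 1), (4, 1, 2), (3, 3, 1), (3, 2, 2), (5, 0, 2)],
}

#: short-tail decoy seeds: the WC pairs form a consecutive >4-mer block, yet
#: the duplex fails every class rule once the non-seed region pairs poorly
#: (seed-only: mismatch ban; dominant: mismatch budget or non-seed minimum;
#: canonical: non-seed minimum)
NEGATIVE_SMALL_SEED = [(5, 0, 2), (6, 0, 1)]

#: large-duplex decoy seeds: a contiguous >4-mer match run that leans on
#: wobbles, failing every class rule in the seed itself (wc <= 2 or gu >= 4,
#: so even extensive 3' pairing cannot rescue the candidate); these decoys
#: carry long, bulged 3' regions and teach the verifier what chance
#: high-scoring alignments look like
NEGATIVE_LARGE_SEED = [(2, 3, 2), (2, 4, 1), (1, 4, 2), (0, 5, 2), (1, 5, 1), (2, 5, 0)]


@dataclass(frozen=True)
class GeneratorSpec:
    seed: int = 0
    n_positives: dict = field(
        default_factory=lambda: {
            TargetClass.SEED_ONLY: 52,
            TargetClass.DOMINANT: 58,
            TargetClass.CANONICAL: 40,
        }
    )
    n_negatives: dict = field(
        default_factory=lambda: {
            TargetClass.SEED_ONLY: 70,
            TargetClass.DOMINANT: 74,
            TargetClass.CANONICAL: 56,
        }
    )
    mirna_length: tuple = (18, 24)
    utr_length: tuple = (80, 120)
    base_probs: tuple = (0.25, 0.25, 0.25, 0.25)  # A, C, G, U
    seed_def: SeedDefinition = SeedDefinition()
    #: inclusive non-seed match ranges per class (the non-seed region
    #: includes miRNA position 1, always realised as a WC anchor)
    nonseed_matches: dict = field(
        default_factory=lambda: {
            TargetClass.SEED_ONLY: (4, 6),
            TargetClass.DOMINANT: (6, 10),
            TargetClass.CANONICAL: (8, 12),
        }
    )
    #: maximum mismatches interleaved into a positive's 3' region; kept low
    #: so the intended duplex outscores chance alignments of its own site
    positive_tail_mismatches: int = 1
    negative_nonseed_matches: tuple = (1, 3)
    #: large-decoy geometry: 3' match range, mismatch range, bulge-run count
    #: range and bulge-run length range; fraction of decoys drawn large
    negative_large_matches: tuple = (6, 12)
    negative_large_mismatches: tuple = (1, 3)
    negative_large_bulges: tuple = (1, 2)
    negative_large_bulge_len: tuple = (1, 2)
    negative_large_fraction: float = 0.5
    # scan fixture geometry
    n_utrs: int = 60
    n_scan_mirnas: int = 25
    n_sites: int = 90


def make_mirna(rng: np.random.Generator, spec: GeneratorSpec, name: str) -> RnaSequence:
    lo, hi = spec.mirna_length
    length = int(rng.integers(lo, hi + 1))
    seq = "".join(rng.choice(list(_BASES), size=length, p=list(spec.base_probs)))
    return RnaSequence(name, seq)


def _random_utr(rng, spec, name: str) -> RnaSequence:
    lo, hi = spec.utr_length
    length = int(rng.integers(lo, hi + 1))
    return RnaSequence(
        name, "".join(rng.choice(list(_BASES), size=length, p=list(spec.base_probs)))
    )


def _arrange_region(start_sum, mirna_seq, indices, counts, rng, enforce=True):
    """Greedily order (w, g, m) kinds over the given 0-based miRNA indices.

    G:U kinds only land on wobble-capable positions (miRNA G or U);
    mismatches only where the running alignment score stays >= 1 (when
    ``enforce``), and never on the last index while matches remain. Returns
    (kinds, final running sum) or None on a dead end.
    """
    w, g, m = counts
    cap = [mirna_seq[i] in _WOBBLE_PARTNER for i in indices]
    kinds: list[str] = []
    total = start_sum
    n = len(indices)
    for t in range(n):
        cap_rest = sum(cap[t:])
        forced_g = g > 0 and cap[t] and g >= cap_rest
        last = t == n - 1
        if forced_g:
            place = "G"
        elif m > 0 and (not enforce or total >= 4) and not (last and w + g > 0):
            place = "M"
        elif g > 0 and cap[t] and (w == 0 or rng.random() < g / (w + g)):
            place = "G"
        elif w > 0:
            place = "W"
        elif g > 0 and cap[t]:
            place = "G"
        elif m > 0:
            if enforce and total < 4:
                return None
            place = "M"
        else:
            return None  # only G left but the position cannot wobble
        kinds.append(place)
        if place == "W":
            w -= 1
        elif place == "G":
            g -= 1
        else:
            m -= 1
        total += _KIND_SCORE[place]
    if (w, g, m) != (0, 0, 0):
        return None
    return kinds, total


def _ends_positive(kinds: list[str]) -> bool:
    """Every proper prefix and suffix scores >= 1 under the alignment scheme."""
    scores = [_KIND_SCORE[k] for k in kinds]
    acc = 0
    for s in scores[:-1]:
        acc += s
        if acc < 1:
            return False
    acc = 0
    for s in reversed(scores[1:]):
        acc += s
        if acc < 1:
            return False
    return True


def _negative_seed_kinds(comp, rng) -> list[str]:
    """Short-tail decoy seed: the WC pairs form one consecutive >4-mer block."""
    wc, _gu, mm = comp
    rest = ["M"] * mm
    cut = int(rng.integers(0, mm + 1))
    kinds = rest[:cut] + ["W"] * wc + rest[cut:]
    return kinds


def _large_decoy_seed_kinds(comp, seed_bases: str, rng):
    """Large-decoy seed: one contiguous match run with every G:U kind on a
    wobble-capable position; None when this seed sequence cannot host it."""
    wc, gu, mm = comp
    run = wc + gu
    cap = [b in _WOBBLE_PARTNER for b in seed_bases]
    offsets = [o for o in range(len(seed_bases) - run + 1) if sum(cap[o : o + run]) >= gu]
    if not offsets:
        return None
    o = offsets[int(rng.integers(0, len(offsets)))]
    capable_in_run = [i for i in range(o, o + run) if cap[i]]
    rng.shuffle(capable_in_run)
    g_pos = set(capable_in_run[:gu])
    kinds = ["M"] * len(seed_bases)
    for i in range(o, o + run):
        kinds[i] = "G" if i in g_pos else "W"
    return kinds


def _large_decoy_tail_kinds(tail_room: int, spec: GeneratorSpec, rng) -> list[str]:
    """Bulged, mismatch-bearing 3' region for a large decoy."""
    m_lo, m_hi = spec.negative_large_matches
    x_lo, x_hi = spec.negative_large_mismatches
    n_mm = int(rng.integers(x_lo, x_hi + 1))
    n_match = int(rng.integers(m_lo, min(m_hi, tail_room - n_mm) + 1))
    kinds = ["W"] * n_match + ["M"] * n_mm
    rng.shuffle(kinds)
    b_lo, b_hi = spec.negative_large_bulges
    for _ in range(int(rng.integers(b_lo, b_hi + 1))):
        # bulges are unpaired target bases ('B'), which cost no miRNA
        # positions, so the duplex always fits the miRNA 3' region
        lo, hi = spec.negative_large_bulge_len
        run = ["B"] * int(rng.integers(lo, hi + 1))
        pos = int(rng.integers(1, len(kinds)))
        kinds[pos:pos] = run
    return kinds


def _tail_kinds(n_matches: int, n_mismatches: int, rng) -> list[str]:
    """3'-region kinds: matches with mismatches singly interleaved between
    them (never adjacent, never terminal), so every suffix stays positive."""
    if n_matches == 0:
        return []
    gaps = min(n_mismatches, n_matches - 1)
    chosen = set(rng.choice(n_matches - 1, size=gaps, replace=False)) if gaps else set()
    out = []
    for i in range(n_matches):
        out.append("W")
        if i in chosen:
            out.append("M")
    return out


def build_kinds(
    mirna: RnaSequence,
    cls: TargetClass | None,
    spec: GeneratorSpec,
    rng,
    max_tries: int = 100,
) -> list[str]:
    """Pair kinds ('W'/'G'/'M') for miRNA positions 1..K, 5'->3'.

    The duplex covers only a 5' prefix of the miRNA: beyond the last 3'
    match the site would pair by chance alone, and a local alignment would
    trim such a tail anyway, so it is simply not constructed. ``cls=None``
    builds a negative decoy. Positives additionally satisfy the
    end-positivity property (see module docstring). Raises if no feasible
    arrangement exists for this miRNA.
    """
    sd = spec.seed_def
    L = len(mirna.seq)
    seed_idx = list(range(sd.start - 1, sd.end))
    avail_gu = sum(mirna.seq[i] in _WOBBLE_PARTNER for i in seed_idx)
    tail_room = L - sd.end  # positions seed_end+1 .. L

    for _try in range(max_tries):
        if cls is None:
            if rng.random() < spec.negative_large_fraction:
                comps = list(NEGATIVE_LARGE_SEED)
                rng.shuffle(comps)
                seed_bases = mirna.seq[sd.start - 1 : sd.end]
                for comp in comps:
                    seed_kinds = _large_decoy_seed_kinds(comp, seed_bases, rng)
                    if seed_kinds is not None:
                        tail = _large_decoy_tail_kinds(tail_room, spec, rng)
                        return ["W"] + seed_kinds + tail
                # this miRNA's seed cannot wobble enough: fall through to a
                # short-tail decoy
            comp = NEGATIVE_SMALL_SEED[rng.integers(0, len(NEGATIVE_SMALL_SEED))]
            seed_kinds = _negative_seed_kinds(comp, rng)
            m_lo, m_hi = spec.negative_nonseed_matches
        else:
            comps = [c for c in SEED_COMPOSITIONS[cls] if c[1] <= avail_gu]
            if not comps:
                raise ValueError(f"no feasible seed composition for {cls} and this miRNA")
            comp = comps[rng.integers(0, len(comps))]
            got = _arrange_region(5, mirna.seq, seed_idx, comp, rng, enforce=True)
            if got is None:
                continue
            seed_kinds, _ = got
            m_lo, m_hi = spec.nonseed_matches[cls]

        n_total = int(rng.integers(m_lo, min(m_hi, 1 + tail_room) + 1))
        n_tail = max(0, n_total - 1)  # position 1 is one non-seed match
        max_mm = max(0, min(n_tail - 1, tail_room - n_tail))
        if cls is not None:
            max_mm = min(max_mm, spec.positive_tail_mismatches)
        m_tail = int(rng.integers(0, max_mm + 1))
        kinds = ["W"] + seed_kinds + _tail_kinds(n_tail, m_tail, rng)
        if cls is not None and not _ends_positive(kinds):
            continue
        return kinds
    raise ValueError(f"could not arrange a {cls} duplex for miRNA {mirna.id!r}")


def realize_duplex(mirna: RnaSequence, kinds: list[str], rng):
    """Realise duplex columns from pair kinds -> (columns, site 5'->3', used).

    Kinds: 'W' Watson-Crick, 'G' wobble, 'M' mismatch, 'B' bulged target
    base (gap in the miRNA), 'D' unpaired miRNA base (gap in the target).
    Kinds other than 'B' consume one miRNA position each, starting at the
    5' end; ``used`` is the number of miRNA positions consumed. Columns run
    5'->3' along the miRNA with target bases 3'->5'; the forward-strand site
    is the reversal of the column target bases.
    """
    columns = []
    i = 0
    for kind in kinds:
        if kind == "B":
            extra = _BASES[rng.integers(0, 4)]
            columns.append(("-", extra, pair_type("-", extra)))
            continue
        base = mirna.seq[i]
        i += 1
        if kind == "W":
            partner = complement(base)
        elif kind == "G":
            partner = _WOBBLE_PARTNER[base]
        elif kind == "D":
            partner = "-"
        else:
            banned = {complement(base), _WOBBLE_PARTNER.get(base, "")}
            choices = [b for b in _BASES if b not in banned]
            partner = choices[rng.integers(0, len(choices))]
        columns.append((base, partner, pair_type(base, partner)))
    site = "".join(tb for _mb, tb, _pt in reversed(columns) if tb != "-")
    return columns, site, i


def synthesize_duplex(
    mirna: RnaSequence, cls: TargetClass | None, spec: GeneratorSpec, rng
):
    """A full-length gap-free duplex of the requested class (None = decoy).

    The realised duplex is re-checked against ``classify``; a mismatch with
    the requested class is a generator bug and raises.
    """
    if cls is TargetClass.NONE:
        raise ValueError("request a real class or None for a decoy")
    kinds = build_kinds(mirna, cls, spec, rng)
    columns, site, used = realize_duplex(mirna, kinds, rng)
    aln = DuplexAlignment(
        mirna_id=mirna.id, target_id="synthetic", window_start=0,
        columns=columns, score=score_alignment(columns),
        target_span=(0, len(site)), mirna_span=(0, used),
    )
    got = classify(*region_counts(aln, spec.seed_def))
    want = cls if cls is not None else TargetClass.NONE
    if got is not want:
        raise AssertionError(f"generator self-check failed: wanted {want}, got {got}")
    return aln, site


def example_from_duplex(aln, site: str, mirna: RnaSequence, label: int,
                        cls: TargetClass, spec: GeneratorSpec,
                        backend=None) -> LabeledExample:
    backend = backend or FallbackBackend()
    energies = compute_thermo_features(aln, mirna, site, backend)
    fv = assemble_feature_vector(aln, site, energies, len(mirna.seq), spec.seed_def)
    return LabeledExample(features=fv, label=label, target_class=cls)


def _make_examples(spec: GeneratorSpec, rng, tag: str):
    """Per-class positive and seed-matched-decoy labelled examples."""
    backend = FallbackBackend()
    by_class: dict[TargetClass, list[LabeledExample]] = {}
    counter = 0
    for cls in (TargetClass.SEED_ONLY, TargetClass.DOMINANT, TargetClass.CANONICAL):
        examples = []
        for want, n in ((cls, spec.n_positives[cls]), (None, spec.n_negatives[cls])):
            label = +1 if want is not None else -1
            for _ in range(n):
                mirna = make_mirna(rng, spec, f"{tag}-mir-{counter}")
                counter += 1
                aln, site = synthesize_duplex(mirna, want, spec, rng)
                examples.append(example_from_duplex(aln, site, mirna, label, cls, spec, backend))
        by_class[cls] = examples
    return by_class


@dataclass
class TruthRecord:
    mirna_id: str
    target_id: str
    start: int
    end: int
    target_class: TargetClass


@dataclass
class Corpus:
    spec: GeneratorSpec
    train_examples: dict  # TargetClass -> list[LabeledExample]
    test_examples: dict   # TargetClass -> list[LabeledExample], fresh draws
    scan_mirnas: list     # list[RnaSequence]
    scan_utrs: list       # list[RnaSequence]
    truth: list           # list[TruthRecord]
    pairs: list           # (mirna_id, target_id) pairs to scan


def implant_site(
    mirna: RnaSequence,
    utr: RnaSequence,
    cls: TargetClass,
    spec: GeneratorSpec,
    rng,
    occupied: list[tuple[int, int]] | None = None,
):
    """Splice a class-``cls`` site for ``mirna`` into the UTR at a random
    free position; returns (modified UTR, (start, end), class)."""
    _aln, site = synthesize_duplex(mirna, cls, spec, rng)
    L = len(site)
    if len(utr.seq) < L:
        raise ValueError("UTR shorter than the site to implant")
    occupied = occupied or []
    for _attempt in range(200):
        start = int(rng.integers(0, len(utr.seq) - L + 1))
        end = start + L
        if all(end + 2 <= s or start >= e + 2 for s, e in occupied):
            break
    else:
        raise ValueError("could not place a non-overlapping site")
    new_seq = utr.seq[:start] + site + utr.seq[end:]
    return RnaSequence(utr.id, new_seq), (start, end), cls


def _make_scan_fixture(spec: GeneratorSpec, rng):
    classes = (TargetClass.SEED_ONLY, TargetClass.DOMINANT, TargetClass.CANONICAL)
    mirnas = [make_mirna(rng, spec, f"scan-mir-{i}") for i in range(spec.n_scan_mirnas)]
    utrs = []
    truth: list[TruthRecord] = []
    pairs: set[tuple[str, str]] = set()

    # distribute sites over UTRs: early UTRs take two sites from different
    # miRNAs (cooperation), the rest one, totalling n_sites
    per_utr = [1] * spec.n_utrs
    extra = spec.n_sites - spec.n_utrs
    if extra < 0 or extra > spec.n_utrs:
        raise ValueError("n_sites must lie in [n_utrs, 2*n_utrs]")
    for i in range(extra):
        per_utr[i] = 2

    # implanting is re-tried per UTR until every implanted site is recovered
    # at the candidate (pre-verifier) stage exactly as constructed: same
    # span, same class, no gap columns. Random flanking context can let the
    # aligner extend a site into a higher-scoring gapped variant whose
    # features no longer match any constructed duplex; such contexts are
    # re-drawn, so the emitted ground truth is reachable by the scanning
    # pipeline in its intended register.
    from .pipeline import PipelineConfig, candidate_sites

    cfg = PipelineConfig(seed_def=spec.seed_def)
    by_mir = {m.id: m for m in mirnas}

    def _recovered_exactly(t: TruthRecord, utr) -> bool:
        for s in candidate_sites(by_mir[t.mirna_id], utr, cfg):
            if (
                s.target_span == (t.start, t.end)
                and s.target_class is t.target_class
                and len(s.alignment.columns) == s.alignment.mirna_span[1] - s.alignment.mirna_span[0]
            ):
                return True
        return False

    site_idx = 0
    for u in range(spec.n_utrs):
        for _attempt in range(200):
            utr = _random_utr(rng, spec, f"scan-utr-{u}")
            occupied: list[tuple[int, int]] = []
            local: list[TruthRecord] = []
            idx = site_idx
            chosen = rng.choice(len(mirnas), size=per_utr[u], replace=False)
            for mi in chosen:
                mirna = mirnas[int(mi)]
                cls = classes[idx % 3]
                idx += 1
                utr, span, cls = implant_site(mirna, utr, cls, spec, rng, occupied)
                occupied.append(span)
                local.append(TruthRecord(mirna.id, utr.id, span[0], span[1], cls))
            if all(_recovered_exactly(t, utr) for t in local):
                break
        else:
            raise RuntimeError(f"could not build a recoverable UTR {u}")
        site_idx = idx
        truth.extend(local)
        pairs.update((t.mirna_id, t.target_id) for t in local)
        utrs.append(utr)
    return mirnas, utrs, truth, sorted(pairs)


def make_corpus(spec: GeneratorSpec = GeneratorSpec()) -> Corpus:
    """Training + test example tables and a scan-ready implanted fixture."""
    rng = np.random.default_rng(spec.seed)
    train = _make_examples(spec, rng, "train")
    test = _make_examples(spec, rng, "test")
    mirnas, utrs, truth, pairs = _make_scan_fixture(spec, rng)
    return Corpus(spec, train, test, mirnas, utrs, truth, pairs)


# ---------------------------------------------------------------- file I/O

def write_examples_tsv(examples: list[LabeledExample], path) -> None:
    with open(path, "w") as fh:
        fh.write("label\ttarget_class\t" + "\t".join(FEATURE_NAMES) + "\n")
        for ex in examples:
            vals = "\t".join(repr(float(v)) for v in ex.features.as_tuple())
            fh.write(f"{ex.label:+d}\t{ex.target_class.value}\t{vals}\n")


def read_examples_tsv(path) -> list[LabeledExample]:
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[2:] != list(FEATURE_NAMES):
            raise ValueError(f"{path}: unexpected feature table header")
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            out.append(
                LabeledExample(
                    features=FeatureVector.from_iterable(parts[2:]),
                    label=int(parts[0]),
                    target_class=TargetClass(parts[1]),
                )
            )
    return out


def write_corpus(corpus: Corpus, outdir) -> None:
    """Emit FASTA corpus, per-class feature TSVs, truth and pairing tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(corpus.scan_mirnas, outdir / "mirnas.fasta")
    write_fasta(corpus.scan_utrs, outdir / "targets.fasta")
    for split, table in (("train", corpus.train_examples), ("test", corpus.test_examples)):
        for cls, examples in table.items():
            write_examples_tsv(examples, outdir / f"{split}_{cls.value.lower()}.tsv")
    with open(outdir / "truth.tsv", "w") as fh:
        fh.write("mirna_id\ttarget_id\tstart\tend\ttarget_class\n")
        for t in corpus.truth:
            fh.write(f"{t.mirna_id}\t{t.target_id}\t{t.start}\t{t.end}\t{t.target_class.value}\n")
    with open(outdir / "pairs.tsv", "w") as fh:
        fh.write("mirna_id\ttarget_id\n")
        for m, t in corpus.pairs:
            fh.write(f"{m}\t{t}\n")


def read_pairs_tsv(path) -> list[tuple[str, str]]:
    pairs = []
    with open(path) as fh:
        fh.readline()
        for line in fh:
            m, t = line.rstrip("\n").split("\t")
            pairs.append((m, t))
    return pairs
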