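"""The 16-dimensional feature vector of a classified miRNA:target duplex.

Features fall into three groups: structural (1-8), thermodynamic (9-12) and
positional (13-16). Several use their own pair-scoring tables, which differ
deliberately from the alignment scheme:

* seed / out-seed scores (1-2): WC 5, G:U 2, anything else (mismatch or gap
  column) -3, summed per region.
* positional pair score (13): WC 5, G:U 1, mismatch -3, gap-containing
  column -1; each column weighted 2 inside the seed and 1 outside.
* matrix score (14): WC 5, wobble 2, insert (gap in miRNA) -1, delete (gap in
  target) -1, symmetric mismatch (identical bases, e.g. A:A) -3, other
  mismatch -2.
* deviations (15-16): perfect-target score minus observed score, for the
  matrix and positional scorers; zero for a perfect complement.

Feature 8 ("proportion") is encoded as the G+C fraction of the target-site
subsequence so that it occupies a single input node.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

from .seq_io import GAP, PairType
from .site_classes import SeedDefinition
from .thermo import ThermoFeatures

#: fixed feature order; also the TSV header used for training tables
FEATURE_NAMES = (
    "seed_score",
    "out_seed_score",
    "wc_pairs",
    "wobble_pairs",
    "mismatches",
    "length_bulge",
    "number_bulges",
    "proportion_gc",
    "free_energy",
    "hybridization_energy",
    "normalized_free_energy",
    "delta_hybridization_energy",
    "positional_pair_score",
    "matrix_score",
    "deviation_matrix_score",
    "deviation_positional_score",
)


@dataclass(frozen=True)
class FeatureVector:
    seed_score: float
    out_seed_score: float
    wc_pairs: float
    wobble_pairs: float
    mismatches: float
    length_bulge: float
    number_bulges: float
    proportion_gc: float
    free_energy: float
    hybridization_energy: float
    normalized_free_energy: float
    delta_hybridization_energy: float
    positional_pair_score: float
    matrix_score: float
    deviation_matrix_score: float
    deviation_positional_score: float

    def as_tuple(self) -> tuple[float, ...]:
        return tuple(getattr(self, f.name) for f in fields(self))

    @classmethod
    def from_iterable(cls, values) -> "FeatureVector":
        vals = list(values)
        if len(vals) != 16:
            raise ValueError(f"expected 16 features, got {len(vals)}")
        return cls(*(float(v) for v in vals))


def _column_regions(aln, seed: SeedDefinition):
    """Yield ``(column, in_seed)``, attributing gap-in-miRNA columns to the
    region of the last consumed miRNA position (as in region_counts)."""
    last_pos = aln.mirna_span[0]
    for col, pos in zip(aln.columns, aln.mirna_positions()):
        if pos is not None:
            last_pos = pos
        yield col, seed.contains(last_pos)


def seed_and_outseed_scores(aln, seed: SeedDefinition = SeedDefinition()):
    """Region complementarity scores: WC 5, G:U 2, other columns -3."""
    totals = {True: 0, False: 0}
    for (_mb, _tb, pt), in_seed in _column_regions(aln, seed):
        if pt is PairType.WC:
            totals[in_seed] += 5
        elif pt is PairType.WOBBLE:
            totals[in_seed] += 2
        else:
            totals[in_seed] -= 3
    return totals[True], totals[False]


def structural_counts(aln, site_seq: str):
    """Counts over all columns plus bulge geometry and site G+C fraction.

    A bulge is a maximal run of consecutive gap columns on one strand;
    ``site_seq`` is the forward-strand target-site subsequence.
    """
    wc = gu = mm = 0
    bulges: list[int] = []
    run_len = 0
    run_type = None
    for _mb, _tb, pt in aln.columns:
        if pt in (PairType.GAP_MIRNA, PairType.GAP_TARGET):
            if pt is run_type:
                run_len += 1
            else:
                if run_len:
                    bulges.append(run_len)
                run_len, run_type = 1, pt
        else:
            if run_len:
                bulges.append(run_len)
            run_len, run_type = 0, None
            if pt is PairType.WC:
                wc += 1
            elif pt is PairType.WOBBLE:
                gu += 1
            else:
                mm += 1
    if run_len:
        bulges.append(run_len)
    length_bulge = max(bulges) if bulges else 0
    proportion = (site_seq.count("G") + site_seq.count("C")) / len(site_seq) if site_seq else 0.0
    return wc, gu, mm, length_bulge, len(bulges), proportion


def positional_pair_score(aln, seed: SeedDefinition = SeedDefinition()) -> int:
    """Pairing x position score; seed columns carry double weight."""
    total = 0
    for (_mb, _tb, pt), in_seed in _column_regions(aln, seed):
        if pt is PairType.WC:
            s = 5
        elif pt is PairType.WOBBLE:
            s = 1
        elif pt is PairType.MISMATCH:
            s = -3
        else:
            s = -1
        total += (2 if in_seed else 1) * s
    return total


def matrix_score(aln) -> int:
    """Sum of per-column substitution-matrix entries (see module docstring)."""
    total = 0
    for mb, tb, pt in aln.columns:
        if pt is PairType.WC:
            total += 5
        elif pt is PairType.WOBBLE:
            total += 2
        elif pt is PairType.GAP_MIRNA:
            total -= 1  # insert
        elif pt is PairType.GAP_TARGET:
            total -= 1  # delete
        elif mb == tb:
            total -= 3  # symmetric mismatch, e.g. A:A
        else:
            total -= 2
    return total


def perfect_matrix_score(mirna_len: int) -> int:
    return 5 * mirna_len


def perfect_positional_score(mirna_len: int, seed: SeedDefinition = SeedDefinition()) -> int:
    n_seed = min(seed.end, mirna_len) - seed.start + 1
    n_seed = max(n_seed, 0)
    return n_seed * 2 * 5 + (mirna_len - n_seed) * 5


def deviation_scores(aln, mirna_len: int, seed: SeedDefinition = SeedDefinition()):
    """Perfect-target score minus observed score for scorers 14 and 13.

    The perfect target is the reverse complement of the miRNA: every column
    WC, no gaps. Deviations are >= 0 for gap-free duplexes.
    """
    dev_matrix = perfect_matrix_score(mirna_len) - matrix_score(aln)
    dev_positional = perfect_positional_score(mirna_len, seed) - positional_pair_score(aln, seed)
    return dev_matrix, dev_positional


def assemble_feature_vector(
    aln,
    site_seq: str,
    energies: ThermoFeatures,
    mirna_len: int,
    seed: SeedDefinition = SeedDefinition(),
) -> FeatureVector:
    """All 16 features for one classified candidate, in fixed order."""
    seed_sc, out_sc = seed_and_outseed_scores(aln, seed)
    wc, gu, mm, lbulge, nbulge, prop = structural_counts(aln, site_seq)
    pps = positional_pair_score(aln, seed)
    msc = matrix_score(aln)
    dev_m, dev_p = deviation_scores(aln, mirna_len, seed)
    return FeatureVector(
        seed_score=seed_sc,
        out_seed_score=out_sc,
        wc_pairs=wc,
        wobble_pairs=gu,
        mismatches=mm,
        length_bulge=lbulge,
        number_bulges=nbulge,
        proportion_gc=prop,
        free_energy=energies.free_energy,
        hybridization_energy=energies.hybridization_energy,
        normalized_free_energy=energies.normalized_free_energy,
        delta_hybridization_energy=energies.delta_hybridization_energy,
        positional_pair_score=pps,
        matrix_score=msc,
        deviation_matrix_score=dev_m,
        deviation_positional_score=dev_p,
    )
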