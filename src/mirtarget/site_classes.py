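"""Seed/non-seed partition of a duplex and the three-class site rules.

Animal miRNA sites fall into three classes by where the pairing strength
lies: 5' seed-only (perfect seed, minimal 3' pairing), 5' dominant (strong
seed plus some 3' pairing) and 3' canonical (weak seed compensated by
extensive 3'-end pairing). The seed region is miRNA positions 2-8 from the
5' end by default (2-9 configurable).

Classification is a strict cascade SEED_ONLY -> DOMINANT -> CANONICAL; the
numeric bounds overlap (a perfect seed also satisfies the dominant bounds)
and the first rule that matches wins. Thresholds are bounds, not exact
counts. A candidate matching none of the rules is NONE and dropped.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .seq_io import GAP, PairType


class TargetClass(enum.Enum):
    SEED_ONLY = "SEED_ONLY"   # Class 1: 5' Seed-only
    DOMINANT = "DOMINANT"     # Class 2: 5' Dominant
    CANONICAL = "CANONICAL"   # Class 3: 3' Canonical
    NONE = "NONE"

    @property
    def report_label(self) -> str:
        return _REPORT_LABELS[self]


_REPORT_LABELS = {
    TargetClass.SEED_ONLY: "Class 1: 5' Seed-only",
    TargetClass.DOMINANT: "Class 2: 5' Dominant",
    TargetClass.CANONICAL: "Class 3: 3' Canonical",
    TargetClass.NONE: "unclassified",
}


@dataclass(frozen=True)
class SeedDefinition:
    """Seed positions on the miRNA, 1-based inclusive from the 5' end."""

    start: int = 2
    end: int = 8

    def __post_init__(self) -> None:
        if not (2 <= self.start < self.end <= 9):
            raise ValueError(f"invalid seed definition {self.start}-{self.end}")

    def contains(self, mirna_pos_1based: int) -> bool:
        return self.start <= mirna_pos_1based <= self.end

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @classmethod
    def parse(cls, text: str) -> "SeedDefinition":
        """Parse a '2-8' / '2-9' style string."""
        try:
            lo, hi = (int(x) for x in text.split("-"))
        except Exception:
            raise ValueError(f"cannot parse seed definition {text!r}") from None
        return cls(lo, hi)


@dataclass
class RegionCounts:
    wc: int = 0
    gu: int = 0
    mismatch: int = 0
    gaps: int = 0  # gap columns attributed to the region (bulge features aside)

    @property
    def matches(self) -> int:
        """Base-paired columns: WC plus wobble."""
        return self.wc + self.gu


def covers_seed(aln, seed: SeedDefinition) -> bool:
    """Whether the alignment's miRNA span includes every seed position."""
    lo, hi = aln.mirna_span
    return lo <= seed.start - 1 and hi >= seed.end


def region_counts(aln, seed: SeedDefinition = SeedDefinition()):
    """Split alignment columns into seed / non-seed counts by miRNA position.

    Base-base columns are attributed by the miRNA position they consume; a
    gap-in-miRNA column (which consumes no miRNA base) is attributed to the
    region of the last consumed miRNA position. Gap columns are tallied
    separately: they are not WC/GU/mismatch, but a gap inside the seed
    disqualifies SEED_ONLY and spends mismatch budget in the other classes.
    """
    seed_rc, non_rc = RegionCounts(), RegionCounts()
    last_pos = aln.mirna_span[0]  # 1-based after increment below
    for (mb, _tb, pt), pos in zip(aln.columns, aln.mirna_positions()):
        if pos is not None:
            last_pos = pos
        region = seed_rc if seed.contains(last_pos) else non_rc
        if pt is PairType.WC:
            region.wc += 1
        elif pt is PairType.WOBBLE:
            region.gu += 1
        elif pt is PairType.MISMATCH:
            region.mismatch += 1
        else:
            region.gaps += 1
        assert not (mb == GAP and pos is not None)
    return seed_rc, non_rc


def classify(seed_counts: RegionCounts, nonseed_counts: RegionCounts) -> TargetClass:
    """Apply the three-class rule cascade to seed / non-seed counts.

    SEED_ONLY: >= 6 WC, no mismatch, no G:U (and no gap) in the seed;
    non-seed >= 4 matches (G:U counts as a match).
    DOMINANT:  >= 5 WC, <= 1 mismatch, <= 2 G:U in the seed; non-seed >= 5.
    CANONICAL: >= 3 WC, <= 4 mismatches, <= 3 G:U in the seed; non-seed >= 7.
    Anything else is NONE. Seed gap columns count against the mismatch budget
    of DOMINANT and CANONICAL.
    """
    s, n = seed_counts, nonseed_counts
    seed_mm = s.mismatch + s.gaps
    if s.wc >= 6 and s.mismatch == 0 and s.gu == 0 and s.gaps == 0 and n.matches >= 4:
        return TargetClass.SEED_ONLY
    if s.wc >= 5 and seed_mm <= 1 and s.gu <= 2 and n.matches >= 5:
        return TargetClass.DOMINANT
    if s.wc >= 3 and seed_mm <= 4 and s.gu <= 3 and n.matches >= 7:
        return TargetClass.CANONICAL
    return TargetClass.NONE


def classify_alignment(aln, seed: SeedDefinition = SeedDefinition()):
    """Classify a duplex alignment; NONE if the seed is not fully covered.

    Returns ``(target_class, seed_counts, nonseed_counts)``.
    """
    if not covers_seed(aln, seed):
        return TargetClass.NONE, RegionCounts(), RegionCounts()
    seed_rc, non_rc = region_counts(aln, seed)
    return classify(seed_rc, non_rc), seed_rc, non_rc
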