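"""Windowed local duplex alignment of a miRNA against a target sequence.

The target is scanned with windows of length ``len(miRNA) + 10`` starting at
every position. Each window is reversed before alignment so that the duplex is
antiparallel: alignment column k pairs miRNA base k' (5'->3') with a target
base read 3'->5'. Reported target coordinates are mapped back to the forward
strand of the input FASTA, 0-based half-open.

Scoring is a local (floor-at-zero) Smith-Waterman with affine gaps realised as
a three-state Gotoh DP: Watson-Crick pair +5, G:U wobble +1, mismatch -3,
first column of a gap run -8, each further column of the same run -2. Gaps are
thus penalised more than mismatches, so mismatches are preferred to gaps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterator, Optional

from .seq_io import GAP, PairType, RnaSequence, pair_type
from .site_classes import TargetClass

#: extra nucleotides a scan window extends beyond the miRNA length
WINDOW_MARGIN = 10

#: minimum number of base-paired (WC or wobble) columns for a window alignment
#: to proceed to classification
CANDIDATE_MIN_PAIRS = 4


@dataclass(frozen=True)
class ScoringScheme:
    wc: int = 5
    gu: int = 1
    mismatch: int = -3
    gap_open: int = -8      # score of the first column of a gap run
    gap_extend: int = -2    # score of each subsequent column of the run

    def __post_init__(self) -> None:
        if not self.gap_open < self.mismatch:
            raise ValueError("gap_open must be more penalising than mismatch")
        if not self.wc > self.gu > 0:
            raise ValueError("require wc > gu > 0")

    def column(self, ptype: PairType) -> int:
        if ptype is PairType.WC:
            return self.wc
        if ptype is PairType.WOBBLE:
            return self.gu
        if ptype is PairType.MISMATCH:
            return self.mismatch
        raise ValueError("gap columns are scored per run, not per column")


Column = tuple[str, str, PairType]  # (miRNA base or '-', target base or '-', type)


@dataclass
class DuplexAlignment:
    """One local miRNA:target duplex.

    ``columns`` run 5'->3' along the miRNA; target bases within them run
    3'->5', i.e. their gap-free concatenation is the reverse of the
    forward-strand site ``target_seq[target_span[0]:target_span[1]]``.
    ``mirna_span`` is the 0-based half-open interval of the miRNA covered.
    """

    mirna_id: str
    target_id: str
    window_start: int
    columns: list[Column]
    score: int
    target_span: tuple[int, int]
    mirna_span: tuple[int, int]

    @property
    def n_pairs(self) -> int:
        return sum(c[2] in (PairType.WC, PairType.WOBBLE) for c in self.columns)

    def mirna_positions(self) -> list[Optional[int]]:
        """1-based miRNA position of each column (None for gap-in-miRNA).

        Gap-in-miRNA columns have no position of their own; callers that need
        a region attribution for them use the last consumed miRNA position
        (see :func:`mirtarget.site_classes.region_counts`).
        """
        pos = self.mirna_span[0]  # 0-based index of next miRNA base
        out: list[Optional[int]] = []
        for mb, _tb, _pt in self.columns:
            if mb == GAP:
                out.append(None)
            else:
                pos += 1
                out.append(pos)  # now 1-based
        return out


@dataclass
class CandidateSite:
    alignment: DuplexAlignment
    target_class: TargetClass = TargetClass.NONE
    seed_counts: object = None
    nonseed_counts: object = None

    @property
    def target_span(self) -> tuple[int, int]:
        return self.alignment.target_span

    @property
    def score(self) -> int:
        return self.alignment.score


def windows(
    target: RnaSequence, mirna_length: int, step: int = 1
) -> Iterator[tuple[int, str]]:
    """Yield ``(start, subsequence)`` scan windows of length miRNA + 10.

    Windows start at 0 and advance by ``step``; trailing windows are truncated
    but never shorter than the miRNA. A target shorter than the miRNA yields
    nothing (with a warning).
    """
    if step < 1:
        raise ValueError("step must be >= 1")
    tlen = len(target)
    if tlen < mirna_length:
        warnings.warn(
            f"target {target.id!r} (length {tlen}) is shorter than the "
            f"miRNA (length {mirna_length}); no windows generated",
            stacklevel=2,
        )
        return
    wlen = mirna_length + WINDOW_MARGIN
    for start in range(0, tlen - mirna_length + 1, step):
        yield start, target.seq[start : start + wlen]


# DP states / traceback codes
_STOP, _M, _X, _Y = 0, 1, 2, 3  # X: gap in target row; Y: gap in miRNA row

_NEG = float("-inf")


def align_duplex(
    mirna: RnaSequence,
    window: RnaSequence | str,
    scheme: ScoringScheme = ScoringScheme(),
    *,
    window_start: int = 0,
    target_id: str = "",
) -> DuplexAlignment:
    """Best local alignment of the miRNA (5'->3') against the reversed window.

    Ties in the traceback prefer a paired (diagonal) column over a gap in the
    target over a gap in the miRNA, so output is deterministic.
    """
    a = mirna.seq
    b_fwd = window.seq if isinstance(window, RnaSequence) else window
    if not a or not b_fwd:
        raise ValueError("both sequences must be non-empty")
    b = b_fwd[::-1]
    m, n = len(a), len(b)
    go, ge = scheme.gap_open, scheme.gap_extend

    # score matrices, row-major (m+1) x (n+1); pointer matrices hold the
    # predecessor state of each cell
    M = [[_NEG] * (n + 1) for _ in range(m + 1)]
    X = [[_NEG] * (n + 1) for _ in range(m + 1)]
    Y = [[_NEG] * (n + 1) for _ in range(m + 1)]
    Mp = [[_STOP] * (n + 1) for _ in range(m + 1)]
    Xp = [[_STOP] * (n + 1) for _ in range(m + 1)]
    Yp = [[_STOP] * (n + 1) for _ in range(m + 1)]

    best, bi, bj = 0, 0, 0
    for i in range(1, m + 1):
        ai = a[i - 1]
        Mi, Xi, Yi = M[i], X[i], Y[i]
        Mu, Xu, Yu = M[i - 1], X[i - 1], Y[i - 1]
        Mpi, Xpi, Ypi = Mp[i], Xp[i], Yp[i]
        for j in range(1, n + 1):
            sub = scheme.column(pair_type(ai, b[j - 1]))
            # paired column: best predecessor, start preferred on ties so a
            # zero-score prefix is trimmed
            pm, px, py = Mu[j - 1], Xu[j - 1], Yu[j - 1]
            val, ptr = 0, _STOP
            if pm > val:
                val, ptr = pm, _M
            if px > val:
                val, ptr = px, _X
            if py > val:
                val, ptr = py, _Y
            Mi[j] = val + sub
            Mpi[j] = ptr
            # gap in target (consumes miRNA base i)
            vo_m, vo_y, ve = Mu[j] + go, Yu[j] + go, Xu[j] + ge
            val, ptr = vo_m, _M
            if ve > val:
                val, ptr = ve, _X
            if vo_y > val:
                val, ptr = vo_y, _Y
            Xi[j] = val
            Xpi[j] = ptr
            # gap in miRNA (consumes window base j)
            vo_m, vo_x, ve = Mi[j - 1] + go, Xi[j - 1] + go, Yi[j - 1] + ge
            val, ptr = vo_m, _M
            if vo_x > val:
                val, ptr = vo_x, _X
            if ve > val:
                val, ptr = ve, _Y
            Yi[j] = val
            Ypi[j] = ptr
            if Mi[j] > best:
                best, bi, bj = Mi[j], i, j

    if best <= 0:
        # no positive-scoring duplex: empty alignment at the local floor
        return DuplexAlignment(
            mirna.id, target_id, window_start, [], 0,
            (window_start + n, window_start + n), (0, 0),
        )

    # traceback from the best paired cell
    cols: list[Column] = []
    i, j, state = bi, bj, _M
    while state != _STOP:
        if state == _M:
            mb, tb = a[i - 1], b[j - 1]
            cols.append((mb, tb, pair_type(mb, tb)))
            state = Mp[i][j]
            i, j = i - 1, j - 1
        elif state == _X:
            cols.append((a[i - 1], GAP, PairType.GAP_TARGET))
            state = Xp[i][j]
            i -= 1
        else:  # _Y
            cols.append((GAP, b[j - 1], PairType.GAP_MIRNA))
            state = Yp[i][j]
            j -= 1
    cols.reverse()
    i0, i1 = i, bi          # miRNA coverage, 0-based half-open
    j0, j1 = j, bj          # coverage on the reversed window
    fwd = (window_start + n - j1, window_start + n - j0)
    return DuplexAlignment(mirna.id, target_id, window_start, cols, best, fwd, (i0, i1))


def score_alignment(columns: list[Column], scheme: ScoringScheme = ScoringScheme()) -> int:
    """Re-score alignment columns, charging gap runs open + (k-1)*extend.

    A run is a maximal stretch of consecutive gap columns on the same strand;
    switching strands opens a new run, matching the DP transitions.
    """
    total = 0
    prev_gap: Optional[PairType] = None
    for _mb, _tb, pt in columns:
        if pt in (PairType.GAP_MIRNA, PairType.GAP_TARGET):
            total += scheme.gap_extend if pt is prev_gap else scheme.gap_open
            prev_gap = pt
        else:
            total += scheme.column(pt)
            prev_gap = None
    return total


_CLASS_PRIORITY = {
    TargetClass.SEED_ONLY: 0,
    TargetClass.DOMINANT: 1,
    TargetClass.CANONICAL: 2,
    TargetClass.NONE: 3,
}


def filter_overlaps(sites: list[CandidateSite]) -> list[CandidateSite]:
    """Keep a maximal-score set of pairwise disjoint target spans.

    Among overlapping candidates the highest alignment score survives; ties
    break by leftmost start, then by class priority (seed-only > dominant >
    canonical). Output is sorted by target start.
    """
    ranked = sorted(
        sites,
        key=lambda s: (
            -s.score,
            s.target_span[0],
            _CLASS_PRIORITY[s.target_class],
            s.target_span[1],
        ),
    )
    kept: list[CandidateSite] = []
    for cand in ranked:
        s0, s1 = cand.target_span
        if all(s1 <= k.target_span[0] or s0 >= k.target_span[1] for k in kept):
            kept.append(cand)
    kept.sort(key=lambda s: s.target_span)
    return kept
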