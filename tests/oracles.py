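"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's dynamic-programming code paths: the
alignment oracle enumerates gapped local alignments as monotone lattice
paths, and the folding oracle enumerates every non-crossing pairing.
"""

from __future__ import annotations

_COMP = {"A": "U", "U": "A", "G": "C", "C": "G"}
_WOBBLE = {("G", "U"), ("U", "G")}


def _col_score(x: str, y: str, wc=5, gu=1, mm=-3) -> int:
    if _COMP[x] == y:
        return wc
    if (x, y) in _WOBBLE:
        return gu
    return mm


def brute_force_local_score(a: str, b: str, wc=5, gu=1, mm=-3, go=-8, ge=-2) -> int:
    """Best gapped local alignment score of a vs b by exhaustive path search.

    Every monotone path through the (len(a)+1) x (len(b)+1) lattice, from
    every start cell, is walked move by move with the running affine score
    (first gap column of a run scores ``go``, later ones ``ge``, a run ends
    when the gapped strand changes); the maximum over all path prefixes is
    the local alignment optimum (empty alignment floor 0).
    """
    m, n = len(a), len(b)
    best = 0

    def walk(i: int, j: int, score: int, last: int) -> None:
        # last: 0 = paired column, 1 = gap in b's strand, 2 = gap in a's strand
        nonlocal best
        if score > best:
            best = score
        if i < m and j < n:
            walk(i + 1, j + 1, score + _col_score(a[i], b[j]), 0)
        if i < m:
            walk(i + 1, j, score + (ge if last == 1 else go), 1)
        if j < n:
            walk(i, j + 1, score + (ge if last == 2 else go), 2)

    for i in range(m):
        for j in range(n):
            walk(i, j, 0, 0)
    return best


_PAIR_E = {
    frozenset(("G", "C")): -3.0,
    frozenset(("A", "U")): -2.0,
    frozenset(("G", "U")): -1.0,
}


def enumerate_fold_energy(seq: str, min_loop: int = 3) -> float:
    """Minimum energy over every valid non-crossing pairing (full enumeration).

    Only use at len(seq) <= ~12; complexity grows fast.
    """

    def rec(positions: tuple[int, ...]) -> float:
        if not positions:
            return 0.0
        first, rest = positions[0], positions[1:]
        best = rec(rest)  # first unpaired
        for idx, k in enumerate(rest):
            if k - first <= min_loop:
                continue
            e = _PAIR_E.get(frozenset((seq[first], seq[k])))
            if e is None:
                continue
            inside = tuple(p for p in rest[:idx] if first < p < k)
            outside = tuple(p for p in rest[idx + 1 :])
            best = min(best, e + rec(inside) + rec(outside))
        return best

    return rec(tuple(range(len(seq))))
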