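"""Thermodynamic duplex features through a pluggable energy backend.

Two backends provide the four energy features (site folding free energy,
duplex hybridization energy, normalized free energy, and the hybridization
energy gap to the perfect duplex):

* ``fallback`` — a self-contained per-pair energy model: G:C -3.0, A:U -2.0,
  G:U -1.0 kcal/mol. Folding maximises total pairing energy over non-crossing
  pairs with a minimum hairpin loop of 3 nt (Nussinov-style DP); duplex energy
  sums pair energies over the fixed alignment columns. It is a deliberately
  simple surrogate whose scale differs from a nearest-neighbor model, but it
  is deterministic, exactly testable, and monotone in duplex stability.
* ``external`` — adapter around RNAfold / RNAcofold executables; parses the
  minimum free energy from the trailing "structure (energy)" line. Never
  silently falls back: an unavailable executable raises.
"""

from __future__ import annotations

import math
import shutil
import subprocess
from dataclasses import dataclass

from .seq_io import GAP, PairType, RnaSequence, complement

#: fallback stacking-free pair energies, kcal/mol
PAIR_ENERGY = {
    frozenset(("G", "C")): -3.0,
    frozenset(("A", "U")): -2.0,
    frozenset(("G", "U")): -1.0,
}
MIN_LOOP = 3  # minimum unpaired nucleotides enclosed by a fold pair


class BackendUnavailableError(RuntimeError):
    """The requested external folding executable cannot be run."""


def pair_energy(x: str, y: str) -> float:
    return PAIR_ENERGY.get(frozenset((x, y)), 0.0)


class FallbackBackend:
    """Built-in per-pair energy model; see module docstring."""

    name = "fallback"

    def fold(self, seq: RnaSequence | str) -> float:
        """Minimum (most negative) folding energy over non-crossing pairings.

        DP over subsequences: E(i,j) = min(E(i+1,j), min over k of
        e(i,k) + E(i+1,k-1) + E(k+1,j)) with the loop constraint k-i-1 >= 3.
        """
        s = seq.seq if isinstance(seq, RnaSequence) else seq
        n = len(s)
        if n == 0:
            raise ValueError("cannot fold an empty sequence")
        E = [[0.0] * n for _ in range(n)]
        for span in range(MIN_LOOP + 1, n):
            for i in range(0, n - span):
                j = i + span
                best = E[i + 1][j] if i + 1 <= j else 0.0
                for k in range(i + MIN_LOOP + 1, j + 1):
                    e = pair_energy(s[i], s[k])
                    if e == 0.0:
                        continue
                    inner = E[i + 1][k - 1] if i + 1 <= k - 1 else 0.0
                    outer = E[k + 1][j] if k + 1 <= j else 0.0
                    cand = e + inner + outer
                    if cand < best:
                        best = cand
                E[i][j] = best
        return E[0][n - 1]

    def duplex(self, aln) -> float:
        """Hybridization energy of the fixed duplex: per-column pair sums."""
        total = 0.0
        for mb, tb, pt in aln.columns:
            if pt in (PairType.WC, PairType.WOBBLE):
                total += pair_energy(mb, tb)
        return total

    def perfect_duplex(self, mirna: RnaSequence) -> float:
        """Energy of the miRNA paired to its full reverse complement."""
        return sum(pair_energy(b, complement(b)) for b in mirna.seq)


class ExternalBackend:
    """RNAfold/RNAcofold subprocess adapter (Vienna-style output contract)."""

    name = "external"

    def __init__(self, fold_exe: str = "RNAfold", cofold_exe: str = "RNAcofold"):
        self.fold_exe = fold_exe
        self.cofold_exe = cofold_exe

    def _run(self, exe: str, seq: str) -> float:
        if shutil.which(exe) is None:
            raise BackendUnavailableError(
                f"{exe!r} not found on PATH; use the fallback backend explicitly "
                "if no external folding tool is installed"
            )
        proc = subprocess.run(
            [exe, "--noPS"], input=seq + "\n", capture_output=True, text=True
        )
        if proc.returncode != 0:
            raise BackendUnavailableError(f"{exe} failed: {proc.stderr.strip()}")
        return _parse_mfe(proc.stdout, exe)

    def fold(self, seq: RnaSequence | str) -> float:
        s = seq.seq if isinstance(seq, RnaSequence) else seq
        return self._run(self.fold_exe, s)

    def duplex(self, aln) -> float:
        mirna = "".join(mb for mb, _t, _p in aln.columns if mb != GAP)
        site_rev = "".join(tb for _m, tb, _p in aln.columns if tb != GAP)
        # columns carry the site 3'->5'; cofold wants both strands 5'->3'
        return self._run(self.cofold_exe, f"{mirna}&{site_rev[::-1]}")

    def perfect_duplex(self, mirna: RnaSequence) -> float:
        rc = "".join(complement(b) for b in reversed(mirna.seq))
        return self._run(self.cofold_exe, f"{mirna.seq}&{rc}")


def _parse_mfe(stdout: str, exe: str) -> float:
    """Extract the parenthesised kcal/mol value from a fold-tool stdout."""
    for line in reversed(stdout.strip().splitlines()):
        if "(" in line and line.rstrip().endswith(")"):
            inner = line[line.rfind("(") + 1 : line.rfind(")")].strip()
            try:
                return float(inner)
            except ValueError:
                continue
    raise BackendUnavailableError(f"could not parse MFE from {exe} output:\n{stdout}")


def get_backend(name: str) -> FallbackBackend | ExternalBackend:
    if name == "fallback":
        return FallbackBackend()
    if name == "external":
        return ExternalBackend()
    raise ValueError(f"unknown energy backend {name!r}")


def normalized_free_energy(free_energy: float, target_len: int, mirna_len: int) -> float:
    """NFE = (-free energy) / ln(target length x miRNA length)."""
    product = target_len * mirna_len
    if product <= 1:
        raise ValueError("target_len * mirna_len must exceed 1")
    return (-1.0 * free_energy) / math.log(product)


def delta_hybridization_energy(mirna: RnaSequence, aln, backend) -> float:
    """Observed duplex energy minus the perfect-target duplex energy.

    Non-negative under the fallback model (the reverse complement is its
    optimum); sign under an external backend follows the same convention.
    """
    return backend.duplex(aln) - backend.perfect_duplex(mirna)


@dataclass(frozen=True)
class ThermoFeatures:
    free_energy: float
    hybridization_energy: float
    normalized_free_energy: float
    delta_hybridization_energy: float


def compute_thermo_features(aln, mirna: RnaSequence, site_seq: str, backend) -> ThermoFeatures:
    """The four energy features for one classified candidate.

    ``site_seq`` is the forward-strand target-site subsequence (the aligned
    span); the site, not the whole transcript, is folded so that the feature
    stays on the scale of the duplex.
    """
    fe = backend.fold(site_seq)
    hyb = backend.duplex(aln)
    nfe = normalized_free_energy(fe, len(site_seq), len(mirna))
    delta = hyb - backend.perfect_duplex(mirna)
    return ThermoFeatures(fe, hyb, nfe, delta)
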