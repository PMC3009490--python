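"""RNA sequence I/O and base-pair typing.

Sequences are held as validated RNA strings (A/C/G/U). DNA input is accepted
and T is silently converted to U, because public 3'UTR FASTA is usually DNA.
The gap symbol used in duplex alignments is ``-`` throughout the package.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from Bio import SeqIO

GAP = "-"

#: sentinel an ambiguity code is mapped to under the lenient alphabet policy;
#: it never pairs, so any column containing it types as MISMATCH.
AMBIGUOUS = "N"

_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G", AMBIGUOUS: AMBIGUOUS}
_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "U"), ("U", "G")}


class AlphabetError(ValueError):
    """A sequence contains a character outside the RNA alphabet."""


class FastaParseError(ValueError):
    """The input file is not parseable as FASTA."""


class PairType(enum.Enum):
    """Classification of one duplex alignment column."""

    WC = "WC"                  # Watson-Crick: A:U or G:C
    WOBBLE = "WOBBLE"          # G:U wobble
    MISMATCH = "MISMATCH"      # any other base-base column
    GAP_MIRNA = "GAP_MIRNA"    # gap on the miRNA strand (target base unpaired)
    GAP_TARGET = "GAP_TARGET"  # gap on the target strand (miRNA base unpaired)


@dataclass(frozen=True)
class RnaSequence:
    """A named RNA sequence over {A, C, G, U} (plus N under lenient policy)."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.seq:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(self.seq) - set("ACGU" + AMBIGUOUS)
        if bad:
            raise AlphabetError(
                f"sequence {self.id!r} contains non-RNA characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


def normalize(raw: str, *, record_id: str = "?", policy: str = "strict") -> str:
    """Uppercase, convert T to U and apply the alphabet policy.

    ``policy='strict'`` rejects anything outside A/C/G/U(/T); ``'lenient'``
    maps every other IUPAC letter to the :data:`AMBIGUOUS` sentinel.
    """
    if policy not in ("strict", "lenient"):
        raise ValueError(f"unknown alphabet policy {policy!r}")
    out = []
    for pos, ch in enumerate(raw.upper().replace("T", "U"), start=1):
        if ch in "ACGU":
            out.append(ch)
        elif policy == "lenient" and ch.isalpha():
            out.append(AMBIGUOUS)
        else:
            raise AlphabetError(
                f"record {record_id!r}: disallowed character {ch!r} at position {pos}"
            )
    return "".join(out)


def read_fasta(path, *, policy: str = "strict") -> list[RnaSequence]:
    """Read a (multi-)FASTA file into validated RNA sequences, order preserved.

    Raises :class:`FastaParseError` for malformed input, :class:`AlphabetError`
    for disallowed characters under the strict policy, and ``ValueError`` for
    duplicate record ids.
    """
    records = []
    seen: set[str] = set()
    try:
        parsed = list(SeqIO.parse(str(path), "fasta"))
    except Exception as exc:  # Bio raises bare ValueError with line context
        raise FastaParseError(f"{path}: {exc}") from exc
    if not parsed:
        raise FastaParseError(f"{path}: no FASTA records found")
    for rec in parsed:
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        records.append(
            RnaSequence(rec.id, normalize(str(rec.seq), record_id=rec.id, policy=policy))
        )
    return records


def write_fasta(seqs, path, *, width: int = 70) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n")
            for i in range(0, len(s.seq), width):
                fh.write(s.seq[i : i + width] + "\n")


def complement(base: str) -> str:
    try:
        return _COMPLEMENT[base]
    except KeyError:
        raise AlphabetError(f"cannot complement {base!r}") from None


def reverse_complement(s: RnaSequence) -> RnaSequence:
    """RNA reverse complement (A<->U, G<->C), id suffixed with ``_rc``."""
    return RnaSequence(s.id + "_rc", "".join(complement(b) for b in reversed(s.seq)))


def pair_type(mirna_base: str, target_base: str) -> PairType:
    """Classify one alignment column; raises on the invalid both-gap column."""
    if mirna_base == GAP and target_base == GAP:
        raise ValueError("invalid alignment column: gap on both strands")
    if mirna_base == GAP:
        return PairType.GAP_MIRNA
    if target_base == GAP:
        return PairType.GAP_TARGET
    pair = (mirna_base, target_base)
    if pair in _WC:
        return PairType.WC
    if pair in _WOBBLE:
        return PairType.WOBBLE
    return PairType.MISMATCH
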