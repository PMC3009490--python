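"""End-to-end site prediction: scan -> classify -> featurize -> verify.

For each (miRNA, target) pair the target is scanned with stride-1 windows of
length miRNA + 10; every window alignment with at least 4 base-paired columns
and a fully covered seed is classified; NONE candidates are dropped;
overlapping candidates are reduced to the best-scoring disjoint set; each
surviving site gets its 16-feature vector and is scored by the neural network
of its class. The optional minimum-free-energy cutoff (default -17.0
kcal/mol) is applied to the hybridization energy after the network, and only
when the external folding backend is active — the fallback model's energy
scale is its own, so a cutoff calibrated for folding-tool output would be
meaningless there.

Coordinates are 0-based half-open on the input target throughout; the GFF3
writer converts to 1-based inclusive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import yaml

from .align import (
    CANDIDATE_MIN_PAIRS,
    CandidateSite,
    DuplexAlignment,
    ScoringScheme,
    align_duplex,
    filter_overlaps,
    windows,
)
from .ann import DEFAULT_THRESHOLD, MlpModel, predict
from .features import FEATURE_NAMES, FeatureVector, assemble_feature_vector
from .seq_io import PairType, RnaSequence
from .site_classes import SeedDefinition, TargetClass, classify_alignment
from .thermo import compute_thermo_features, get_backend

log = logging.getLogger("mirtarget")

DEFAULT_MFE_CUTOFF = -17.0


@dataclass(frozen=True)
class PipelineConfig:
    seed_def: SeedDefinition = SeedDefinition()
    scheme: ScoringScheme = ScoringScheme()
    backend: str = "fallback"
    #: hybridization-energy cutoff, kcal/mol; only enforced with the
    #: external backend unless force_mfe_cutoff is set
    mfe_cutoff: float = DEFAULT_MFE_CUTOFF
    force_mfe_cutoff: bool = False
    threshold: float = DEFAULT_THRESHOLD
    step: int = 1
    min_pairs: int = CANDIDATE_MIN_PAIRS
    rng_seed: int = 0

    @property
    def cutoff_active(self) -> bool:
        return self.backend == "external" or self.force_mfe_cutoff

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        if "seed_def" in raw:
            kwargs["seed_def"] = SeedDefinition.parse(str(raw.pop("seed_def")))
        if "scheme" in raw:
            kwargs["scheme"] = ScoringScheme(**raw.pop("scheme"))
        kwargs.update(raw)
        kwargs.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**kwargs)


@dataclass
class PredictionRecord:
    mirna_id: str
    target_id: str
    start: int            # 0-based half-open on the target
    end: int
    target_class: TargetClass
    alignment_score: int
    features: FeatureVector
    ann_score: float
    verdict: bool
    alignment_text: str = ""

    TSV_COLUMNS = (
        "mirna_id", "target_id", "start", "end", "target_class",
        "alignment_score", "ann_score", "verdict", *FEATURE_NAMES,
    )

    def tsv_row(self) -> str:
        vals = [
            self.mirna_id, self.target_id, str(self.start), str(self.end),
            self.target_class.value, str(self.alignment_score),
            f"{self.ann_score:.6f}", str(int(self.verdict)),
        ]
        vals += [repr(float(v)) for v in self.features.as_tuple()]
        return "\t".join(vals)

    @classmethod
    def from_tsv_row(cls, line: str) -> "PredictionRecord":
        parts = line.rstrip("\n").split("\t")
        return cls(
            mirna_id=parts[0], target_id=parts[1],
            start=int(parts[2]), end=int(parts[3]),
            target_class=TargetClass(parts[4]),
            alignment_score=int(parts[5]),
            ann_score=float(parts[6]),
            verdict=bool(int(parts[7])),
            features=FeatureVector.from_iterable(parts[8:24]),
        )


def _render_alignment(aln: DuplexAlignment) -> str:
    """Three-line duplex rendering: miRNA 5'->3', pairing line, site 3'->5'."""
    mline = "".join(c[0] for c in aln.columns)
    tline = "".join(c[1] for c in aln.columns)
    marks = {PairType.WC: "|", PairType.WOBBLE: ":", PairType.MISMATCH: " "}
    pline = "".join(marks.get(c[2], " ") for c in aln.columns)
    return f"miRNA  5' {mline} 3'\n          {pline}\ntarget 3' {tline} 5'"


def candidate_sites(
    mirna: RnaSequence,
    target: RnaSequence,
    cfg: PipelineConfig = PipelineConfig(),
) -> list[CandidateSite]:
    """Classified, overlap-filtered candidates for one (miRNA, target) pair.

    This is the pre-verification stage: every window alignment with at least
    ``cfg.min_pairs`` base pairs and a class other than NONE survives into
    the disjoint best-scoring set.
    """
    best_by_span: dict[tuple[int, int], CandidateSite] = {}
    for start, window in windows(target, len(mirna.seq), cfg.step):
        aln = align_duplex(
            mirna, window, cfg.scheme, window_start=start, target_id=target.id
        )
        if aln.n_pairs < cfg.min_pairs:
            continue
        cls, seed_rc, non_rc = classify_alignment(aln, cfg.seed_def)
        if cls is TargetClass.NONE:
            continue
        key = aln.target_span
        prev = best_by_span.get(key)
        if prev is None or aln.score > prev.score:
            best_by_span[key] = CandidateSite(aln, cls, seed_rc, non_rc)
    sites = filter_overlaps(list(best_by_span.values()))
    log.debug(
        "%s vs %s: %d distinct candidate spans, %d after overlap filter",
        mirna.id, target.id, len(best_by_span), len(sites),
    )
    return sites


def scan(
    mirnas: list[RnaSequence],
    targets: list[RnaSequence],
    models: dict[TargetClass, MlpModel],
    cfg: PipelineConfig = PipelineConfig(),
    pairs: list[tuple[str, str]] | None = None,
) -> list[PredictionRecord]:
    """Predict target sites for every (miRNA, target) combination.

    ``pairs`` restricts the scan to the listed (miRNA id, target id)
    combinations; by default the full cross-product is scanned. All
    classified sites are reported; ``verdict`` marks the ones the class
    network accepts (and, when active, that pass the energy cutoff).
    """
    for cls in (TargetClass.SEED_ONLY, TargetClass.DOMINANT, TargetClass.CANONICAL):
        if cls not in models:
            raise ValueError(f"missing model for class {cls.value}")
    backend = get_backend(cfg.backend)
    mirna_by_id = {m.id: m for m in mirnas}
    target_by_id = {t.id: t for t in targets}
    if pairs is None:
        pair_list = [(m.id, t.id) for m in mirnas for t in targets]
    else:
        for mid, tid in pairs:
            if mid not in mirna_by_id:
                raise ValueError(f"pair references unknown miRNA {mid!r}")
            if tid not in target_by_id:
                raise ValueError(f"pair references unknown target {tid!r}")
        pair_list = list(pairs)

    records: list[PredictionRecord] = []
    for mid, tid in pair_list:
        mirna, target = mirna_by_id[mid], target_by_id[tid]
        if len(target.seq) < len(mirna.seq):
            continue
        for site in candidate_sites(mirna, target, cfg):
            aln = site.alignment
            s0, s1 = aln.target_span
            site_seq = target.seq[s0:s1]
            energies = compute_thermo_features(aln, mirna, site_seq, backend)
            fv = assemble_feature_vector(aln, site_seq, energies, len(mirna.seq), cfg.seed_def)
            score, accept = predict(models[site.target_class], fv)
            if cfg.threshold != models[site.target_class].threshold:
                accept = score >= cfg.threshold
            if cfg.cutoff_active and energies.hybridization_energy > cfg.mfe_cutoff:
                accept = False
            records.append(
                PredictionRecord(
                    mirna_id=mirna.id, target_id=target.id,
                    start=s0, end=s1, target_class=site.target_class,
                    alignment_score=aln.score, features=fv,
                    ann_score=score, verdict=accept,
                    alignment_text=_render_alignment(aln),
                )
            )
    records.sort(key=lambda r: (r.mirna_id, r.target_id, r.start))
    n_accepted = sum(r.verdict for r in records)
    log.info("scan: %d classified sites, %d verified", len(records), n_accepted)
    return records


# ---------------------------------------------------------------- reporting

def write_tsv(records: list[PredictionRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(PredictionRecord.TSV_COLUMNS) + "\n")
        for r in records:
            fh.write(r.tsv_row() + "\n")


def read_tsv(path) -> list[PredictionRecord]:
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != PredictionRecord.TSV_COLUMNS:
            raise ValueError(f"{path}: unexpected report header")
        for line in fh:
            out.append(PredictionRecord.from_tsv_row(line))
    return out


def _gff3_escape(text: str) -> str:
    out = []
    for ch in text:
        if ch in "%;=&,\t":
            out.append(f"%{ord(ch):02X}")
        else:
            out.append(ch)
    return "".join(out)


def write_gff3(records: list[PredictionRecord], path) -> None:
    """GFF3 report; internal 0-based half-open spans become 1-based inclusive."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for r in records:
            attrs = ";".join(
                [
                    f"ID={_gff3_escape(r.mirna_id)}:{_gff3_escape(r.target_id)}:{r.start}",
                    f"mirna={_gff3_escape(r.mirna_id)}",
                    f"target_class={_gff3_escape(r.target_class.report_label)}",
                    f"verdict={int(r.verdict)}",
                    f"alignment_score={r.alignment_score}",
                ]
            )
            fh.write(
                "\t".join(
                    [
                        r.target_id, "mirtarget", "miRNA_target_site",
                        str(r.start + 1), str(r.end), f"{r.ann_score:.4f}",
                        "+", ".", attrs,
                    ]
                )
                + "\n"
            )


def write_alignment_report(records: list[PredictionRecord], path) -> None:
    """Human-readable per-site report with the rendered duplex."""
    with open(path, "w") as fh:
        fh.write("# deviations are perfect-target score minus observed score\n")
        for r in records:
            fh.write(
                f"## {r.mirna_id} -> {r.target_id} [{r.start},{r.end}) "
                f"{r.target_class.report_label} S={r.alignment_score} "
                f"ann={r.ann_score:.4f} verdict={'yes' if r.verdict else 'no'}\n"
            )
            if r.alignment_text:
                fh.write(r.alignment_text + "\n")
            fh.write("\n")


def report(records: list[PredictionRecord], prefix, formats=("tsv",)) -> list[Path]:
    """Write the requested report files next to ``prefix``."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    written = []
    if "tsv" in formats:
        p = prefix.with_suffix(".tsv")
        write_tsv(records, p)
        written.append(p)
    if "gff3" in formats:
        p = prefix.with_suffix(".gff3")
        write_gff3(records, p)
        written.append(p)
    if "txt" in formats:
        p = prefix.with_suffix(".txt")
        write_alignment_report(records, p)
        written.append(p)
    return written


def verify_record(record: PredictionRecord, mirna: RnaSequence, target: RnaSequence,
                  cfg: PipelineConfig = PipelineConfig()) -> bool:
    """Re-extract the reported span and check it reproduces score and class."""
    window = target.seq[record.start : record.end]
    aln = align_duplex(mirna, RnaSequence(target.id, window), cfg.scheme,
                       window_start=record.start, target_id=target.id)
    cls, _s, _n = classify_alignment(aln, cfg.seed_def)
    return aln.score == record.alignment_score and cls is record.target_class
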