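"""End-to-end orchestration, quality tiers, and run configuration.

`run_pipeline` exercises the whole toolkit on a synthetic two-lineage
community: genome generation → partial assemblies → per-assembly QC →
cross-lineage chimera benchmark → read simulation and fragment recruitment.
Every run writes its resolved configuration next to the results so a bundle
can be reproduced byte-for-byte from the written config.

Per-assembly QC reports use truth-based marker detection (threshold 0), so
completeness reflects actual genome recovery; the detection-threshold
blindness is quantified separately by the chimera benchmark, which is its
subject.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

from sagqc._version import __version__ as _version
from sagqc.chimera import default_benchmark_assemblies, run_benchmark
from sagqc.markers import MarkerSet, qc_report, write_qc_reports
from sagqc.recruitment import (
    AlignmentRecord,
    abundance_report,
    write_abundance_reports,
)
from sagqc.synthetic import (
    Gene,
    ParameterError,
    simulate_reads,
    write_fastq,
)

__all__ = [
    "QualityTier",
    "RunConfig",
    "assign_quality_tier",
    "run_pipeline",
    "read_gene_table",
]


@dataclass(frozen=True)
class QualityTier:
    tier: str  # high | medium | low | NA
    completeness_percent: float
    contamination_percent: float
    has_16s: bool


def assign_quality_tier(completeness: float, contamination: float,
                        has_16s: bool) -> QualityTier:
    """Community-standard draft-genome tiers.

    high: completeness > 90, contamination < 5, rRNA present;
    medium: completeness >= 50, contamination < 10;
    NA: contamination > 100 (the marker statistic no longer describes a
    single genome); low otherwise.
    """
    if not 0.0 <= completeness <= 100.0 or contamination < 0.0:
        raise ParameterError("invalid completeness/contamination")
    if contamination > 100.0:
        tier = "NA"
    elif completeness > 90.0 and contamination < 5.0 and has_16s:
        tier = "high"
    elif completeness >= 50.0 and contamination < 10.0:
        tier = "medium"
    else:
        tier = "low"
    return QualityTier(tier, completeness, contamination, has_16s)


# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Resolved parameters of one synthetic end-to-end run."""

    seed: int = 1
    output_dir: str = "sagqc_run"
    # community
    genome_size_bp: int = 1_000_000
    n_markers: int = 100
    n_accessory_genes: int = 400
    gene_length_bp: int = 900
    gc_a: float = 0.66
    gc_b: float = 0.70
    divergence_b: float = 0.35
    within_lineage_divergence: float = 0.0
    # assemblies
    n_a: int = 15
    n_b: int = 4
    recovery_a: list[float] | None = None
    recovery_b: list[float] | None = None
    fragmentation: int = 5
    # thresholds
    detection_identity_threshold: float = 0.70
    # recruitment
    n_reads: int = 2000
    read_length: int = 150
    on_target_read_divergence: float = 0.05
    off_target_read_divergence: float = 0.20
    min_overlap_bp: int = 100
    min_recruit_identity: float = 0.90

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        data = (json.loads(text) if str(path).endswith(".json")
                else yaml.safe_load(text))
        return cls.from_dict(data)


def _truth_alignments(reads, contigs: dict[str, str], reference_id: str,
                      read_length: int) -> list[AlignmentRecord]:
    """Score each simulated read against its known origin (substitution-only
    reads: identity is the per-site match fraction)."""
    records = []
    for r in reads:
        origin = contigs[r.source_contig][r.start:r.start + read_length]
        matches = sum(a == b for a, b in zip(r.sequence, origin))
        records.append(AlignmentRecord(
            read_id=r.read_id,
            reference_id=reference_id,
            overlap_bp=read_length,
            identity=matches / read_length,
        ))
    return records


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full synthetic benchmark; returns a result bundle dict
    and writes TSV/JSON reports plus the resolved config under
    config.output_dir. Deterministic under a fixed seed."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "resolved_config.yaml")

    try:
        group_a, group_b, marker_db = default_benchmark_assemblies(
            config.seed,
            n_a=config.n_a,
            n_b=config.n_b,
            recovery_a=config.recovery_a,
            recovery_b=config.recovery_b,
            divergence_b=config.divergence_b,
            detection_identity_threshold=config.detection_identity_threshold,
            n_markers=config.n_markers,
            genome_size_bp=config.genome_size_bp,
            n_accessory_genes=config.n_accessory_genes,
            gene_length_bp=config.gene_length_bp,
            fragmentation=config.fragmentation,
            materialize_sequence=True,
        )
    except Exception as exc:
        raise RuntimeError(f"[generate] {exc}") from exc

    try:
        truth_db = MarkerSet(marker_db.set_id, marker_db.families,
                             detection_identity_threshold=0.0)
        reports = [qc_report(a, truth_db) for a in group_a + group_b]
        tiers = {
            rep.assembly_id: assign_quality_tier(
                rep.completeness_percent, rep.contamination_percent, True).tier
            for rep in reports
        }
        write_qc_reports(reports, out / "qc_reports.tsv", out / "qc_reports.json")
    except Exception as exc:
        raise RuntimeError(f"[qc] {exc}") from exc

    try:
        summary, per_pair = run_benchmark(group_a, group_b, marker_db,
                                          output_dir=out)
    except Exception as exc:
        raise RuntimeError(f"[chimera] {exc}") from exc

    try:
        # recruitment: reads from the target population at low divergence
        # vs. reads from a diverged relative population of the same
        # reference, scored against their genomic origin
        ref = max(group_a, key=lambda a: a.total_length)
        contigs = {f.fragment_id: f.sequence for f in ref.fragments}
        on_reads = simulate_reads(ref, config.n_reads, config.read_length,
                                  config.on_target_read_divergence, config.seed)
        off_reads = simulate_reads(ref, config.n_reads, config.read_length,
                                   config.off_target_read_divergence,
                                   config.seed + 1)
        write_fastq(on_reads + off_reads, out / "reads.fastq")
        records = _truth_alignments(on_reads + off_reads, contigs,
                                    ref.assembly_id, config.read_length)
        total = len(on_reads) + len(off_reads)
        report = abundance_report(
            records, ref.assembly_id, ref.total_length, total,
            config.min_overlap_bp, config.min_recruit_identity)
        write_abundance_reports([report], out / "abundance.tsv")
    except Exception as exc:
        raise RuntimeError(f"[recruitment] {exc}") from exc

    bundle = {
        "version": _version,
        "seed": config.seed,
        "n_assemblies": len(group_a) + len(group_b),
        "quality_tiers": tiers,
        "qc_reports": [r.as_dict() for r in reports],
        "chimera_summary": summary.as_dict(),
        "abundance": report.as_dict(),
    }
    (out / "log.json").write_text(json.dumps(
        {"version": _version, "config": config.to_dict()}, indent=2) + "\n")
    (out / "bundle.json").write_text(json.dumps(bundle, indent=2) + "\n")
    return bundle


def read_gene_table(path: str | Path) -> list[Gene]:
    """Read a gene truth TSV (1-based inclusive) back to internal genes."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    genes = []
    for row in df.itertuples(index=False):
        genes.append(Gene(
            gene_id=str(row.gene_id),
            family_id=str(row.family_id),
            is_marker=bool(int(row.is_marker)),
            contig=str(row.contig),
            start=int(row.start) - 1,
            end=int(row.end),
            strand=str(row.strand),
            divergence=float(row.divergence),
            lineage_id=str(getattr(row, "lineage_id", "")),
        ))
    return genes
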