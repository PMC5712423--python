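"""Single-copy marker-gene QC: completeness, contamination, GC, genome size.

Completeness is the percent of marker families detected at least once;
contamination is the percent of excess copies, 100 x sum(max(0, count-1))
over the marker-set size. Predicted genome size is assembly size divided by
completeness, reported in Mbp at one decimal (half-away-from-zero) and NA
below 1% completeness, where the ratio is dominated by noise.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from importlib import resources
from pathlib import Path
from typing import Iterable

import pandas as pd

from sagqc.synthetic import (
    InputError,
    ParameterError,
    PartialAssembly,
    SyntheticGenome,
)

__all__ = [
    "MarkerSet",
    "MarkerHitTable",
    "QCReport",
    "detect_markers",
    "completeness",
    "contamination",
    "predict_genome_size",
    "gc_percent",
    "qc_report",
    "write_qc_reports",
    "load_published_assembly_stats",
]


@dataclass(frozen=True)
class MarkerSet:
    """An ordered set of single-copy marker families with a detection
    identity threshold (a gene counts as a marker hit only when its identity
    to the database family is >= the threshold)."""

    set_id: str
    families: tuple[str, ...]
    detection_identity_threshold: float = 0.70

    def __post_init__(self):
        if not self.families:
            raise ParameterError("marker set must be non-empty")
        if len(set(self.families)) != len(self.families):
            raise ParameterError("marker family ids must be unique")
        if not 0.0 <= self.detection_identity_threshold <= 1.0:
            raise ParameterError("detection_identity_threshold must be in [0,1]")

    def __len__(self) -> int:
        return len(self.families)


@dataclass
class MarkerHitTable:
    assembly_id: str
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        for fam, c in self.counts.items():
            if c < 0:
                raise InputError(f"negative copy count for {fam}")


@dataclass
class QCReport:
    assembly_id: str
    assembly_length_mbp: float
    gc_percent: float
    completeness_percent: float
    contamination_percent: float
    predicted_genome_size_mbp: float | None

    def as_dict(self) -> dict:
        return {
            "assembly_id": self.assembly_id,
            "assembly_length_mbp": self.assembly_length_mbp,
            "gc_percent": self.gc_percent,
            "completeness_percent": self.completeness_percent,
            "contamination_percent": self.contamination_percent,
            "predicted_genome_size_mbp": self.predicted_genome_size_mbp,
        }


# ---------------------------------------------------------------------------


def detect_markers(
    assembly: PartialAssembly | SyntheticGenome,
    marker_db: MarkerSet,
    hits: pd.DataFrame | str | Path | None = None,
) -> MarkerHitTable:
    """Count marker-family copies in an assembly.

    Truth mode (hits is None): uses the assembly's gene truth table; a
    marker gene is detected when its identity to the database family,
    1 - divergence, is >= the detection threshold.

    Hits mode: `hits` is a similarity-search table (TSV path or DataFrame
    with columns gene_id, family_id, identity, alignment_length, evalue);
    each gene contributes its best-identity hit, hits to families outside
    the marker set are skipped with a warning.
    """
    assembly_id = (assembly.genome_id if isinstance(assembly, SyntheticGenome)
                   else assembly.assembly_id)
    families = set(marker_db.families)
    thr = marker_db.detection_identity_threshold
    counts: dict[str, int] = {}

    if hits is None:
        genes = (assembly.gene_table if isinstance(assembly, SyntheticGenome)
                 else assembly.genes)
        if genes is None:
            raise InputError("truth mode requires a gene table on the assembly")
        for g in genes:
            if g.is_marker and g.family_id in families:
                if (1.0 - g.divergence) >= thr:
                    counts[g.family_id] = counts.get(g.family_id, 0) + 1
    else:
        if isinstance(hits, (str, Path)):
            hits = pd.read_csv(hits, sep="\t")
        required = {"gene_id", "family_id", "identity"}
        if not required.issubset(hits.columns):
            raise InputError(f"hit table must have columns {sorted(required)}")
        unknown = set(hits["family_id"]) - families
        if unknown:
            warnings.warn(
                f"skipping hits to {len(unknown)} unknown marker families",
                stacklevel=2,
            )
            hits = hits[hits["family_id"].isin(families)]
        # one hit per gene: keep its best identity
        best = hits.sort_values(["gene_id", "identity"]).groupby("gene_id").tail(1)
        best = best[best["identity"] >= thr]
        counts = best.groupby("family_id").size().to_dict()

    return MarkerHitTable(assembly_id=assembly_id, counts=counts)


def completeness(hits: MarkerHitTable, marker_db: MarkerSet) -> float:
    """Percent of marker families present at least once."""
    present = sum(1 for f in marker_db.families if hits.counts.get(f, 0) >= 1)
    return 100.0 * present / len(marker_db)


def contamination(hits: MarkerHitTable, marker_db: MarkerSet) -> float:
    """Percent of excess single-copy marker copies."""
    excess = sum(max(0, hits.counts.get(f, 0) - 1) for f in marker_db.families)
    return 100.0 * excess / len(marker_db)


def predict_genome_size(assembly_length_mbp: float,
                        completeness_percent: float) -> float | None:
    """Assembly size divided by completeness; one decimal, half-away-from-zero.

    Returns None (NA) below 1% completeness.
    """
    assembly_length_mbp = float(assembly_length_mbp)
    completeness_percent = float(completeness_percent)
    if assembly_length_mbp < 0:
        raise ParameterError("assembly_length_mbp must be >= 0")
    if not 0.0 <= completeness_percent <= 100.0:
        raise ParameterError("completeness_percent must be in [0,100]")
    if completeness_percent < 1.0:
        return None
    # exact decimal division so ties like 2.86/40% = 7.15 round away from zero
    value = Decimal(repr(assembly_length_mbp)) * 100 / Decimal(repr(completeness_percent))
    return float(value.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def gc_percent(contigs: str | Iterable[str]) -> float:
    """GC percent over A/C/G/T bases; N excluded from the denominator."""
    if isinstance(contigs, str):
        contigs = [contigs]
    gc = at = 0
    for seq in contigs:
        s = seq.upper()
        gc += s.count("G") + s.count("C")
        at += s.count("A") + s.count("T")
    denom = gc + at
    if denom == 0:
        raise InputError("GC content undefined: no A/C/G/T bases")
    return 100.0 * gc / denom


def qc_report(
    assembly: PartialAssembly | SyntheticGenome,
    marker_db: MarkerSet,
    hits: pd.DataFrame | str | Path | None = None,
) -> QCReport:
    """Full QC report for one assembly (truth-mode marker detection by default)."""
    table = detect_markers(assembly, marker_db, hits)
    comp = completeness(table, marker_db)
    cont = contamination(table, marker_db)
    seqs = list((assembly.contigs if isinstance(assembly, SyntheticGenome)
                 else {f.fragment_id: f.sequence for f in assembly.fragments}).values())
    length_bp = sum(len(s) for s in seqs)
    length_mbp = length_bp / 1e6
    try:
        gc = gc_percent(seqs) if length_bp else float("nan")
    except InputError:
        gc = float("nan")
    return QCReport(
        assembly_id=table.assembly_id,
        assembly_length_mbp=length_mbp,
        gc_percent=gc,
        completeness_percent=comp,
        contamination_percent=cont,
        predicted_genome_size_mbp=predict_genome_size(length_mbp, comp),
    )


def write_qc_reports(reports: Iterable[QCReport], tsv_path: str | Path,
                     json_path: str | Path | None = None) -> None:
    rows = [r.as_dict() for r in reports]
    df = pd.DataFrame(rows)
    df.to_csv(tsv_path, sep="\t", index=False, na_rep="NA")
    if json_path is not None:
        Path(json_path).write_text(json.dumps(rows, indent=2, default=str) + "\n")


def load_published_assembly_stats() -> pd.DataFrame:
    """Published per-assembly statistics shipped as a fixture.

    Columns: assembly_id, lineage_class, kind, assembly_mbp, gc_percent,
    has_16s, completeness_pct (string; may be "<1"), predicted_size_mbp
    (may be NA), contamination_pct (string; may be "<1"), quality,
    size_reproducible (1 where the printed size is reproduced by
    predict_genome_size from the integer-precision printed inputs).
    """
    path = resources.files("sagqc").joinpath("data/published_assembly_stats.tsv")
    with path.open() as fh:
        return pd.read_csv(fh, sep="\t", dtype={"completeness_pct": str,
                                                "contamination_pct": str})
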