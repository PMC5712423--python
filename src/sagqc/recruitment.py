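"""Fragment recruitment: alignment filtering, per-Mbp abundance, bin screens.

Reads are recruited to a reference when their alignment spans at least 100 bp
of the reference at >= 90% nucleotide identity (both inclusive, both
configurable). Identity is 1 - edit_distance / aligned_columns, with the
edit distance taken from the SAM NM tag and aligned columns counting
matches, mismatches and indel columns; the overlap is the aligned reference
span. Relative abundance is the fraction of all metagenome reads recruited,
per Mbp of reference.

SAM input follows 1-based SAM conventions (parsed with pysam); the tabular
dialect is a TSV with columns read_id, reference_id, identity, overlap_bp.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import pysam

from sagqc.synthetic import InputError, ParameterError

__all__ = [
    "AlignmentRecord",
    "ParseSummary",
    "AbundanceReport",
    "parse_alignments",
    "filter_recruits",
    "relative_abundance",
    "abundance_report",
    "write_abundance_reports",
    "screen_bins",
    "screen_16s_hits",
]


@dataclass(frozen=True)
class AlignmentRecord:
    read_id: str
    reference_id: str
    overlap_bp: int
    identity: float
    mapped: bool = True

    def __post_init__(self):
        if self.mapped and self.overlap_bp < 1:
            raise InputError("mapped records need overlap_bp >= 1")
        if not 0.0 <= self.identity <= 1.0:
            raise InputError("identity must be in [0,1]")


@dataclass
class ParseSummary:
    n_parsed: int = 0
    n_unmapped: int = 0
    n_secondary_or_supplementary: int = 0
    n_missing_edit_distance: int = 0
    n_malformed: int = 0


@dataclass
class AbundanceReport:
    reference_id: str
    reference_length_mbp: float
    n_reads_passing: int
    total_reads: int
    relative_abundance_per_mbp: float

    def as_dict(self) -> dict:
        return self.__dict__.copy()


# ---------------------------------------------------------------------------


def parse_alignments(path: str | Path) -> tuple[list[AlignmentRecord], ParseSummary]:
    """Parse SAM (.sam) or the tabular dialect (.tsv) into alignment records.

    SAM: secondary/supplementary and unmapped records are excluded; records
    without an NM tag are rejected and counted in the summary.
    """
    path = Path(path)
    if path.suffix.lower() == ".sam":
        return _parse_sam(path)
    return _parse_tsv(path)


def _parse_sam(path: Path) -> tuple[list[AlignmentRecord], ParseSummary]:
    records: list[AlignmentRecord] = []
    summary = ParseSummary()
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam:
            try:
                if aln.is_unmapped:
                    summary.n_unmapped += 1
                    continue
                if aln.is_secondary or aln.is_supplementary:
                    summary.n_secondary_or_supplementary += 1
                    continue
                if not aln.has_tag("NM"):
                    summary.n_missing_edit_distance += 1
                    continue
                nm = aln.get_tag("NM")
                stats = aln.get_cigar_stats()[0]
                # aligned columns: M/=/X plus I and D; overlap: reference span
                m = stats[0] + stats[7] + stats[8]
                ins, dele = stats[1], stats[2]
                aligned_cols = m + ins + dele
                overlap = m + dele
                if aligned_cols <= 0 or overlap <= 0:
                    summary.n_malformed += 1
                    continue
                identity = 1.0 - nm / aligned_cols
                records.append(
                    AlignmentRecord(
                        read_id=aln.query_name,
                        reference_id=aln.reference_name,
                        overlap_bp=overlap,
                        identity=max(0.0, identity),
                    )
                )
                summary.n_parsed += 1
            except (ValueError, TypeError) as exc:  # pragma: no cover - defensive
                summary.n_malformed += 1
                warnings.warn(f"skipping malformed SAM record: {exc}", stacklevel=2)
    return records, summary


def _parse_tsv(path: Path) -> tuple[list[AlignmentRecord], ParseSummary]:
    df = pd.read_csv(path, sep="\t")
    required = {"read_id", "reference_id", "identity", "overlap_bp"}
    if not required.issubset(df.columns):
        raise InputError(f"tabular alignments need columns {sorted(required)}")
    records: list[AlignmentRecord] = []
    summary = ParseSummary()
    for row in df.itertuples(index=False):
        try:
            records.append(
                AlignmentRecord(
                    read_id=str(row.read_id),
                    reference_id=str(row.reference_id),
                    overlap_bp=int(row.overlap_bp),
                    identity=float(row.identity),
                )
            )
            summary.n_parsed += 1
        except (InputError, ValueError) as exc:
            summary.n_malformed += 1
            warnings.warn(f"skipping malformed alignment row: {exc}", stacklevel=2)
    return records, summary


def filter_recruits(
    records: Sequence[AlignmentRecord],
    min_overlap_bp: int = 100,
    min_identity: float = 0.90,
) -> list[AlignmentRecord]:
    """Keep mapped records with overlap >= min_overlap_bp and identity >=
    min_identity (both inclusive); one best alignment per (read, reference),
    best = highest identity, then longest overlap, then lexicographically
    smallest reference id."""
    best: dict[tuple[str, str], AlignmentRecord] = {}
    for r in records:
        if not r.mapped:
            continue
        if r.overlap_bp < min_overlap_bp or r.identity < min_identity:
            continue
        key = (r.read_id, r.reference_id)
        cur = best.get(key)
        if cur is None or (r.identity, r.overlap_bp, _neg_lex(r.reference_id)) > (
            cur.identity, cur.overlap_bp, _neg_lex(cur.reference_id)
        ):
            best[key] = r
    return [best[k] for k in sorted(best)]


def _neg_lex(s: str):
    # invert lexicographic order so "smaller reference id wins" under max()
    return tuple(-b for b in s.encode("utf-8"))


def relative_abundance(
    n_passing: int, total_reads: int, reference_length_mbp: float
) -> float:
    """(n_passing / total_reads) / reference_length_mbp."""
    if total_reads < 1:
        raise ParameterError("total_reads must be >= 1")
    if reference_length_mbp <= 0:
        raise ParameterError("reference_length_mbp must be > 0")
    if n_passing < 0:
        raise ParameterError("n_passing must be >= 0")
    return (n_passing / total_reads) / reference_length_mbp


def abundance_report(
    records: Sequence[AlignmentRecord],
    reference_id: str,
    reference_length_bp: int,
    total_reads: int,
    min_overlap_bp: int = 100,
    min_identity: float = 0.90,
) -> AbundanceReport:
    """Filter records for one reference and summarize its recruitment."""
    passing = [
        r
        for r in filter_recruits(records, min_overlap_bp, min_identity)
        if r.reference_id == reference_id
    ]
    mbp = reference_length_bp / 1e6
    return AbundanceReport(
        reference_id=reference_id,
        reference_length_mbp=mbp,
        n_reads_passing=len(passing),
        total_reads=total_reads,
        relative_abundance_per_mbp=relative_abundance(len(passing), total_reads, mbp),
    )


def write_abundance_reports(reports: Iterable[AbundanceReport], path: str | Path) -> None:
    pd.DataFrame([r.as_dict() for r in reports]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# screens


def screen_bins(
    hit_table: pd.DataFrame | str | Path,
    min_hits: int = 200,
    max_evalue: float = 1e-50,
) -> list[str]:
    """Bins worth further analysis: >= min_hits hits at e-value <= max_evalue."""
    if isinstance(hit_table, (str, Path)):
        hit_table = pd.read_csv(hit_table, sep="\t")
    if not {"bin_id", "evalue"}.issubset(hit_table.columns):
        raise InputError("bin hit table needs columns bin_id, evalue")
    qualifying = hit_table[hit_table["evalue"] <= max_evalue]
    counts = qualifying.groupby("bin_id").size()
    return sorted(counts[counts >= min_hits].index.tolist())


def screen_16s_hits(
    hits: pd.DataFrame | str | Path,
    min_identity: float = 0.85,
    min_length_bp: int = 600,
) -> pd.DataFrame:
    """16S similarity-search screen: identity >= min_identity, alignment
    length >= min_length_bp, one record per subject (best identity, then
    longest alignment)."""
    if isinstance(hits, (str, Path)):
        hits = pd.read_csv(hits, sep="\t")
    required = {"subject_id", "identity", "alignment_length"}
    if not required.issubset(hits.columns):
        raise InputError(f"16S hit table needs columns {sorted(required)}")
    kept = hits[
        (hits["identity"] >= min_identity)
        & (hits["alignment_length"] >= min_length_bp)
    ]
    kept = kept.sort_values(
        ["subject_id", "identity", "alignment_length"],
        ascending=[True, False, False],
    )
    return kept.groupby("subject_id", as_index=False).head(1).reset_index(drop=True)
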