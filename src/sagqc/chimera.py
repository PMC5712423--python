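"""Cross-lineage chimera contamination benchmark.

Combines every partial assembly of one lineage with every partial assembly
of a second, diverged lineage, and compares two contamination measures on
each combined assembly:

* actual contamination — duplicated-marker fraction computed from truth
  annotations, counting every marker gene regardless of its divergence from
  the reference database;
* estimated contamination — the same statistic computed through
  threshold-gated marker detection, so marker homologs diverged below the
  database's detection threshold are invisible.

When the database covers lineage A but lineage B sits below the detection
threshold, the estimator is blind to cross-lineage contamination and the
estimated values fall significantly below the actual ones; the benchmark
quantifies this with a pooled-variance two-sample t-test.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from sagqc.markers import MarkerSet, contamination, detect_markers
from sagqc.synthetic import (
    InputError,
    LineageModel,
    ParameterError,
    PartialAssembly,
    generate_lineage_pair,
    make_chimera,
    marker_family_ids,
    simulate_partial_assembly,
)
from sagqc._seeds import child_rng

__all__ = [
    "ChimeraResult",
    "BenchmarkSummary",
    "enumerate_pairs",
    "actual_contamination",
    "estimated_contamination",
    "two_sample_t_equal_var",
    "run_benchmark",
    "default_benchmark_assemblies",
    "DEFAULT_RECOVERY_A",
    "DEFAULT_RECOVERY_B",
]

# Benchmark defaults mirror the published design: 15 assemblies of the
# reference-covered lineage vs. 4 of the diverged lineage, with recovery
# fractions spanning the reported completeness range of 1-40%.
DEFAULT_RECOVERY_A: tuple[float, ...] = tuple(np.round(np.linspace(0.01, 0.40, 15), 4))
DEFAULT_RECOVERY_B: tuple[float, ...] = tuple(np.round(np.linspace(0.01, 0.40, 4), 4))


@dataclass(frozen=True)
class ChimeraResult:
    pair_id: tuple[str, str]
    actual_contamination_percent: float
    estimated_contamination_percent: float


@dataclass
class BenchmarkSummary:
    n_pairs: int
    mean_actual: float
    mean_estimated: float
    t_statistic: float
    p_value: float

    def as_dict(self) -> dict:
        return {
            "n_pairs": self.n_pairs,
            "mean_actual_contamination_percent": self.mean_actual,
            "mean_estimated_contamination_percent": self.mean_estimated,
            "t_statistic": self.t_statistic,
            "p_value": self.p_value,
        }


def enumerate_pairs(
    group_a: Sequence[PartialAssembly], group_b: Sequence[PartialAssembly]
) -> list[tuple[PartialAssembly, PartialAssembly]]:
    """Full Cartesian product |A| x |B|, ordered lexicographically by id."""
    if not group_a or not group_b:
        raise InputError("both assembly groups must be non-empty")
    ids_a = {a.assembly_id for a in group_a}
    ids_b = {b.assembly_id for b in group_b}
    if ids_a & ids_b:
        raise InputError("assembly groups must be disjoint")
    sa = sorted(group_a, key=lambda a: a.assembly_id)
    sb = sorted(group_b, key=lambda b: b.assembly_id)
    return list(itertools.product(sa, sb))


def _truth_marker_counts(assembly: PartialAssembly, families: set[str]) -> dict[str, int]:
    counts: dict[str, int] = {}
    if assembly.genes is None:
        raise InputError(f"{assembly.assembly_id}: truth gene table missing")
    for g in assembly.genes:
        if g.is_marker and g.family_id in families:
            counts[g.family_id] = counts.get(g.family_id, 0) + 1
    return counts


def actual_contamination(
    a: PartialAssembly, b: PartialAssembly, marker_db: MarkerSet
) -> float:
    """Duplicated-marker percent of the combined assembly from truth
    annotations: every marker gene counts, regardless of divergence."""
    fams = set(marker_db.families)
    ca = _truth_marker_counts(a, fams)
    cb = _truth_marker_counts(b, fams)
    excess = sum(
        max(0, ca.get(f, 0) + cb.get(f, 0) - 1) for f in marker_db.families
    )
    return 100.0 * excess / len(marker_db)


def estimated_contamination(
    a: PartialAssembly, b: PartialAssembly, marker_db: MarkerSet
) -> float:
    """Contamination of the combined assembly as an identity-thresholded
    marker detector sees it (divergent homologs are invisible)."""
    combined = make_chimera(a, b)
    return contamination(detect_markers(combined, marker_db), marker_db)


def two_sample_t_equal_var(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pooled-variance Student t with |x|+|y|-2 df; two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ParameterError("each sample needs at least two observations")
    nx, ny = x.size, y.size
    df = nx + ny - 2
    sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / df
    diff = x.mean() - y.mean()
    if sp2 == 0.0:
        if diff == 0.0:
            return 0.0, 1.0
        raise ParameterError("degenerate input: zero pooled variance, unequal means")
    t = diff / math.sqrt(sp2 * (1.0 / nx + 1.0 / ny))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(p)


def run_benchmark(
    group_a: Sequence[PartialAssembly],
    group_b: Sequence[PartialAssembly],
    marker_db: MarkerSet,
    output_dir: str | Path | None = None,
) -> tuple[BenchmarkSummary, pd.DataFrame]:
    """Both contamination measures for every cross-lineage pair, plus the
    equal-variance t-test of estimated vs. actual across pairs."""
    results = []
    for a, b in enumerate_pairs(group_a, group_b):
        results.append(
            ChimeraResult(
                pair_id=(a.assembly_id, b.assembly_id),
                actual_contamination_percent=actual_contamination(a, b, marker_db),
                estimated_contamination_percent=estimated_contamination(a, b, marker_db),
            )
        )
    per_pair = pd.DataFrame(
        {
            "assembly_id_a": [r.pair_id[0] for r in results],
            "assembly_id_b": [r.pair_id[1] for r in results],
            "actual_contamination_percent": [
                r.actual_contamination_percent for r in results
            ],
            "estimated_contamination_percent": [
                r.estimated_contamination_percent for r in results
            ],
        }
    )
    try:
        t, p = two_sample_t_equal_var(
            per_pair["estimated_contamination_percent"],
            per_pair["actual_contamination_percent"],
        )
    except ParameterError:
        # every pair identical within each measure (e.g. all assemblies
        # complete): the test statistic is undefined
        t, p = math.nan, math.nan
    summary = BenchmarkSummary(
        n_pairs=len(results),
        mean_actual=float(per_pair["actual_contamination_percent"].mean()),
        mean_estimated=float(per_pair["estimated_contamination_percent"].mean()),
        t_statistic=t,
        p_value=p,
    )
    if output_dir is not None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        per_pair.to_csv(out / "chimera_pairs.tsv", sep="\t", index=False)
        (out / "chimera_summary.json").write_text(
            json.dumps(summary.as_dict(), indent=2) + "\n"
        )
    return summary, per_pair


def default_benchmark_assemblies(
    seed: int,
    *,
    n_a: int = 15,
    n_b: int = 4,
    recovery_a: Sequence[float] | None = None,
    recovery_b: Sequence[float] | None = None,
    divergence_b: float = 0.35,
    detection_identity_threshold: float = 0.70,
    n_markers: int = 100,
    genome_size_bp: int = 1_000_000,
    n_accessory_genes: int = 400,
    gene_length_bp: int = 900,
    fragmentation: int = 5,
    materialize_sequence: bool = False,
) -> tuple[list[PartialAssembly], list[PartialAssembly], MarkerSet]:
    """Build the default benchmark inputs: lineage A covered by the marker
    database, lineage B diverged below the detection threshold.

    Genome size defaults to 1 Mbp — recovery and marker statistics are
    size-invariant, and the smaller genomes keep replicated runs fast.
    """
    if recovery_a is None:
        recovery_a = tuple(np.round(np.linspace(0.01, 0.40, n_a), 4))
    if recovery_b is None:
        recovery_b = tuple(np.round(np.linspace(0.01, 0.40, n_b), 4))
    if len(recovery_a) != n_a or len(recovery_b) != n_b:
        raise ParameterError("recovery fraction lists must match group sizes")

    model_a = LineageModel(
        "lineageA", genome_size_bp=genome_size_bp, gc_target=0.66,
        n_markers=n_markers, n_accessory_genes=n_accessory_genes,
        divergence_from_reference=0.0,
    )
    model_b = LineageModel(
        "lineageB", genome_size_bp=genome_size_bp, gc_target=0.70,
        n_markers=n_markers, n_accessory_genes=n_accessory_genes,
        divergence_from_reference=divergence_b,
    )
    n_genomes = max(n_a, n_b)
    genomes = generate_lineage_pair(
        model_a, model_b, between_lineage_divergence=divergence_b,
        n_genomes_per_lineage=n_genomes, seed=seed,
        gene_length_bp=gene_length_bp,
    )
    genomes_a = genomes[:n_genomes][:n_a]
    genomes_b = genomes[n_genomes:][:n_b]
    rng = child_rng(seed, "bench-assemblies")
    group_a = [
        simulate_partial_assembly(
            g, r, fragmentation, int(rng.integers(0, 2**31 - 1)),
            assembly_id=f"A{idx:02d}.r{r:g}",
            materialize_sequence=materialize_sequence,
        )
        for idx, (g, r) in enumerate(zip(genomes_a, recovery_a))
    ]
    group_b = [
        simulate_partial_assembly(
            g, r, fragmentation, int(rng.integers(0, 2**31 - 1)),
            assembly_id=f"B{idx:02d}.r{r:g}",
            materialize_sequence=materialize_sequence,
        )
        for idx, (g, r) in enumerate(zip(genomes_b, recovery_b))
    ]
    marker_db = MarkerSet(
        "universal", tuple(marker_family_ids(n_markers)),
        detection_identity_threshold=detection_identity_threshold,
    )
    return group_a, group_b, marker_db
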