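# sagqc

Quality assessment and benchmarking for single-amplified genomes (SAGs) and
metagenome bins, built around single-copy marker genes — and around the
question of when marker-based QC can be trusted.

Single-cell and metagenomic sequencing routinely produce partial genome
assemblies from uncultured lineages. Their quality is judged almost
universally with single-copy marker genes: *completeness* is the fraction of
expected marker families found, and *contamination* is the excess of
duplicated markers,

```
completeness  = 100 · |{f : c_f ≥ 1}| / |F|
contamination = 100 · Σ_f max(0, c_f − 1) / |F|
```

where `c_f` is the copy count of marker family `f` in the assembly and `F`
the marker set. From completeness, the size of the complete genome is
predicted as `assembly size / completeness`. These estimators have a blind
spot: a marker detector that requires sequence similarity to a reference
database cannot see contamination contributed by lineages *absent from that
database*. A chimeric bin combining two deeply diverged class-level lineages
can therefore look contamination-free. `sagqc` implements the estimators,
the genome-size predictor, fragment-recruitment abundance, reciprocal-best-hit
AAI — and a fully synthetic two-lineage benchmark that quantifies the blind
spot end to end.

## What's in the box

- `sagqc.synthetic` — deterministic generator of two-lineage communities:
  pangenomes with single-copy markers at controlled between-lineage
  divergence, partial SAG-like assemblies at chosen recovery fractions,
  deliberate cross-lineage chimeras, and short reads at controlled identity.
- `sagqc.markers` — marker detection (truth tables or tabular similarity
  hits), completeness, contamination, GC%, and genome-size prediction; ships
  the published per-assembly statistics table as a fixture.
- `sagqc.chimera` — the cross-lineage chimera benchmark: all |A|×|B| pairwise
  combinations, actual vs. estimated contamination, equal-variance two-sample
  t-test.
- `sagqc.recruitment` — SAM/TSV alignment parsing, the ≥100 bp / ≥90 %
  identity recruitment filter, reads-per-Mbp relative abundance, the
  ≥200-hit / ≤1e-50 bin screen and the ≥85 % / ≥600 bp 16S screen.
- `sagqc.comparative` — reciprocal-best-hit AAI and pairwise nucleotide
  identity with exact global alignment.
- `sagqc.pipeline` / `sagqc` CLI — end-to-end runs, MIMAG-style quality
  tiers, TSV/JSON reports.

## Worked example

Reproduce the contamination-blindness experiment on a synthetic community:
15 partial assemblies of a lineage covered by the marker database are
combined pairwise with 4 partial assemblies of a second lineage diverged 35 %
from it (detection threshold 70 % identity, 100-marker set, recovery
fractions spanning 1–40 %):

```
$ sagqc chimera-bench --seed 1 --out-dir bench_demo
{
  "n_pairs": 60,
  "mean_actual_contamination_percent": 3.933333333333333,
  "mean_estimated_contamination_percent": 0.0,
  "t_statistic": -5.814878218225118,
  "p_value": 5.286885593184075e-08
}
```

All 60 chimeras carry real cross-lineage contamination (mean ≈ 3.9 % of the
marker set duplicated), yet the threshold-gated estimator reports 0 % for
every pair — the diverged lineage's markers fall below the detection
threshold and are invisible. The pooled-variance t-test confirms the
estimated values are significantly below the actual ones (p ≪ 0.001).
Per-pair values land in `bench_demo/chimera_pairs.tsv`.

Genome-size prediction from an assembly of 2.61 Mbp at 32 % completeness:

```
$ sagqc genome-size --assembly-mbp 2.61 --completeness 32
8.2
```

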