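# Methods

## Marker-based QC statistics

Let `F` be an ordered set of single-copy marker families and `c_f` the
number of copies of family `f` detected in an assembly. The package uses

- completeness `= 100 · |{f ∈ F : c_f ≥ 1}| / |F|` — presence, not copies,
  so duplication does not inflate completeness;
- contamination `= 100 · Σ_f max(0, c_f − 1) / |F|` — the uniform-weight
  excess-copy fraction of the marker set;
- predicted genome size `= assembly Mbp / (completeness / 100)`, reported at
  one decimal with half-away-from-zero rounding (done in exact decimal
  arithmetic so ties such as 2.86 Mbp at 40 % → 7.15 → 7.2 are not corrupted
  by binary floating point), and reported as NA when completeness < 1 %,
  where the ratio is dominated by noise;
- GC % `= 100 · (G+C)/(A+C+G+T)` with N excluded from the denominator;
  empty or all-N input is an error, not 0.

Detection is identity-gated: a gene counts toward `c_f` only when its
identity to the database representation of `f` is at least the marker set's
`detection_identity_threshold` (inclusive `≥`). In truth mode the identity
is `1 − divergence` with the divergence recorded by the generator; in hits
mode it comes from a tabular similarity search (best hit per gene). The
default threshold is 0.70: below it, marker homologs from a class-level
lineage diverged ~35 % from the database are invisible, which is exactly
the failure mode the chimera benchmark measures; within-lineage genes at
the default divergence are always seen. The threshold is configurable.

A packaged TSV fixture carries the published per-assembly statistics
(assembly size, GC, completeness, predicted size, contamination, quality
label) used by tests and the acceptance script. Published completeness is
printed as integers, and some printed sizes are only consistent with
unrounded inputs that were not published; rows that do not reproduce from
integer-precision inputs are flagged `size_reproducible = 0` in the fixture
and excluded from replay checks (e.g. 0.29 Mbp at 6 % gives 4.8, not the
printed 4.9). The published average completeness of 18.2 % is not
reproducible from the printed values under any rounding convention we
tested and is not used as a check.

## Synthetic two-lineage communities

The generator produces the study conditions for every downstream statistic,
with no external data.

**Genomes.** A genome is `n_contigs` (default 4) contigs of i.i.d. random
nucleotides at the lineage's target GC, carrying fixed-length (default
900 bp), non-overlapping genes: `n_markers` single-copy marker families
interleaved uniformly with accessory genes. Defaults per lineage —
7 Mbp genomes, GC 0.66–0.70, 100 markers — follow the large-genome,
high-GC regime of the uncultured lineages that motivate the toolkit (6–8
Mbp, 64–71 % GC); tests and the benchmark scale the genome length down
(0.3–5 Mbp) because every recovery and marker statistic is
length-invariant, and state the size they use.

**Divergence.** Substitution-only (per-site substitution to a uniformly
chosen different base; no indels). A reference marker database is drawn
first; lineage A's canonical markers derive from it at
`divergence_from_reference`, and lineage B's derive from lineage A's at the
requested between-lineage divergence, so with `d_A = 0` lineage B sits at
the requested divergence from the database. Each gene stores its *realized*
divergence from the database (computed by direct comparison), which is what
truth-mode detection consumes — the stored value is measured, never
assumed. A single mutation round makes the expected realized divergence
equal the requested rate; the class-level split of ~12–15 % nucleotide
divergence and the deeper 35 % marker divergence used in the benchmark are
both just parameter choices of the same mechanism. Within-lineage
divergence is exposed as a free parameter (default 0): field observations
constrain it only in AAI terms, not nucleotide terms.

**Partial assemblies.** `fragmentation` windows are placed uniformly at
random without overlap, with total length exactly `recovery_fraction ×
genome length` (random integer compositions of window and gap lengths;
adjacent windows merge). Every site is covered with probability exactly
`r`; a gene is recovered only when fully contained in a window, giving an
edge bias of order `fragmentation · gene_length / genome_length` (≤ 0.01
at the defaults used in tests), so expected marker presence ≈ `r`. Because
total recovered length is fixed and markers are evenly spaced, the marker
presence count is slightly *sub*-binomial in variance. `recovery = 1`
returns the genome itself; `recovery = 0` an empty assembly.

**Chimeras.** Disjoint union of two partial assemblies; fragment-level
provenance (source contig, coordinates, lineage) is preserved for
truth-based scoring. Identifier collisions are an error.

**Reads.** Drawn uniformly over contigs (forward strand only — recruitment
statistics are strand-agnostic here because identity is computed against
the known origin), mutated at `per_read_divergence`, origin recorded in the
FASTQ header. Expected identity to the reference is `1 − d`.

**Determinism.** One master seed; every operation derives its own generator
from `(master, tag…)` via `numpy.random.SeedSequence`, with strings hashed
by crc32 (process-stable). Identical seeds and parameters give
byte-identical outputs.

**Not modeled.** Amplification bias, platform error profiles, indels (off
by default), assembly graphs, strand-aware read simulation, rRNA genes.
Passing tests therefore demonstrate the estimators' behavior under ideal
marker statistics, not performance on real amplification-biased SAGs.

## Chimera benchmark

All `|A| × |B|` cross-lineage pairs (deterministic lexicographic order) are
scored with two measures of the same statistic:

- **actual contamination** — the excess-copy formula applied to truth
  annotations, counting every marker gene regardless of divergence:
  `100 · Σ_f max(0, c_f^A + c_f^B − 1)/|F|`. Under independent recovery at
  fractions `r_a, r_b` its expectation is `100 · r_a · r_b` (a family is
  duplicated exactly when both partials recovered it), which the tests
  verify by Monte-Carlo. No canonical definition exists for the “actual” contamination of a
  deliberately combined assembly; this one is adopted because it applies
  the same statistic to both measures, and is documented as our choice.
- **estimated contamination** — the same formula applied through
  identity-gated detection, so lineage-B markers diverged below the
  threshold vanish.

The two samples of per-pair values are compared with a pooled-variance
two-sample Student t-test (two-sided as a conservative default; the direction is reported
separately). Zero pooled variance with equal means returns `t = 0, p = 1`;
with unequal means it is signalled as degenerate (the benchmark records NaN
in that case, which arises only when every pair is identical, e.g. all
assemblies complete).

**Default design.** 15 lineage-A vs. 4 lineage-B assemblies (the published
group sizes), lineage B at 0.35 divergence from the database, threshold
0.70, 100 markers, genomes 1 Mbp, fragmentation 5. Recovery fractions
default to values evenly spanning 1–40 %, the published completeness range
of the SAGs. We deliberately span the range rather than replay the literal
printed completeness column: ten of the nineteen printed values are below
1 %, assemblies that carry almost no markers and contribute almost no
information, and with them the 60-pair t-test has roughly coin-flip power
at the p < 0.001 level (median p ≈ 0.0015 over 400 simulated designs).
Either design produces the same direction (estimated < actual); the
spanning design makes the significance statement reproducible run-to-run.
The literal column remains available through the fixture and the
`--recovery-tsv` option.

## Recruitment

Identity is `1 − NM / aligned_columns` (aligned columns = M/=/X + I + D
from the CIGAR), the overlap is the aligned reference span, both standard
recruitment conventions ("nucleotide identity" alone underdetermines them). Filters are inclusive at 100 bp and 0.90 identity; each read
counts at most once per reference (best alignment: highest identity, then
longest overlap, then lexicographically smallest reference id). Relative
abundance is `(passing / total reads) / reference Mbp`. SAM input uses
1-based SAM conventions (via pysam); internal intervals are 0-based
half-open. The bin screen keeps bins with ≥ 200 hits at e-value ≤ 1e-50;
the 16S screen keeps hits at ≥ 85 % identity and ≥ 600 bp, one per subject.
Whether the published 100 bp criterion meant aligned span or read length is
not stated; aligned reference span is adopted. Multi-mapping reads are
counted once per reference (best hit), also an undocumented choice in the
source.

## Comparative statistics

Reciprocal best hits are scored by exact global (NW) edit distance (edlib),
deterministic and exact for desk-scale protein sets — no heuristic search,
no score randomness. Ties break by protein id; alignment paths are computed
in a canonical orientation (lexicographically smaller sequence first) so
identity is symmetric in its arguments. Pair identity is matches / aligned
columns of the optimal path; coverage of a global alignment is
`min(|a|,|b|) / max(|a|,|b|)`. Default RBH thresholds (identity ≥ 0.30,
coverage ≥ 0.70) are our choice — widely used online AAI calculators do not publish
their thresholds — and are configurable. AAI is the
unweighted mean pair identity × 100; undefined (an error, not 0) with zero
pairs. Note that optimal global alignment slightly inflates recovered
identity above `1 − d` at high divergence (gaps can substitute for mismatch
runs): at amino-acid divergence 0.54 the recovered AAI is ~47–48 % rather
than 46.2 %; this is inherent to alignment-based identity, not a bug.

## Quality tiers

high: completeness > 90 ∧ contamination < 5 ∧ rRNA present; medium:
completeness ≥ 50 ∧ contamination < 10; NA: contamination > 100 (the
single-genome interpretation has collapsed); low otherwise. The published
label column is itself not fully consistent with any fixed rule (some rows
with 34–59 % contamination print NA, one 63 %-complete bin prints Low); the
replay checks assert only rows that the stated rule reproduces.

## Problem sizes and numerical choices

Monte-Carlo checks use 200 replicate assemblies (500 for the
closed-form contamination check) on 0.3–5 Mbp genomes with 50–100 markers
and fragmentation 5 — sizes at which the quantities under test are
indistinguishable from their full-scale values because all statistics
depend only on recovery fractions, marker counts, and divergences.
Genome-size recovery experiments use 5 Mbp truth genomes so the one-decimal
Mbp rounding of the predictor (±0.05 Mbp) is ≤ 1 % of truth. All
randomness flows from the single seed described above.
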