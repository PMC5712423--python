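"""Synthetic two-lineage communities for QC benchmarking.

Generates pangenomes for two class-level lineages whose marker genes are
diverged by a controlled amount, partial SAG-like assemblies at chosen
recovery fractions, deliberate cross-lineage chimeras, and short reads at
controlled identity to their reference. Everything is deterministic under a
single master seed (see :mod:`sagqc._seeds` for the splitting rule).

Sequence model
--------------
Genomes are a set of contigs carrying fixed-length, non-overlapping genes
(markers interleaved uniformly with accessory genes) on a random background
at the lineage's target GC. Divergence is per-site independent substitution
to a uniformly chosen different base; no indels. Lineage A's canonical
marker sequences derive from a reference marker database at
``divergence_from_reference``; lineage B's derive from lineage A's at the
requested between-lineage divergence. Each gene records its *realized*
per-site divergence from the reference database, which is what truth-mode
marker detection consumes.

Coordinates are 0-based half-open internally; TSV output is 1-based
inclusive with a +/- strand column.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from sagqc._seeds import child_rng

__all__ = [
    "ParameterError",
    "InputError",
    "LineageModel",
    "Gene",
    "SyntheticGenome",
    "ContigFragment",
    "PartialAssembly",
    "SimRead",
    "generate_lineage_pair",
    "simulate_partial_assembly",
    "make_chimera",
    "simulate_reads",
    "simulate_protein_sets",
    "gene_sequence",
    "cross_lineage_marker_divergence",
    "marker_family_ids",
    "write_fasta",
    "write_gene_table",
    "write_fastq",
]


class ParameterError(ValueError):
    """A numeric parameter is outside its admissible range."""


class InputError(ValueError):
    """An input object violates a structural precondition."""


# ---------------------------------------------------------------------------
# sequence primitives (internal code space: A=0 C=1 G=2 T=3)

_CODE_TO_ASCII = np.frombuffer(b"ACGT", dtype=np.uint8)
_ASCII_TO_CODE = np.zeros(256, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ASCII_TO_CODE[_b] = _i
    _ASCII_TO_CODE[_b + 32] = _i  # lowercase

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


def _codes_to_str(codes: np.ndarray) -> str:
    return bytes(_CODE_TO_ASCII[codes]).decode("ascii")


def _str_to_codes(seq: str) -> np.ndarray:
    return _ASCII_TO_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _random_codes(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    # base order A,C,G,T: C and G each carry gc/2
    p = np.array([(1.0 - gc) / 2, gc / 2, gc / 2, (1.0 - gc) / 2])
    return rng.choice(4, size=n, p=p).astype(np.uint8)


def _mutate(codes: np.ndarray, divergence: float, rng: np.random.Generator,
            alphabet_size: int = 4) -> np.ndarray:
    """Substitute each site w.p. `divergence` to a uniformly chosen different symbol."""
    out = codes.copy()
    if divergence <= 0.0:
        return out
    mask = rng.random(codes.size) < divergence
    n_mut = int(mask.sum())
    if n_mut:
        shift = rng.integers(1, alphabet_size, size=n_mut)
        out[mask] = (out[mask] + shift) % alphabet_size
    return out


def _revcomp(codes: np.ndarray) -> np.ndarray:
    return (3 - codes)[::-1]


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class LineageModel:
    """Parameters of one class-level lineage.

    genome_size_bp and gc_target default to the middle of the ranges typical
    for large-genome, high-GC uncultured lineages (6-8 Mbp, 64-71% GC).
    divergence_from_reference is the expected per-site nucleotide divergence
    of this lineage's marker genes from the reference marker database.
    """

    lineage_id: str
    genome_size_bp: int = 7_000_000
    gc_target: float = 0.68
    n_markers: int = 100
    n_accessory_genes: int = 900
    divergence_from_reference: float = 0.0

    def __post_init__(self):
        if self.genome_size_bp <= 0:
            raise ParameterError("genome_size_bp must be positive")
        if not 0.0 <= self.gc_target <= 1.0:
            raise ParameterError("gc_target must be in [0,1]")
        if self.n_markers < 1:
            raise ParameterError("n_markers must be >= 1")
        if self.n_accessory_genes < 0:
            raise ParameterError("n_accessory_genes must be >= 0")
        if not 0.0 <= self.divergence_from_reference <= 1.0:
            raise ParameterError("divergence_from_reference must be in [0,1]")


@dataclass(frozen=True)
class Gene:
    """One gene placement; start/end are 0-based half-open on `contig`.

    `divergence` is the realized per-site divergence of this gene from the
    reference marker database (0.0 for accessory genes, which have no
    database counterpart).
    """

    gene_id: str
    family_id: str
    is_marker: bool
    contig: str
    start: int
    end: int
    strand: str
    divergence: float
    lineage_id: str


@dataclass
class SyntheticGenome:
    genome_id: str
    lineage_id: str
    contigs: dict[str, str]
    gene_table: list[Gene]
    truth_genome_size_bp: int

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.contigs.values())


@dataclass(frozen=True)
class ContigFragment:
    """A contig of a partial assembly: a window of a source contig."""

    fragment_id: str
    sequence: str
    source_genome_id: str
    source_contig: str
    source_start: int
    source_end: int
    lineage_id: str

    def __len__(self) -> int:
        return self.source_end - self.source_start


@dataclass
class PartialAssembly:
    assembly_id: str
    source_genome_id: str
    fragments: list[ContigFragment]
    genes: list[Gene]
    recovery_fraction: float | None
    seed: int | None

    @property
    def total_length(self) -> int:
        return sum(len(f) for f in self.fragments)

    @property
    def contigs(self) -> dict[str, str]:
        return {f.fragment_id: f.sequence for f in self.fragments}

    @property
    def lineage_ids(self) -> set[str]:
        return {f.lineage_id for f in self.fragments}


@dataclass(frozen=True)
class SimRead:
    read_id: str
    sequence: str
    source_reference: str
    source_contig: str
    start: int


# ---------------------------------------------------------------------------
# generation


def marker_family_ids(n_markers: int) -> list[str]:
    return [f"M{i:04d}" for i in range(n_markers)]


def _accessory_family_ids(lineage_id: str, n: int) -> list[str]:
    return [f"{lineage_id}:acc{i:05d}" for i in range(n)]


def _gene_schedule(n_markers: int, n_accessory: int, lineage_id: str) -> list[tuple[str, bool]]:
    """Order of gene families along the genome, markers spread uniformly."""
    g = n_markers + n_accessory
    marker_slots = set(np.floor(np.arange(n_markers) * g / n_markers).astype(int).tolist())
    acc_ids = iter(_accessory_family_ids(lineage_id, n_accessory))
    mark_ids = iter(marker_family_ids(n_markers))
    schedule = []
    for slot in range(g):
        if slot in marker_slots:
            schedule.append((next(mark_ids), True))
        else:
            schedule.append((next(acc_ids), False))
    return schedule


def _build_genome(
    model: LineageModel,
    genome_id: str,
    marker_canon: dict[str, np.ndarray],
    acc_canon: dict[str, np.ndarray],
    reference_db: dict[str, np.ndarray],
    within_lineage_divergence: float,
    gene_length_bp: int,
    n_contigs: int,
    rng: np.random.Generator,
) -> SyntheticGenome:
    size = model.genome_size_bp
    g = model.n_markers + model.n_accessory_genes
    if g * gene_length_bp > size:
        raise ParameterError(
            f"genome_size_bp {size} too small for {g} genes of {gene_length_bp} bp"
        )
    schedule = _gene_schedule(model.n_markers, model.n_accessory_genes, model.lineage_id)

    base_len = size // n_contigs
    contig_lens = [base_len] * (n_contigs - 1) + [size - base_len * (n_contigs - 1)]
    # contiguous blocks of the schedule per contig, sized by contig length
    counts = [round(g * cl / size) for cl in contig_lens]
    counts[-1] = g - sum(counts[:-1])

    contigs: dict[str, str] = {}
    gene_table: list[Gene] = []
    idx = 0
    gi = 0
    for ci, (clen, k) in enumerate(zip(contig_lens, counts)):
        contig_id = f"{genome_id}|{model.lineage_id}|contig_{ci}"
        background = _random_codes(rng, clen, model.gc_target)
        if k > 0:
            slot = clen // k
            if slot < gene_length_bp:
                raise ParameterError("contigs too short for the gene schedule")
            for j in range(k):
                family_id, is_marker = schedule[idx]
                idx += 1
                canonical = marker_canon[family_id] if is_marker else acc_canon[family_id]
                seq = _mutate(canonical, within_lineage_divergence, rng)
                if is_marker:
                    div = float(np.mean(seq != reference_db[family_id]))
                else:
                    div = 0.0
                strand = "+" if rng.random() < 0.5 else "-"
                start = j * slot
                end = start + gene_length_bp
                background[start:end] = seq if strand == "+" else _revcomp(seq)
                gene_table.append(
                    Gene(
                        gene_id=f"{genome_id}:g{gi:05d}",
                        family_id=family_id,
                        is_marker=is_marker,
                        contig=contig_id,
                        start=start,
                        end=end,
                        strand=strand,
                        divergence=div,
                        lineage_id=model.lineage_id,
                    )
                )
                gi += 1
        contigs[contig_id] = _codes_to_str(background)

    return SyntheticGenome(
        genome_id=genome_id,
        lineage_id=model.lineage_id,
        contigs=contigs,
        gene_table=gene_table,
        truth_genome_size_bp=size,
    )


def generate_lineage_pair(
    model_a: LineageModel,
    model_b: LineageModel,
    between_lineage_divergence: float,
    n_genomes_per_lineage: int,
    seed: int,
    *,
    within_lineage_divergence: float = 0.0,
    gene_length_bp: int = 900,
    n_contigs: int = 4,
) -> list[SyntheticGenome]:
    """Generate two lineages sharing a marker-family set.

    Marker sequences of the two lineages differ by `between_lineage_divergence`
    expected per-site substitutions. Returns lineage A genomes followed by
    lineage B genomes; genome ids are ``{lineage_id}-{k:02d}``.
    """
    if not 0.0 <= between_lineage_divergence <= 0.5:
        raise ParameterError("between_lineage_divergence must be in [0, 0.5]")
    if not 0.0 <= within_lineage_divergence <= 0.5:
        raise ParameterError("within_lineage_divergence must be in [0, 0.5]")
    if n_genomes_per_lineage < 1:
        raise ParameterError("n_genomes_per_lineage must be >= 1")
    if model_a.n_markers != model_b.n_markers:
        raise ParameterError("both lineages must share one marker-family set")
    if gene_length_bp < 1 or n_contigs < 1:
        raise ParameterError("gene_length_bp and n_contigs must be >= 1")

    families = marker_family_ids(model_a.n_markers)
    gc_ref = (model_a.gc_target + model_b.gc_target) / 2.0
    rng_db = child_rng(seed, "refdb")
    reference_db = {f: _random_codes(rng_db, gene_length_bp, gc_ref) for f in families}

    rng_a = child_rng(seed, "canon", model_a.lineage_id)
    marker_canon_a = {
        f: _mutate(reference_db[f], model_a.divergence_from_reference, rng_a)
        for f in families
    }
    rng_b = child_rng(seed, "canon", model_b.lineage_id)
    marker_canon_b = {
        f: _mutate(marker_canon_a[f], between_lineage_divergence, rng_b)
        for f in families
    }

    acc_canon = {}
    for model in (model_a, model_b):
        rng_acc = child_rng(seed, "accessory", model.lineage_id)
        acc_canon[model.lineage_id] = {
            f: _random_codes(rng_acc, gene_length_bp, model.gc_target)
            for f in _accessory_family_ids(model.lineage_id, model.n_accessory_genes)
        }

    genomes: list[SyntheticGenome] = []
    for model, canon in ((model_a, marker_canon_a), (model_b, marker_canon_b)):
        for k in range(n_genomes_per_lineage):
            gid = f"{model.lineage_id}-{k:02d}"
            rng = child_rng(seed, "genome", model.lineage_id, k)
            genomes.append(
                _build_genome(
                    model, gid, canon, acc_canon[model.lineage_id], reference_db,
                    within_lineage_divergence, gene_length_bp, n_contigs, rng,
                )
            )
    return genomes


# ---------------------------------------------------------------------------
# partial assemblies and chimeras


def _compose(total: int, parts: int, rng: np.random.Generator) -> np.ndarray:
    """Random composition of `total` into `parts` non-negative integers."""
    if parts == 1:
        return np.array([total])
    cuts = np.sort(rng.integers(0, total + 1, size=parts - 1))
    return np.diff(np.concatenate(([0], cuts, [total])))


def simulate_partial_assembly(
    genome: SyntheticGenome,
    recovery_fraction: float,
    fragmentation: int,
    seed: int,
    *,
    assembly_id: str | None = None,
    materialize_sequence: bool = True,
) -> PartialAssembly:
    """Sample `fragmentation` non-overlapping genome windows totalling
    recovery_fraction x genome length; a gene is recovered only if fully
    contained in a window, so each site is covered with probability exactly
    recovery_fraction and marker presence matches it in expectation (up to a
    small edge bias of order fragmentation x gene_length / genome_length).

    materialize_sequence=False skips building fragment sequence strings, for
    statistics-only Monte-Carlo work.
    """
    if not 0.0 <= recovery_fraction <= 1.0:
        raise ParameterError("recovery_fraction must be in [0,1]")
    if fragmentation < 1:
        raise ParameterError("fragmentation must be >= 1")
    if assembly_id is None:
        assembly_id = f"{genome.genome_id}.r{recovery_fraction:g}.s{seed}"

    contig_ids = list(genome.contigs)
    contig_lens = np.array([len(genome.contigs[c]) for c in contig_ids])
    offsets = np.concatenate(([0], np.cumsum(contig_lens)))
    L = int(offsets[-1])
    T = int(round(recovery_fraction * L))

    rng = child_rng(seed, "partial", genome.genome_id)
    fragments: list[ContigFragment] = []
    genes: list[Gene] = []

    if T > 0:
        win_lens = _compose(T, fragmentation, rng)
        gap_lens = _compose(L - T, fragmentation + 1, rng)
        # interleave: gap0 win0 gap1 win1 ... winK gapK+1
        windows = []
        pos = 0
        for w, gap in zip(win_lens, gap_lens):
            pos += int(gap)
            if w > 0:
                if windows and windows[-1][1] == pos:  # zero gap: one contig
                    windows[-1] = (windows[-1][0], pos + int(w))
                else:
                    windows.append((pos, pos + int(w)))
            pos += int(w)

        genes_by_contig: dict[str, list[Gene]] = {}
        for gobj in genome.gene_table:
            genes_by_contig.setdefault(gobj.contig, []).append(gobj)

        fi = 0
        for ws, we in windows:
            # intersect window with contig spans
            first = int(np.searchsorted(offsets, ws, side="right") - 1)
            ci = first
            while ci < len(contig_ids) and offsets[ci] < we:
                cs, ce = int(offsets[ci]), int(offsets[ci + 1])
                fs, fe = max(ws, cs) - cs, min(we, ce) - cs
                if fe > fs:
                    cid = contig_ids[ci]
                    fid = f"{assembly_id}|frag_{fi}"
                    fi += 1
                    seq = genome.contigs[cid][fs:fe] if materialize_sequence else ""
                    fragments.append(
                        ContigFragment(
                            fragment_id=fid,
                            sequence=seq,
                            source_genome_id=genome.genome_id,
                            source_contig=cid,
                            source_start=fs,
                            source_end=fe,
                            lineage_id=genome.lineage_id,
                        )
                    )
                    for gobj in genes_by_contig.get(cid, ()):
                        if gobj.start >= fs and gobj.end <= fe:
                            genes.append(
                                replace(gobj, contig=fid,
                                        start=gobj.start - fs, end=gobj.end - fs)
                            )
                ci += 1

    return PartialAssembly(
        assembly_id=assembly_id,
        source_genome_id=genome.genome_id,
        fragments=fragments,
        genes=genes,
        recovery_fraction=recovery_fraction,
        seed=seed,
    )


def make_chimera(a: PartialAssembly, b: PartialAssembly,
                 assembly_id: str | None = None) -> PartialAssembly:
    """Disjoint union of two partial assemblies; per-contig provenance kept."""
    ids_a = {f.fragment_id for f in a.fragments}
    ids_b = {f.fragment_id for f in b.fragments}
    clash = ids_a & ids_b
    if clash:
        raise InputError(f"fragment identifier collision: {sorted(clash)[:3]} ...")
    return PartialAssembly(
        assembly_id=assembly_id or f"{a.assembly_id}+{b.assembly_id}",
        source_genome_id=f"{a.source_genome_id}+{b.source_genome_id}",
        fragments=list(a.fragments) + list(b.fragments),
        genes=list(a.genes) + list(b.genes),
        recovery_fraction=None,
        seed=None,
    )


# ---------------------------------------------------------------------------
# reads


def simulate_reads(
    reference: SyntheticGenome | PartialAssembly,
    n_reads: int,
    read_length: int,
    per_read_divergence: float,
    seed: int,
) -> list[SimRead]:
    """Draw reads uniformly over contigs (forward strand) and substitute
    sites at `per_read_divergence`, so expected identity to the reference is
    1 - per_read_divergence. Read origin is recorded for truth-based tests.
    """
    if n_reads < 0:
        raise ParameterError("n_reads must be >= 0")
    if not 0.0 <= per_read_divergence <= 0.5:
        raise ParameterError("per_read_divergence must be in [0, 0.5]")
    contigs = (reference.contigs if isinstance(reference, SyntheticGenome)
               else {f.fragment_id: f.sequence for f in reference.fragments})
    ref_id = (reference.genome_id if isinstance(reference, SyntheticGenome)
              else reference.assembly_id)
    if n_reads == 0:
        return []
    if not contigs:
        raise InputError("reference has no contigs")
    lens = {c: len(s) for c, s in contigs.items()}
    if read_length < 1 or read_length > min(lens.values()):
        raise InputError("read_length must be in [1, shortest contig length]")

    ids = sorted(contigs)
    starts_per = np.array([lens[c] - read_length + 1 for c in ids], dtype=float)
    p = starts_per / starts_per.sum()
    rng = child_rng(seed, "reads", ref_id)
    which = rng.choice(len(ids), size=n_reads, p=p)
    reads: list[SimRead] = []
    for i, ci in enumerate(which):
        cid = ids[int(ci)]
        start = int(rng.integers(0, lens[cid] - read_length + 1))
        codes = _str_to_codes(contigs[cid][start:start + read_length])
        codes = _mutate(codes, per_read_divergence, rng)
        reads.append(SimRead(
            read_id=f"{ref_id}.r{i:06d}",
            sequence=_codes_to_str(codes),
            source_reference=ref_id,
            source_contig=cid,
            start=start,
        ))
    return reads


# ---------------------------------------------------------------------------
# proteins (for AAI parameter-recovery experiments)


def simulate_protein_sets(n_proteins: int, length: int, divergence: float,
                          seed: int, ids: tuple[str, str] = ("gnmA", "gnmB")):
    """Two orthologous protein sets at the given expected amino-acid divergence."""
    from sagqc.comparative import ProteinSet

    if n_proteins < 1 or length < 1:
        raise ParameterError("n_proteins and length must be >= 1")
    if not 0.0 <= divergence <= 1.0:
        raise ParameterError("divergence must be in [0,1]")
    rng = child_rng(seed, "proteins")
    k = len(AA_ALPHABET)
    prots_a, prots_b = [], []
    for i in range(n_proteins):
        a = rng.integers(0, k, size=length).astype(np.uint8)
        b = _mutate(a, divergence, rng, alphabet_size=k)
        prots_a.append((f"{ids[0]}.p{i:04d}", "".join(AA_ALPHABET[c] for c in a)))
        prots_b.append((f"{ids[1]}.p{i:04d}", "".join(AA_ALPHABET[c] for c in b)))
    return ProteinSet(ids[0], prots_a), ProteinSet(ids[1], prots_b)


# ---------------------------------------------------------------------------
# truth-based measurements and IO


def gene_sequence(source: SyntheticGenome | PartialAssembly, gene: Gene) -> str:
    """Extract a gene's coding-strand sequence from its contig/fragment."""
    contigs = (source.contigs if isinstance(source, SyntheticGenome)
               else {f.fragment_id: f.sequence for f in source.fragments})
    seq = contigs[gene.contig][gene.start:gene.end]
    if gene.strand == "-":
        seq = _codes_to_str(_revcomp(_str_to_codes(seq)))
    return seq


def cross_lineage_marker_divergence(genomes_a: Sequence[SyntheticGenome],
                                    genomes_b: Sequence[SyntheticGenome]) -> float:
    """Mean per-site divergence over all cross-lineage marker pairs, by
    direct sequence comparison (independent of any stored divergence)."""
    divs = []
    for ga in genomes_a:
        seqs_a = {g.family_id: _str_to_codes(gene_sequence(ga, g))
                  for g in ga.gene_table if g.is_marker}
        for gb in genomes_b:
            for g in gb.gene_table:
                if g.is_marker and g.family_id in seqs_a:
                    sb = _str_to_codes(gene_sequence(gb, g))
                    divs.append(float(np.mean(seqs_a[g.family_id] != sb)))
    if not divs:
        raise InputError("no shared marker families between the two groups")
    return float(np.mean(divs))


def write_fasta(source: SyntheticGenome | PartialAssembly, path: str | Path) -> None:
    """Contig FASTA; headers carry genome or assembly provenance."""
    path = Path(path)
    with path.open("w") as fh:
        if isinstance(source, SyntheticGenome):
            for cid, seq in source.contigs.items():
                fh.write(f">{cid}\n")
                _write_wrapped(fh, seq)
        else:
            for frag in source.fragments:
                fh.write(f">{frag.fragment_id} source={frag.source_contig}:"
                         f"{frag.source_start}-{frag.source_end} "
                         f"lineage={frag.lineage_id}\n")
                _write_wrapped(fh, frag.sequence)


def _write_wrapped(fh, seq: str, width: int = 80) -> None:
    for i in range(0, len(seq), width):
        fh.write(seq[i:i + width] + "\n")


def write_gene_table(genes: Iterable[Gene], path: str | Path) -> None:
    """Gene truth table as TSV, 1-based inclusive coordinates."""
    with Path(path).open("w") as fh:
        fh.write("gene_id\tfamily_id\tis_marker\tcontig\tstart\tend\tstrand"
                 "\tdivergence\tlineage_id\n")
        for g in genes:
            fh.write(f"{g.gene_id}\t{g.family_id}\t{int(g.is_marker)}\t{g.contig}"
                     f"\t{g.start + 1}\t{g.end}\t{g.strand}\t{g.divergence:.6f}"
                     f"\t{g.lineage_id}\n")


def write_fastq(reads: Iterable[SimRead], path: str | Path, quality: str = "I") -> None:
    """FASTQ with fixed quality; read origin kept in the header."""
    with Path(path).open("w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id} origin={r.source_contig}:{r.start}\n"
                     f"{r.sequence}\n+\n{quality * len(r.sequence)}\n")
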