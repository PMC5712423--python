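"""Generator invariants: determinism, divergence, GC, recovery calibration."""

import numpy as np
import pytest

from sagqc.markers import gc_percent
from sagqc.synthetic import (
    InputError,
    LineageModel,
    ParameterError,
    cross_lineage_marker_divergence,
    generate_lineage_pair,
    gene_sequence,
    make_chimera,
    simulate_partial_assembly,
    simulate_reads,
)


def test_same_seed_is_byte_identical(lineage_models):
    a, b = lineage_models
    g1 = generate_lineage_pair(a, b, 0.13, 1, seed=7)
    g2 = generate_lineage_pair(a, b, 0.13, 1, seed=7)
    for x, y in zip(g1, g2):
        assert x.contigs == y.contigs
        assert x.gene_table == y.gene_table


def test_zero_divergence_gives_identical_markers(lineage_models):
    a, b = lineage_models
    a0 = LineageModel("linA", genome_size_bp=a.genome_size_bp, n_markers=a.n_markers,
                      n_accessory_genes=a.n_accessory_genes)
    b0 = LineageModel("linB", genome_size_bp=b.genome_size_bp, n_markers=b.n_markers,
                      n_accessory_genes=b.n_accessory_genes)
    ga, gb = generate_lineage_pair(a0, b0, 0.0, 1, seed=3)
    seqs_a = {g.family_id: gene_sequence(ga, g) for g in ga.gene_table if g.is_marker}
    seqs_b = {g.family_id: gene_sequence(gb, g) for g in gb.gene_table if g.is_marker}
    assert seqs_a == seqs_b


def test_requested_divergence_is_realized(small_pair):
    genomes_a, genomes_b = small_pair
    observed = cross_lineage_marker_divergence(genomes_a, genomes_b)
    # +/- 20% relative of the requested 0.35
    assert 0.28 <= observed <= 0.42


def test_divergence_near_class_level_split(lineage_models):
    a, b = lineage_models
    genomes = generate_lineage_pair(a, b, 0.13, 5, seed=11)
    observed = cross_lineage_marker_divergence(genomes[:5], genomes[5:])
    assert 0.104 <= observed <= 0.156


def test_marker_single_copy_per_complete_genome(small_pair):
    for genome in [*small_pair[0], *small_pair[1]]:
        fams = [g.family_id for g in genome.gene_table if g.is_marker]
        assert len(fams) == 50
        assert len(set(fams)) == 50


def test_gene_coordinates_within_contigs_and_non_overlapping(small_pair):
    for genome in [*small_pair[0], *small_pair[1]]:
        by_contig = {}
        for g in genome.gene_table:
            assert 0 <= g.start < g.end <= len(genome.contigs[g.contig])
            by_contig.setdefault(g.contig, []).append((g.start, g.end))
        for spans in by_contig.values():
            spans.sort()
            for (s1, e1), (s2, _) in zip(spans, spans[1:]):
                assert e1 <= s2


def test_realized_gc_tracks_target(small_pair):
    genomes_a, genomes_b = small_pair
    gc_a = gc_percent(list(genomes_a[0].contigs.values())) / 100
    gc_b = gc_percent(list(genomes_b[0].contigs.values())) / 100
    assert abs(gc_a - 0.66) < 0.02
    assert abs(gc_b - 0.70) < 0.02


def test_invalid_parameters_rejected(lineage_models):
    a, b = lineage_models
    with pytest.raises(ParameterError):
        generate_lineage_pair(a, b, 0.7, 1, seed=1)
    with pytest.raises(ParameterError):
        generate_lineage_pair(a, b, 0.1, 0, seed=1)
    with pytest.raises(ParameterError):
        LineageModel("x", gc_target=1.5)


# ---------------------------------------------------------------------------
# partial assemblies


def test_full_recovery_equals_source(small_pair):
    genome = small_pair[0][0]
    full = simulate_partial_assembly(genome, 1.0, 5, seed=9)
    assert full.total_length == genome.total_length
    assert sorted(f.sequence for f in full.fragments) == sorted(genome.contigs.values())
    assert len(full.genes) == len(genome.gene_table)


def test_zero_recovery_is_empty(small_pair):
    genome = small_pair[0][0]
    empty = simulate_partial_assembly(genome, 0.0, 5, seed=9)
    assert empty.total_length == 0
    assert empty.fragments == [] and empty.genes == []


def test_assembled_length_matches_recovery_fraction(small_pair):
    genome = small_pair[0][0]
    pa = simulate_partial_assembly(genome, 0.3, 5, seed=1)
    assert pa.total_length == round(0.3 * genome.total_length)
    assert pa.total_length <= genome.truth_genome_size_bp


def test_marker_recovery_calibration(calibration_genome):
    """Mean marker presence over 200 seeds tracks the recovery fraction."""
    presence = []
    for s in range(200):
        pa = simulate_partial_assembly(calibration_genome, 0.3, 5, s,
                                       materialize_sequence=False)
        presence.append(sum(1 for g in pa.genes if g.is_marker) / 100)
    assert abs(float(np.mean(presence)) - 0.3) < 0.03


def test_partial_assembly_determinism(small_pair):
    genome = small_pair[0][0]
    p1 = simulate_partial_assembly(genome, 0.4, 7, seed=5)
    p2 = simulate_partial_assembly(genome, 0.4, 7, seed=5)
    assert [f.sequence for f in p1.fragments] == [f.sequence for f in p2.fragments]
    assert p1.genes == p2.genes


# ---------------------------------------------------------------------------
# chimeras


def test_chimera_identity_and_additivity(small_pair, marker_db):
    genome_a = small_pair[0][0]
    genome_b = small_pair[1][0]
    a = simulate_partial_assembly(genome_a, 0.3, 5, seed=1)
    b = simulate_partial_assembly(genome_b, 0.4, 5, seed=2)
    empty = simulate_partial_assembly(genome_b, 0.0, 5, seed=3)

    with_empty = make_chimera(a, empty)
    assert with_empty.fragments == a.fragments
    assert with_empty.genes == a.genes

    combined = make_chimera(a, b)
    assert combined.total_length == a.total_length + b.total_length
    # provenance survives the round trip
    lineages = {f.fragment_id: f.lineage_id for f in combined.fragments}
    for f in a.fragments:
        assert lineages[f.fragment_id] == "linA"
    for f in b.fragments:
        assert lineages[f.fragment_id] == "linB"


def test_chimera_rejects_id_collisions(small_pair):
    genome = small_pair[0][0]
    a = simulate_partial_assembly(genome, 0.3, 5, seed=1)
    with pytest.raises(InputError):
        make_chimera(a, a)


# ---------------------------------------------------------------------------
# reads


def test_reads_are_exact_substrings_at_zero_divergence(small_pair):
    genome = small_pair[0][0]
    reads = simulate_reads(genome, 100, 150, 0.0, seed=4)
    assert len(reads) == 100
    for r in reads:
        assert genome.contigs[r.source_contig][r.start:r.start + 150] == r.sequence


def test_read_identity_matches_divergence(small_pair):
    genome = small_pair[0][0]
    reads = simulate_reads(genome, 1000, 150, 0.05, seed=4)
    identities = [
        sum(a == b for a, b in zip(
            r.sequence, genome.contigs[r.source_contig][r.start:r.start + 150])) / 150
        for r in reads
    ]
    assert abs(float(np.mean(identities)) - 0.95) < 0.01


def test_read_edge_cases(small_pair):
    genome = small_pair[0][0]
    assert simulate_reads(genome, 0, 150, 0.0, seed=1) == []
    with pytest.raises(InputError):
        simulate_reads(genome, 10, genome.total_length + 1, 0.0, seed=1)
    with pytest.raises(ParameterError):
        simulate_reads(genome, 10, 150, 0.9, seed=1)
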