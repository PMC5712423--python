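"""Chimera benchmark: pair enumeration, the two contamination measures,
and the pooled-variance t-test."""

import numpy as np
import pytest
from scipy import stats

from sagqc.chimera import (
    actual_contamination,
    default_benchmark_assemblies,
    enumerate_pairs,
    estimated_contamination,
    run_benchmark,
    two_sample_t_equal_var,
)
from sagqc.markers import MarkerSet
from sagqc.synthetic import (
    InputError,
    ParameterError,
    generate_lineage_pair,
    simulate_partial_assembly,
)


def _partials(genomes, r, base_seed):
    return [simulate_partial_assembly(g, r, 5, base_seed + i)
            for i, g in enumerate(genomes)]


# ---------------------------------------------------------------------------
# pair enumeration


def test_pair_counts(small_pair):
    a = _partials(small_pair[0] * 8, 0.2, 100)[:15]
    b = _partials(small_pair[1] * 2, 0.2, 200)[:4]
    # ids must be unique for enumeration
    for i, x in enumerate(a):
        x.assembly_id = f"A{i:02d}"
    for i, x in enumerate(b):
        x.assembly_id = f"B{i:02d}"
    assert len(enumerate_pairs(a, b)) == 60
    assert len(enumerate_pairs(a[:1], b[:1])) == 1
    pairs = enumerate_pairs(a[:3], b[:2])
    assert [(x.assembly_id, y.assembly_id) for x, y in pairs] == [
        ("A00", "B00"), ("A00", "B01"), ("A01", "B00"),
        ("A01", "B01"), ("A02", "B00"), ("A02", "B01"),
    ]


def test_enumerate_rejects_empty_groups(small_pair):
    a = _partials(small_pair[0], 0.2, 1)
    with pytest.raises(InputError):
        enumerate_pairs(a, [])
    with pytest.raises(InputError):
        enumerate_pairs([], a)


# ---------------------------------------------------------------------------
# contamination measures


def test_actual_contamination_with_empty_partner_is_zero(small_pair, marker_db):
    a = simulate_partial_assembly(small_pair[0][0], 0.3, 5, seed=1)
    empty = simulate_partial_assembly(small_pair[1][0], 0.0, 5, seed=2)
    assert actual_contamination(a, empty, marker_db) == 0.0


def test_actual_contamination_symmetry(small_pair, marker_db):
    a = simulate_partial_assembly(small_pair[0][0], 0.3, 5, seed=1)
    b = simulate_partial_assembly(small_pair[1][0], 0.4, 5, seed=2)
    assert actual_contamination(a, b, marker_db) == actual_contamination(b, a, marker_db)


def test_disjoint_marker_subsets_give_zero(small_pair, marker_db):
    a = simulate_partial_assembly(small_pair[0][0], 0.2, 5, seed=3)
    b = simulate_partial_assembly(small_pair[1][0], 0.2, 5, seed=4)
    fams_a = {g.family_id for g in a.genes if g.is_marker}
    b.genes = [g for g in b.genes if g.family_id not in fams_a]
    assert actual_contamination(a, b, marker_db) == 0.0


def test_actual_contamination_monte_carlo_matches_closed_form(
        calibration_genome, marker_db_100):
    """E[actual] = 100 * r_a * r_b under independent recovery."""
    values = []
    for s in range(500):
        a = simulate_partial_assembly(calibration_genome, 0.3, 5, 2 * s,
                                      materialize_sequence=False,
                                      assembly_id=f"a{s}")
        b = simulate_partial_assembly(calibration_genome, 0.4, 5, 2 * s + 1,
                                      materialize_sequence=False,
                                      assembly_id=f"b{s}")
        values.append(actual_contamination(a, b, marker_db_100))
    assert abs(float(np.mean(values)) - 12.0) < 1.0


def test_estimated_equals_actual_when_both_lineages_detectable(small_pair, marker_db):
    g1, g2 = small_pair[0]  # both lineage A: divergence 0 from the database
    a = simulate_partial_assembly(g1, 0.4, 5, seed=5)
    b = simulate_partial_assembly(g2, 0.5, 5, seed=6)
    assert estimated_contamination(a, b, marker_db) == \
        actual_contamination(a, b, marker_db)


def test_estimated_blind_to_diverged_lineage(small_pair, marker_db):
    a = simulate_partial_assembly(small_pair[0][0], 0.4, 5, seed=5)
    b = simulate_partial_assembly(small_pair[1][0], 0.5, 5, seed=6)
    assert estimated_contamination(a, b, marker_db) == 0.0
    assert actual_contamination(a, b, marker_db) > 0.0


def test_identity_exactly_at_threshold_is_counted(small_pair):
    db_at = MarkerSet("at", tuple(f"M{i:04d}" for i in range(50)),
                      detection_identity_threshold=0.70)
    a = simulate_partial_assembly(small_pair[0][0], 0.5, 5, seed=7)
    b = simulate_partial_assembly(small_pair[0][1], 0.5, 5, seed=8)
    # force partner genes to sit exactly at the threshold boundary
    from dataclasses import replace
    b.genes = [replace(g, divergence=0.30) for g in b.genes]
    est = estimated_contamination(a, b, db_at)
    act = actual_contamination(a, b, db_at)
    assert est == act  # inclusive >= keeps boundary genes visible


# ---------------------------------------------------------------------------
# t-test


def test_t_test_identical_samples():
    assert two_sample_t_equal_var([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == (0.0, 1.0)


def test_t_test_hand_computed_example():
    t, p = two_sample_t_equal_var([1, 2, 3], [4, 5, 6])
    assert t == pytest.approx(-3.6742346141747673, abs=1e-9)
    assert p == pytest.approx(0.021311641128756727, abs=1e-6)


def test_t_test_antisymmetry():
    t1, p1 = two_sample_t_equal_var([1, 2, 3], [4, 5, 7])
    t2, p2 = two_sample_t_equal_var([4, 5, 7], [1, 2, 3])
    assert t1 == -t2 and p1 == p2


def test_t_test_agrees_with_independent_implementation():
    rng = np.random.default_rng(0)
    for _ in range(5):
        x = rng.normal(0, 1, size=12)
        y = rng.normal(0.5, 1, size=9)
        t, p = two_sample_t_equal_var(x, y)
        ref = stats.ttest_ind(x, y, equal_var=True)
        assert abs(t - ref.statistic) < 1e-9
        assert abs(p - ref.pvalue) < 1e-9


def test_t_test_degenerate_cases():
    with pytest.raises(ParameterError):
        two_sample_t_equal_var([1.0], [2.0, 3.0])
    with pytest.raises(ParameterError):
        two_sample_t_equal_var([1.0, 1.0], [2.0, 2.0])  # zero variance, unequal means


# ---------------------------------------------------------------------------
# full benchmark


def test_benchmark_reproduces_estimator_blindness(tmp_path):
    group_a, group_b, db = default_benchmark_assemblies(
        seed=1, genome_size_bp=500_000, n_accessory_genes=200)
    summary, per_pair = run_benchmark(group_a, group_b, db, output_dir=tmp_path)
    assert summary.n_pairs == 60
    assert summary.mean_estimated < summary.mean_actual
    assert summary.p_value < 0.001
    # estimated never exceeds actual when lineage B is below threshold
    assert (per_pair["estimated_contamination_percent"]
            <= per_pair["actual_contamination_percent"]).all()
    assert (tmp_path / "chimera_pairs.tsv").exists()
    assert (tmp_path / "chimera_summary.json").exists()


def test_benchmark_no_blindness_at_zero_divergence():
    group_a, group_b, db = default_benchmark_assemblies(
        seed=2, divergence_b=0.0, genome_size_bp=400_000,
        n_accessory_genes=150, n_a=6, n_b=3)
    summary, _ = run_benchmark(group_a, group_b, db)
    assert summary.mean_estimated == pytest.approx(summary.mean_actual)
    assert summary.p_value > 0.9
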