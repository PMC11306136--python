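"""Discretization, plug-in entropy/MI, null-tail calibration, bipartite
edge inference."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cadnet.coexpression import (
    CalibrationError,
    DiscretizedProfile,
    calibrate_null,
    default_n_bins,
    discretize,
    entropy,
    infer_coexpression,
    mutual_information,
    threshold_from_null,
)
from cadnet.variants import SeedGeneSet


def _profile_from_counts(joint: np.ndarray):
    """Label vectors realizing a given 2-D contingency table."""
    a, b = [], []
    for i, j in np.ndindex(*joint.shape):
        a.extend([i] * joint[i, j])
        b.extend([j] * joint[i, j])
    return (
        DiscretizedProfile("a", np.array(a), joint.shape[0]),
        DiscretizedProfile("b", np.array(b), joint.shape[1]),
    )


def _direct_mi(joint: np.ndarray) -> float:
    """Oracle: direct summation of sum p log(p / (p_row p_col))."""
    p = joint / joint.sum()
    rows = p.sum(axis=1)
    cols = p.sum(axis=0)
    total = 0.0
    for i, j in np.ndindex(*p.shape):
        if p[i, j] > 0:
            total += p[i, j] * math.log(p[i, j] / (rows[i] * cols[j]))
    return total


def test_equal_frequency_binning_at_240_by_15():
    rng = np.random.default_rng(0)
    prof = discretize(rng.normal(size=240), 15)
    assert np.bincount(prof.bins).tolist() == [16] * 15


def test_constant_vector_collapses_to_single_bin():
    prof = discretize(np.ones(50), 5)
    assert set(prof.bins) == {0}
    assert entropy(prof) == 0.0


def test_ties_break_by_stable_sample_order():
    prof = discretize(np.array([1.0, 1.0, 0.0, 0.0]), 2)
    assert prof.bins.tolist() == [1, 1, 0, 0]


@given(st.lists(st.integers(-1000, 1000), min_size=6, max_size=60, unique=True))
def test_monotone_transform_leaves_bins_unchanged(values):
    v = np.array(values, dtype=float) / 100.0
    base = discretize(v, 3).bins
    transformed = discretize(np.exp(v), 3).bins
    assert (base == transformed).all()


def test_entropy_known_values():
    uniform = discretize(np.arange(8, dtype=float), 4)
    assert entropy(uniform) == pytest.approx(math.log(4))
    half_quarter = DiscretizedProfile("g", np.array([0, 0, 1, 2]), 3)
    assert entropy(half_quarter) == pytest.approx(1.5 * math.log(2))


def test_mi_of_independent_and_diagonal_tables():
    a, b = _profile_from_counts(np.array([[1, 1], [1, 1]]))
    assert mutual_information(a, b).mi == pytest.approx(0.0, abs=1e-12)
    a, b = _profile_from_counts(np.array([[2, 0], [0, 2]]))
    assert mutual_information(a, b).mi == pytest.approx(math.log(2))


def test_mi_self_equals_entropy_and_symmetry():
    rng = np.random.default_rng(1)
    a = discretize(rng.normal(size=100), 8)
    b = discretize(rng.normal(size=100), 8)
    assert mutual_information(a, a).mi == entropy(a)
    ab, ba = mutual_information(a, b), mutual_information(b, a)
    assert ab.mi == ba.mi
    assert ab.mi >= 0
    assert ab.mi <= min(ab.entropy_a, ab.entropy_b) + 1e-12
    assert ab.mi == pytest.approx(ab.entropy_a + ab.entropy_b - ab.joint_entropy)


def test_mi_matches_direct_summation_oracle():
    rng = np.random.default_rng(2)
    for _ in range(100):
        shape = rng.integers(2, 7, size=2)
        joint = rng.integers(0, 6, size=shape)
        if joint.sum() == 0:
            joint[0, 0] = 1
        a, b = _profile_from_counts(joint)
        assert mutual_information(a, b).mi == pytest.approx(
            max(0.0, _direct_mi(joint)), abs=1e-10
        )


def test_length_mismatch_raises():
    a = discretize(np.arange(10, dtype=float), 2)
    b = discretize(np.arange(12, dtype=float), 2)
    with pytest.raises(ValueError, match="length mismatch"):
        mutual_information(a, b)


def test_threshold_monotone_in_p_target():
    rng = np.random.default_rng(3)
    null = rng.exponential(0.05, size=20_000)
    thresholds = [
        threshold_from_null(null, p, 0.1)[2] for p in (1e-4, 1e-8, 1e-15)
    ]
    assert thresholds == sorted(thresholds)


def test_threshold_at_resolution_limit_matches_expected_maximum():
    """At p_target = 1/n the fitted cutoff sits at the top of the null
    range: close to the expected maximum scale*ln(n) of n exponential
    draws (the realized maximum itself fluctuates Gumbel-wide)."""
    rng = np.random.default_rng(4)
    scale = 0.05
    null = rng.exponential(scale, size=50_000)
    _, _, thr = threshold_from_null(null, 1.0 / null.size, 0.1)
    assert thr == pytest.approx(scale * math.log(null.size), rel=0.05)
    assert np.quantile(null, 0.999) < thr < 1.5 * null.max()


def test_degenerate_null_raises_calibration_error():
    with pytest.raises(CalibrationError):
        threshold_from_null(np.ones(1000), 1e-6, 0.1)


def test_calibration_reproducible_under_seed(expression):
    expr = expression.iloc[:40]
    c1 = calibrate_null(expr, n_permutations=2000, rng_seed=5)
    c2 = calibrate_null(expr, n_permutations=2000, rng_seed=5)
    assert c1.mi_threshold == c2.mi_threshold
    assert (c1.null_mi == c2.null_mi).all()
    assert c1.slope < 0
    assert c1.extrapolated  # 1e-15 is far below 1/2000


def test_data_processing_inequality_on_noisy_chains():
    """Markov chain x -> y -> z: MI(x, z) should not exceed MI(x, y)."""
    rng = np.random.default_rng(6)
    mi_xy, mi_xz = [], []
    for _ in range(20):
        x = rng.normal(size=240)
        y = x + rng.normal(scale=0.5, size=240)
        z = y + rng.normal(scale=0.5, size=240)
        px, py, pz = (discretize(v, 15) for v in (x, y, z))
        mi_xy.append(mutual_information(px, py).mi)
        mi_xz.append(mutual_information(px, pz).mi)
    assert np.median(mi_xz) <= np.median(mi_xy)


def test_inference_is_bipartite_and_skips_absent_seeds(expression, ground_truth, caplog):
    expr = expression.iloc[:60]
    seeds = SeedGeneSet(genes=set(ground_truth["seed_genes"]) | {"NOT_A_GENE"})
    calib = calibrate_null(expr, n_permutations=5000, rng_seed=0)
    edges = infer_coexpression(expr, seeds, calib)
    seed_set = set(ground_truth["seed_genes"])
    for e in edges:
        assert e.gene_a in seed_set or e.gene_b in seed_set
        assert e.kind == "coexpression"
        assert 0 < e.score <= 1
    assert "NOT_A_GENE" not in {g for e in edges for g in (e.gene_a, e.gene_b)}


def test_default_bin_count_follows_sqrt_rule():
    assert default_n_bins(240) == 15
    assert default_n_bins(4) == 2
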