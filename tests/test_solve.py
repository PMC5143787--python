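"""Solver tests: Kaczmarz sweeps, Hoyer sparsity, thresholding, SCP driver."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from scpkaczmarz import (
    DegenerateInputError,
    InvalidParameterError,
    ShapeError,
    SolverConfig,
    apply_preconditioner,
    classical_kaczmarz,
    compute_preconditioner,
    find_beta,
    hoyer_sparsity,
    kaczmarz_sweep,
    make_random_system,
    scp_kaczmarz,
    sparsity_threshold,
    wanted_sparsity_from_fraction,
)


# ---------------------------------------------------------------- sweeps


def test_sweep_identity_rows_solves_exactly():
    x = kaczmarz_sweep(np.eye(2), np.array([1.0, 2.0]), np.zeros(2))
    np.testing.assert_array_equal(x, [1.0, 2.0])


def test_sweep_two_rows_hand_computed():
    """Rows (1,0), (1,1) with y = (1,2): two successive orthogonal projections
    from the origin land on (1.5, 0.5)."""
    B = np.array([[1.0, 0.0], [1.0, 1.0]])
    x = kaczmarz_sweep(B, np.array([1.0, 2.0]), np.zeros(2))
    np.testing.assert_allclose(x, [1.5, 0.5], rtol=1e-14)


def test_sweep_last_row_projection_is_exact(rng):
    """Immediately after its update, each row's equation holds; the final row's
    residual is therefore zero at the end of the sweep."""
    B = rng.normal(size=(5, 8))
    y = rng.normal(size=5)
    x = kaczmarz_sweep(B, y, rng.normal(size=8))
    assert abs(B[-1] @ x - y[-1]) < 1e-10 * np.linalg.norm(y)


def test_one_sweep_solves_preconditioned_consistent_system(rng):
    A = rng.normal(size=(20, 50))
    x0 = rng.normal(size=50)
    system = apply_preconditioner(compute_preconditioner(A, loading=0.0), A @ x0)
    x = kaczmarz_sweep(system.B, system.y, np.zeros(50))
    assert np.linalg.norm(system.B @ x - system.y) < 1e-8


def test_sweep_errors():
    with pytest.raises(DegenerateInputError):
        kaczmarz_sweep(np.zeros((2, 3)), np.zeros(2), np.zeros(3))
    with pytest.raises(ShapeError):
        kaczmarz_sweep(np.eye(2), np.zeros(3), np.zeros(2))


# ---------------------------------------------------------------- sparsity


def test_hoyer_reference_values():
    x = np.zeros(300)
    x[7] = 3.2
    assert hoyer_sparsity(x) == pytest.approx(1.0, abs=1e-12)
    assert hoyer_sparsity(np.full(64, 0.5)) == pytest.approx(0.0, abs=1e-12)
    x10 = np.r_[np.ones(10), np.zeros(290)]
    expected = (math.sqrt(300) - math.sqrt(10)) / (math.sqrt(300) - 1)
    assert hoyer_sparsity(x10) == pytest.approx(expected, rel=1e-14)
    assert round(hoyer_sparsity(x10), 2) == 0.87


def test_hoyer_errors():
    with pytest.raises(DegenerateInputError):
        hoyer_sparsity(np.zeros(10))
    with pytest.raises(InvalidParameterError):
        hoyer_sparsity(np.array([1.0]))


@settings(derandomize=True, max_examples=60)
@given(
    st.lists(st.floats(-1e6, 1e6, allow_nan=False), min_size=2, max_size=60).filter(
        lambda v: any(abs(x) > 1e-6 for x in v)
    )
)
def test_hoyer_range_property(values):
    s = hoyer_sparsity(np.array(values))
    assert -1e-12 <= s <= 1.0 + 1e-12


def test_threshold_examples():
    np.testing.assert_array_equal(
        sparsity_threshold(np.array([2.0, -1.0, 0.0]), 0.0), [2.0, 0.0, 0.0]
    )
    np.testing.assert_array_equal(
        sparsity_threshold(np.array([5.0, 1.0, 0.1]), 0.5), [5.0, 0.0, 0.0]
    )
    np.testing.assert_array_equal(
        sparsity_threshold(np.array([3.0, 3.0, 1.0]), 1.0), [3.0, 3.0, 0.0]
    )
    with pytest.raises(InvalidParameterError):
        sparsity_threshold(np.array([1.0]), 1.5)


def _find_beta_oracle(x, psi):
    """Exhaustive search: apply every candidate cutoff explicitly and score the
    thresholded vector with hoyer_sparsity (independent of the cumulative-norm
    route used by find_beta)."""
    pos = np.unique(x[x > 0])[::-1]
    best = (np.inf, None)
    for cutoff in pos:
        xt = np.where(x >= cutoff, x, 0.0)
        obj = abs(hoyer_sparsity(xt) - psi)
        if obj < best[0] - 1e-15:
            best = (obj, xt)
    return best


@pytest.mark.parametrize("seed", range(12))
@pytest.mark.parametrize("psi", [0.3, 0.6, 0.9, 1.0])
def test_find_beta_matches_exhaustive_search(seed, psi):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(5, 120))
    x = rng.normal(size=n)
    if seed % 3 == 0:  # inject ties
        x[: n // 2] = np.round(x[: n // 2], 1)
    beta, xt = find_beta(x, psi)
    obj_oracle, _ = _find_beta_oracle(x, psi)
    assert abs(hoyer_sparsity(xt) - psi) == pytest.approx(obj_oracle, abs=1e-12)
    assert 0.0 < beta <= 1.0
    # xt is x with entries below the cutoff zeroed: every kept entry is x's
    # value, and no dropped positive exceeds the smallest kept one.
    kept = xt != 0
    np.testing.assert_array_equal(xt[kept], x[kept])
    if np.any(~kept & (x > 0)):
        assert x[~kept & (x > 0)].max() <= xt[kept].min()


def test_find_beta_degenerate_and_trivial_cases():
    x = np.array([10.0, 0.1, 0.05, 0.0])
    beta, xt = find_beta(x, 1.0)
    assert hoyer_sparsity(xt) == pytest.approx(1.0, abs=1e-12)
    assert np.count_nonzero(xt) == 1
    # psi equal to the sparsity of the full positive part keeps every positive.
    full = np.where(x > 0, x, 0.0)
    beta, xt = find_beta(x, hoyer_sparsity(full))
    np.testing.assert_array_equal(xt, full)
    with warnings.catch_warnings(record=True) as rec:
        warnings.simplefilter("always")
        beta, xt = find_beta(np.array([-1.0, -2.0]), 0.5)
    assert rec and np.all(xt == 0) and beta == 1.0
    with pytest.raises(DegenerateInputError):
        find_beta(np.zeros(4), 0.5)
    with pytest.raises(InvalidParameterError):
        find_beta(np.ones(4), 0.0)


def test_wanted_sparsity_from_fraction_values():
    assert wanted_sparsity_from_fraction(1.0, 300) == 0.0
    assert wanted_sparsity_from_fraction(1 / 300, 300) == pytest.approx(1.0)
    expected = (math.sqrt(300) - math.sqrt(10)) / (math.sqrt(300) - 1)
    assert wanted_sparsity_from_fraction(10 / 300, 300) == pytest.approx(expected)
    with pytest.raises(InvalidParameterError):
        wanted_sparsity_from_fraction(0.0, 300)
    with pytest.raises(InvalidParameterError):
        wanted_sparsity_from_fraction(0.5, 1)


# ---------------------------------------------------------------- drivers


def test_config_validation():
    with pytest.raises(InvalidParameterError):
        SolverConfig(wanted_sparsity=0.0)
    with pytest.raises(InvalidParameterError):
        SolverConfig(max_iterations=0)
    with pytest.raises(InvalidParameterError):
        SolverConfig(access_order="random")


def test_single_iteration_accounting(rng):
    A = rng.normal(size=(8, 12))
    phi = rng.normal(size=8)
    cfg = SolverConfig(max_iterations=1, tolerance=0.0)
    x, trace = scp_kaczmarz(A, phi, cfg)
    assert len(trace) == 1 and trace.iteration == [1]
    assert np.all(x >= 0)  # one sweep followed by one threshold


def test_update_norm_stop_rule(rng):
    """A consistent preconditioned system converges in one sweep, so the
    update-norm rule stops the unconstrained driver at the second sweep."""
    A = rng.normal(size=(10, 30))
    phi = A @ rng.normal(size=30)
    cfg = SolverConfig(
        max_iterations=50, tolerance=1e-10, apply_sparsity_constraint=False
    )
    _, trace = scp_kaczmarz(A, phi, cfg)
    assert len(trace) == 2
    assert trace.update_norm[-1] < 1e-10


def test_scp_reduces_to_classical_baseline(rng):
    """Constraint off and W = I: bit-identical iterates to the classical solver."""
    A = rng.normal(size=(12, 20))
    phi = rng.normal(size=12)
    cfg = SolverConfig(
        max_iterations=7, tolerance=0.0, apply_sparsity_constraint=False,
        record_iterates=True,
    )
    x1, t1 = scp_kaczmarz(A, phi, cfg, precondition=False)
    x2, t2 = classical_kaczmarz(A, phi, cfg)
    assert np.array_equal(x1, x2)
    for a, b in zip(t1.iterates, t2.iterates):
        assert np.array_equal(a, b)


def test_classical_converges_to_direct_solution():
    A, _, phi = make_random_system(25, 25, "geometric", seed=2, decay=0.9)
    cfg = SolverConfig(max_iterations=2000, tolerance=1e-12)
    x, _ = classical_kaczmarz(A, phi, cfg)
    assert np.linalg.norm(x - np.linalg.solve(A, phi)) < 1e-6


def test_classical_converges_to_minimum_norm_solution():
    A, _, phi = make_random_system(20, 40, "geometric", seed=4, decay=0.9)
    cfg = SolverConfig(max_iterations=3000, tolerance=1e-13)
    x, _ = classical_kaczmarz(A, phi, cfg)
    assert np.linalg.norm(x - np.linalg.pinv(A) @ phi) < 1e-6


def test_scp_recovers_sparse_ground_truth():
    """Noiseless consistent system with a sparse nonnegative truth: the SCP
    iteration recovers support and values when psi matches the truth."""
    A, x_true, phi = make_random_system(60, 100, "flat", seed=5, support_size=5)
    psi = hoyer_sparsity(x_true)
    cfg = SolverConfig(wanted_sparsity=psi, max_iterations=200, tolerance=1e-10)
    x, trace = scp_kaczmarz(A, phi, cfg, x_true=x_true)
    assert trace.delta[-1] < 0.05
    recovered = set(np.flatnonzero(x > 1e-8 * x.max()))
    assert recovered == set(np.flatnonzero(x_true))
    assert trace.sparsity[-1] == pytest.approx(psi, abs=0.05)


def test_scp_iterates_nonnegative_with_matched_sparsity(rng):
    A, x_true, phi = make_random_system(30, 80, "geometric", seed=11, decay=0.8)
    cfg = SolverConfig(
        wanted_sparsity=0.85, max_iterations=25, tolerance=0.0, record_iterates=True
    )
    _, trace = scp_kaczmarz(A, phi, cfg)
    assert trace.iterates and all(np.all(it >= 0) for it in trace.iterates)
    for s in trace.sparsity:
        assert 0.0 <= s <= 1.0


def test_trace_dataframe_columns(rng):
    A = rng.normal(size=(6, 9))
    _, trace = scp_kaczmarz(A, rng.normal(size=6), SolverConfig(max_iterations=3, tolerance=0.0))
    df = trace.to_dataframe()
    assert list(df.columns) == ["k", "delta", "dice", "sparsity", "update_norm", "beta"]
    assert len(df) == 3
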