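"""Moment estimators, binomial noise inversion, gradient matching, bootstrap."""

import numpy as np
import pytest

import reactionet as rn
from reactionet.simulate import SnapshotSeries


def series_from_matrices(mats, times=None):
    times = np.arange(len(mats), dtype=float) if times is None else np.asarray(times)
    n = mats[0].shape[1]
    return SnapshotSeries(times, [np.asarray(m) for m in mats], [f"X{i}" for i in range(n)])


def test_two_cell_mean_and_variance():
    x = np.array([[0], [2]])
    s = series_from_matrices([x, x, x])
    m = rn.empirical_moments(s, max_order=2)
    assert m.values[(0,)][0] == 1.0
    assert m.values[(0, 0)][0] == 2.0  # unbiased: ((0-1)^2 + (2-1)^2)/(2-1)


def test_identical_cells_zero_central_moments():
    x = np.full((6, 2), 7)
    s = series_from_matrices([x, x, x])
    m = rn.empirical_moments(s, max_order=3)
    for key, v in m.values.items():
        if len(key) >= 2:
            np.testing.assert_allclose(v, 0.0)


def test_symmetric_sample_zero_third_moment():
    x = np.array([[1], [2], [2], [3], [0], [4]])
    s = series_from_matrices([x, x, x])
    m = rn.empirical_moments(s, max_order=3)
    np.testing.assert_allclose(m.values[(0, 0, 0)], 0.0, atol=1e-12)


def test_too_few_cells_rejected():
    x = np.array([[1], [2], [3]])
    s = series_from_matrices([x, x, x])
    with pytest.raises(ValueError):
        rn.empirical_moments(s, max_order=3)  # order 3 needs >= 4 cells


def test_noise_correction_identity_at_p1(enzymatic_snapshots):
    m = rn.empirical_moments(enzymatic_snapshots, max_order=3)
    mc = rn.correct_binomial_noise(m, 1.0)
    for k in m.values:
        np.testing.assert_array_equal(mc.values[k], m.values[k])


def test_noise_correction_first_two_orders_closed_form():
    """E[X] = E[X_obs]/p and Var[X] = (Var[X_obs] - p(1-p)E[X])/p^2."""
    t = np.array([0.0, 1.0, 2.0])
    vals = {(0,): np.full(3, 2.0), (0, 0): np.full(3, 3.0)}
    m = rn.MomentTimeSeries(t, vals, np.full(3, 100), 2)
    mc = rn.correct_binomial_noise(m, 0.5)
    np.testing.assert_allclose(mc.values[(0,)], 4.0)
    np.testing.assert_allclose(mc.values[(0, 0)], (3.0 - 0.25 * 4.0) / 0.25)


def test_noise_correction_invalid_p(enzymatic_snapshots):
    m = rn.empirical_moments(enzymatic_snapshots, max_order=2)
    with pytest.raises(ValueError):
        rn.correct_binomial_noise(m, 0.0)


def test_noise_correction_clips_negative_variance():
    t = np.array([0.0, 1.0, 2.0])
    # Var_obs far below the binomial-noise floor p(1-p)E[X] -> negative estimate
    vals = {(0,): np.full(3, 5.0), (0, 0): np.full(3, 0.1)}
    m = rn.MomentTimeSeries(t, vals, np.full(3, 100), 2)
    mc = rn.correct_binomial_noise(m, 0.1)
    assert np.all(mc.values[(0, 0)] == 0.0)


@pytest.mark.parametrize("p", [0.05, 0.1, 1.0])
def test_noise_correction_consistency_orders_1_to_3(enzymatic_snapshots, p):
    """simulate -> corrupt(p) -> estimate -> correct recovers clean-data
    estimates within 3 bootstrap SDs for the vast majority of entries."""
    clean = rn.empirical_moments(enzymatic_snapshots, max_order=3)
    noisy = rn.apply_binomial_noise(enzymatic_snapshots, p, seed=17)
    corrected = rn.correct_binomial_noise(rn.empirical_moments(noisy, max_order=3), p)
    eqs = rn.derive_moment_equations(
        rn.fixture_network("enzymatic"), max_order=1
    )  # light design side; moments SDs are what we need
    sd_m, _, _ = rn.bootstrap_variability(noisy, eqs, B=60, seed=17, p=p, method="fds", max_order=3)
    sd_c, _, _ = rn.bootstrap_variability(
        enzymatic_snapshots, eqs, B=60, seed=18, p=None, method="fds", max_order=3
    )
    total = ok = 0
    for key in clean.values:
        tol = 3 * np.sqrt(sd_m[key] ** 2 + sd_c[key] ** 2) + 1e-9
        ok += int(np.sum(np.abs(corrected.values[key] - clean.values[key]) <= tol))
        total += len(clean.time_points)
    assert ok / total >= 0.9


def test_gradients_constant_and_linear_series():
    t = np.linspace(0, 10, 7)
    const = {(0,): np.full(7, 5.0)}
    lin = {(0,): 2.5 * t + 1}
    for method in ("spline", "fds"):
        g0 = rn.estimate_gradients(rn.MomentTimeSeries(t, const, np.full(7, 10), 1), method)
        np.testing.assert_allclose(g0.values[(0,)], 0.0, atol=1e-10)
        g1 = rn.estimate_gradients(rn.MomentTimeSeries(t, lin, np.full(7, 10), 1), method)
        np.testing.assert_allclose(g1.values[(0,)], 2.5, rtol=1e-9)


def test_spline_beats_fds_on_exponential_decay():
    """On e^{-t} sampled at 13 points the spline derivative is within a few
    percent at interior points, and FDS is worse overall."""
    t = np.linspace(0, 4, 13)
    m = rn.MomentTimeSeries(t, {(0,): np.exp(-t)}, np.full(13, 10), 1)
    true = -np.exp(-t)
    gs = rn.estimate_gradients(m, "spline").values[(0,)]
    gf = rn.estimate_gradients(m, "fds").values[(0,)]
    interior = slice(2, 11)
    assert np.max(np.abs((gs[interior] - true[interior]) / true[interior])) < 0.02
    assert np.linalg.norm(gf - true) > np.linalg.norm(gs - true)


def test_smooth_requires_trajectories(enzymatic_snapshots):
    m = rn.empirical_moments(enzymatic_snapshots, max_order=2)
    with pytest.raises(ValueError):
        rn.estimate_gradients(m, "smooth")


def test_bootstrap_reproducible_and_clt_scaling(death_network):
    t = np.array([0.5, 1.0, 1.5, 2.0, 3.0])
    eqs = rn.derive_moment_equations(death_network, max_order=2)
    s_small = rn.ssa_simulate(death_network, [100], t, 500, seed=21)
    s_big = rn.ssa_simulate(death_network, [100], t, 2000, seed=22)
    sd_a = rn.bootstrap_variability(s_small, eqs, B=100, seed=5)[0]
    sd_a2 = rn.bootstrap_variability(s_small, eqs, B=100, seed=5)[0]
    np.testing.assert_array_equal(sd_a[(0,)], sd_a2[(0,)])
    sd_b = rn.bootstrap_variability(s_big, eqs, B=100, seed=5)[0]
    ratio = np.median(sd_b[(0,)] / sd_a[(0,)])
    assert 0.4 <= ratio <= 0.6  # quadrupling cells halves the SD of the mean


def test_bootstrap_rejects_tiny_B(enzymatic_snapshots, death_network):
    eqs = rn.derive_moment_equations(death_network, max_order=2)
    with pytest.raises(ValueError):
        rn.bootstrap_variability(enzymatic_snapshots, eqs, B=1, seed=0)
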