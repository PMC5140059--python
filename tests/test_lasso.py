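"""Two-step sparse regression: FG whitening, ADMM lasso path, selection."""

import itertools

import numpy as np
import pytest

import reactionet as rn
from reactionet.lasso import (
    FGResult,
    RegressionSystem,
    bounded_nnls,
    information_criterion,
    lambda_max,
    select_model,
    step1_fg,
    step2_adaptive_relaxed_lasso,
)


def make_system(A, b, known=None, sd_b=None, sd_A=None, n_time=None):
    """Wrap a plain (A, b) into a RegressionSystem with mean-row labels."""
    n, L = A.shape
    labels = [((0,), float(j)) for j in range(n)]
    return RegressionSystem(
        b, A,
        np.ones(n) if sd_b is None else sd_b,
        np.ones((n, L)) if sd_A is None else sd_A,
        labels, list(range(L)), 1,
        np.zeros(L, bool) if known is None else known,
    )


def run_two_step(A, b, known=None, seed=0, **kw):
    sys_ = make_system(A, b, known)
    fg = step1_fg(sys_)
    path = step2_adaptive_relaxed_lasso(fg, sys_.row_labels, sys_.known_mask, seed=seed, **kw)
    return sys_, fg, path


def planted_system(n_rows=40, L=6, sparsity=2, seed=0, noise=0.0):
    rng = np.random.default_rng(seed)
    A = rng.uniform(0.5, 2.0, size=(n_rows, L)) * rng.integers(0, 2, size=(n_rows, L))
    A += 0.1 * rng.uniform(size=(n_rows, L))
    k = np.zeros(L)
    k[rng.choice(L, sparsity, replace=False)] = rng.uniform(0.5, 2.0, sparsity)
    b = A @ k + noise * rng.normal(size=n_rows)
    return A, b, k


def test_soft_threshold_closed_form():
    """Single unit column, a'b = 3, ktilde = 1, lambda = 2: the penalised
    optimum of (3-k)^2 + 2k is k = 2; the relaxed refit restores k = 3."""
    A = np.eye(3)[:, :1]
    b = np.array([3.0, 0.0, 0.0])
    fg = FGResult(
        k_ls=np.array([3.0]), sigma2_eps=np.ones(3), k_fg=np.array([3.0]),
        support=np.array([0]), weights=np.array([1.0]), b_scaled=b, A_scaled=A,
    )
    labels = [((0,), float(j)) for j in range(3)]
    path = step2_adaptive_relaxed_lasso(
        fg, labels, np.zeros(1, bool), n_lambda=1, folds=3, seed=0
    )
    # shrink the grid to the single value lambda = 2 by monkeypatched solve
    from reactionet.lasso import _admm_weighted_l1

    z, *_ = _admm_weighted_l1(A, b, 2.0, np.array([1.0]), np.zeros(1))
    assert z[0] == pytest.approx(2.0, abs=1e-6)
    k_relaxed = bounded_nnls(A, b)
    assert k_relaxed[0] == pytest.approx(3.0, abs=1e-12)


def test_lambda_max_zeroes_everything():
    A, b, _ = planted_system(seed=3, noise=0.05)
    ktilde = np.ones(A.shape[1])
    lmax = lambda_max(A, b, ktilde, np.zeros(A.shape[1], bool))
    np.testing.assert_allclose(lmax, 2 * np.max(ktilde * (A.T @ b)))
    from reactionet.lasso import _admm_weighted_l1

    z, *_ = _admm_weighted_l1(A, b, lmax * 1.001, 1 / ktilde, np.zeros(A.shape[1]))
    np.testing.assert_allclose(z, 0.0, atol=1e-7)


def test_lambda_zero_equals_nnls():
    A, b, _ = planted_system(seed=4, noise=0.05)
    from reactionet.lasso import _admm_weighted_l1

    z, *_ = _admm_weighted_l1(A, b, 0.0, np.ones(A.shape[1]), np.zeros(A.shape[1]))
    k_nnls = bounded_nnls(A, b)
    np.testing.assert_allclose(z, k_nnls, atol=1e-5)


def test_fg_recovers_consistent_system():
    """Noiseless b = A k_true with unit SDs: NNLS is exact and the support
    contains the truth."""
    A, b, k_true = planted_system(seed=5, noise=0.0)
    sys_ = make_system(A, b)
    fg = step1_fg(sys_)
    np.testing.assert_allclose(fg.k_fg, k_true, atol=1e-8)
    assert set(np.flatnonzero(k_true)) <= set(fg.support)


def test_fg_uniform_sd_matches_plain_nnls():
    A, b, _ = planted_system(seed=6, noise=0.1)
    sys_u = make_system(A, b, sd_b=np.full(len(b), 2.0), sd_A=np.zeros_like(A))
    fg = step1_fg(sys_u)
    k_plain = bounded_nnls(A, b)
    np.testing.assert_allclose(fg.k_fg, k_plain, atol=1e-9)


def test_whitening_uses_first_order_pilot():
    """Residual variances combine sd_b and sd_A via the pilot rates."""
    A, b, k_true = planted_system(seed=7, noise=0.0)
    sd_b = np.full(len(b), 0.5)
    sd_A = np.full(A.shape, 0.2)
    sys_ = make_system(A, b, sd_b=sd_b, sd_A=sd_A)
    fg = step1_fg(sys_)
    expect = sd_b**2 + (sd_A**2) @ (fg.k_ls**2)
    np.testing.assert_allclose(fg.sigma2_eps, expect)


def test_exhaustive_bic_oracle_equivalence():
    """On small noiseless systems the two-step procedure returns the same
    support as exhaustive best-BIC enumeration over all 2^L subsets."""
    for seed in range(4):
        A, b, k_true = planted_system(n_rows=30, L=5, sparsity=2, seed=10 + seed)
        best, best_bic = None, np.inf
        for r in range(len(k_true) + 1):
            for sub in itertools.combinations(range(len(k_true)), r):
                if sub:
                    k = bounded_nnls(A[:, list(sub)], b)
                    rss = float(np.sum((b - A[:, list(sub)] @ k) ** 2))
                else:
                    rss = float(b @ b)
                bic = information_criterion(rss, len(b), r)
                if bic < best_bic - 1e-9:
                    best, best_bic = set(sub), bic
        sys_, fg, path = run_two_step(A, b, seed=seed)
        sel = select_model(path)
        assert set(sel.selected.tolist()) == best == set(np.flatnonzero(k_true))


def test_collinear_duplicate_never_improves_bic():
    A, b, k_true = planted_system(n_rows=30, L=5, sparsity=2, seed=30)
    truth = np.flatnonzero(k_true)
    k0 = bounded_nnls(A[:, truth], b)
    rss0 = float(np.sum((b - A[:, truth] @ k0) ** 2))
    bic0 = information_criterion(rss0, len(b), len(truth))
    dup = list(truth) + [truth[0]]
    k1 = bounded_nnls(A[:, dup], b)
    rss1 = float(np.sum((b - A[:, dup] @ k1) ** 2))
    bic1 = information_criterion(rss1, len(b), len(dup))
    assert bic1 >= bic0


def test_prior_knowledge_always_selected():
    A, b, k_true = planted_system(n_rows=30, L=6, sparsity=2, seed=41, noise=0.05)
    known = np.zeros(6, bool)
    dead = int(np.flatnonzero(k_true == 0)[0])
    known[dead] = True  # prior knowledge on a reaction absent from the truth
    sys_, fg, path = run_two_step(A, b, known=known, seed=1)
    sel = select_model(path)
    assert dead in sel.selected
    # at the largest penalty only prior-knowledge coefficients are active
    assert set(np.flatnonzero(path.penalized[0] > 0)) <= set(
        np.flatnonzero(path.known_in_phi)
    )


def test_path_active_set_monotone_in_lambda():
    A, b, _ = planted_system(n_rows=40, L=6, sparsity=3, seed=50, noise=0.02)
    sys_, fg, path = run_two_step(A, b, seed=2)
    sizes = [(p > 0).sum() for p in path.penalized]
    diffs = np.diff(sizes)  # grid is decreasing in lambda: sizes non-decreasing
    assert np.sum(diffs < 0) <= 1  # allow one ADMM borderline flip


def test_stability_frequencies_in_unit_interval():
    A, b, _ = planted_system(n_rows=40, L=6, sparsity=2, seed=51, noise=0.05)
    sys_, fg, path = run_two_step(A, b, seed=3)
    assert np.all(path.stability_freq >= 0) and np.all(path.stability_freq <= 1)


def test_single_lambda_path_selected():
    A, b, k_true = planted_system(n_rows=30, L=5, sparsity=2, seed=52)
    sys_, fg, path = run_two_step(A, b, seed=4, n_lambda=1, lambda_min_ratio=1.0)
    sel = select_model(path)
    assert sel.lambda_star == path.lambda_grid[0]


def test_concat_replicates_identity_and_idempotence():
    A, b, _ = planted_system(seed=60, noise=0.05)
    sys_ = make_system(A, b)
    assert rn.concat_replicates([sys_]) is sys_
    double = rn.concat_replicates([sys_, sys_])
    fg1 = step1_fg(sys_)
    fg2 = step1_fg(double)
    np.testing.assert_allclose(fg1.k_fg, fg2.k_fg, atol=1e-8)


def test_concat_rejects_mismatched_libraries():
    A, b, _ = planted_system(seed=61)
    s1 = make_system(A, b)
    s2 = make_system(A[:, :5], b)
    with pytest.raises(ValueError):
        rn.concat_replicates([s1, s2])


def test_assemble_system_shapes(enzymatic):
    eqs = rn.derive_moment_equations(enzymatic, max_order=2)
    t = np.linspace(0, 1, 7)
    rng = np.random.default_rng(0)
    keys = [k for o in (1, 2, 3) for k in itertools.combinations_with_replacement(range(4), o)]
    m = rn.MomentTimeSeries(t, {k: rng.uniform(1, 2, 7) for k in keys}, np.full(7, 10), 3)
    g = rn.GradientTimeSeries(t, {k: rng.normal(size=7) for k in keys if len(k) <= 2}, "spline")
    s2 = rn.assemble_system(eqs, m, g, orders=2)
    assert s2.A.shape[0] == 14 * 7 == len(s2.b) == 98
    s1 = rn.assemble_system(eqs, m, g, orders=1)
    assert s1.A.shape[0] == 4 * 7 == 28
    # block-major ordering: first T rows belong to the first mean
    assert all(key == (0,) for key, _ in s2.row_labels[:7])


def test_zero_gradients_zero_solution(enzymatic):
    eqs = rn.derive_moment_equations(enzymatic, max_order=2)
    t = np.linspace(0, 1, 5)
    rng = np.random.default_rng(1)
    keys = [k for o in (1, 2, 3) for k in itertools.combinations_with_replacement(range(4), o)]
    m = rn.MomentTimeSeries(t, {k: rng.uniform(1, 2, 5) for k in keys}, np.full(5, 10), 3)
    g = rn.GradientTimeSeries(t, {k: np.zeros(5) for k in keys if len(k) <= 2}, "spline")
    sys_ = rn.assemble_system(eqs, m, g, orders=2)
    fg_k = bounded_nnls(sys_.A, sys_.b)
    np.testing.assert_allclose(fg_k, 0.0, atol=1e-12)
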