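"""The reactionet lasso: stepwise sparse regression for network recovery.

Gradient matching turns the moment equations into the linear model
``b_hat = A_hat k + eps`` with ``eps = eps_A k - eps_b``: both the response
(moment-gradient estimates) and the design matrix (stoichiometric moment
function evaluations) carry sampling noise, and the residual variance depends
on the unknown rates themselves.  The procedure is therefore stepwise:

Step 1 (feasible generalized least squares).  A pilot nonnegative least
squares fit on the first-order (mean) rows yields k_LS; per-row residual
variances sigma_j^2 = sd_b_j^2 + sum_l k_LS_l^2 sd_A_jl^2 whiten the system;
a nonnegative fit of the whitened full system gives k_FG, whose support Phi
prunes the candidate library.

Step 2 (adaptive relaxed lasso).  On the whitened system restricted to Phi,
solve for a decreasing grid of penalties

    min_{k >= 0}  || b_S - A_S,Phi k ||^2  +  lambda sum_i |k_i / ktilde_i|

by ADMM, with adaptive weights ktilde from the Step-1 pseudoinverse solution.
Each active set is refit without penalty (relaxed lasso); five-fold
cross-validation provides stability-selection frequencies; BIC picks the
model, followed by backward stepwise refinement.  Prior-knowledge reactions
are never penalised and are held strictly positive in every fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg
from scipy.optimize import nnls

from .estimate import GradientTimeSeries, MomentTimeSeries, evaluate_design
from .moments import MomentEquations, moment_basis

logger = logging.getLogger("reactionet")

__all__ = [
    "RegressionSystem",
    "FGResult",
    "PathResult",
    "SelectionResult",
    "assemble_system",
    "concat_replicates",
    "step1_fg",
    "step2_adaptive_relaxed_lasso",
    "select_model",
    "bounded_nnls",
    "information_criterion",
]

_RSS_FLOOR = 1e-12  # keeps ln(RSS/n) finite on exactly-consistent systems
_KNOWN_LB = 1e-12  # strict-positivity surrogate for prior-knowledge rates


# ---------------------------------------------------------------------------
# containers


@dataclass
class RegressionSystem:
    """Stacked gradient-matching system: rows ordered moment-block-major,
    then time; columns are candidate reactions."""

    b: np.ndarray
    A: np.ndarray
    sd_b: np.ndarray
    sd_A: np.ndarray
    row_labels: list  # (moment key, time)
    col_labels: list  # rate_id per column
    orders_included: int
    known_mask: np.ndarray

    def __post_init__(self):
        if not (len(self.b) == self.A.shape[0] == len(self.row_labels)):
            raise ValueError("row dimensions inconsistent")
        if self.A.shape[1] != len(self.col_labels):
            raise ValueError("column dimensions inconsistent")

    @property
    def first_order_rows(self) -> np.ndarray:
        return np.array([len(key) == 1 for key, _ in self.row_labels])


@dataclass
class FGResult:
    """Step-1 output: pilot fit, residual variances, whitened system, support."""

    k_ls: np.ndarray
    sigma2_eps: np.ndarray
    k_fg: np.ndarray
    support: np.ndarray  # column indices in Phi
    weights: np.ndarray  # ktilde over Phi
    b_scaled: np.ndarray
    A_scaled: np.ndarray


@dataclass
class PathResult:
    """Regularisation path of Step 2 over the support Phi."""

    lambda_grid: np.ndarray
    coefficients: np.ndarray  # (n_lambda, |Phi|) relaxed refits
    penalized: np.ndarray  # (n_lambda, |Phi|) ADMM solutions
    cv_error: np.ndarray
    stability_freq: np.ndarray  # (n_lambda, |Phi|)
    rss: np.ndarray
    n_active: np.ndarray
    bic: np.ndarray
    support: np.ndarray
    known_in_phi: np.ndarray
    b_scaled: np.ndarray
    A_phi: np.ndarray
    n_rows: int
    admm_converged: np.ndarray = field(default=None)  # type: ignore[assignment]


@dataclass
class SelectionResult:
    """Final reported model."""

    selected: np.ndarray  # column indices into the full library
    k_hat: np.ndarray
    lambda_star: float
    bic_star: float
    provenance: dict  # rate_id -> stability frequency at lambda_star


# ---------------------------------------------------------------------------
# assembly


def assemble_system(
    eqs: MomentEquations,
    m: MomentTimeSeries,
    g: GradientTimeSeries,
    sd=None,
    orders: int = 2,
    known_mask=None,
) -> RegressionSystem:
    """Stack response and design per the block layout: for each target moment
    (means first, then second moments), one row per time point.

    ``sd`` is the ``(moments_sd, gradients_sd, design_sd)`` triple from
    :func:`reactionet.estimate.bootstrap_variability`; if omitted, unit
    standard deviations are used (appropriate for noiseless oracle systems).
    """
    targets = [r for r in moment_basis(eqs.n_species, orders)]
    T = len(m.time_points)
    L = max((l for per in eqs.functions.values() for l in per), default=-1) + 1
    design = evaluate_design(eqs, m)
    grad_sd = des_sd = None
    if sd is not None:
        _, grad_sd, des_sd = sd

    rows = len(targets) * T
    b = np.empty(rows)
    A = np.zeros((rows, L))
    sd_b = np.ones(rows)
    sd_A = np.zeros((rows, L)) if sd is not None else np.ones((rows, L))
    labels = []
    r_i = 0
    for key in targets:
        if key not in g.values:
            raise KeyError(f"gradient estimates missing for target {key}")
        for j, t in enumerate(m.time_points):
            b[r_i] = g.values[key][j]
            if grad_sd is not None:
                sd_b[r_i] = grad_sd[key][j]
            for l in eqs.functions[key]:
                A[r_i, l] = design[(key, l)][j]
                if des_sd is not None:
                    sd_A[r_i, l] = des_sd[(key, l)][j]
            labels.append((key, t))
            r_i += 1
    if known_mask is None:
        known_mask = np.zeros(L, dtype=bool)
    return RegressionSystem(b, A, sd_b, sd_A, labels, list(range(L)), orders, np.asarray(known_mask, bool))


def concat_replicates(systems: list) -> RegressionSystem:
    """Stack replicate systems row-wise; downstream steps are unchanged."""
    if len(systems) == 0:
        raise ValueError("no systems to concatenate")
    first = systems[0]
    for s in systems[1:]:
        if s.col_labels != first.col_labels:
            raise ValueError("replicates built over different candidate libraries")
        if not np.array_equal(s.known_mask, first.known_mask):
            raise ValueError("replicates disagree on prior-knowledge reactions")
    if len(systems) == 1:
        return first
    return RegressionSystem(
        np.concatenate([s.b for s in systems]),
        np.vstack([s.A for s in systems]),
        np.concatenate([s.sd_b for s in systems]),
        np.vstack([s.sd_A for s in systems]),
        [lab for s in systems for lab in s.row_labels],
        first.col_labels,
        first.orders_included,
        first.known_mask,
    )


# ---------------------------------------------------------------------------
# nonnegative least squares with optional strict-positive lower bounds


def bounded_nnls(A: np.ndarray, b: np.ndarray, lb: np.ndarray | None = None) -> np.ndarray:
    """argmin ||b - A k||^2 subject to k >= lb (elementwise, lb >= 0)."""
    if A.shape[1] == 0:
        return np.zeros(0)
    if lb is None or not np.any(lb > 0):
        k, _ = nnls(A, b)
        return k
    y, _ = nnls(A, b - A @ lb)
    return y + lb


def information_criterion(rss: float, n: int, s: int, criterion: str = "BIC") -> float:
    rss = max(rss, _RSS_FLOOR)
    pen = s * np.log(n) if criterion == "BIC" else 2.0 * s
    return n * np.log(rss / n) + pen


# ---------------------------------------------------------------------------
# Step 1: feasible generalized least squares


def step1_fg(
    sys: RegressionSystem,
    support_threshold: float = 1e-6,
    kls_rows: str = "first_order",
) -> FGResult:
    """Whiten the system and prune the candidate library.

    ``kls_rows`` selects the rows used for the pilot fit that calibrates the
    residual variances: ``"first_order"`` (means only, the robust default) or
    ``"all"``.
    """
    lb = np.where(sys.known_mask, _KNOWN_LB, 0.0)
    rows1 = sys.first_order_rows if kls_rows == "first_order" else np.ones(len(sys.b), bool)
    if not np.any(rows1):
        raise ValueError("system contains no first-order rows")
    k_ls = bounded_nnls(sys.A[rows1], sys.b[rows1], lb)

    sigma2 = sys.sd_b**2 + (sys.sd_A**2) @ (k_ls**2)
    if np.any(sigma2 <= 0):
        positive = sigma2[sigma2 > 0]
        floor = positive.min() if positive.size else 1.0
        logger.warning("flooring %d zero residual variances at %.3g", int(np.sum(sigma2 <= 0)), floor)
        sigma2 = np.where(sigma2 <= 0, floor, sigma2)

    w = 1.0 / np.sqrt(sigma2)
    b_s = w * sys.b
    A_s = w[:, None] * sys.A

    k_fg = bounded_nnls(A_s, b_s, lb)
    kmax = k_fg.max() if k_fg.size else 0.0
    support = np.flatnonzero((k_fg > support_threshold * kmax) | sys.known_mask)
    if support.size == 0:
        raise ValueError("Step 1 support is empty: no reaction explains the gradients")

    k_pinv = linalg.pinv(A_s[:, support]) @ b_s
    weights = np.maximum(np.abs(k_pinv), _KNOWN_LB)
    return FGResult(k_ls, sigma2, k_fg, support, weights, b_s, A_s)


# ---------------------------------------------------------------------------
# ADMM solver for the nonnegative adaptive lasso


def _admm_weighted_l1(
    A: np.ndarray,
    b: np.ndarray,
    lam: float,
    pen_w: np.ndarray,
    lb: np.ndarray,
    z0=None,
    u0=None,
    rho: float = 1.0,
    eps_abs: float = 1e-8,
    eps_rel: float = 1e-6,
    max_iter: int = 10_000,
):
    """min ||b - A k||^2 + lam * sum_i pen_w_i k_i  s.t.  k >= lb.

    Under the nonnegativity constraint the weighted l1 penalty is linear, so
    the z-update is a shifted projection.  rho is rescaled adaptively (factor
    2) when the primal/dual residual ratio exceeds 10.
    """
    n = A.shape[1]
    AtA2 = 2.0 * (A.T @ A)
    Atb2 = 2.0 * (A.T @ b)
    z = np.zeros(n) if z0 is None else z0.copy()
    u = np.zeros(n) if u0 is None else u0.copy()
    cho = linalg.cho_factor(AtA2 + rho * np.eye(n))
    converged = False
    for _ in range(max_iter):
        k = linalg.cho_solve(cho, Atb2 + rho * (z - u))
        z_old = z
        z = np.maximum(k + u - lam * pen_w / rho, lb)
        u = u + k - z
        r_norm = np.linalg.norm(k - z)
        s_norm = np.linalg.norm(rho * (z - z_old))
        eps_pri = np.sqrt(n) * eps_abs + eps_rel * max(np.linalg.norm(k), np.linalg.norm(z))
        eps_dual = np.sqrt(n) * eps_abs + eps_rel * np.linalg.norm(rho * u)
        if r_norm <= eps_pri and s_norm <= eps_dual:
            converged = True
            break
        if s_norm > 0 and r_norm / max(s_norm, 1e-300) > 10:
            rho *= 2.0
            u /= 2.0
            cho = linalg.cho_factor(AtA2 + rho * np.eye(n))
        elif r_norm > 0 and s_norm / max(r_norm, 1e-300) > 10:
            rho /= 2.0
            u *= 2.0
            cho = linalg.cho_factor(AtA2 + rho * np.eye(n))
    return z, u, rho, converged


def lambda_max(A: np.ndarray, b: np.ndarray, ktilde: np.ndarray, known: np.ndarray) -> float:
    """Smallest penalty that zeroes every non-prior coefficient (KKT bound)."""
    if np.any(known):
        k_prior = np.zeros(A.shape[1])
        k_prior[known] = bounded_nnls(A[:, known], b, np.full(int(known.sum()), _KNOWN_LB))
        r = b - A @ k_prior
    else:
        r = b
    corr = 2.0 * ktilde * (A.T @ r)
    corr = corr[~known]
    return float(corr.max()) if corr.size and corr.max() > 0 else 1.0


def _stratified_folds(row_labels, n_folds: int, rng) -> np.ndarray:
    """Fold assignment per row, stratified by moment block."""
    fold = np.empty(len(row_labels), dtype=int)
    blocks: dict = {}
    for i, (key, _) in enumerate(row_labels):
        blocks.setdefault(key, []).append(i)
    for idx in blocks.values():
        idx = np.array(idx)
        rng.shuffle(idx)
        fold[idx] = np.arange(len(idx)) % n_folds
    return fold


def step2_adaptive_relaxed_lasso(
    fg: FGResult,
    row_labels,
    known_mask: np.ndarray,
    n_lambda: int = 50,
    lambda_min_ratio: float = 1e-6,
    folds: int = 5,
    seed: int = 0,
) -> PathResult:
    """Trace the adaptive relaxed lasso path over the Step-1 support.

    For every penalty on a decreasing log grid from the analytic all-zero
    bound, the weighted nonnegative lasso is solved by ADMM (warm-started
    along the path), the active set is refit without penalty, and five-fold
    cross-validation stratified by moment block records held-out error and
    per-reaction selection frequencies.
    """
    phi = fg.support
    if phi.size == 0:
        raise ValueError("empty support")
    A = fg.A_scaled[:, phi]
    b = fg.b_scaled
    known = known_mask[phi]
    ktilde = fg.weights
    pen_w = np.where(known, 0.0, 1.0 / ktilde)
    lb = np.where(known, _KNOWN_LB, 0.0)
    n, p = A.shape

    lmax = lambda_max(A, b, ktilde, known)
    grid = lmax * np.logspace(0, np.log10(lambda_min_ratio), n_lambda)

    rng = np.random.default_rng(seed)
    fold_of = _stratified_folds(row_labels, folds, rng)

    # precondition the ADMM iterations by unit-norm columns; in the scaled
    # variable k'_j = ||A_j|| k_j the problem is identical, so solutions map
    # back exactly, but the quadratic term is far better conditioned
    col_norm = np.linalg.norm(A, axis=0)
    col_norm[col_norm == 0] = 1.0

    def trace(Atr, btr):
        zs = np.zeros((n_lambda, p))
        ok = np.zeros(n_lambda, dtype=bool)
        An = Atr / col_norm
        pw = pen_w / col_norm
        lbn = lb * col_norm
        z = u = None
        rho = 1.0
        for i, lam in enumerate(grid):
            z, u, rho, conv = _admm_weighted_l1(An, btr, lam, pw, lbn, z, u, rho)
            zs[i] = z / col_norm
            ok[i] = conv
        return zs, ok

    z_full, conv_full = trace(A, b)
    if not conv_full.all():
        logger.warning("ADMM did not converge for %d/%d penalties", int((~conv_full).sum()), n_lambda)

    active_full = (z_full > lb[None, :]) | known[None, :]
    coef = np.zeros((n_lambda, p))
    rss = np.empty(n_lambda)
    n_active = active_full.sum(axis=1)
    for i in range(n_lambda):
        act = active_full[i]
        if act.any():
            coef[i, act] = bounded_nnls(A[:, act], b, lb[act])
        rss[i] = float(np.sum((b - A @ coef[i]) ** 2))
    bic = np.array(
        [information_criterion(rss[i], n, int(n_active[i])) for i in range(n_lambda)]
    )

    cv_err = np.zeros(n_lambda)
    freq = np.zeros((n_lambda, p))
    for f in range(folds):
        tr, te = fold_of != f, fold_of == f
        z_f, _ = trace(A[tr], b[tr])
        act_f = (z_f > lb[None, :]) | known[None, :]
        freq += act_f
        for i in range(n_lambda):
            kf = np.zeros(p)
            if act_f[i].any():
                kf[act_f[i]] = bounded_nnls(A[tr][:, act_f[i]], b[tr], lb[act_f[i]])
            cv_err[i] += float(np.mean((b[te] - A[te] @ kf) ** 2))
    cv_err /= folds
    freq /= folds

    return PathResult(
        grid, coef, z_full, cv_err, freq, rss, n_active, bic,
        phi, known, b, A, n, admm_converged=conv_full,
    )


# ---------------------------------------------------------------------------
# model selection


def select_model(
    path: PathResult,
    criterion: str = "BIC",
    stability_threshold: float = 0.8,
    elbow_if_more_than: int = 1000,
) -> SelectionResult:
    """Pick the final model from the path.

    The penalty is chosen by minimum BIC/AIC of the full-data relaxed refits
    (for libraries larger than ``elbow_if_more_than`` candidates, the elbow
    variant: the sparsest model whose criterion is within 1% of the total
    drop).  Active reactions at the chosen penalty are filtered by
    stability-selection frequency, then pruned by backward stepwise
    elimination — repeatedly dropping the reaction whose removal increases
    the residual sum of squares least, while the criterion does not increase.
    Prior-knowledge reactions are never dropped.
    """
    if len(path.lambda_grid) == 0:
        raise ValueError("empty regularization path")
    n = path.n_rows
    ic = (
        path.bic
        if criterion == "BIC"
        else np.array(
            [information_criterion(r, n, int(s), "AIC") for r, s in zip(path.rss, path.n_active)]
        )
    )
    i_min = int(np.argmin(ic))
    if len(path.support) > elbow_if_more_than:
        drop = ic[0] - ic[i_min]
        ok = np.flatnonzero(ic - ic[i_min] <= 0.01 * max(drop, 0.0))
        i_star = int(ok[0]) if ok.size else i_min
    else:
        # exact BIC ties (e.g. zero-residual refits of the same active set
        # further down the path) break toward the smallest penalty, where the
        # cross-validated selection frequencies have stabilised
        tol = 1e-6 * max(1.0, abs(ic[i_min]))
        i_star = int(np.flatnonzero(ic <= ic[i_min] + tol)[-1])
    lam_star = float(path.lambda_grid[i_star])

    active = (path.penalized[i_star] > 0) | path.known_in_phi
    stable = path.stability_freq[i_star] >= stability_threshold
    members = np.flatnonzero((active & stable) | path.known_in_phi)
    if members.size == 0:
        members = np.flatnonzero(active)

    A, b = path.A_phi, path.b_scaled
    lb_all = np.where(path.known_in_phi, _KNOWN_LB, 0.0)

    def fit(idx):
        k = bounded_nnls(A[:, idx], b, lb_all[idx])
        rss = float(np.sum((b - A[:, idx] @ k) ** 2))
        return k, rss

    cur = list(members)
    k_cur, rss_cur = fit(cur)
    ic_cur = information_criterion(rss_cur, n, len(cur), criterion)
    improved = True
    while improved and len(cur) > 1:
        improved = False
        best = None
        for j in cur:
            if path.known_in_phi[j]:
                continue
            trial = [i for i in cur if i != j]
            k_t, rss_t = fit(trial)
            if best is None or rss_t < best[2]:
                best = (j, k_t, rss_t, trial)
        if best is not None:
            ic_t = information_criterion(best[2], n, len(best[3]), criterion)
            if ic_t <= ic_cur:
                _, k_cur, rss_cur, cur = best
                ic_cur = ic_t
                improved = True

    selected = path.support[np.array(cur, dtype=int)]
    prov = {
        int(path.support[j]): float(path.stability_freq[i_star, j]) for j in cur
    }
    return SelectionResult(selected, k_cur, lam_star, float(ic_cur), prov)
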