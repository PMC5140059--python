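"""Empirical moment, gradient and variability estimation from snapshots.

The estimators operate strictly on the snapshot data model: at every time
point the cells are an i.i.d. sample from the evolving abundance
distribution, and no cell identity links time points.

Noise correction inverts the binomial-thinning measurement model
X_obs ~ Bi(X, p) with known capture efficiency p.  For first and second
moments the inversions are

    E[X] = E[X_obs] / p
    Var[X] = (Var[X_obs] - p (1 - p) E[X]) / p^2
    Cov[X_1, X_2] = Cov[X_1_obs, X_2_obs] / p^2

and third moments are corrected through the falling-factorial identity
E[(X_obs)_(r)] = p^r E[(X)_(r)], exact for binomial thinning.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

from .moments import MomentEquations, evaluate_design_entry, required_input_moments
from .simulate import SnapshotSeries, TrajectorySet

logger = logging.getLogger("reactionet")

__all__ = [
    "MomentTimeSeries",
    "GradientTimeSeries",
    "empirical_moments",
    "correct_binomial_noise",
    "estimate_gradients",
    "bootstrap_variability",
]


@dataclass
class MomentTimeSeries:
    """Moment estimates per time point: ``values[key]`` is a (T,) array where
    ``key`` is the sorted species-index tuple of the moment."""

    time_points: np.ndarray
    values: dict
    n_cells: np.ndarray
    max_order: int
    boot_sd: dict = field(default_factory=dict)

    def to_frame(self):
        import pandas as pd

        rows = []
        for key, v in sorted(self.values.items()):
            for j, t in enumerate(self.time_points):
                rows.append(
                    {
                        "moment_index": ":".join(map(str, key)),
                        "time": t,
                        "estimate": v[j],
                        "boot_sd": self.boot_sd.get(key, np.full_like(v, np.nan))[j],
                    }
                )
        return pd.DataFrame(rows)


@dataclass
class GradientTimeSeries:
    """Moment time-derivative estimates dM_r/dt at the snapshot times."""

    time_points: np.ndarray
    values: dict
    method: str
    boot_sd: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# empirical central moments


def _multisets(n_species: int, order: int):
    return list(itertools.combinations_with_replacement(range(n_species), order))


def _moments_from_matrix(x: np.ndarray, max_order: int) -> dict:
    """Unbiased sample moments for one snapshot matrix (cells x species)."""
    c, n = x.shape
    out = {}
    mu = x.mean(axis=0)
    for i in range(n):
        out[(i,)] = mu[i]
    y = x - mu
    if max_order >= 2:
        for i, j in _multisets(n, 2):
            out[(i, j)] = (y[:, i] * y[:, j]).sum() / (c - 1)
    if max_order >= 3:
        h3 = c * c / ((c - 1) * (c - 2))
        for i, j, k in _multisets(n, 3):
            out[(i, j, k)] = h3 * (y[:, i] * y[:, j] * y[:, k]).mean()
    return out


def empirical_moments(s: SnapshotSeries, max_order: int = 3) -> MomentTimeSeries:
    """Sample means, unbiased (co)variances and (for ``max_order=3``)
    unbiased third central moments (h-statistics) at every time point."""
    if max_order not in (2, 3):
        raise ValueError("max_order must be 2 or 3")
    min_cells = 4 if max_order == 3 else 2
    if any(c.shape[0] < min_cells for c in s.counts):
        raise ValueError(f"need at least {min_cells} cells per time point for order {max_order}")
    n = s.n_species
    keys = [k for o in range(1, max_order + 1) for k in _multisets(n, o)]
    values = {k: np.empty(len(s.time_points)) for k in keys}
    for j, x in enumerate(s.counts):
        m = _moments_from_matrix(np.asarray(x, dtype=float), max_order)
        for k in keys:
            values[k][j] = m[k]
    return MomentTimeSeries(s.time_points, values, s.n_cells, max_order)


# ---------------------------------------------------------------------------
# binomial noise correction (multi-index factorial-moment inversion)

# (x)_r as a polynomial in powers of x, and x^r in falling factorials
_FALLING = {0: {0: 1.0}, 1: {1: 1.0}, 2: {2: 1.0, 1: -1.0}, 3: {3: 1.0, 2: -3.0, 1: 2.0}}
_POWER = {0: {0: 1.0}, 1: {1: 1.0}, 2: {2: 1.0, 1: 1.0}, 3: {3: 1.0, 2: 3.0, 1: 1.0}}


def _key_to_counts(key):
    out: dict[int, int] = {}
    for i in key:
        out[i] = out.get(i, 0) + 1
    return out


def _counts_to_key(counts):
    return tuple(sorted(i for i, r in counts.items() for _ in range(r)))


def _convert(table: dict, rules: dict) -> dict:
    """Apply a per-coordinate power-basis change to a multi-index moment table."""
    out = {}
    for key, _ in table.items():
        counts = _key_to_counts(key)
        species = sorted(counts)
        acc = 0.0
        for combo in itertools.product(*(rules[counts[i]].items() for i in species)):
            coeff = 1.0
            new_counts = {}
            for i, (power, c) in zip(species, combo):
                coeff *= c
                if power > 0:
                    new_counts[i] = power
            sub = _counts_to_key(new_counts)
            acc = acc + coeff * (table[sub] if sub else 1.0)
        out[key] = acc
    return out


def _central_to_raw(values: dict) -> dict:
    mu = {k[0]: v for k, v in values.items() if len(k) == 1}
    raw = {}
    for key in values:
        positions = list(key)
        acc = 0.0
        for mask in itertools.product([0, 1], repeat=len(positions)):
            sub = tuple(sorted(p for p, m in zip(positions, mask) if m))
            if len(sub) == 1:
                central = 0.0  # E[X - mu] = 0
            elif len(sub) == 0:
                central = 1.0
            else:
                central = values[sub]
            coeff = np.prod([mu[p] for p, m in zip(positions, mask) if not m], axis=0) if mask.count(0) else 1.0
            acc = acc + coeff * central
        raw[key] = acc
    for i, m in mu.items():
        raw[(i,)] = m
    return raw


def _raw_to_central(raw: dict) -> dict:
    mu = {k[0]: v for k, v in raw.items() if len(k) == 1}
    central = {}
    for key in raw:
        if len(key) == 1:
            central[key] = raw[key]
            continue
        positions = list(key)
        acc = 0.0
        for mask in itertools.product([0, 1], repeat=len(positions)):
            sub = tuple(sorted(p for p, m in zip(positions, mask) if m))
            coeff = 1.0
            for p, m in zip(positions, mask):
                if not m:
                    coeff = coeff * (-mu[p])
            acc = acc + coeff * (raw[sub] if sub else 1.0)
        central[key] = acc
    return central


def correct_binomial_noise(m: MomentTimeSeries, p: float) -> MomentTimeSeries:
    """Invert binomial thinning with known capture efficiency p on a moment
    table (orders 1-3).  Corrected variances that come out negative — possible
    at low p and finite samples — are clipped to zero with a warning."""
    if not 0 < p <= 1:
        raise ValueError("capture efficiency p must lie in (0, 1]")
    if p == 1.0:
        return MomentTimeSeries(m.time_points, {k: v.copy() for k, v in m.values.items()}, m.n_cells, m.max_order)
    raw_obs = _central_to_raw(m.values)
    fact_obs = _convert(raw_obs, _FALLING)
    fact_true = {k: v / p ** len(k) for k, v in fact_obs.items()}
    raw_true = _convert(fact_true, _POWER)
    central = _raw_to_central(raw_true)
    clipped = 0
    for key in central:
        if len(key) == 2 and key[0] == key[1]:
            neg = central[key] < 0
            clipped += int(np.sum(neg))
            central[key] = np.where(neg, 0.0, central[key])
    if clipped:
        logger.warning("noise correction clipped %d negative variance estimates to 0", clipped)
    return MomentTimeSeries(m.time_points, central, m.n_cells, m.max_order)


# ---------------------------------------------------------------------------
# gradient matching


def _dense_target_moments(traj: TrajectorySet, targets) -> dict:
    x = traj.counts.astype(float)  # (cells, D, N)
    mu = x.mean(axis=0)  # (D, N)
    y = x - mu
    c = x.shape[0]
    out = {}
    for key in targets:
        if len(key) == 1:
            out[key] = mu[:, key[0]]
        else:
            i, j = key
            out[key] = (y[:, :, i] * y[:, :, j]).sum(axis=0) / (c - 1)
    return out


def _moving_average(v: np.ndarray, window: int) -> np.ndarray:
    # centered moving average; windows shrink *symmetrically* at the edges
    # (sizes 1, 3, 5, ...) so the effective sample position never shifts —
    # an asymmetric shrink would bias the end-point derivatives
    half = window // 2
    out = np.empty_like(np.asarray(v, dtype=float))
    n = len(v)
    for i in range(n):
        h = min(half, i, n - 1 - i)
        out[i] = v[i - h : i + h + 1].mean()
    return out


def estimate_gradients(
    m: MomentTimeSeries,
    method: str = "spline",
    trajectories: TrajectorySet | None = None,
    smooth_window: int = 5,
    targets=None,
) -> GradientTimeSeries:
    """Estimate dM_r/dt at the snapshot times for every target moment of
    order <= 2.

    * ``spline`` — derivative of the cubic interpolating spline (not-a-knot
      end conditions: a natural spline's forced zero end-curvature badly
      biases the boundary derivatives of decaying moment curves);
    * ``fds`` — nonuniform central differences (one-sided at the ends);
    * ``smooth`` — sliding-window-smoothed finite differences of densely
      sampled ensemble moments; an oracle available only with simulated
      trajectories.
    """
    t = m.time_points
    if len(t) < 3:
        raise ValueError("gradient estimation needs at least 3 time points")
    if targets is None:
        targets = [k for k in m.values if len(k) <= 2]
    grads = {}
    if method == "spline":
        for key in targets:
            grads[key] = CubicSpline(t, m.values[key])(t, 1)
    elif method == "fds":
        for key in targets:
            grads[key] = np.gradient(m.values[key], t)
    elif method == "smooth":
        if trajectories is None:
            raise ValueError("smooth gradients require retained trajectories")
        dense = _dense_target_moments(trajectories, targets)
        td = trajectories.t_dense
        for key in targets:
            sm = _moving_average(dense[key], smooth_window)
            dsm = np.gradient(sm, td)
            grads[key] = np.interp(t, td, dsm)
    else:
        raise ValueError(f"unknown gradient method {method!r}")
    return GradientTimeSeries(t, grads, method)


# ---------------------------------------------------------------------------
# bootstrap of the full estimator pipeline


def evaluate_design(eqs: MomentEquations, m: MomentTimeSeries) -> dict:
    """Design entries F_rl evaluated at the empirical moments: a map
    (target key, rate_id) -> (T,) array."""
    need = required_input_moments(eqs)
    missing = need - set(m.values)
    if missing:
        raise KeyError(f"moment table lacks required indices: {sorted(missing)}")
    out = {}
    for r in eqs.targets:
        for l, poly in eqs.functions[r].items():
            out[(r, l)] = np.asarray(evaluate_design_entry(poly, m.values), dtype=float)
    return out


def _pipeline_once(counts, s: SnapshotSeries, eqs, p, method, max_order, trajectories, smooth_window):
    sub = SnapshotSeries(s.time_points, counts, s.species_names, s.noise_p, s.replicate_id)
    m = empirical_moments(sub, max_order=max_order)
    if p is not None and p < 1:
        # clip warnings are expected and uninformative on bootstrap replicates
        level = logger.level
        logger.setLevel(logging.ERROR)
        try:
            m = correct_binomial_noise(m, p)
        finally:
            logger.setLevel(level)
    g = estimate_gradients(m, method, trajectories=trajectories, smooth_window=smooth_window)
    a = evaluate_design(eqs, m)
    return m, g, a


def _smooth_gradient_boot(traj: TrajectorySet, targets, t_eval, B, rng, smooth_window):
    """Bootstrap SDs of the smooth-oracle gradients.

    Cell resampling with replacement is expressed through multinomial weights,
    so each replicate's dense ensemble moments are weighted raw moments — one
    matrix product per moment index instead of a full re-estimation.
    """
    x = traj.counts.astype(float)  # (C, D, N)
    C = x.shape[0]
    td = traj.t_dense
    W = rng.multinomial(C, np.full(C, 1.0 / C), size=B) / C  # (B, C)
    mean_b = {}
    for i in {i for key in targets for i in key}:
        mean_b[i] = W @ x[:, :, i]  # (B, D)
    out = {}
    for key in targets:
        if len(key) == 1:
            raw = mean_b[key[0]]
            series = raw
        else:
            i, j = key
            raw = W @ (x[:, :, i] * x[:, :, j])
            series = (raw - mean_b[i] * mean_b[j]) * (C / (C - 1))
        sm = np.apply_along_axis(_moving_average, 1, series, smooth_window)
        dsm = np.gradient(sm, td, axis=1)
        grads = np.stack([np.interp(t_eval, td, row) for row in dsm])
        out[key] = grads.std(axis=0, ddof=1)
    return out


def bootstrap_variability(
    s: SnapshotSeries,
    eqs: MomentEquations,
    B: int = 200,
    seed: int = 0,
    p: float | None = None,
    method: str = "spline",
    max_order: int = 3,
    trajectories: TrajectorySet | None = None,
    smooth_window: int = 5,
):
    """Bootstrap standard deviations of moments, gradients and design entries.

    Cells are resampled with replacement independently per time point, B
    times, and the full pipeline (moments -> noise correction -> gradients ->
    stoichiometric moment functions) is re-evaluated on each replicate.
    Returns ``(moments_sd, gradients_sd, design_sd)`` dictionaries keyed like
    the corresponding point-estimate tables.
    """
    if B < 2:
        raise ValueError("bootstrap needs B >= 2 replicates")
    if B < 50:
        warnings.warn("B < 50 bootstrap replicates gives unstable SD estimates")
    rng = np.random.default_rng(seed)
    mom_acc: dict = {}
    grad_acc: dict = {}
    des_acc: dict = {}
    # smooth gradients bootstrap over the dense ensemble below; the snapshot
    # loop then only supplies moment/design SDs (fds is the cheapest filler)
    snap_method = "fds" if method == "smooth" else method
    for _ in range(B):
        counts = [c[rng.integers(0, c.shape[0], size=c.shape[0])] for c in s.counts]
        m, g, a = _pipeline_once(counts, s, eqs, p, snap_method, max_order, None, smooth_window)
        for k, v in m.values.items():
            mom_acc.setdefault(k, []).append(v)
        if method != "smooth":
            for k, v in g.values.items():
                grad_acc.setdefault(k, []).append(v)
        for k, v in a.items():
            des_acc.setdefault(k, []).append(v)
    sd = lambda acc: {k: np.std(np.stack(v), axis=0, ddof=1) for k, v in acc.items()}
    grad_sd = sd(grad_acc) if method != "smooth" else None
    if method == "smooth":
        if trajectories is None:
            raise ValueError("smooth bootstrap requires retained trajectories")
        targets = [k for k in mom_acc if len(k) <= 2]
        grad_sd = _smooth_gradient_boot(
            trajectories, targets, s.time_points, B, rng, smooth_window
        )
    return sd(mom_acc), grad_sd, sd(des_acc)
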