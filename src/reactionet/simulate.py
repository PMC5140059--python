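"""Exact stochastic simulation of snapshot ensembles.

Each cell is an independent Gillespie (direct-method) realisation of the
network's chemical master equation, recorded at the requested snapshot times.
Cells are never tracked across time points by the estimators — the snapshot
data model — but a densely sampled ensemble (:class:`TrajectorySet`) can be
retained for the "smooth" oracle gradient available only in simulation.

Measurement noise of single-cell instruments is modelled as binomial thinning
with capture efficiency p: each molecule is detected independently with
probability p.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import ReactionNetwork

try:  # numba accelerates the event loop ~100x; the pure-python path is identical
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f


__all__ = [
    "SnapshotSeries",
    "TrajectorySet",
    "ssa_simulate",
    "apply_binomial_noise",
    "select_time_points",
]


@dataclass
class SnapshotSeries:
    """Per-time-point matrices of per-cell integer species counts."""

    time_points: np.ndarray  # (T,), strictly increasing
    counts: list  # list of (C, N) int arrays, one per time point
    species_names: list
    noise_p: float | None = None
    replicate_id: int = 0

    def __post_init__(self):
        self.time_points = np.asarray(self.time_points, dtype=float)
        if np.any(np.diff(self.time_points) <= 0):
            raise ValueError("time points must be strictly increasing")
        n = len(self.species_names)
        for c in self.counts:
            if c.ndim != 2 or c.shape[1] != n:
                raise ValueError("each snapshot must be a (cells x species) matrix")
            if c.shape[0] < 2:
                raise ValueError("at least two cells per time point required")
            if np.any(c < 0):
                raise ValueError("counts must be nonnegative")

    @property
    def n_species(self) -> int:
        return len(self.species_names)

    @property
    def n_cells(self) -> np.ndarray:
        return np.array([c.shape[0] for c in self.counts])

    def subsample(self, n: int, seed: int) -> "SnapshotSeries":
        """Randomly keep ``n`` cells per time point (without replacement)."""
        rng = np.random.default_rng(seed)
        kept = [c[rng.choice(c.shape[0], size=n, replace=False)] for c in self.counts]
        return SnapshotSeries(self.time_points, kept, self.species_names, self.noise_p, self.replicate_id)


@dataclass
class TrajectorySet:
    """Densely sampled ensemble retained for the smooth oracle gradient."""

    t_dense: np.ndarray  # (D,)
    counts: np.ndarray  # (cells, D, N)
    species_names: list = field(default_factory=list)


@njit(cache=True)
def _ssa_cell(x0, t_grid, t_dense, react_a, react_b, stoich, rates, seed, out_grid, out_dense):
    np.random.seed(seed)
    n_rx = rates.shape[0]
    x = x0.copy()
    t = 0.0
    ig, idn = 0, 0
    props = np.empty(n_rx)
    while ig < t_grid.shape[0] or idn < t_dense.shape[0]:
        a0 = 0.0
        for l in range(n_rx):
            a, b = react_a[l], react_b[l]
            if a < 0:
                g = 1.0
            elif b < 0:
                g = x[a]
            elif a == b:
                g = x[a] * (x[a] - 1.0)
            else:
                g = x[a] * x[b]
            p = rates[l] * g
            props[l] = p if p > 0 else 0.0
            a0 += props[l]
        if a0 <= 0.0:
            t_next = np.inf
        else:
            t_next = t - np.log(np.random.random()) / a0
        # record all snapshot times passed before the next event fires
        while ig < t_grid.shape[0] and t_grid[ig] < t_next:
            out_grid[ig] = x
            ig += 1
        while idn < t_dense.shape[0] and t_dense[idn] < t_next:
            out_dense[idn] = x
            idn += 1
        if t_next == np.inf:
            break
        # pick the reaction
        u = np.random.random() * a0
        acc = 0.0
        l_fire = n_rx - 1
        for l in range(n_rx):
            acc += props[l]
            if u <= acc:
                l_fire = l
                break
        x = x + stoich[l_fire]
        t = t_next


def _reaction_arrays(network: ReactionNetwork):
    L = network.n_reactions
    ra = np.full(L, -1, dtype=np.int64)
    rb = np.full(L, -1, dtype=np.int64)
    for l, rx in enumerate(network.reactions):
        if len(rx.reactants) >= 1:
            ra[l] = rx.reactants[0]
        if len(rx.reactants) == 2:
            rb[l] = rx.reactants[1]
    return ra, rb, network.stoichiometry_matrix().astype(np.float64)


def _cell_seed(master: int, cell: int) -> int:
    return int(np.random.SeedSequence(master, spawn_key=(cell,)).generate_state(1, np.uint32)[0])


def ssa_simulate(
    network: ReactionNetwork,
    x0,
    t_grid,
    n_cells: int,
    seed: int,
    keep_trajectories: bool = False,
    n_dense: int = 201,
    replicate_id: int = 0,
):
    """Simulate a snapshot ensemble by the direct-method Gillespie algorithm.

    Each cell uses an independent RNG stream derived from ``seed`` and the
    cell index, so enlarging ``n_cells`` leaves earlier cells unchanged.
    Returns a :class:`SnapshotSeries`, or a ``(SnapshotSeries,
    TrajectorySet)`` pair when ``keep_trajectories`` is set (the trajectory
    set samples ``n_dense`` uniform times spanning the snapshot horizon).

    ``x0`` is either an integer vector or a callable ``rng -> vector``
    sampling per-cell initial states.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing")
    rates = network.rates()
    if np.any(rates < 0):
        raise ValueError("rates must be nonnegative")
    ra, rb, stoich = _reaction_arrays(network)
    N = network.n_species

    x0_sampler = x0 if callable(x0) else None
    if x0_sampler is None:
        x0 = np.asarray(x0, dtype=float)
        if x0.shape != (N,) or np.any(x0 < 0) or np.any(x0 != np.round(x0)):
            raise ValueError("x0 must be a nonnegative integer vector of length N")

    t_dense = (
        np.linspace(min(0.0, t_grid[0]), t_grid[-1], n_dense)
        if keep_trajectories
        else np.empty(0)
    )
    grid_out = np.zeros((n_cells, len(t_grid), N))
    dense_out = np.zeros((n_cells, len(t_dense), N))
    x0_rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(2**31,)))
    for c in range(n_cells):
        xc = np.asarray(x0_sampler(x0_rng), dtype=float) if x0_sampler else x0
        if np.any(xc < 0):
            raise ValueError("sampled initial state has negative counts")
        _ssa_cell(
            xc, t_grid, t_dense, ra, rb, stoich, rates,
            _cell_seed(seed, c), grid_out[c], dense_out[c],
        )
    snaps = SnapshotSeries(
        t_grid,
        [grid_out[:, j].astype(np.int64) for j in range(len(t_grid))],
        network.species_names,
        noise_p=None,
        replicate_id=replicate_id,
    )
    if keep_trajectories:
        return snaps, TrajectorySet(t_dense, dense_out.astype(np.int64), network.species_names)
    return snaps


def apply_binomial_noise(s: SnapshotSeries, p: float, seed: int) -> SnapshotSeries:
    """Binomially thin every count: each molecule is detected with probability p."""
    if not 0 < p <= 1:
        raise ValueError("capture efficiency p must lie in (0, 1]")
    if s.noise_p is not None:
        raise ValueError("snapshot series already carries measurement noise")
    if p == 1.0:
        return SnapshotSeries(s.time_points, [c.copy() for c in s.counts], s.species_names, 1.0, s.replicate_id)
    rng = np.random.default_rng(seed)
    noisy = [rng.binomial(c, p) for c in s.counts]
    return SnapshotSeries(s.time_points, noisy, s.species_names, p, s.replicate_id)


def select_time_points(t_dense, scheme) -> np.ndarray:
    """Choose snapshot times: ``("uniform", n)`` spans the dense range with n
    equally spaced points including both endpoints; an explicit list passes
    through sorted."""
    t_dense = np.asarray(t_dense, dtype=float)
    if isinstance(scheme, tuple) and scheme[0] == "uniform":
        n = int(scheme[1])
        if n < 3:
            raise ValueError("at least 3 time points required for gradient estimation")
        return np.linspace(t_dense.min(), t_dense.max(), n)
    t = np.sort(np.asarray(scheme, dtype=float))
    if len(t) < 3:
        raise ValueError("at least 3 time points required for gradient estimation")
    if t[0] < t_dense.min() or t[-1] > t_dense.max():
        raise ValueError("requested time points outside the simulated span")
    return t
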