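"""End-to-end inference: snapshots in, selected reaction network out."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .estimate import (
    bootstrap_variability,
    correct_binomial_noise,
    empirical_moments,
    estimate_gradients,
)
from .lasso import (
    FGResult,
    PathResult,
    RegressionSystem,
    SelectionResult,
    assemble_system,
    select_model,
    step1_fg,
    step2_adaptive_relaxed_lasso,
)
from .moments import derive_moment_equations, required_input_moments
from .network import CandidateLibrary
from .simulate import SnapshotSeries, TrajectorySet

__all__ = ["InferenceResult", "build_system", "infer_network", "stage_seed"]

_STAGES = {"simulate": 0, "noise": 1, "bootstrap": 2, "cv": 3, "replicate": 4}


def stage_seed(master: int, stage: str, index: int = 0) -> int:
    """Deterministically expand a master seed into independent per-stage
    streams, so any stage can be re-run in isolation."""
    ss = np.random.SeedSequence(master, spawn_key=(_STAGES[stage], index))
    return int(ss.generate_state(1, np.uint32)[0])


@dataclass
class InferenceResult:
    system: RegressionSystem
    fg: FGResult
    path: PathResult
    selection: SelectionResult
    library: CandidateLibrary

    @property
    def selected_reactions(self) -> list:
        return [self.library.network.reactions[i] for i in self.selection.selected]


def build_system(
    snapshots: SnapshotSeries,
    library: CandidateLibrary,
    capture_p: float | None = None,
    gradient_method: str = "spline",
    orders: int = 2,
    bootstrap_B: int = 200,
    seed: int = 0,
    trajectories: TrajectorySet | None = None,
    smooth_window: int = 5,
) -> RegressionSystem:
    """Estimate moments, correct noise, match gradients, bootstrap the
    variability and assemble the gradient-matching regression system."""
    eqs = derive_moment_equations(library.network, max_order=orders)
    max_in = max((len(k) for k in required_input_moments(eqs)), default=2)
    max_order = 3 if max_in >= 3 else 2

    m = empirical_moments(snapshots, max_order=max_order)
    p = capture_p if capture_p is not None else snapshots.noise_p
    if p is not None and p < 1:
        m = correct_binomial_noise(m, p)
    g = estimate_gradients(m, gradient_method, trajectories=trajectories, smooth_window=smooth_window)
    sd = None
    if bootstrap_B:
        sd = bootstrap_variability(
            snapshots, eqs,
            B=bootstrap_B, seed=stage_seed(seed, "bootstrap"),
            p=p, method=gradient_method, max_order=max_order,
            trajectories=trajectories, smooth_window=smooth_window,
        )
    return assemble_system(eqs, m, g, sd, orders=orders, known_mask=library.known_mask)


def infer_network(
    snapshots,
    library: CandidateLibrary,
    capture_p: float | None = None,
    gradient_method: str = "spline",
    orders: int = 2,
    bootstrap_B: int = 200,
    seed: int = 0,
    support_threshold: float = 1e-6,
    n_lambda: int = 50,
    folds: int = 5,
    stability_threshold: float = 0.8,
    criterion: str = "BIC",
    trajectories=None,
    smooth_window: int = 5,
    kls_rows: str = "first_order",
) -> InferenceResult:
    """Run the full reactionet lasso on one snapshot series or a list of
    replicate series (replicates are concatenated row-wise)."""
    from .lasso import concat_replicates

    snaps = snapshots if isinstance(snapshots, (list, tuple)) else [snapshots]
    trajs = trajectories if isinstance(trajectories, (list, tuple)) else [trajectories] * len(snaps)
    systems = [
        build_system(
            s, library, capture_p, gradient_method, orders,
            bootstrap_B, stage_seed(seed, "replicate", i), tr, smooth_window,
        )
        for i, (s, tr) in enumerate(zip(snaps, trajs))
    ]
    system = concat_replicates(systems)

    fg = step1_fg(system, support_threshold=support_threshold, kls_rows=kls_rows)
    path = step2_adaptive_relaxed_lasso(
        fg, system.row_labels, system.known_mask,
        n_lambda=n_lambda, folds=folds, seed=stage_seed(seed, "cv"),
    )
    selection = select_model(path, criterion=criterion, stability_threshold=stability_threshold)
    return InferenceResult(system, fg, path, selection, library)
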