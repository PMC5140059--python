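"""Run configuration: every knob of a simulate/infer/evaluate run in one
validated, serialisable record."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml


@dataclass
class RunConfig:
    network_spec: str
    t_start: float = 0.0
    t_end: float = 40.0
    n_time_points: int = 13
    time_points: list | None = None  # explicit list overrides the uniform grid
    n_cells: int = 10_000
    n_replicates: int = 1
    capture_p: float = 1.0
    gradient_method: str = "spline"
    orders: int = 2
    bootstrap_B: int = 200
    n_lambda: int = 50
    lambda_min_ratio: float = 1e-6
    folds: int = 5
    stability_threshold: float = 0.8
    criterion: str = "BIC"
    prior_reactions: list = field(default_factory=list)  # [{reactants, products}]
    seed: int = 0
    output_dir: str = "runs/out"

    def __post_init__(self):
        if self.t_end <= self.t_start:
            raise ValueError("t_end must exceed t_start")
        if self.time_points is None and self.n_time_points < 3:
            raise ValueError("need at least 3 time points")
        if not 0 < self.capture_p <= 1:
            raise ValueError("capture_p must lie in (0, 1]")
        if self.gradient_method not in ("spline", "fds", "smooth"):
            raise ValueError(f"unknown gradient method {self.gradient_method!r}")
        if self.orders not in (1, 2):
            raise ValueError("orders must be 1 or 2")
        if self.n_cells < 4:
            raise ValueError("need at least 4 cells per time point")
        if self.bootstrap_B < 50:
            raise ValueError("bootstrap_B must be at least 50")
        if self.criterion not in ("BIC", "AIC"):
            raise ValueError("criterion must be BIC or AIC")
        if not 0 <= self.stability_threshold <= 1:
            raise ValueError("stability_threshold must lie in [0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def to_dict(self) -> dict:
        return asdict(self)

    def grid(self):
        import numpy as np

        if self.time_points is not None:
            return np.sort(np.asarray(self.time_points, dtype=float))
        return np.linspace(self.t_start, self.t_end, self.n_time_points)
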