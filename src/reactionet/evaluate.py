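"""Scoring recovered networks against ground truth and reconstructing means.

Reactions are identified by their canonical (sorted reactants, sorted
products) pair; a conversion additionally matches its reverse, since the
candidate enumeration keeps one canonical direction per species pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .network import Reaction, ReactionNetwork

__all__ = ["Confusion", "confusion", "path_tradeoff", "reconstruct_means"]


@dataclass
class Confusion:
    tp: int
    fp: int
    fn: int
    tp_known: int = 0


def _match_keys(r: Reaction) -> set:
    keys = {r.key}
    if len(r.reactants) == 1 and len(r.products) == 1:  # conversion: direction-free
        keys.add((r.products, r.reactants))
    return keys


def confusion(selected: list, truth: list, known: list | None = None) -> Confusion:
    """Count true/false positives and false negatives by canonical identity."""
    truth_keys = set().union(*(_match_keys(r) for r in truth)) if truth else set()
    known_keys = set().union(*(_match_keys(r) for r in known)) if known else set()
    tp = fp = tp_known = 0
    for r in selected:
        if _match_keys(r) & truth_keys:
            tp += 1
            if _match_keys(r) & known_keys:
                tp_known += 1
        else:
            fp += 1
    return Confusion(tp, fp, len(truth) - tp, tp_known)


def path_tradeoff(path, library, truth: list) -> list:
    """Per-penalty (lambda, tp, fp) triples over the regularisation path,
    scored on the penalized active sets (plus prior-knowledge reactions)."""
    reactions = library.network.reactions
    out = []
    for i, lam in enumerate(path.lambda_grid):
        active_local = np.flatnonzero(
            (path.penalized[i] > 0) | path.known_in_phi
        )
        sel = [reactions[path.support[j]] for j in active_local]
        c = confusion(sel, truth)
        out.append((float(lam), c.tp, c.fp))
    return out


def reconstruct_means(
    network: ReactionNetwork,
    rates,
    x0,
    t_grid,
    observed_means: np.ndarray | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
):
    """Integrate the deterministic mean equations d mu/dt = S^T (k * g(mu))
    of the recovered network on ``t_grid``.

    This first-order closure drops the covariance contribution to bimolecular
    propensities, matching the usual mass-action rate equations.  Returns the
    (T, N) mean trajectories and, when ``observed_means`` is given, the
    per-species RMSE against them.
    """
    rates = np.asarray(rates, dtype=float)
    if np.any(rates < 0):
        raise ValueError("rates must be nonnegative")
    S = network.stoichiometry_matrix().astype(float)
    reactants = [r.reactants for r in network.reactions]

    def g(mu):
        out = np.empty(len(reactants))
        for l, ra in enumerate(reactants):
            if len(ra) == 0:
                out[l] = 1.0
            elif len(ra) == 1:
                out[l] = mu[ra[0]]
            elif ra[0] == ra[1]:
                out[l] = mu[ra[0]] * (mu[ra[0]] - 1.0)
            else:
                out[l] = mu[ra[0]] * mu[ra[1]]
        return out

    def rhs(_, mu):
        return S.T @ (rates * g(mu))

    t_grid = np.asarray(t_grid, dtype=float)
    sol = solve_ivp(
        rhs, (t_grid[0], t_grid[-1]), np.asarray(x0, dtype=float),
        t_eval=t_grid, rtol=rtol, atol=atol, method="LSODA",
    )
    if not sol.success:
        raise RuntimeError(f"mean-equation integration failed: {sol.message}")
    mu = sol.y.T
    if observed_means is None:
        return mu
    rmse = np.sqrt(np.mean((mu - observed_means) ** 2, axis=0))
    return mu, rmse
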