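"""Central-moment equations for mass-action networks.

For a network with stoichiometry vectors ``s_l`` and propensities
``a_l(x) = k_l g_l(x)``, the chemical master equation implies ordinary
differential equations for the means and central moments that are *linear* in
the rate constants:

    dM_r/dt = sum_l k_l F_rl(M)

with stoichiometric moment functions

    F_{mu_i, l} = s_li E[g_l]
    F_{C_ij, l} = s_li Cov(X_j, g_l) + s_lj Cov(X_i, g_l) + s_li s_lj E[g_l]

Every expectation is expanded about the mean, e.g. E[X_a X_b] =
mu_a mu_b + C_ab, so each F is a polynomial in means, second and (for
bimolecular propensities) third central moments.  Because the regression
targets stop at order two while order-three moments enter only as *inputs*
estimated from data, no moment-closure approximation is needed.

Moment indexing convention: a moment is keyed by the sorted tuple of the
species indices it involves — ``(i,)`` is the mean of species i, ``(i, j)``
the central second moment (variance if i == j), ``(i, j, k)`` a central third
moment.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .network import Reaction, ReactionNetwork, stoichiometry_vector

__all__ = [
    "MomentKey",
    "moment_basis",
    "MomentPoly",
    "MomentEquations",
    "derive_moment_equations",
    "required_input_moments",
    "evaluate_design_entry",
]

#: a moment index: sorted tuple of species indices, length = moment order.
MomentKey = tuple

# ---------------------------------------------------------------------------
# polynomial arithmetic over moment symbols


class MomentPoly(dict):
    """Sparse polynomial over moment symbols.

    Maps a monomial — a sorted tuple of :data:`MomentKey` factors — to its
    real coefficient.  The empty tuple is the constant monomial.
    """

    @classmethod
    def zero(cls) -> "MomentPoly":
        return cls()

    @classmethod
    def term(cls, coeff: float, *keys: MomentKey) -> "MomentPoly":
        mono = tuple(sorted(tuple(sorted(k)) for k in keys))
        return cls({mono: coeff}) if coeff != 0 else cls()

    def __add__(self, other: "MomentPoly") -> "MomentPoly":
        out = MomentPoly(self)
        for mono, c in other.items():
            out[mono] = out.get(mono, 0.0) + c
            if out[mono] == 0:
                del out[mono]
        return out

    def scaled(self, a: float) -> "MomentPoly":
        if a == 0:
            return MomentPoly()
        return MomentPoly({m: a * c for m, c in self.items()})

    def keys_used(self) -> set:
        return {k for mono in self for k in mono}

    def __call__(self, moments: dict):
        return evaluate_design_entry(self, moments)

    def pretty(self, names: list[str] | None = None) -> str:
        def sym(key):
            lbl = ",".join(names[i] if names else str(i) for i in key)
            return {1: f"mu[{lbl}]", 2: f"C[{lbl}]", 3: f"M3[{lbl}]"}[len(key)]

        if not self:
            return "0"
        parts = []
        for mono in sorted(self):
            c = self[mono]
            body = "*".join(sym(k) for k in mono) or "1"
            parts.append(f"{'+' if c >= 0 else '-'} {abs(c):g}*{body}")
        return " ".join(parts).lstrip("+ ")


def _expected_g(reaction: Reaction) -> MomentPoly:
    """E[g_l(X)] expanded in central moments."""
    ra = reaction.reactants
    if len(ra) == 0:
        return MomentPoly.term(1.0)
    if len(ra) == 1:
        return MomentPoly.term(1.0, (ra[0],))
    a, b = ra
    if a != b:
        # E[X_a X_b] = mu_a mu_b + C_ab
        return MomentPoly.term(1.0, (a,), (b,)) + MomentPoly.term(1.0, (a, b))
    # E[X_a (X_a - 1)] = mu_a^2 + C_aa - mu_a
    return (
        MomentPoly.term(1.0, (a,), (a,))
        + MomentPoly.term(1.0, (a, a))
        + MomentPoly.term(-1.0, (a,))
    )


def _cov_x_g(i: int, reaction: Reaction) -> MomentPoly:
    """Cov(X_i, g_l(X)) expanded in central moments (order <= 3)."""
    ra = reaction.reactants
    if len(ra) == 0:
        return MomentPoly.zero()
    if len(ra) == 1:
        return MomentPoly.term(1.0, (i, ra[0]))
    a, b = ra
    if a != b:
        # Cov(X_i, X_a X_b) = mu_a C_ib + mu_b C_ia + M3_iab
        return (
            MomentPoly.term(1.0, (a,), (i, b))
            + MomentPoly.term(1.0, (b,), (i, a))
            + MomentPoly.term(1.0, (i, a, b))
        )
    # Cov(X_i, X_a^2 - X_a) = 2 mu_a C_ia + M3_iaa - C_ia
    return (
        MomentPoly.term(2.0, (a,), (i, a))
        + MomentPoly.term(1.0, (i, a, a))
        + MomentPoly.term(-1.0, (i, a))
    )


# ---------------------------------------------------------------------------
# basis and derivation


def moment_basis(n_species: int, max_order: int = 2) -> list[MomentKey]:
    """Regression-target moment indices: means, then variances, then
    covariances (i < j), each block lexicographic."""
    if max_order not in (1, 2):
        raise ValueError("regression targets are limited to orders 1 and 2")
    basis: list[MomentKey] = [(i,) for i in range(n_species)]
    if max_order == 2:
        basis += [(i, i) for i in range(n_species)]
        basis += list(itertools.combinations(range(n_species), 2))
    return basis


@dataclass
class MomentEquations:
    """dM_r/dt = sum_l k_l F_rl for each target moment r.

    ``functions`` maps each target key to a sparse ``{rate_id: MomentPoly}``
    of the reactions with a nonzero contribution.
    """

    targets: list[MomentKey]
    functions: dict[MomentKey, dict[int, MomentPoly]]
    n_species: int

    def report(self, species_names: list[str] | None = None) -> str:
        """Human-readable listing, one line per (target, reaction) pair."""
        lines = []
        for r in self.targets:
            lbl = ",".join(species_names[i] if species_names else str(i) for i in r)
            head = f"d{'mu' if len(r) == 1 else 'C'}[{lbl}]/dt"
            for l, poly in sorted(self.functions[r].items()):
                lines.append(f"{head}  k{l}: {poly.pretty(species_names)}")
        return "\n".join(lines)


def derive_moment_equations(network: ReactionNetwork, max_order: int = 2) -> MomentEquations:
    """Derive the stoichiometric moment functions F_rl for every target
    moment of order <= ``max_order`` and every reaction in the network."""
    n = network.n_species
    targets = moment_basis(n, max_order)
    functions: dict[MomentKey, dict[int, MomentPoly]] = {r: {} for r in targets}

    for l, rx in enumerate(network.reactions):
        s = stoichiometry_vector(rx, n)
        eg = _expected_g(rx)
        touched = np.nonzero(s)[0]
        cov_cache = {int(i): _cov_x_g(int(i), rx) for i in range(n)}
        for i in touched:
            f = eg.scaled(float(s[i]))
            if f:
                key = (int(i),)
                functions[key][l] = functions[key].get(l, MomentPoly()) + f
        if max_order >= 2:
            for key in targets:
                if len(key) != 2:
                    continue
                i, j = key
                if s[i] == 0 and s[j] == 0:
                    continue
                f = cov_cache[j].scaled(float(s[i])) + cov_cache[i].scaled(float(s[j]))
                f = f + eg.scaled(float(s[i] * s[j]))
                if f:
                    functions[key][l] = functions[key].get(l, MomentPoly()) + f
    # drop exact-zero leftovers
    for r in targets:
        functions[r] = {l: p for l, p in functions[r].items() if p}
    return MomentEquations(targets, functions, n)


def required_input_moments(eqs: MomentEquations) -> set:
    """Every moment index appearing in any stoichiometric moment function."""
    out: set = set()
    for per_target in eqs.functions.values():
        for poly in per_target.values():
            out |= poly.keys_used()
    return out


def evaluate_design_entry(f: MomentPoly, moments: dict):
    """Evaluate a stoichiometric moment function at given moment values.

    ``moments`` maps moment keys to scalars or aligned numpy arrays (e.g. one
    value per time point); the result broadcasts accordingly.
    """
    total = 0.0
    for mono, c in f.items():
        term = c
        for key in mono:
            try:
                term = term * moments[key]
            except KeyError:
                raise KeyError(f"missing moment value for index {key}") from None
        total = total + term
    return total
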