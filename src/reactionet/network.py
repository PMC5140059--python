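"""Mass-action reaction networks and candidate reaction libraries.

A network is a list of named species plus a list of reactions, each with at
most two reactant and two product molecules.  The same container doubles as a
ground-truth model (rates present) and as the overcomplete candidate library
over which structure learning operates (rates absent).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Species",
    "Reaction",
    "ReactionNetwork",
    "CandidateLibrary",
    "enumerate_candidates",
    "stoichiometry_vector",
    "mass_action_propensity",
    "fixture_network",
]


@dataclass(frozen=True)
class Species:
    """A chemical species with a canonical position in the state vector."""

    name: str
    index: int


@dataclass(frozen=True)
class Reaction:
    """A unary or binary mass-action reaction.

    ``reactants`` and ``products`` are sorted tuples of species indices with
    total multiplicity at most two on each side.  ``rate_value`` is the
    mass-action rate constant; it is ``None`` for library candidates.  For a
    doubled reactant (homodimerisation) the propensity convention is
    ``g(x) = x (x - 1)`` with no 1/2 factor; the factor is absorbed into the
    rate constant.
    """

    reactants: tuple[int, ...]
    products: tuple[int, ...]
    rate_id: int = 0
    rate_value: float | None = None

    def __post_init__(self):
        object.__setattr__(self, "reactants", tuple(sorted(self.reactants)))
        object.__setattr__(self, "products", tuple(sorted(self.products)))
        if len(self.reactants) > 2 or len(self.products) > 2:
            raise ValueError("at most two molecules on each side of a reaction")
        if self.reactants == self.products:
            raise ValueError("reactant and product multisets must differ")
        if self.rate_value is not None and self.rate_value < 0:
            raise ValueError("rate constants must be nonnegative")

    @property
    def key(self) -> tuple[tuple[int, ...], tuple[int, ...]]:
        """Canonical identity: (sorted reactants, sorted products)."""
        return (self.reactants, self.products)

    def label(self, species: list[Species]) -> str:
        fmt = lambda side: " + ".join(species[i].name for i in side) if side else "0"
        return f"{fmt(self.reactants)} -> {fmt(self.products)}"


@dataclass
class ReactionNetwork:
    """An ordered species list plus an ordered reaction list."""

    species: list[Species]
    reactions: list[Reaction]

    def __post_init__(self):
        names = [s.name for s in self.species]
        if len(set(names)) != len(names):
            raise ValueError("species names must be unique")
        for pos, s in enumerate(self.species):
            if s.index != pos:
                raise ValueError("species indices must be contiguous 0..N-1")
        n = len(self.species)
        for r in self.reactions:
            for i in (*r.reactants, *r.products):
                if not 0 <= i < n:
                    raise ValueError(f"reaction references unknown species {i}")

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    @property
    def species_names(self) -> list[str]:
        return [s.name for s in self.species]

    def with_rates(self, rates) -> "ReactionNetwork":
        rates = np.asarray(rates, dtype=float)
        if rates.shape != (self.n_reactions,):
            raise ValueError("one rate per reaction required")
        rx = [replace(r, rate_value=float(k)) for r, k in zip(self.reactions, rates)]
        return ReactionNetwork(self.species, rx)

    def rates(self) -> np.ndarray:
        if any(r.rate_value is None for r in self.reactions):
            raise ValueError("network has reactions without rate values")
        return np.array([r.rate_value for r in self.reactions])

    def stoichiometry_matrix(self) -> np.ndarray:
        """(L x N) matrix of net stoichiometric changes."""
        return np.array(
            [stoichiometry_vector(r, self.n_species) for r in self.reactions],
            dtype=np.int64,
        ).reshape(self.n_reactions, self.n_species)


@dataclass
class CandidateLibrary:
    """An enumerated reaction library with optional prior-knowledge flags."""

    network: ReactionNetwork
    known_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.known_mask is None:
            self.known_mask = np.zeros(self.network.n_reactions, dtype=bool)
        self.known_mask = np.asarray(self.known_mask, dtype=bool)
        if self.known_mask.shape != (self.network.n_reactions,):
            raise ValueError("known_mask must have one entry per reaction")
        keys = [r.key for r in self.network.reactions]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate candidate reactions in library")

    def mark_known(self, reactions: list[Reaction]) -> "CandidateLibrary":
        """Return a copy with the given reactions flagged as prior knowledge."""
        keys = {r.key for r in reactions}
        mask = np.array([r.key in keys for r in self.network.reactions])
        missing = keys - {r.key for r in self.network.reactions}
        if missing:
            raise ValueError(f"prior-knowledge reactions not in library: {missing}")
        return CandidateLibrary(self.network, mask)


def stoichiometry_vector(reaction: Reaction, n_species: int) -> np.ndarray:
    """Net change vector s_l: products minus reactants, per species."""
    for i in (*reaction.reactants, *reaction.products):
        if i >= n_species:
            raise ValueError("reaction references species beyond n_species")
    s = np.zeros(n_species, dtype=np.int64)
    for i in reaction.products:
        s[i] += 1
    for i in reaction.reactants:
        s[i] -= 1
    return s


def mass_action_propensity(reaction: Reaction):
    """Return the state-dependent factor g_l of the propensity a_l = k_l g_l(x).

    Returned as a callable on integer count vectors; g is x_a for a unary
    reactant, x_a*x_b for distinct reactants, x_a*(x_a - 1) for a homodimer,
    and 1 for an empty reactant side (zeroth-order source reactions, which can
    appear in explicit network specifications though never in enumerated
    libraries).
    """
    ra = reaction.reactants
    if len(ra) == 0:
        return lambda x: np.ones(np.shape(x)[:-1]) if np.ndim(x) > 1 else 1.0
    if len(ra) == 1:
        a = ra[0]
        return lambda x: np.asarray(x)[..., a]
    a, b = ra
    if a == b:
        return lambda x: np.asarray(x)[..., a] * (np.asarray(x)[..., a] - 1)
    return lambda x: np.asarray(x)[..., a] * np.asarray(x)[..., b]


def enumerate_candidates(
    species: list[Species],
    allowed_pairs: dict | None = None,
) -> CandidateLibrary:
    """Enumerate every unary/binary candidate reaction over the species.

    Three forms are generated, in this deterministic order, each block sorted
    lexicographically by species indices:

    * conversions A -> B, one per unordered pair, canonical direction from the
      lower to the higher species index;
    * splits A -> B + C with A, B, C pairwise distinct;
    * associations A + B -> C with A, B, C pairwise distinct.

    For N species this yields C(N,2) + N*C(N-1,2) + C(N,2)*(N-2) candidates
    (2275 for N = 14).

    ``allowed_pairs``, if given, is a module constraint of the form
    ``{"modules": {name: [species names]}, "cross_module_reactions":
    [(reactants, products), ...]}``: the three forms are enumerated within each
    module only, and the explicit cross-module list is appended verbatim.
    """
    if len(species) < 2:
        raise ValueError("candidate enumeration needs at least two species")
    name_to_idx = {s.name: s.index for s in species}

    if allowed_pairs is None:
        groups = [list(range(len(species)))]
        cross: list[Reaction] = []
    else:
        modules = allowed_pairs.get("modules", {})
        seen: set[int] = set()
        groups = []
        for members in modules.values():
            idx = sorted(name_to_idx[m] for m in members)
            if seen & set(idx):
                raise ValueError("modules must partition the species")
            seen |= set(idx)
            groups.append(idx)
        cross = []
        for reactants, products in allowed_pairs.get("cross_module_reactions", []):
            cross.append(
                Reaction(
                    tuple(name_to_idx[m] for m in reactants),
                    tuple(name_to_idx[m] for m in products),
                )
            )

    conversions, splits, assocs = [], [], []
    for idx in groups:
        for a, b in itertools.combinations(idx, 2):
            conversions.append(Reaction((a,), (b,)))
        for a in idx:
            for b, c in itertools.combinations([i for i in idx if i != a], 2):
                splits.append(Reaction((a,), (b, c)))
        for a, b in itertools.combinations(idx, 2):
            for c in idx:
                if c != a and c != b:
                    assocs.append(Reaction((a, b), (c,)))

    order = lambda r: (r.reactants, r.products)
    ordered = sorted(conversions, key=order) + sorted(splits, key=order) + sorted(assocs, key=order)
    ordered += [r for r in cross if r.key not in {q.key for q in ordered}]
    reactions = [replace(r, rate_id=i) for i, r in enumerate(ordered)]
    return CandidateLibrary(ReactionNetwork(list(species), reactions))


def make_species(names: list[str]) -> list[Species]:
    return [Species(n, i) for i, n in enumerate(names)]


#: default rate constants for the enzymatic fixture: association E+S->ES,
#: dissociation ES->E+S, catalysis ES->E+P (Km = (k_off+k_cat)/k_on = 100).
ENZYMATIC_RATES = (0.002, 0.1, 0.1)

#: default initial copy numbers (E, S, ES, P) for the enzymatic fixture.
ENZYMATIC_X0 = (100, 200, 0, 0)

#: snapshot window start: ~4 relaxation times of the fast binding mode
#: (tau = 1/(k_on(E0+S0) + k_off + k_cat) ~ 1.25), so that the sampled
#: dynamics lie on the slow manifold that interpolation can resolve.
ENZYMATIC_T_START = 5.0

#: simulation horizon giving >90% substrate conversion under the defaults.
ENZYMATIC_T_END = 50.0


def fixture_network(
    kind: str,
    n_species: int = 4,
    n_reactions: int = 3,
    seed: int = 0,
    rates=None,
) -> ReactionNetwork:
    """Build a benchmark network.

    ``kind="enzymatic"`` returns the four-species Michaelis-Menten motif
    E + S -> ES, ES -> E + S, ES -> E + P with configurable rates.
    ``kind="random_sparse"`` samples ``n_reactions`` distinct candidates from
    the unconstrained library over ``n_species`` generic species,
    reproducibly under ``seed``, with rates drawn log-uniformly in
    [1e-2, 1].
    """
    if kind == "enzymatic":
        sp = make_species(["E", "S", "ES", "P"])
        k = ENZYMATIC_RATES if rates is None else tuple(rates)
        rx = [
            Reaction((0, 1), (2,), 0, k[0]),
            Reaction((2,), (0, 1), 1, k[1]),
            Reaction((2,), (0, 3), 2, k[2]),
        ]
        return ReactionNetwork(sp, rx)
    if kind == "random_sparse":
        sp = make_species([f"X{i}" for i in range(n_species)])
        lib = enumerate_candidates(sp)
        if n_reactions > lib.network.n_reactions:
            raise ValueError(
                f"requested {n_reactions} reactions but the library has only "
                f"{lib.network.n_reactions}"
            )
        rng = np.random.default_rng(seed)
        pick = rng.choice(lib.network.n_reactions, size=n_reactions, replace=False)
        if rates is None:
            rates = 10.0 ** rng.uniform(-2, 0, size=n_reactions)
        rx = [
            replace(lib.network.reactions[j], rate_id=i, rate_value=float(k))
            for i, (j, k) in enumerate(zip(sorted(pick), rates))
        ]
        return ReactionNetwork(sp, rx)
    raise ValueError(f"unknown fixture kind: {kind!r}")
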