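"""Reaction networks, mass-action propensities and truncated state spaces.

A network is a set of species together with mass-action reactions given by
integer reactant/product stoichiometries and a positive rate constant.  The
stochastic propensity of reaction ``r`` in state ``X`` follows the standard
falling-factorial combinatorics

    a_r(X) = c_r * prod_s X_s (X_s - 1) ... (X_s - m_{r,s} + 1),

with no division by ``m!``; rate-constant units are ``(molecules^(order-1) s)^-1``
so that zeroth-order propensities are the constant itself.

The chemical master equation lives on an infinite lattice; all numerical work
here happens on a finite box ``Omega`` (:class:`StateSpace`), enumerated in
lexicographic order over species in declaration order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "SpeciesSet",
    "Reaction",
    "ReactionNetwork",
    "StateSpace",
    "propensity",
    "propensity_table",
    "builtin_network",
    "read_network",
    "write_network",
    "BUILTIN_NAMES",
]


class ConfigError(ValueError):
    """A network configuration violated the schema."""


@dataclass(frozen=True)
class SpeciesSet:
    """Ordered collection of species identifiers."""

    names: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.names) == 0:
            raise ValueError("species set must be nonempty")
        if len(set(self.names)) != len(self.names):
            raise ValueError(f"duplicate species names: {self.names}")
        if any(not n for n in self.names):
            raise ValueError("species names must be nonempty strings")

    @property
    def N(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)


@dataclass(frozen=True)
class Reaction:
    """A single mass-action reaction.

    ``reactant_stoich`` and ``product_stoich`` are per-species molecule
    counts (length N); ``rate_constant`` is the stochastic rate constant.
    """

    reactant_stoich: tuple[int, ...]
    product_stoich: tuple[int, ...]
    rate_constant: float

    def __post_init__(self) -> None:
        if len(self.reactant_stoich) != len(self.product_stoich):
            raise ValueError("stoichiometry vectors differ in length")
        if any(m < 0 for m in self.reactant_stoich + self.product_stoich):
            raise ValueError("stoichiometries must be nonnegative")
        if not (self.rate_constant > 0):
            raise ValueError(f"rate constant must be positive, got {self.rate_constant}")

    @property
    def net_change(self) -> tuple[int, ...]:
        return tuple(p - m for m, p in zip(self.reactant_stoich, self.product_stoich))

    @property
    def order(self) -> int:
        return sum(self.reactant_stoich)


@dataclass(frozen=True)
class ReactionNetwork:
    species: SpeciesSet
    reactions: tuple[Reaction, ...]

    def __post_init__(self) -> None:
        if len(self.reactions) == 0:
            raise ValueError("network needs at least one reaction")
        for rx in self.reactions:
            if len(rx.reactant_stoich) != self.species.N:
                raise ValueError("reaction stoichiometry length != species count")

    @property
    def N(self) -> int:
        return self.species.N

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    def reactant_matrix(self) -> np.ndarray:
        """(R, N) integer matrix of reactant stoichiometries."""
        return np.array([rx.reactant_stoich for rx in self.reactions], dtype=np.int64)

    def net_change_matrix(self) -> np.ndarray:
        """(R, N) integer matrix of net state changes."""
        return np.array([rx.net_change for rx in self.reactions], dtype=np.int64)

    def rate_constants(self) -> np.ndarray:
        return np.array([rx.rate_constant for rx in self.reactions], dtype=float)


@dataclass(frozen=True)
class StateSpace:
    """Finite box Omega of molecule counts, one [lower, upper] range per species.

    States are enumerated lexicographically in species declaration order
    (first species varies slowest); every vectorized table in the package
    indexes states in this fixed order.
    """

    lower: tuple[int, ...]
    upper: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.lower) != len(self.upper):
            raise ValueError("bound vectors differ in length")
        if any(l < 0 for l in self.lower):
            raise ValueError("lower bounds must be nonnegative")
        if any(u < l for l, u in zip(self.lower, self.upper)):
            raise ValueError("upper bound below lower bound")

    @property
    def N(self) -> int:
        return len(self.lower)

    @property
    def shape(self) -> tuple[int, ...]:
        return tuple(u - l + 1 for l, u in zip(self.lower, self.upper))

    @property
    def n_states(self) -> int:
        return int(np.prod(self.shape))

    def states(self) -> np.ndarray:
        """(n_states, N) integer array of all states in enumeration order."""
        axes = [np.arange(l, u + 1) for l, u in zip(self.lower, self.upper)]
        mesh = np.meshgrid(*axes, indexing="ij")
        return np.stack([m.ravel() for m in mesh], axis=1).astype(np.int64)

    def ravel_index(self, X: np.ndarray) -> np.ndarray:
        """Flat enumeration index of states ``X`` (…, N); caller guarantees membership."""
        X = np.asarray(X, dtype=np.int64)
        rel = X - np.array(self.lower, dtype=np.int64)
        return np.ravel_multi_index(tuple(rel[..., s] for s in range(self.N)), self.shape)

    def contains(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.int64)
        lo = np.array(self.lower)
        hi = np.array(self.upper)
        return np.all((X >= lo) & (X <= hi), axis=-1)

    def boundary_mask(self) -> np.ndarray:
        """Boolean mask over states touching a *truncating* face of the box.

        Upper faces always truncate the lattice; a lower face only does if
        its bound is positive (count 0 is a genuine state, not an artifact).
        """
        S = self.states()
        lo = np.array(self.lower)
        hi = np.array(self.upper)
        return np.any((S == hi) | ((S == lo) & (lo > 0)), axis=1)


# ---------------------------------------------------------------------------
# Propensities
# ---------------------------------------------------------------------------

def propensity(network: ReactionNetwork, r: int, X: Sequence[int]) -> float:
    """Stochastic mass-action propensity of reaction ``r`` in state ``X``."""
    if not 0 <= r < network.n_reactions:
        raise IndexError(f"reaction index {r} out of range")
    X = np.asarray(X, dtype=np.int64)
    if X.shape != (network.N,):
        raise ValueError(f"state must have length {network.N}")
    if np.any(X < 0):
        raise ValueError("negative molecule count")
    rx = network.reactions[r]
    a = rx.rate_constant
    for s, m in enumerate(rx.reactant_stoich):
        for l in range(m):
            a *= X[s] - l
    return max(float(a), 0.0)


def propensity_table(network: ReactionNetwork, states: np.ndarray) -> np.ndarray:
    """(n_states, R) propensities for every state row of ``states``."""
    states = np.asarray(states, dtype=np.int64)
    n = states.shape[0]
    out = np.empty((n, network.n_reactions), dtype=float)
    for r, rx in enumerate(network.reactions):
        a = np.full(n, rx.rate_constant)
        for s, m in enumerate(rx.reactant_stoich):
            for l in range(m):
                a = a * (states[:, s] - l)
        out[:, r] = np.maximum(a, 0.0)
    return out


# ---------------------------------------------------------------------------
# Built-in benchmark fixtures
# ---------------------------------------------------------------------------

def _rx(species: SpeciesSet, reactants: Mapping[str, int], products: Mapping[str, int],
        rate: float) -> Reaction:
    m = [0] * species.N
    p = [0] * species.N
    for name, cnt in reactants.items():
        m[species.index(name)] = cnt
    for name, cnt in products.items():
        p[species.index(name)] = cnt
    return Reaction(tuple(m), tuple(p), rate)


def _schlogl() -> tuple[ReactionNetwork, StateSpace, dict[tuple[int, ...], float]]:
    sp = SpeciesSet(("X",))
    rxs = (
        _rx(sp, {"X": 3}, {"X": 2}, 1.5e-3),   # 3X -> 2X
        _rx(sp, {"X": 2}, {"X": 3}, 1.5e-1),   # 2X -> 3X
        _rx(sp, {"X": 1}, {}, 3.5),            # X -> 0
        _rx(sp, {}, {"X": 1}, 22.0),           # 0 -> X
    )
    net = ReactionNetwork(sp, rxs)
    omega = StateSpace((0,), (150,))
    init = {(1,): 38.01, (2,): 2.10e3}
    return net, omega, init


def _wilhelm() -> tuple[ReactionNetwork, StateSpace, dict[tuple[int, ...], float]]:
    sp = SpeciesSet(("X", "Y"))
    rxs = (
        _rx(sp, {"Y": 1}, {"X": 2}, 35.0),           # Y -> 2X
        _rx(sp, {"X": 2}, {"X": 1, "Y": 1}, 1.0),    # 2X -> X + Y
        _rx(sp, {"X": 1, "Y": 1}, {"Y": 1}, 1.0),    # X + Y -> Y
        _rx(sp, {"X": 1}, {}, 9.74),                 # X -> 0
        _rx(sp, {}, {"X": 1}, 30.0),                 # 0 -> X
    )
    net = ReactionNetwork(sp, rxs)
    omega = StateSpace((0, 0), (120, 120))
    init = {(1, 0): 15.94, (0, 1): 7.14,
            (2, 0): 2.55e2, (1, 1): 1.24e2, (0, 2): 50.93}
    return net, omega, init


def _brusselator() -> tuple[ReactionNetwork, StateSpace, dict[tuple[int, ...], float]]:
    sp = SpeciesSet(("X", "Y"))
    rxs = (
        _rx(sp, {}, {"X": 1}, 10.0),                     # 0 -> X
        _rx(sp, {"X": 2, "Y": 1}, {"X": 3}, 9.0e-3),     # 2X + Y -> 3X
        _rx(sp, {"X": 1}, {"Y": 1}, 3.0),                # X -> Y
        _rx(sp, {"X": 1}, {}, 1.0),                      # X -> 0
    )
    net = ReactionNetwork(sp, rxs)
    omega = StateSpace((0, 0), (120, 120))
    init = {(1, 0): 10.68, (0, 1): 23.40,
            (2, 0): 1.46e2, (1, 1): 2.11e2, (0, 2): 5.79e2}
    return net, omega, init


def _viral() -> tuple[ReactionNetwork, StateSpace, dict[tuple[int, ...], float]]:
    # Goutsias' reduced model of viral infection: D = (template) DNA,
    # P = protein, R = RNA.
    sp = SpeciesSet(("D", "P", "R"))
    rxs = (
        _rx(sp, {"D": 1, "P": 1}, {}, 1.0),              # D + P -> 0
        _rx(sp, {"D": 1}, {"R": 1, "D": 1}, 3.0),        # D -> R + D
        _rx(sp, {"R": 1}, {}, 1.0),                      # R -> 0
        _rx(sp, {"R": 1}, {"D": 1, "R": 1}, 10.0),       # R -> D + R
        _rx(sp, {"R": 1}, {"P": 1, "R": 1}, 110.0),      # R -> P + R
        _rx(sp, {"P": 1}, {}, 200.0),                    # P -> 0
    )
    net = ReactionNetwork(sp, rxs)
    omega = StateSpace((0, 0, 0), (80, 80, 150))
    init = {(1, 0, 0): 15.41, (0, 1, 0): 25.53, (0, 0, 1): 49.56,
            (2, 0, 0): 2.37e2, (1, 1, 0): 3.89e2, (1, 0, 1): 7.65e2,
            (0, 2, 0): 6.42e2, (0, 1, 1): 1.26e3, (0, 0, 2): 2.41e3}
    return net, omega, init


_BUILTINS = {
    "schlogl": _schlogl,
    "wilhelm": _wilhelm,
    "brusselator": _brusselator,
    "viral": _viral,
}
BUILTIN_NAMES = tuple(_BUILTINS)


def builtin_network(name: str):
    """Return ``(network, state_space, initial_factorial_moments)`` for a benchmark.

    ``initial_factorial_moments`` maps exponent multi-indices (in species
    declaration order) to the first/second-order factorial moments of the
    benchmark's initial distribution, e.g. ``{(2,): 2100.0}`` for E[X(X-1)].
    """
    try:
        factory = _BUILTINS[name]
    except KeyError:
        raise KeyError(f"unknown builtin network {name!r}; choose from {BUILTIN_NAMES}")
    return factory()


# ---------------------------------------------------------------------------
# Config serialization (YAML; JSON is a YAML subset and parses too)
# ---------------------------------------------------------------------------

def _network_to_dict(network: ReactionNetwork, omega: StateSpace) -> dict:
    names = network.species.names
    rxs = []
    for rx in network.reactions:
        rxs.append({
            "reactants": {names[s]: int(m) for s, m in enumerate(rx.reactant_stoich) if m},
            "products": {names[s]: int(p) for s, p in enumerate(rx.product_stoich) if p},
            "rate": float(rx.rate_constant),
        })
    return {
        "species": list(names),
        "reactions": rxs,
        "state_space": {"lower": list(map(int, omega.lower)),
                        "upper": list(map(int, omega.upper))},
    }


def write_network(network: ReactionNetwork, omega: StateSpace) -> str:
    """Serialize a network + state space to a YAML config string."""
    return yaml.safe_dump(_network_to_dict(network, omega), sort_keys=False)


def read_network(text: str) -> tuple[ReactionNetwork, StateSpace]:
    """Parse a YAML/JSON network config; inverse of :func:`write_network`."""
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"config is not valid YAML/JSON: {exc}") from exc
    if not isinstance(doc, Mapping):
        raise ConfigError("config root must be a mapping")
    for key in ("species", "reactions", "state_space"):
        if key not in doc:
            raise ConfigError(f"missing required key {key!r}")
    names = doc["species"]
    if not isinstance(names, list) or not all(isinstance(n, str) for n in names):
        raise ConfigError("'species' must be a list of strings")
    sp = SpeciesSet(tuple(names))

    def side(mapping, where: str) -> tuple[int, ...]:
        counts = [0] * sp.N
        if mapping is None:
            return tuple(counts)
        if not isinstance(mapping, Mapping):
            raise ConfigError(f"{where} must be a mapping of species to counts")
        for name, cnt in mapping.items():
            if name not in names:
                raise ConfigError(f"{where} references unknown species {name!r}")
            if not isinstance(cnt, int) or cnt < 0:
                raise ConfigError(f"{where}[{name!r}] must be a nonnegative integer")
            counts[sp.index(name)] = cnt
        return tuple(counts)

    rxs = []
    for i, r in enumerate(doc["reactions"]):
        if not isinstance(r, Mapping) or "rate" not in r:
            raise ConfigError(f"reactions[{i}] must be a mapping with a 'rate' key")
        rate = r["rate"]
        if not isinstance(rate, (int, float)) or not rate > 0:
            raise ConfigError(f"reactions[{i}].rate must be a positive number, got {rate!r}")
        rxs.append(Reaction(side(r.get("reactants"), f"reactions[{i}].reactants"),
                            side(r.get("products"), f"reactions[{i}].products"),
                            float(rate)))
    ss = doc["state_space"]
    if not isinstance(ss, Mapping) or "lower" not in ss or "upper" not in ss:
        raise ConfigError("'state_space' must contain 'lower' and 'upper' lists")
    lower, upper = ss["lower"], ss["upper"]
    if len(lower) != sp.N or len(upper) != sp.N:
        raise ConfigError("state_space bounds must have one entry per species")
    if not all(isinstance(b, int) for b in list(lower) + list(upper)):
        raise ConfigError("state_space bounds must be integers")
    try:
        omega = StateSpace(tuple(lower), tuple(upper))
        net = ReactionNetwork(sp, tuple(rxs))
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc
    return net, omega
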