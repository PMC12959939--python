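"""Effects library: statistics entering the actor objective function and
the multinomial-logit choice probabilities driving micro-steps.

Seven effect families are supported: ``outdegree``, ``reciprocity``,
``transitive_triads``, ``dist2`` (number of vertices at geodesic distance
two), ``covariate_ego``, ``covariate_alter`` and ``dyadic_covariate``.
Actor covariates enter raw; dyadic covariates are mean-centered over the
off-diagonal cells, matching the conventions of the printed statistic
formulas.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np

from . import _core
from .networks import DirectedNetwork

__all__ = [
    "ActorCovariate",
    "DyadCovariate",
    "EffectSpec",
    "SaomParameters",
    "EffectModel",
    "compile_effects",
    "actor_statistic",
    "objective",
    "choice_probabilities",
    "EFFECT_NAMES",
]

EFFECT_CODES = {
    "outdegree": _core.OUTDEGREE,
    "reciprocity": _core.RECIPROCITY,
    "transitive_triads": _core.TRANSITIVE_TRIADS,
    "dist2": _core.DIST2,
    "covariate_ego": _core.COVARIATE_EGO,
    "covariate_alter": _core.COVARIATE_ALTER,
    "dyadic_covariate": _core.DYADIC_COVARIATE,
}
EFFECT_NAMES = tuple(EFFECT_CODES)
_COVARIATE_EFFECTS = {"covariate_ego", "covariate_alter"}
_DYADIC_EFFECTS = {"dyadic_covariate"}


@dataclasses.dataclass(frozen=True)
class ActorCovariate:
    """One value per node (e.g. an indicator of group membership).

    Ego/alter statistics use the grand-mean-centered values v_i - v-bar
    when ``centered`` (the default, following standard SAOM practice --
    with uncentered indicators the intercept-like outdegree weight is
    confounded with the covariate effects and calibrated parameter sets
    produce far denser networks than intended).
    """

    name: str
    values: np.ndarray
    centered: bool = True
    mean: float = dataclasses.field(init=False, default=0.0)

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1:
            raise ValueError(f"actor covariate {self.name!r} must be a vector")
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "mean",
                           float(vals.mean()) if self.centered else 0.0)

    def centered_values(self) -> np.ndarray:
        return self.values - self.mean


@dataclasses.dataclass(frozen=True)
class DyadCovariate:
    """One value per (ordered) node pair; the diagonal is ignored.

    When ``centered`` the off-diagonal mean is subtracted and cached in
    ``mean`` so the statistic uses w_ij - w-bar.
    """

    name: str
    values: np.ndarray
    centered: bool = True
    mean: float = dataclasses.field(init=False, default=0.0)

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 2 or vals.shape[0] != vals.shape[1]:
            raise ValueError(f"dyadic covariate {self.name!r} must be square")
        n = vals.shape[0]
        off = ~np.eye(n, dtype=bool)
        mean = float(vals[off].mean()) if self.centered else 0.0
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "mean", mean)

    def centered_values(self) -> np.ndarray:
        out = self.values - self.mean
        np.fill_diagonal(out, 0.0)
        return out


@dataclasses.dataclass(frozen=True)
class EffectSpec:
    """One named effect, optionally bound to a covariate."""

    name: str
    covariate: str | None = None

    def __post_init__(self):
        if self.name not in EFFECT_CODES:
            raise ValueError(
                f"unknown effect {self.name!r}; choose from {sorted(EFFECT_CODES)}")
        needs_cov = self.name in _COVARIATE_EFFECTS | _DYADIC_EFFECTS
        if needs_cov and not self.covariate:
            raise ValueError(f"effect {self.name!r} requires a covariate reference")
        if not needs_cov and self.covariate:
            raise ValueError(f"effect {self.name!r} takes no covariate")

    @property
    def label(self) -> str:
        return f"{self.name}({self.covariate})" if self.covariate else self.name


@dataclasses.dataclass
class SaomParameters:
    """SAOM parameters: per-period change rates and effect weights phi."""

    rates: np.ndarray  # one rate per period, all > 0
    phi: np.ndarray    # one weight per effect

    def __post_init__(self):
        self.rates = np.atleast_1d(np.asarray(self.rates, dtype=float))
        self.phi = np.asarray(self.phi, dtype=float)
        if np.any(self.rates <= 0):
            raise ValueError("rates must all be positive")

    def rate_for_period(self, m: int) -> float:
        """Rate for period m (0-based); a single rate applies everywhere."""
        if self.rates.size == 1:
            return float(self.rates[0])
        return float(self.rates[m])


@dataclasses.dataclass
class EffectModel:
    """Compiled effect specification: arrays consumable by the kernels."""

    effects: tuple[EffectSpec, ...]
    codes: np.ndarray          # (p,) int64 effect codes
    acov: np.ndarray           # (p, n) actor covariate values (0 if unused)
    dcov: np.ndarray           # (p, n, n) centered dyadic values (0 if unused)
    directed: bool
    n_nodes: int

    @property
    def n_effects(self) -> int:
        return len(self.effects)

    @property
    def labels(self) -> list[str]:
        return [e.label for e in self.effects]


def compile_effects(
    effects: Sequence[EffectSpec],
    n_nodes: int,
    directed: bool = True,
    covariates: Mapping[str, ActorCovariate | DyadCovariate] | None = None,
) -> EffectModel:
    """Resolve covariate references and pack effects into kernel arrays."""
    covariates = covariates or {}
    p = len(effects)
    codes = np.zeros(p, dtype=np.int64)
    acov = np.zeros((p, n_nodes), dtype=np.float64)
    dcov = np.zeros((p, n_nodes, n_nodes), dtype=np.float64)
    for e, spec in enumerate(effects):
        if not directed and spec.name == "reciprocity":
            raise ValueError("reciprocity is undefined for undirected networks")
        codes[e] = EFFECT_CODES[spec.name]
        if spec.name in _COVARIATE_EFFECTS:
            cov = covariates.get(spec.covariate)
            if not isinstance(cov, ActorCovariate):
                raise ValueError(
                    f"effect {spec.label!r} needs actor covariate {spec.covariate!r}")
            if cov.values.shape[0] != n_nodes:
                raise ValueError(
                    f"covariate {cov.name!r} has length {cov.values.shape[0]}, "
                    f"expected {n_nodes}")
            acov[e] = cov.centered_values()
        elif spec.name in _DYADIC_EFFECTS:
            cov = covariates.get(spec.covariate)
            if not isinstance(cov, DyadCovariate):
                raise ValueError(
                    f"effect {spec.label!r} needs dyadic covariate {spec.covariate!r}")
            if cov.values.shape[0] != n_nodes:
                raise ValueError(f"dyadic covariate {cov.name!r} has wrong shape")
            if not directed and not np.allclose(cov.values, cov.values.T):
                raise ValueError(
                    f"dyadic covariate {cov.name!r} must be symmetric for "
                    "undirected networks")
            dcov[e] = cov.centered_values()
    return EffectModel(tuple(effects), codes, acov, dcov, directed, n_nodes)


def actor_statistic(model: EffectModel, net: DirectedNetwork, actor: int,
                    effect_index: int) -> float:
    """Statistic of one compiled effect from ``actor``'s perspective."""
    if not 0 <= actor < net.n_nodes:
        raise ValueError(f"actor index {actor} out of range")
    return float(_core.actor_stat(
        np.ascontiguousarray(net.adjacency), actor,
        model.codes[effect_index], model.acov[effect_index],
        model.dcov[effect_index], model.directed))


def objective(model: EffectModel, net: DirectedNetwork, actor: int,
              phi: np.ndarray) -> float:
    """Objective function g_i = sum_e phi_e * statistic_e(i, u)."""
    phi = np.asarray(phi, dtype=float)
    return float(sum(
        phi[e] * actor_statistic(model, net, actor, e)
        for e in range(model.n_effects)))


def choice_probabilities(model: EffectModel, net: DirectedNetwork, actor: int,
                         phi: np.ndarray) -> np.ndarray:
    """Multinomial-logit probabilities over actor ``actor``'s alternatives.

    Returns a length-n vector indexed by target node j; the entry at
    ``j == actor`` is the probability of leaving the network unchanged,
    every other entry the probability of toggling the tie toward j.
    """
    if not 0 <= actor < net.n_nodes:
        raise ValueError(f"actor index {actor} out of range")
    phi = np.asarray(phi, dtype=float)
    n = net.n_nodes
    u = np.ascontiguousarray(net.adjacency)
    dst = np.empty((n, model.n_effects), dtype=np.float64)
    probs = np.empty(n, dtype=np.float64)
    _core.choice_probs(u, actor, phi, model.codes, model.acov, model.dcov,
                       model.directed, dst, probs)
    return probs
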