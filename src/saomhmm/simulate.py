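"""Continuous-time SAOM forward simulation.

Change opportunities arrive as a Poisson process with total intensity
n * delta (constant actor rates); each opportunity selects an actor
uniformly, who then toggles at most one tie according to the
multinomial-logit choice probabilities.  Periods are simulated by
accumulating exponential waiting times rather than pre-drawing a Poisson
count, matching the continuous-time description and leaving room for
non-constant rates later.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import _core
from .effects import EffectModel, SaomParameters
from .networks import DirectedNetwork, NetworkPanel

__all__ = [
    "MicroStep",
    "SamplePath",
    "total_rate",
    "select_actor",
    "micro_step",
    "simulate_period",
    "simulate_panel",
]


@dataclasses.dataclass(frozen=True)
class MicroStep:
    """One opportunity for change: at ``time``, ``actor`` toggles its tie
    toward ``target``; ``target == actor`` encodes no change."""

    time: float
    actor: int
    target: int


@dataclasses.dataclass
class SamplePath:
    """Ordered micro-steps augmenting one period of the panel."""

    steps: list[MicroStep]
    period: int = 0

    def __post_init__(self):
        times = [s.time for s in self.steps]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("micro-step times must be strictly increasing")

    @property
    def n_steps(self) -> int:
        return len(self.steps)

    def step_array(self) -> np.ndarray:
        """``(R, 2)`` array of (actor, target) pairs."""
        if not self.steps:
            return np.empty((0, 2), dtype=np.int64)
        return np.array([[s.actor, s.target] for s in self.steps], dtype=np.int64)

    def replay(self, start: DirectedNetwork) -> DirectedNetwork:
        """Apply the toggles in order to ``start``."""
        u = start.adjacency.copy()
        for s in self.steps:
            if s.actor != s.target:
                u[s.actor, s.target] = 1 - u[s.actor, s.target]
                if not start.directed:
                    u[s.target, s.actor] = u[s.actor, s.target]
        return DirectedNetwork(u, start.directed)


def total_rate(params: SaomParameters, n: int, period: int = 0) -> float:
    """Total intensity lambda = n * delta of the opportunity process."""
    return n * params.rate_for_period(period)


def select_actor(n: int, rng: np.random.Generator) -> int:
    """Uniform actor selection (constant rate functions)."""
    return int(rng.integers(n))


def micro_step(model: EffectModel, net: DirectedNetwork, actor: int,
               phi: np.ndarray, rng: np.random.Generator
               ) -> tuple[DirectedNetwork, int]:
    """Perform one micro-step decision for ``actor``; returns the next
    network and the chosen target (== actor when nothing changes)."""
    from .effects import choice_probabilities

    probs = choice_probabilities(model, net, actor, phi)
    j = int(rng.choice(net.n_nodes, p=probs))
    if j == actor:
        return net, j
    u = net.adjacency.copy()
    u[actor, j] = 1 - u[actor, j]
    if not net.directed:
        u[j, actor] = u[actor, j]
    return DirectedNetwork(u, net.directed), j


def simulate_period(model: EffectModel, u_start: DirectedNetwork,
                    params: SaomParameters, duration: float,
                    rng: np.random.Generator, period: int = 0
                    ) -> tuple[DirectedNetwork, SamplePath]:
    """Simulate one inter-wave period, returning the end network and the
    full micro-step sample path."""
    if duration < 0:
        raise ValueError("duration must be non-negative")
    u = np.ascontiguousarray(u_start.adjacency.copy())
    steps, times = _core.simulate_period_path(
        u, params.phi, params.rate_for_period(period), float(duration),
        model.codes, model.acov, model.dcov, model.directed, rng)
    path = SamplePath(
        steps=[MicroStep(float(t), int(i), int(j))
               for t, (i, j) in zip(times, steps)],
        period=period)
    return DirectedNetwork(u, u_start.directed), path


def simulate_panel(model: EffectModel, u_1: DirectedNetwork,
                   params: SaomParameters, times: np.ndarray,
                   rng: np.random.Generator) -> NetworkPanel:
    """Simulate a latent panel wave by wave from the first network."""
    times = np.asarray(times, dtype=float)
    nets = [u_1.copy()]
    for m in range(1, len(times)):
        dur = times[m] - times[m - 1]
        net, _ = simulate_period(model, nets[-1], params, dur, rng,
                                 period=m - 1)
        nets.append(net)
    return NetworkPanel(networks=nets, times=times, role="latent")
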