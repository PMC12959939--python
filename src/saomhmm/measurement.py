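"""Measurement model: independent per-dyad edge noise.

Given the true network u, each true edge survives into the observed
network with probability 1 - beta (beta = false-negative rate) and each
true non-edge appears as an edge with probability alpha (false-positive
rate), independently across dyads.  The emission density factorizes over
dyads, which yields a closed-form M-step for (alpha, beta) from posterior
discordance-count expectations.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Sequence

import numpy as np

from .networks import DirectedNetwork, NetworkPanel, discordance_counts

__all__ = [
    "MeasurementParameters",
    "emission_log_probability",
    "corrupt",
    "corrupt_panel",
    "mstep_rates",
]


@dataclasses.dataclass(frozen=True)
class MeasurementParameters:
    """False-positive rate alpha and false-negative rate beta."""

    alpha: float
    beta: float

    def __post_init__(self):
        if not (0 <= self.alpha < 1 and 0 <= self.beta < 1):
            raise ValueError("alpha and beta must lie in [0, 1)")
        if self.alpha > 1 - self.beta:
            warnings.warn(
                "alpha > 1 - beta: observations are anti-correlated with the "
                "true network", stacklevel=2)


def _xlogy(x: float, y: float) -> float:
    if x == 0:
        return 0.0
    return x * math.log(y) if y > 0 else -math.inf


def emission_log_probability(y: DirectedNetwork, u: DirectedNetwork,
                             meas: MeasurementParameters) -> float:
    """log f(y | u) = log[alpha^c (1-alpha)^d beta^b (1-beta)^a]."""
    dc = discordance_counts(u, y)
    return (_xlogy(dc.c, meas.alpha) + _xlogy(dc.d, 1 - meas.alpha)
            + _xlogy(dc.b, meas.beta) + _xlogy(dc.a, 1 - meas.beta))


def emission_logprob_particles(y: np.ndarray, particles: np.ndarray,
                               meas: MeasurementParameters,
                               directed: bool) -> np.ndarray:
    """Vectorized log f(y | u_k) for a stack of particles ``(K, n, n)``."""
    n = y.shape[0]
    if directed:
        mask = ~np.eye(n, dtype=bool)
    else:
        mask = np.triu(np.ones((n, n), dtype=bool), k=1)
    yv = y[mask].astype(np.float64)
    uv = particles[:, mask].astype(np.float64)
    a = uv @ yv
    b = uv.sum(axis=1) - a
    c = (1.0 - uv) @ yv
    d = (1.0 - uv).sum(axis=1) - c
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (np.where(c > 0, c * np.log(meas.alpha) if meas.alpha > 0
                        else -np.inf, 0.0)
               + np.where(d > 0, d * np.log1p(-meas.alpha), 0.0)
               + np.where(b > 0, b * np.log(meas.beta) if meas.beta > 0
                          else -np.inf, 0.0)
               + np.where(a > 0, a * np.log1p(-meas.beta), 0.0))
    return out


def corrupt(u: DirectedNetwork, meas: MeasurementParameters,
            rng: np.random.Generator) -> DirectedNetwork:
    """Draw one observed network from f(y | u)."""
    n = u.n_nodes
    flips = rng.random((n, n))
    y = u.adjacency.copy()
    keep_mask = u.adjacency == 1
    y[keep_mask & (flips < meas.beta)] = 0
    y[(~keep_mask) & (flips < meas.alpha)] = 1
    np.fill_diagonal(y, 0)
    if not u.directed:
        upper = np.triu(y, k=1)
        y = upper + upper.T
    return DirectedNetwork(y, u.directed)


def corrupt_panel(panel: NetworkPanel, meas: MeasurementParameters,
                  rng: np.random.Generator,
                  error_free_first: bool = True) -> NetworkPanel:
    """Corrupt every wave (the first wave is kept error-free by default,
    matching the assumption that it is observed without error)."""
    nets = []
    for m, net in enumerate(panel.networks):
        if m == 0 and error_free_first:
            nets.append(net.copy())
        else:
            nets.append(corrupt(net, meas, rng))
    return NetworkPanel(networks=nets, times=panel.times.copy(), role="observed")


def mstep_rates(lines: Sequence[NetworkPanel],
                observed: NetworkPanel) -> MeasurementParameters:
    """Closed-form M-step for (alpha, beta) from sampled latent series.

    alpha-hat = E[C] / E[C + D] and beta-hat = E[B] / E[A + B], with the
    posterior expectations approximated by equal-weight averages of the
    discordance counts over the latent lines and waves m = 2..M.  The
    first wave is conditioned error-free and contributes nothing.
    """
    A = B = C = D = 0
    for line in lines:
        if line.n_waves != observed.n_waves:
            raise ValueError("latent line and observed panel wave counts differ")
        for m in range(1, observed.n_waves):
            dc = discordance_counts(line.networks[m], observed.networks[m])
            A += dc.a
            B += dc.b
            C += dc.c
            D += dc.d
    if C + D == 0 or A + B == 0:
        raise ValueError(
            "degenerate latent sample: all-complete or all-empty true networks "
            "leave a rate undetermined")
    return MeasurementParameters(alpha=C / (C + D), beta=B / (A + B))
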