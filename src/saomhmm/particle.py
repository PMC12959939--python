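"""Particle filtering over latent network series.

A bootstrap-style forward filter for the hidden SAOM: wave 1 holds the
single error-free particle y_t1; at each later wave, ancestors are drawn
with probability proportional to the emission density of the *previous*
wave's observation given the previous wave's particles, and each chosen
ancestor is evolved through one SAOM period.  Ancestral lines traced
back through the recorded parent indices provide approximate draws from
the conditional law of the latent series given the observations.

Note the weight timing: the final observation never reweights the last
wave (the terminal line index is uniform).  ``weight_final=True`` opts
into additionally weighting the terminal index by the last wave's
emission density.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import _core
from .effects import EffectModel, SaomParameters
from .measurement import MeasurementParameters, emission_logprob_particles
from .networks import DirectedNetwork, NetworkPanel

__all__ = [
    "ParticleSystem",
    "LatentSeriesSample",
    "forward_filter",
    "sample_ancestral_lines",
]


@dataclasses.dataclass
class ParticleSystem:
    """K latent-network particles per wave with ancestor bookkeeping.

    ``particles[0]`` has shape (1, n, n) (the error-free first wave);
    ``particles[m]`` for m >= 1 has shape (K, n, n).  ``ancestors[m - 1]``
    holds, for each wave-m particle, the index of its wave-(m-1) parent.
    ``log_weights[m]`` are the emission log densities log f(y_m | zeta_m^k).
    """

    particles: list[np.ndarray]
    ancestors: list[np.ndarray]
    log_weights: list[np.ndarray]
    times: np.ndarray
    directed: bool
    K: int

    @property
    def n_waves(self) -> int:
        return len(self.particles)

    def effective_sample_sizes(self) -> np.ndarray:
        """Per-wave ESS of the normalized emission weights."""
        out = np.empty(self.n_waves)
        for m, lw in enumerate(self.log_weights):
            w = np.exp(lw - lw.max())
            w /= w.sum()
            out[m] = 1.0 / np.sum(w ** 2)
        return out


@dataclasses.dataclass
class LatentSeriesSample:
    """H sampled ancestral lines: ``lines[h]`` is an (M, n, n) array."""

    lines: np.ndarray   # (H, M, n, n)
    indices: np.ndarray  # (H, M) particle index per wave

    @property
    def n_lines(self) -> int:
        return self.lines.shape[0]

    def panels(self, times: np.ndarray, directed: bool) -> list[NetworkPanel]:
        out = []
        for h in range(self.n_lines):
            nets = [DirectedNetwork(self.lines[h, m].copy(), directed)
                    for m in range(self.lines.shape[1])]
            out.append(NetworkPanel(networks=nets, times=np.asarray(times),
                                    role="latent"))
        return out


def _resample(log_w: np.ndarray, K: int, rng: np.random.Generator,
              systematic: bool) -> np.ndarray:
    mx = log_w.max()
    if not np.isfinite(mx):
        raise RuntimeError(
            "all particle weights vanished (emission density zero for every "
            "particle); floor alpha and beta away from 0 to avoid this")
    w = np.exp(log_w - mx)
    w /= w.sum()
    if systematic:
        pos = (rng.random() + np.arange(K)) / K
        return np.searchsorted(np.cumsum(w), pos).astype(np.int64)
    return rng.choice(len(w), size=K, p=w).astype(np.int64)


def forward_filter(observed: NetworkPanel, params: SaomParameters,
                   meas: MeasurementParameters, model: EffectModel,
                   K: int, rng: np.random.Generator,
                   systematic: bool = False) -> ParticleSystem:
    """Run the forward particle system over the observed panel."""
    if K < 1:
        raise ValueError("K must be >= 1")
    n = observed.n_nodes
    M = observed.n_waves
    durs = observed.durations()
    y = [np.ascontiguousarray(w.adjacency) for w in observed.networks]

    particles = [y[0][None, :, :].copy()]
    ancestors: list[np.ndarray] = []
    log_weights = [emission_logprob_particles(y[0], particles[0], meas,
                                              observed.directed)]
    for m in range(1, M):
        prev = particles[m - 1]
        if prev.shape[0] == 1:
            idx = np.zeros(K, dtype=np.int64)
        else:
            idx = _resample(log_weights[m - 1], K, rng, systematic)
        out = np.empty((K, n, n), dtype=np.int8)
        _core.propagate_particles(
            prev, idx, params.phi, params.rate_for_period(m - 1),
            float(durs[m - 1]), model.codes, model.acov, model.dcov,
            model.directed, rng, out)
        particles.append(out)
        ancestors.append(idx)
        log_weights.append(emission_logprob_particles(y[m], out, meas,
                                                      observed.directed))
    return ParticleSystem(particles=particles, ancestors=ancestors,
                          log_weights=log_weights, times=observed.times.copy(),
                          directed=observed.directed, K=K)


def sample_ancestral_lines(ps: ParticleSystem, H: int,
                           rng: np.random.Generator,
                           weight_final: bool = False) -> LatentSeriesSample:
    """Trace H ancestral lines back through the particle genealogy.

    The terminal index is uniform over particles (the default, mirroring
    the filter recursion as printed)
    or, with ``weight_final``, drawn proportionally to the final wave's
    emission weights."""
    M = ps.n_waves
    n = ps.particles[0].shape[1]
    lines = np.empty((H, M, n, n), dtype=np.int8)
    indices = np.empty((H, M), dtype=np.int64)
    K = ps.particles[-1].shape[0]
    if weight_final and M > 1:
        zM = _resample(ps.log_weights[-1], H, rng, systematic=False)
    else:
        zM = rng.integers(K, size=H)
    for h in range(H):
        z = int(zM[h])
        indices[h, M - 1] = z
        lines[h, M - 1] = ps.particles[M - 1][z]
        for m in range(M - 2, -1, -1):
            z = int(ps.ancestors[m][z])
            indices[h, m] = z
            lines[h, m] = ps.particles[m][z]
    return LatentSeriesSample(lines=lines, indices=indices)
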