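"""SAOM parameter estimation by Robbins-Monro stochastic approximation.

Two routines are provided, both for a single network series or pooled
over several series that share observation times:

* :func:`fit_mom` -- method of moments: per-period forward simulations
  conditional on the previous wave; the update direction is the gap
  between observed and simulated target statistics (per-period Hamming
  change for the rates, cross-sectional statistic totals for the effect
  weights).
* :func:`fit_ml` -- sample-path-augmented maximum likelihood: each period
  is augmented with a micro-step path drawn by Metropolis-Hastings
  conditional on its endpoints; the complete-data score drives the
  updates (missing information principle).

Both run internally on (log rate, phi) so rate positivity is automatic,
estimate the scaling matrix D in a first phase by the score-function
(likelihood-ratio) method with ridge regularization, and return the mean
of the last half of the second-phase iterates.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from . import _core
from .effects import EffectModel, SaomParameters
from .networks import DirectedNetwork, NetworkPanel
from .simulate import MicroStep, SamplePath

__all__ = [
    "RobbinsMonroConfig",
    "default_rm_config",
    "EstimatorReport",
    "NonConvergenceError",
    "sample_path_logprob",
    "mh_sample_path",
    "complete_data_score",
    "fit_mom",
    "fit_ml",
]


class NonConvergenceError(RuntimeError):
    """Raised when a Robbins-Monro run diverges; carries the report."""

    def __init__(self, message: str, report: "EstimatorReport | None" = None):
        super().__init__(message)
        self.report = report


@dataclasses.dataclass
class RobbinsMonroConfig:
    """Tuning knobs for the stochastic-approximation runs.

    Phase 1 estimates the derivative matrix D by the score-function
    method over ``phase1_iters`` simulations.  Phase 2 runs
    ``phase2_iters`` updating steps split into ``n_subphases`` subphases
    of increasing length; the gain is constant within a subphase
    (``a0 / 2**(k-1)`` in subphase k) and the reported estimate is the
    mean of the final subphase's iterates.  With ``refresh_scaling`` the
    D matrix is re-estimated once after the first subphase, at the
    then-current parameter value.  ``mh_*`` settings apply to the path
    sampler in :func:`fit_ml` only.
    """

    a0: float = 0.5
    gain_exponent: float = 0.75
    n_subphases: int = 4
    phase1_iters: int = 80
    phase2_iters: int = 250
    refresh_scaling: bool = True
    max_step: float = 0.3
    ridge: float = 0.05
    condition_cap: float = 30.0
    mh_burn_in: int = 400
    mh_props_per_iter: int = 40
    n_diagnostic: int = 40
    phi_bound: float = 15.0
    log_rate_bound: float = 3.7

    def __post_init__(self):
        if self.a0 <= 0 or not 0 < self.gain_exponent <= 1:
            raise ValueError("gains must be positive and non-increasing")
        if self.phase1_iters < 1 or self.phase2_iters < 1:
            raise ValueError("phase iteration counts must be >= 1")


def default_rm_config(method: str) -> RobbinsMonroConfig:
    """Method-specific stochastic-approximation defaults.

    The ML routine needs long Metropolis-Hastings burn-in so the
    augmenting paths carry the correct number of opportunities (checked
    against the Fisher identity: the data-averaged conditional mean of
    the opportunity count must equal n*delta*dt), and a tight condition
    cap to damp random-walk wander along weakly identified directions
    when choices are nearly separated.  The MoM routine mixes nothing
    and tolerates a looser cap.
    """
    if method == "ml":
        return RobbinsMonroConfig(a0=0.25, phase1_iters=40,
                                  phase2_iters=400, condition_cap=8.0,
                                  mh_burn_in=3000, mh_props_per_iter=80)
    return RobbinsMonroConfig()


@dataclasses.dataclass
class EstimatorReport:
    """Estimates with optional standard errors and fit diagnostics."""

    labels: list[str]
    estimates: np.ndarray
    method: str
    se: np.ndarray | None = None
    converged: bool = True
    diverged: bool = False
    iterations: int = 0
    history: np.ndarray | None = None
    diagnostics: dict = dataclasses.field(default_factory=dict)
    settings: dict = dataclasses.field(default_factory=dict)
    warnings: list = dataclasses.field(default_factory=list)

    @property
    def t_ratios(self) -> np.ndarray | None:
        if self.se is None:
            return None
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.estimates / self.se

    def as_dict(self) -> dict:
        return dict(zip(self.labels, self.estimates.tolist()))


# ---------------------------------------------------------------------------
# sample-path likelihood and score


def _n_rates(params: SaomParameters) -> int:
    return params.rates.size


def sample_path_logprob(model: EffectModel, path: SamplePath,
                        u_start: DirectedNetwork, params: SaomParameters,
                        duration: float) -> float:
    """Log probability of one augmenting sample path (times integrated
    out): Poisson factor for the opportunity count, uniform actor
    selection, and the logit choice factor of every micro-step."""
    n = u_start.n_nodes
    steps = path.step_array()
    if steps.size and (steps.min() < 0 or steps.max() >= n):
        raise ValueError("path contains out-of-range node indices")
    score = np.zeros(1 + model.n_effects)
    lp = _core.path_logprob_score(
        np.ascontiguousarray(u_start.adjacency), steps, params.phi,
        params.rate_for_period(path.period), float(duration), model.codes,
        model.acov, model.dcov, model.directed, False, score)
    return float(lp)


def complete_data_score(model: EffectModel, params: SaomParameters,
                        series: NetworkPanel,
                        paths: Sequence[SamplePath]) -> np.ndarray:
    """Gradient of the complete-data log-likelihood with respect to
    (delta, phi), summing the per-period path scores.  With a single
    shared rate the rate components are pooled into one slot."""
    if len(paths) != series.n_waves - 1:
        raise ValueError("need one sample path per period")
    nr = _n_rates(params)
    out = np.zeros(nr + model.n_effects)
    durs = series.durations()
    score = np.zeros(1 + model.n_effects)
    for m, path in enumerate(paths):
        rate = params.rate_for_period(m)
        _core.path_logprob_score(
            np.ascontiguousarray(series.networks[m].adjacency),
            path.step_array(), params.phi, rate, float(durs[m]),
            model.codes, model.acov, model.dcov, model.directed, True, score)
        slot = 0 if nr == 1 else m
        out[slot] += score[0] / rate  # log-rate score -> d/d(delta)
        out[nr:] += score[1:]
    return out


def _direct_path_steps(u0: np.ndarray, u1: np.ndarray, directed: bool,
                       rng: np.random.Generator) -> np.ndarray:
    """A minimal toggle sequence carrying u0 to u1, in random order."""
    diff = (u0 != u1)
    if not directed:
        diff = np.triu(diff, k=1)
    else:
        np.fill_diagonal(diff, False)
    pairs = np.argwhere(diff)
    if len(pairs) == 0:
        return np.empty((0, 2), dtype=np.int64)
    order = rng.permutation(len(pairs))
    steps = pairs[order].astype(np.int64)
    if not directed:
        flip = rng.random(len(steps)) < 0.5
        steps[flip] = steps[flip][:, ::-1]
    return np.ascontiguousarray(steps)


def mh_sample_path(model: EffectModel, u_start: DirectedNetwork,
                   u_end: DirectedNetwork, params: SaomParameters,
                   duration: float, rng: np.random.Generator,
                   n_sweeps: int = 500, period: int = 0,
                   init_steps: np.ndarray | None = None) -> SamplePath:
    """Draw a sample path connecting ``u_start`` to ``u_end`` from (an
    approximation of) its conditional law under the current parameters."""
    if u_start.n_nodes != u_end.n_nodes or u_start.directed != u_end.directed:
        raise ValueError("endpoint networks must share shape and directedness")
    if init_steps is None:
        init_steps = _direct_path_steps(u_start.adjacency, u_end.adjacency,
                                        model.directed, rng)
    steps, _ = _core.mh_path_update(
        np.ascontiguousarray(u_start.adjacency), init_steps, params.phi,
        params.rate_for_period(period), float(duration), model.codes,
        model.acov, model.dcov, model.directed, int(n_sweeps), rng)
    R = len(steps)
    # event times are order statistics of uniforms and carry no extra
    # information given R; assign evenly spaced representative times
    times = (np.arange(1, R + 1) / (R + 1)) * duration
    return SamplePath(
        steps=[MicroStep(float(t), int(i), int(j))
               for t, (i, j) in zip(times, steps)],
        period=period)


# ---------------------------------------------------------------------------
# shared Robbins-Monro machinery


def _as_series_list(series) -> list[NetworkPanel]:
    if isinstance(series, NetworkPanel):
        return [series]
    out = list(series)
    if not out:
        raise ValueError("need at least one network series")
    t0 = out[0].times
    for s in out[1:]:
        if s.n_waves != out[0].n_waves or not np.allclose(s.times, t0):
            raise ValueError("pooled series must share observation times")
        if s.n_nodes != out[0].n_nodes or s.directed != out[0].directed:
            raise ValueError("pooled series must share shape and directedness")
    return out


def _init_theta(series: list[NetworkPanel], model: EffectModel,
                init: SaomParameters | None) -> np.ndarray:
    """Parameter vector [log delta_1..log delta_{M-1}, phi]."""
    M = series[0].n_waves
    n = series[0].n_nodes
    durs = series[0].durations()
    if init is not None:
        rates = (np.full(M - 1, init.rates[0]) if init.rates.size == 1
                 else np.asarray(init.rates, dtype=float))
        phi = np.asarray(init.phi, dtype=float)
        return np.concatenate([np.log(rates), phi])
    from .networks import hamming
    rates = np.empty(M - 1)
    for m in range(M - 1):
        ham = np.mean([hamming(s.networks[m], s.networks[m + 1]) for s in series])
        rates[m] = max(1.5 * ham / (n * durs[m]), 0.2)
    return np.concatenate([np.log(rates), np.zeros(model.n_effects)])


def _theta_to_params(theta: np.ndarray, n_periods: int) -> SaomParameters:
    return SaomParameters(rates=np.exp(theta[:n_periods]), phi=theta[n_periods:])


def _solve_scaling(D: np.ndarray, ridge: float,
                   condition_cap: float = 30.0) -> np.ndarray:
    """Regularized inverse of the phase-1 derivative estimate.

    The matrix is symmetrized and its eigenvalues floored at a fraction
    of the largest one, bounding the condition number: weakly identified
    directions then take gradient-sized rather than exploding steps.
    """
    dim = D.shape[0]
    scale = max(np.abs(np.diag(D)).mean(), 1e-3)
    S = (D + D.T) / 2.0 + ridge * scale * np.eye(dim)
    try:
        vals, vecs = np.linalg.eigh(S)
        floor = max(np.abs(vals).max() / condition_cap, 1e-8)
        vals = np.maximum(np.abs(vals), floor)
        Dinv = (vecs / vals) @ vecs.T
        if not np.all(np.isfinite(Dinv)):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        diag = np.abs(np.diag(D)) + ridge * scale
        Dinv = np.diag(1.0 / diag)
    return Dinv


def _project_bounds(theta: np.ndarray, n_periods: int,
                    rm: RobbinsMonroConfig) -> tuple[np.ndarray, bool]:
    """Clip iterates into the admissible box; report whether it bit."""
    if not np.all(np.isfinite(theta)):
        raise _Diverged
    clipped = theta.copy()
    clipped[:n_periods] = np.clip(theta[:n_periods], -rm.log_rate_bound,
                                  rm.log_rate_bound)
    clipped[n_periods:] = np.clip(theta[n_periods:], -rm.phi_bound,
                                  rm.phi_bound)
    return clipped, bool(np.any(clipped != theta))


class _Diverged(Exception):
    pass


def _subphase_lengths(total: int, n_sub: int) -> list[int]:
    w = np.array([2.0 ** k for k in range(n_sub)])
    lens = np.maximum((total * w / w.sum()).astype(int), 1)
    lens[-1] += total - lens.sum()
    return lens.tolist()


def _phase2(theta0: np.ndarray, Dinv: np.ndarray, draw, rm: RobbinsMonroConfig,
            n_periods: int, estimate_D=None
            ) -> tuple[np.ndarray, np.ndarray, int]:
    """Generic phase-2 loop: ``draw(theta)`` returns the update direction
    (moment gap or score).  Returns (estimate, history, bound_hits)."""
    theta, _ = _project_bounds(theta0, n_periods, rm)
    history = np.empty((rm.phase2_iters, theta.size))
    lengths = _subphase_lengths(rm.phase2_iters, rm.n_subphases)
    l = 0
    bound_hits = 0
    for k, n_k in enumerate(lengths):
        a_k = rm.a0 / 2.0 ** k
        sub_start = l
        for _ in range(n_k):
            step = a_k * (Dinv @ draw(theta))
            step = np.clip(step, -rm.max_step, rm.max_step)
            theta, hit = _project_bounds(theta + step, n_periods, rm)
            bound_hits += hit
            history[l] = theta
            l += 1
        if k == 0 and estimate_D is not None and rm.refresh_scaling:
            theta = history[sub_start:l].mean(axis=0)
            Dinv = estimate_D(theta)
    tail = history[rm.phase2_iters - lengths[-1]:]
    return tail.mean(axis=0), history, bound_hits


def _report_from_divergence(labels, theta, history, method, settings):
    n_hist = len(history)
    rep = EstimatorReport(
        labels=labels, estimates=np.asarray(theta), method=method,
        converged=False, diverged=True, iterations=n_hist,
        history=np.asarray(history) if n_hist else None, settings=settings,
        warnings=["Robbins-Monro iterates exceeded the divergence bound"])
    return rep


# ---------------------------------------------------------------------------
# method of moments


def _mom_observed(series: list[NetworkPanel], model: EffectModel) -> np.ndarray:
    from .networks import hamming
    M = series[0].n_waves
    p = model.n_effects
    obs = np.zeros(M - 1 + p)
    stat = np.empty(p)
    for s in series:
        for m in range(M - 1):
            obs[m] += hamming(s.networks[m], s.networks[m + 1])
            _core.total_stats(np.ascontiguousarray(s.networks[m + 1].adjacency),
                              model.codes, model.acov, model.dcov,
                              model.directed, stat)
            obs[M - 1:] += stat
    return obs


def fit_mom(series, model: EffectModel, init: SaomParameters | None = None,
            rm: RobbinsMonroConfig | None = None,
            rng: np.random.Generator | None = None) -> EstimatorReport:
    """Method-of-moments fit, pooled over the supplied series.

    Each iteration simulates every period forward from the data's
    previous wave and moves the parameters along D^-1 (observed -
    simulated).  Raises :class:`NonConvergenceError` on divergence.
    """
    series = _as_series_list(series)
    rm = rm or default_rm_config("mom")
    rng = rng or np.random.default_rng()
    M = series[0].n_waves
    n = series[0].n_nodes
    p = model.n_effects
    n_periods = M - 1
    dim = n_periods + p
    durs = series[0].durations()
    waves = [[np.ascontiguousarray(s.networks[m].adjacency) for m in range(M)]
             for s in series]
    obs = _mom_observed(series, model)
    theta = _init_theta(series, model, init)
    stat = np.empty(p)
    dst = np.empty((n, p))
    probs = np.empty(n)

    def simulate(theta, with_score):
        params = _theta_to_params(theta, n_periods)
        sim = np.zeros(dim)
        score = np.zeros(dim)
        sc = np.zeros(1 + p)
        for wv in waves:
            for m in range(n_periods):
                u = wv[m].copy()
                rate = params.rate_for_period(m)
                if with_score:
                    steps, _ = _core.simulate_period_path(
                        u, params.phi, rate, float(durs[m]), model.codes,
                        model.acov, model.dcov, model.directed, rng)
                    _core.path_logprob_score(
                        wv[m], steps, params.phi, rate, float(durs[m]),
                        model.codes, model.acov, model.dcov, model.directed,
                        True, sc)
                    score[m] += sc[0]
                    score[n_periods:] += sc[1:]
                else:
                    _core.evolve_period(u, params.phi, rate, float(durs[m]),
                                        model.codes, model.acov, model.dcov,
                                        model.directed, rng, dst, probs)
                sim[m] += int(np.sum(u != wv[m]) if model.directed
                              else np.sum(np.triu(u != wv[m], k=1)))
                _core.total_stats(u, model.codes, model.acov, model.dcov,
                                  model.directed, stat)
                sim[n_periods:] += stat
        return sim, score

    def estimate_D(th):
        """Derivative matrix by the score-function (likelihood-ratio)
        identity dE[s]/d(theta) = cov(s, score), from fresh simulations."""
        sims = np.empty((rm.phase1_iters, dim))
        scores = np.empty((rm.phase1_iters, dim))
        for it in range(rm.phase1_iters):
            sims[it], scores[it] = simulate(th, True)
        sc_c = scores - scores.mean(axis=0)
        si_c = sims - sims.mean(axis=0)
        D = si_c.T @ sc_c / rm.phase1_iters
        return _solve_scaling(D, rm.ridge, rm.condition_cap)

    Dinv = estimate_D(theta)
    labels = [f"rate_period_{m + 1}" for m in range(n_periods)] + model.labels
    settings = {"method": "mom", "n_series": len(series),
                "phase1_iters": rm.phase1_iters,
                "phase2_iters": rm.phase2_iters}
    try:
        est_theta, history, bound_hits = _phase2(
            theta, Dinv, lambda th: obs - simulate(th, False)[0], rm,
            n_periods, estimate_D=estimate_D)
    except _Diverged:
        raise NonConvergenceError(
            "method-of-moments Robbins-Monro run diverged",
            _report_from_divergence(labels, np.full(dim, np.nan), [], "mom",
                                    settings))

    # post-fit moment diagnostic at the estimate
    gaps = np.empty((rm.n_diagnostic, dim))
    for it in range(rm.n_diagnostic):
        gaps[it] = obs - simulate(est_theta, False)[0]
    gap_t = gaps.mean(axis=0) / np.maximum(gaps.std(axis=0, ddof=1), 1e-12)

    estimates = est_theta.copy()
    estimates[:n_periods] = np.exp(est_theta[:n_periods])
    warn = []
    if np.any(est_theta[:n_periods] < -rm.log_rate_bound + 0.05):
        warn.append("rate estimate at the zero boundary")
    if bound_hits > rm.phase2_iters // 4:
        warn.append("estimates repeatedly hit the admissible bounds")
    return EstimatorReport(
        labels=labels, estimates=estimates, method="mom",
        converged=bool(np.all(np.abs(gap_t) < 4.0)), iterations=rm.phase2_iters,
        history=history, settings=settings,
        diagnostics={"moment_gap_t": gap_t.tolist()}, warnings=warn)


# ---------------------------------------------------------------------------
# maximum likelihood with path augmentation


def fit_ml(series, model: EffectModel, init: SaomParameters | None = None,
           rm: RobbinsMonroConfig | None = None,
           rng: np.random.Generator | None = None) -> EstimatorReport:
    """Sample-path-augmented maximum likelihood fit, pooled over series.

    Per-period Metropolis-Hastings chains over augmenting paths persist
    across Robbins-Monro iterations (a fresh set of sweeps is run at the
    current parameters before each score evaluation)."""
    series = _as_series_list(series)
    rm = rm or default_rm_config("ml")
    rng = rng or np.random.default_rng()
    M = series[0].n_waves
    p = model.n_effects
    n_periods = M - 1
    dim = n_periods + p
    durs = series[0].durations()
    waves = [[np.ascontiguousarray(s.networks[m].adjacency) for m in range(M)]
             for s in series]
    theta = _init_theta(series, model, init)

    paths = [[_direct_path_steps(wv[m], wv[m + 1], model.directed, rng)
              for m in range(n_periods)] for wv in waves]

    def refresh_and_score(theta, n_props, info_out=None):
        params = _theta_to_params(theta, n_periods)
        total = np.zeros(dim)
        sc = np.zeros(1 + p)
        ifo = np.zeros((1 + p, 1 + p))
        for s_idx, wv in enumerate(waves):
            for m in range(n_periods):
                rate = params.rate_for_period(m)
                steps, _ = _core.mh_path_update(
                    wv[m], paths[s_idx][m], params.phi, rate, float(durs[m]),
                    model.codes, model.acov, model.dcov, model.directed,
                    n_props, rng)
                paths[s_idx][m] = steps
                _core.path_logprob_score_info(
                    wv[m], steps, params.phi, rate, float(durs[m]),
                    model.codes, model.acov, model.dcov, model.directed,
                    True, sc, ifo)
                total[m] += sc[0]
                total[n_periods:] += sc[1:]
                if info_out is not None:
                    info_out[m, m] += ifo[0, 0]
                    info_out[n_periods:, n_periods:] += ifo[1:, 1:]
        return total

    def estimate_D(th):
        """Observed-data information via the missing-information
        principle: D = E[complete-data information] - cov(complete-data
        score) over conditional path draws."""
        scores = np.empty((rm.phase1_iters, dim))
        info = np.zeros((dim, dim))
        for it in range(rm.phase1_iters):
            scores[it] = refresh_and_score(th, rm.mh_props_per_iter, info)
        info /= rm.phase1_iters
        s_c = scores - scores.mean(axis=0)
        D = info - s_c.T @ s_c / rm.phase1_iters
        return _solve_scaling(D, rm.ridge, rm.condition_cap)

    # burn-in at the starting value, then phase 1
    refresh_and_score(theta, rm.mh_burn_in)
    Dinv = estimate_D(theta)
    labels = [f"rate_period_{m + 1}" for m in range(n_periods)] + model.labels
    settings = {"method": "ml", "n_series": len(series),
                "phase1_iters": rm.phase1_iters,
                "phase2_iters": rm.phase2_iters,
                "mh_props_per_iter": rm.mh_props_per_iter}
    try:
        est_theta, history, bound_hits = _phase2(
            theta, Dinv,
            lambda th: refresh_and_score(th, rm.mh_props_per_iter),
            rm, n_periods, estimate_D=estimate_D)
    except _Diverged:
        raise NonConvergenceError(
            "maximum-likelihood Robbins-Monro run diverged",
            _report_from_divergence(labels, np.full(dim, np.nan), [], "ml",
                                    settings))

    # post-fit score diagnostic
    diag = np.empty((rm.n_diagnostic, dim))
    for it in range(rm.n_diagnostic):
        diag[it] = refresh_and_score(est_theta, rm.mh_props_per_iter)
    score_t = diag.mean(axis=0) / np.maximum(diag.std(axis=0, ddof=1), 1e-12)

    estimates = est_theta.copy()
    estimates[:n_periods] = np.exp(est_theta[:n_periods])
    warn = []
    if np.any(est_theta[:n_periods] < -rm.log_rate_bound + 0.05):
        warn.append("rate estimate at the zero boundary")
    if bound_hits > rm.phase2_iters // 4:
        warn.append("estimates repeatedly hit the admissible bounds")
    return EstimatorReport(
        labels=labels, estimates=estimates, method="ml",
        converged=bool(np.all(np.abs(score_t) < 4.0)),
        iterations=rm.phase2_iters, history=history, settings=settings,
        diagnostics={"score_t": score_t.tolist()}, warnings=warn)
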