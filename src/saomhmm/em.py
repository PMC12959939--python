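"""EM estimation of the full hidden-Markov SAOM.

Each EM iteration alternates an E-step approximated by particle
filtering and ancestral-line sampling with two closed/iterative M-steps:
the measurement rates (alpha, beta) have a closed form from posterior
discordance counts, and the SAOM parameters gamma are re-estimated on
the sampled latent series (pooled, multi-group style) by Robbins-Monro
(maximum likelihood or method of moments).  Convergence is declared on
the relative L1 change of a moving average of the parameter history.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .effects import EffectModel, SaomParameters
from .estimation import (EstimatorReport, NonConvergenceError,
                         RobbinsMonroConfig, fit_ml, fit_mom)
from .measurement import MeasurementParameters, corrupt_panel, mstep_rates
from .networks import NetworkPanel
from .particle import forward_filter, sample_ancestral_lines
from .simulate import simulate_panel

__all__ = ["EmConfig", "EmState", "em_fit", "convergence_check", "bootstrap_se"]


@dataclasses.dataclass
class EmConfig:
    """Settings of the EM loop.

    ``K`` particles per wave; ``H_rates`` ancestral lines for the
    measurement M-step; ``H_gamma`` (typically much smaller) lines pooled
    in the gamma M-step.  Convergence uses a window-5 moving average and
    a relative L1 threshold of 0.01 by default.
    """

    K: int = 2000
    H_rates: int = 200
    H_gamma: int = 20
    max_iter: int = 20
    tol: float = 0.01
    window: int = 5
    init_alpha: float = 0.05
    init_beta: float = 0.05
    rate_floor: float = 1e-6
    weight_final: bool = False
    max_gamma_step: float = 1.0
    update_gamma: bool = True  # False freezes gamma (isolates the rate M-step)
    rm: RobbinsMonroConfig = dataclasses.field(
        default_factory=lambda: RobbinsMonroConfig(
            phase1_iters=20, phase2_iters=100, mh_burn_in=150,
            n_diagnostic=8))
    rm_init: RobbinsMonroConfig | None = None

    def __post_init__(self):
        if not (1 <= self.H_gamma <= self.H_rates <= self.K):
            raise ValueError("need H_gamma <= H_rates <= K")
        if self.tol <= 0:
            raise ValueError("convergence threshold must be positive")


@dataclasses.dataclass
class EmState:
    """Parameter history of an EM run (rows: alpha, beta, rates, phi)."""

    history: list[np.ndarray] = dataclasses.field(default_factory=list)
    window: int = 5
    tol: float = 0.01
    converged: bool = False

    @property
    def iteration(self) -> int:
        return len(self.history)

    def moving_average(self, p: int | None = None) -> np.ndarray:
        """Mean of iterations p - window + 1 .. p (1-based ``p``)."""
        p = self.iteration if p is None else p
        if p < self.window:
            raise ValueError("not enough iterations for the moving average")
        return np.mean(self.history[p - self.window:p], axis=0)


def convergence_check(state: EmState) -> bool:
    """Moving-average criterion: relative L1 change below the threshold.

    Evaluable only once ``window + 1`` iterations exist; a zero-norm
    previous average makes the criterion unusable and raises."""
    p = state.iteration
    if p < state.window + 1:
        return False
    cur = state.moving_average(p)
    prev = state.moving_average(p - 1)
    denom = np.abs(prev).sum()
    if denom == 0:
        raise ZeroDivisionError(
            "moving-average norm is zero; the relative convergence criterion "
            "is unusable for this parameterization")
    return bool(np.abs(cur - prev).sum() / denom < state.tol)


def em_fit(observed: NetworkPanel, model: EffectModel, config: EmConfig,
           rng: np.random.Generator, gamma_method: str = "ml",
           init_gamma: SaomParameters | None = None,
           seed: int | None = None, verbose: bool = False) -> EstimatorReport:
    """Fit the hidden-Markov SAOM to an observed panel.

    gamma is initialized by a standard SAOM fit to the observed panel
    (unless ``init_gamma`` is supplied) and (alpha, beta) by the
    configured defaults; the EM loop then iterates filter -> ancestral
    sampling -> closed-form rate M-step -> pooled gamma M-step until the
    moving-average criterion fires or ``max_iter`` is reached.
    """
    if gamma_method not in ("ml", "mom"):
        raise ValueError("gamma_method must be 'ml' or 'mom'")
    fit_gamma = fit_ml if gamma_method == "ml" else fit_mom
    M = observed.n_waves
    n_periods = M - 1

    # initial SAOM-only fit on the observed series
    if init_gamma is None and not config.update_gamma:
        raise ValueError("update_gamma=False requires an init_gamma")
    if init_gamma is None:
        rm0 = config.rm_init or config.rm
        init_report = fit_gamma(observed, model, rm=rm0, rng=rng)
        gamma = SaomParameters(rates=init_report.estimates[:n_periods],
                               phi=init_report.estimates[n_periods:])
    else:
        gamma = init_gamma
        init_report = None
    alpha, beta = config.init_alpha, config.init_beta

    labels = (["alpha", "beta"]
              + [f"rate_period_{m + 1}" for m in range(n_periods)]
              + model.labels)
    state = EmState(window=config.window, tol=config.tol)
    warnings_list: list[str] = []
    floored = False
    for p in range(1, config.max_iter + 1):
        a_f = max(alpha, config.rate_floor)
        b_f = max(beta, config.rate_floor)
        if (a_f, b_f) != (alpha, beta):
            floored = True
        meas = MeasurementParameters(alpha=a_f, beta=b_f)
        ps = forward_filter(observed, gamma, meas, model, config.K, rng)
        sample = sample_ancestral_lines(ps, config.H_rates, rng,
                                        weight_final=config.weight_final)
        lines = sample.panels(observed.times, observed.directed)
        new_meas = mstep_rates(lines, observed)
        alpha, beta = new_meas.alpha, new_meas.beta
        if not config.update_gamma:
            state.history.append(
                np.concatenate([[alpha, beta], gamma.rates
                                if gamma.rates.size == n_periods
                                else np.full(n_periods, gamma.rates[0]),
                                gamma.phi]))
            if convergence_check(state):
                state.converged = True
                break
            continue
        try:
            rep = fit_gamma(lines[:config.H_gamma], model, init=gamma,
                            rm=config.rm, rng=rng)
            # damp the EM update: a trust region on (log rate, phi) keeps
            # the desk-scale particle approximation from overshooting
            old = np.concatenate([np.log(np.broadcast_to(
                gamma.rates if gamma.rates.size == n_periods
                else np.full(n_periods, gamma.rates[0]), (n_periods,))),
                gamma.phi])
            new = np.concatenate([np.log(rep.estimates[:n_periods]),
                                  rep.estimates[n_periods:]])
            stepped = old + np.clip(new - old, -config.max_gamma_step,
                                    config.max_gamma_step)
            gamma = SaomParameters(rates=np.exp(stepped[:n_periods]),
                                   phi=stepped[n_periods:])
        except NonConvergenceError:
            warnings_list.append(
                f"gamma M-step diverged at EM iteration {p}; previous "
                "estimate retained")
        state.history.append(
            np.concatenate([[alpha, beta], gamma.rates
                            if gamma.rates.size == n_periods
                            else np.full(n_periods, gamma.rates[0]),
                            gamma.phi]))
        if verbose:
            print(f"EM iter {p}: " + " ".join(
                f"{v:.3f}" for v in state.history[-1]))
        if convergence_check(state):
            state.converged = True
            break
    if floored:
        warnings_list.append(
            f"alpha/beta floored at {config.rate_floor} during filtering")
    if not state.converged:
        warnings_list.append(
            "EM did not meet the moving-average criterion; reporting the "
            "final moving average")

    if state.iteration >= state.window:
        final = state.moving_average()
    else:
        final = state.history[-1]
    return EstimatorReport(
        labels=labels, estimates=final, method=f"em-{gamma_method}",
        converged=state.converged, iterations=state.iteration,
        history=np.asarray(state.history),
        settings={"seed": seed, "K": config.K, "H_rates": config.H_rates,
                  "H_gamma": config.H_gamma, "max_iter": config.max_iter,
                  "tol": config.tol, "window": config.window,
                  "gamma_method": gamma_method,
                  "weight_final": config.weight_final},
        diagnostics={
            "init_gamma": (init_report.estimates.tolist()
                           if init_report is not None else None),
            "final_ess": ps.effective_sample_sizes().tolist()},
        warnings=warnings_list)


def bootstrap_se(gamma: SaomParameters, meas: MeasurementParameters,
                 model: EffectModel, wave1, times, config: EmConfig,
                 B: int, rng: np.random.Generator,
                 gamma_method: str = "ml") -> tuple[np.ndarray, np.ndarray]:
    """Parametric-bootstrap standard errors for a fitted hidden-Markov
    SAOM: simulate B panels from the fitted model (conditioning on the
    observed first wave, corrupting waves 2..M at the fitted rates), re-run
    the EM fit on each, and return (se, replicate_estimates).

    Replicates whose gamma step diverges are excluded with a warning
    entry (a NaN row) rather than silently dropped.
    """
    if B < 2:
        raise ValueError("need at least B = 2 bootstrap replicates")
    reps = []
    for b in range(B):
        latent = simulate_panel(model, wave1, gamma, times, rng)
        obs = corrupt_panel(latent, meas, rng, error_free_first=True)
        try:
            rep = em_fit(obs, model, config, rng, gamma_method=gamma_method)
            reps.append(rep.estimates)
        except NonConvergenceError:
            dim = 2 + (len(times) - 1) + gamma.phi.size
            reps.append(np.full(dim, np.nan))
    reps = np.asarray(reps)
    ok = ~np.isnan(reps).any(axis=1)
    se = np.nanstd(reps[ok], axis=0, ddof=1)
    return se, reps
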