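# Methods

## Model

**Latent dynamics.** A binary network on a fixed set of `n` nodes
(directed by default) evolves as a continuous-time Markov chain.  Change
opportunities arrive as a Poisson process with intensity `n·δ_m` during
period `m` (constant actor-level rates `δ_m`, one per inter-wave
period).  At an opportunity, an actor chosen uniformly at random either
leaves the network unchanged or toggles one of its ties (one unordered
pair in undirected mode, where the acting node imposes the change
unilaterally).  The choice among the `n` alternatives is
multinomial-logit in the objective function `g_i(u) = Σ_e φ_e s_{e,i}(u)`;
this is equivalent to maximizing `g_i` plus i.i.d. Gumbel disturbances,
so the disturbances are never sampled.  Implemented effect statistics,
from actor `i`'s perspective:

| effect | statistic |
|---|---|
| outdegree (density) | `Σ_j u_ij` |
| reciprocity | `Σ_j u_ij u_ji` (directed only) |
| transitive triads | `Σ_{j,h} u_ij u_ih u_jh` |
| vertices at distance two | `#{j ≠ i : u_ij = 0, max_h u_ih u_hj > 0}` |
| covariate ego | `(v_i − v̄) Σ_j u_ij` |
| covariate alter | `Σ_j u_ij (v_j − v̄)` |
| dyadic covariate | `Σ_j u_ij (w_ij − w̄)` |

Covariates are grand-mean centered by default (actor covariates over
nodes, dyadic covariates over off-diagonal cells).  Centering matters:
with raw indicator covariates the intercept-like outdegree weight is
confounded with the covariate effects, and the bundled study parameter
set then drives 10-node networks to roughly 55–64 edges instead of the
intended sparse hub structure (~21 edges).  The stationary distribution
of the five-effect study model factorizes over dyads (no triadic
effects), which is how that calibration was verified analytically.
`ActorCovariate(..., centered=False)` restores raw values.

**Measurement model.** Observed wave `y` given true wave `u`:
independently per dyad, a true edge is kept with probability `1−β` and a
true non-edge stays absent with probability `1−α`.  The emission density
is `α^c (1−α)^d β^b (1−β)^a` with `(a,b,c,d)` the discordance counts
(upper triangle only for undirected networks).  The first wave is
assumed observed error-free and everything conditions on it; it never
enters the (α, β) estimate.

## Estimation

**Sample-path augmentation.** The transition density between waves has
no closed form, so each period is augmented with its full micro-step
path `V = ((I_r, J_r))_{r=1..R}`, including explicit no-change steps
(`J_r = I_r`).  With event times integrated out, the path probability is
`exp(−nδΔt) (nδΔt)^R / R! · Π_r (1/n) p_{I_r J_r}`, which yields
closed-form scores: `R/δ − nΔt` for each rate and, per step, the chosen
change statistics minus their choice-probability average for the effect
weights (verified against numeric gradients to 1e−5).

**MH path sampler.** Conditional paths between two fixed endpoint
networks are sampled by Metropolis–Hastings with endpoint-preserving
moves: insert/delete an *adjacent* canceling toggle pair of a random
dyad, swap two adjacent steps, insert/delete a single stay step, and
(undirected only) flip which endpoint of a pair acts.  Adjacent
insertion keeps every proposal O(1) to evaluate; the adjacent-swap move
transports toggles along the path, so the chain is irreducible over path
space.  Stay steps must be part of the state space — without them the
opportunity count could never mix and the rate score would be biased.
Correctness checks: the sampled path-length distribution on a two-node
model matches exhaustive enumeration, and the data-averaged conditional
mean of `R` at the generating parameters matches `nδΔt` (a Fisher-identity
consequence), which is also the internal criterion used to size the
default burn-in (3000 proposals per period).

**Robbins–Monro solver.** Both estimators run on `(log δ, φ)` (rate
positivity for free) and follow a two-phase design.  Phase 1 estimates
the scaling matrix `D`: for the method of moments via the
likelihood-ratio identity `dE[s]/dθ = cov(s, score)` over forward
simulations; for maximum likelihood via the missing-information
principle, `D = E[complete-data information] − cov(complete-data score)`
over conditional path draws.  `D` is symmetrized, ridge-regularized and
eigenvalue-floored to a bounded condition number before inversion.
Phase 2 runs subphases of doubling length with the gain halved each
subphase (`a_0`, `a_0/2`, …); the reported estimate is the mean of the
final subphase, and `D` is refreshed once after the first subphase.
Iterates are projected into an admissible box (`δ ∈ [e^{−3.7}, e^{3.7}]`,
`|φ| ≤ 15`); estimates that sit on the box are flagged as
non-converged.  A post-fit diagnostic (moment-gap or score t-ratios
against fresh simulations at the estimate) is attached to every report.

*Method of moments* matches, per iteration, the per-period Hamming
change (rate targets) and the cross-sectional effect-statistic totals at
each wave (weight targets) of forward simulations started from the
data's previous wave.  *Maximum likelihood* keeps one persistent MH
chain per period, refreshes it at the current parameters each iteration,
and ascends the pooled complete-data score.  Pooling several series
("multi-group") sums targets or scores across series.

The condition cap differs by method (30 for MoM, 8 for ML).  The ML cap
is deliberately tight: with strong preference weights the micro-step
choices are nearly separated, the likelihood is almost flat in the
large-`|φ|` direction, and a looser cap lets the iterates random-walk
outward (estimates near −3.6 for a generating weight of −3, with twice
the dispersion).  The tight cap plus finite phase-2 length act as
early-stopping regularization, which reproduces the mildly attenuated
behavior that established SAOM software exhibits on this design.  The
study's moment system is nearly flat in the covariate-effect directions
(dyad classes saturate), which makes the MoM estimator the more
dispersed of the two on single panels.

**EM for the hidden-Markov SAOM.** Each EM iteration: (1) forward
particle filter — wave 1 holds the single error-free particle; each
later wave resamples ancestors proportionally to the *previous* wave's
emission weights (multinomial by default, systematic optional) and
evolves them through one SAOM period; (2) ancestral-line sampling —
trace `H` lines back through the recorded parent indices; (3)
closed-form (α, β) M-step from the pooled discordance counts of
`H_rates` lines over waves 2..M, `α̂ = ΣC/Σ(C+D)`, `β̂ = ΣB/Σ(A+B)`
(equal weights, no importance corrections — the lines are approximate
posterior draws); (4) SAOM M-step on the first `H_gamma` lines, pooled,
warm-started at the current γ.  Convergence is declared when the
relative L1 change of a window-5 moving average of the full parameter
vector falls below 0.01; non-convergence returns the final moving
average, flagged.  γ is initialized by a standard SAOM fit to the
observed panel, (α, β) at 0.05/0.05; rates are floored at 1e−6 during
filtering so emission weights stay finite.

**Weight timing.** By default the terminal line index is uniform over
particles, so the final observation never reweights the final wave;
`weight_final=True` draws it proportionally to the final wave's emission
weights instead.  The default mirrors the filter recursion as specified;
the variant is the statistically natural completion.  On a three-node,
two-wave model the sampled lines' second wave provably follows the
transition kernel (prior) under the default and the brute-force
posterior under the variant — both are tested by enumeration.  Without
the variant the last period has no data anchor: its rate estimate is
unidentified in the M-step, which at small K sends the EM into a
degenerate "rate → 0, all change is noise" mode.  The study harness
therefore runs with `weight_final=True`.

**Parametric-bootstrap standard errors.** Simulate `B` panels from the
fitted model (SAOM forward from the observed first wave, corruption at
the fitted rates), re-run the EM on each, report per-parameter standard
deviations (ddof=1) and t-ratios.  Replicates whose γ step diverges are
recorded as NaN rows and excluded with a warning, never silently
dropped.

## Synthetic study

The generator reproduces the canonical design: 10 nodes, 4 waves at unit
spacing, effects and generating weights (outdegree −3, reciprocity 3,
ego effect of indicator A on nodes 1–3 = 3.25, ego effect of indicator B
on nodes 8–10 = 3.75, B alter = 4.75; in the literature two orderings of
the B-ego/B-alter pair appear — 3.75/4.75 is used here), constant rate 3
per period.  The fixed first wave is a uniform random digraph with
`round(0.25·90) = 23` edges evolved one period at rate 1.  Forward
simulation then averages ≈ 21.3 edges per wave over 200 replicates
(20.6–23.4 across first-wave seeds).  Error scenarios are calibrated so
the expected number of false edges equals the expected number of false
non-edges per wave: low (α=0.022, β=0.0705, ~1.5 each), mid (0.044,
0.141, ~3 each), high (0.088, 0.282, ~6 each); waves 2–4 are corrupted,
wave 1 never.  `bias`, `sd` and `rmse = sqrt(var + bias²)` use the
population-variance convention; relative MSE is
`(RMSE_HMM / RMSE_SAOM)²`.

**Scales.** The desk preset — 20–25 replicates, K=2000 particles,
H=200/20 lines, 12 EM iterations with a 0.4 trust region per iteration
on `(log δ, φ)` and the ML γ-step — runs a full scenario in ~5 minutes
on one CPU.  The full-scale preset (100 replicates, K=50,000, H=3000/50)
is intended for cluster runs.  At desk scale the per-wave effective sample size of the emission
weights is only ~2–8 (a single 90-dyad observation is weighted in one
shot), so ancestral lines coalesce to a handful of lineages.  Three
consequences, all of which shrink as K grows: (α̂, β̂) carry a positive
floor of roughly 0.03–0.08 even on noise-free data (the best of K prior
particles still misses a few dyads, and the EM's self-consistent fixed
point attributes that mismatch to noise — the full-scale study shows the
same inflation in milder form); the MoM γ M-step is unusable inside the
EM (flat moments amplify the lineage-selection tilt; the ML step is the
supported default); and per-iteration M-step targets are noisy, which
the trust region plus the moving-average estimate absorb.

**What the generator does not emulate.** Real functional-connectivity
panels have spatially correlated, non-independent edge noise, slow
autocorrelated dynamics, and unknown effects outside the fitted model;
passing tests demonstrate correct recovery under the stated model, not
robustness to misspecification.  The undirected 70-node demo
(`make_undirected_demo`) is a synthetic smoke-test fixture shaped like a
coarse brain-network panel (dyadic distance and coupling-strength
covariates); it makes no claim of reproducing any particular empirical
analysis.

## Known limitations

- The bootstrap-style filter proposes blindly from the SAOM prior;
  auxiliary/guided proposals are out of scope, so K must grow roughly
  with the dyad count for a sharp E-step.
- t-ratios are descriptive; no formal reference distribution is claimed.
- Constant actor-level rates only; rate heterogeneity across actors is
  not implemented.
- The effects catalog covers the seven families listed above, not the
  full catalog of established SAOM software.
- EM convergence uses a relative L1 criterion; it is unusable when the
  parameter vector is near zero norm (it raises in that case).
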