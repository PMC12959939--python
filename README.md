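# saomhmm

Stochastic actor-oriented models (SAOMs) for longitudinal network panels
whose edges are observed with noise.

SAOMs model a changing binary network as a continuous-time Markov
process: change opportunities arrive at rate *n·δ*; at each opportunity a
uniformly chosen actor *i* toggles at most one of its ties, preferring
states with high objective function

&nbsp;&nbsp;&nbsp;&nbsp;*g_i(u) = Σ_e φ_e · s_{e,i}(u)*,

a weighted sum of effect statistics (outdegree, reciprocity, transitive
triads, vertices at distance two, ego/alter covariate terms, dyadic
covariate terms), which makes the micro-step choice multinomial-logit.
The standard framework assumes the panel waves are observed without
error.  `saomhmm` removes that assumption: the SAOM evolution is treated
as a hidden Markov process, and each observed wave *y* is an independent
per-dyad corruption of the true wave *u* with false-positive rate α and
false-negative rate β,

&nbsp;&nbsp;&nbsp;&nbsp;*f(y | u) = α^c (1−α)^d β^b (1−β)^a*,

where *(a, b, c, d)* cross-tabulate true vs observed edge status.  The
package estimates (α, β, δ, φ) jointly by an EM algorithm whose E-step
is approximated by particle filtering over latent networks (with
ancestral-line sampling of whole latent series) and whose M-steps are a
closed form for (α, β) and a Robbins–Monro stochastic approximation for
the SAOM parameters — either sample-path-augmented maximum likelihood
(via a Metropolis–Hastings sampler over augmenting micro-step paths) or
a method-of-moments variant.  A standard noise-blind SAOM estimator is
included for comparison, along with a replicated simulation-study
harness quantifying how much accuracy the noise-aware estimator
recovers.

Intended users: network scientists with panel data whose edges are
inferred rather than directly observed — functional brain connectivity,
survey-based social networks, co-authorship windows.

## Worked example

```python
import numpy as np
import saomhmm as sh

rng = np.random.default_rng(11)
model = sh.study_model(10)                 # 5 effects, 2 indicator covariates
wave1 = sh.make_initial_network(model, rng)
latent = sh.simulate_true_panel(model, wave1, rng)          # 4 waves, rate 3
noisy = sh.corrupt_panel(latent, sh.MeasurementParameters(0.044, 0.141), rng)

naive = sh.fit_mom(noisy, model, rng=rng)  # noise-blind SAOM fit
print(dict(zip(naive.labels[3:], naive.estimates[3:].round(2))))

cfg = sh.EmConfig(K=2000, H_rates=200, H_gamma=20, max_iter=12,
                  weight_final=True, max_gamma_step=0.4)
hmm = sh.em_fit(noisy, model, cfg, rng, gamma_method="ml")
print(dict(zip(hmm.labels, hmm.estimates.round(3))))
```

Printed output from this exact script (generating weights were
−3, 3, 3.25, 3.75, 4.75 and α=0.044, β=0.141):

```
{'outdegree': -1.06, 'reciprocity': 0.5, 'covariate_ego(A)': 1.38,
 'covariate_ego(B)': 1.72, 'covariate_alter(B)': 1.55}
{'alpha': 0.09, 'beta': 0.159, 'rate_period_1': 3.206, 'rate_period_2': 1.234,
 'rate_period_3': 0.482, 'outdegree': -2.755, 'reciprocity': 1.584,
 'covariate_ego(A)': 4.203, 'covariate_ego(B)': 4.962, 'covariate_alter(B)': 4.131}
```

The noise-blind fit is attenuated toward 0 on every effect (the noise
dilutes the signal); the hidden-Markov fit recovers most of the
magnitude — four of the five weights land within about one standard
error of the generating values on this single panel — and estimates the
error rates alongside.  Single-panel estimates remain noisy at these
desk-scale particle counts; the replicated comparison (25 panels) in
`tests/test_acceptance.py` or via `sh.run_scenario(sh.StudyConfig(...))`
is the meaningful accuracy statement.

## Command line

```
saomhmm simulate   --config model.yaml --init wave1.csv --seed 1 --out panel/
saomhmm corrupt    --panel panel/panel.json --alpha 0.044 --beta 0.141 --seed 2 --out noisy/
saomhmm fit-saom   --panel noisy/panel.json --effects-config effects.yaml --seed 3 --out fit/
saomhmm fit-hmm    --panel noisy/panel.json --effects-config effects.yaml --seed 4 --out hmm/
saomhmm bootstrap  --fit hmm/hmm_fit.json --panel noisy/panel.json \
                   --effects-config effects.yaml -B 10 --seed 5 --out se/
saomhmm study      --scenario mid --replicates 25 --seed 6 --out-dir study/
```

Panels are stored as one 0/1 CSV per wave plus a JSON manifest;
covariates as CSV tables; reports as self-describing JSON.  Every run
logs its seed and a configuration hash, and identical invocations
reproduce identical outputs.

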