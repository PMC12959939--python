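"""Sample-path likelihoods, complete-data scores and the MH path sampler.

The two-node model keeps path space small enough for exhaustive
enumeration, which provides the independent oracles here.
"""

import itertools
import math

import numpy as np
import pytest

import saomhmm as sh
from saomhmm.estimation import mh_sample_path, sample_path_logprob
from test_simulator import two_node_model, two_node_net, TWO_NODE_STATES


def make_path(steps, duration=1.0, period=0):
    R = len(steps)
    times = [(r + 1) / (R + 1) * duration for r in range(R)]
    return sh.SamplePath([sh.MicroStep(t, i, j)
                          for t, (i, j) in zip(times, steps)], period=period)


def enumerate_path_probs(model, u_start, phi, rate, duration, max_R):
    """Exact probability of every micro-step sequence with R <= max_R on
    the 2-node model; returns a list of (steps, endpoint, prob)."""
    options = [(0, 0), (0, 1), (1, 1), (1, 0)]  # stays and toggles
    params = sh.SaomParameters(rates=[rate], phi=phi)
    out = []
    for R in range(max_R + 1):
        for seq in itertools.product(options, repeat=R):
            path = make_path(list(seq), duration)
            lp = sample_path_logprob(model, path, u_start, params, duration)
            end = path.replay(u_start)
            out.append((seq, (end.adjacency[0, 1], end.adjacency[1, 0]),
                        math.exp(lp)))
    return out


class TestSamplePathLogprob:
    def test_empty_path_is_poisson_zero_term(self):
        model = two_node_model()
        params = sh.SaomParameters(rates=[1.7], phi=[0.0, 0.0])
        lp = sample_path_logprob(model, make_path([]), two_node_net((0, 0)),
                                 params, 1.3)
        assert lp == pytest.approx(-2 * 1.7 * 1.3)

    def test_one_step_path_hand_value(self):
        model = two_node_model()
        phi = np.array([0.7, -0.4])
        delta, dt = 1.2, 1.0
        start = two_node_net((0, 0))
        params = sh.SaomParameters(rates=[delta], phi=phi)
        lp = sample_path_logprob(model, make_path([(0, 1)]), start, params, dt)
        p_toggle = sh.choice_probabilities(model, start, 0, phi)[1]
        expected = (math.log(math.exp(-2 * delta * dt) * (2 * delta * dt))
                    + math.log(0.5) + math.log(p_toggle))
        assert lp == pytest.approx(expected)

    def test_total_probability_bounded_by_one(self):
        model = two_node_model()
        total = sum(p for _, _, p in enumerate_path_probs(
            model, two_node_net((1, 0)), np.array([0.3, 0.6]), 0.5, 1.0, 2))
        assert total <= 1.0
        # with a tiny rate nearly all mass sits at R <= 2
        total_small = sum(p for _, _, p in enumerate_path_probs(
            model, two_node_net((1, 0)), np.array([0.3, 0.6]), 0.05, 1.0, 2))
        assert total_small == pytest.approx(1.0, abs=1e-3)

    def test_invalid_indices_rejected(self):
        model = two_node_model()
        params = sh.SaomParameters(rates=[1.0], phi=[0.0, 0.0])
        with pytest.raises(ValueError, match="out-of-range"):
            sample_path_logprob(model, make_path([(0, 5)]),
                                two_node_net((0, 0)), params, 1.0)


class TestCompleteDataScore:
    def _study_paths(self, rng, study_model, study_wave1):
        params = sh.true_parameters()
        nets = [study_wave1]
        paths = []
        for m in range(3):
            end, path = sh.simulate_period(study_model, nets[-1], params,
                                           1.0, rng, period=m)
            nets.append(end)
            paths.append(path)
        series = sh.NetworkPanel(nets, [0, 1, 2, 3], role="latent")
        return series, paths

    def test_matches_central_finite_differences(self, rng, study_model,
                                                study_wave1):
        series, paths = self._study_paths(rng, study_model, study_wave1)
        params = sh.SaomParameters(rates=[2.7, 3.1, 3.4],
                                   phi=np.array([-2.5, 2.2, 3.0, 3.1, 4.0]))
        score = sh.complete_data_score(study_model, params, series, paths)

        def loglik(rates, phi):
            p = sh.SaomParameters(rates=rates, phi=phi)
            return sum(sample_path_logprob(study_model, paths[m],
                                           series.networks[m], p, 1.0)
                       for m in range(3))

        h = 1e-5
        for k in range(3):
            up, dn = params.rates.copy(), params.rates.copy()
            up[k] += h
            dn[k] -= h
            num = (loglik(up, params.phi) - loglik(dn, params.phi)) / (2 * h)
            assert score[k] == pytest.approx(num, abs=1e-5, rel=1e-5)
        for e in range(5):
            up, dn = params.phi.copy(), params.phi.copy()
            up[e] += h
            dn[e] -= h
            num = (loglik(params.rates, up) - loglik(params.rates, dn)) / (2 * h)
            assert score[3 + e] == pytest.approx(num, abs=1e-4, rel=1e-5)

    def test_rate_component_closed_form(self, rng, study_model, study_wave1):
        series, paths = self._study_paths(rng, study_model, study_wave1)
        params = sh.SaomParameters(rates=[2.0, 3.0, 4.0],
                                   phi=sh.true_parameters().phi)
        score = sh.complete_data_score(study_model, params, series, paths)
        for m in range(3):
            R = paths[m].n_steps
            assert score[m] == pytest.approx(R / params.rates[m] - 10 * 1.0)

    def test_stay_only_paths_give_stay_choice_gradients(self):
        """Paths of pure no-change steps contribute the gradients of the
        stay-choice probabilities (and nothing else) to the phi score."""
        model = two_node_model()
        phi = np.array([0.8, -0.3])
        start = two_node_net((1, 0))
        params = sh.SaomParameters(rates=[1.0], phi=phi)
        series = sh.NetworkPanel([start, start.copy()], [0, 1], role="latent")
        paths = [make_path([(0, 0), (1, 1)])]
        score = sh.complete_data_score(model, params, series, paths)
        # hand evaluation: d/dphi log p_stay = -sum_alt p_alt * delta_alt
        expected = np.zeros(2)
        from saomhmm import _core
        for actor in [0, 1]:
            dst = np.empty((2, 2))
            probs = np.empty(2)
            _core.choice_probs(np.ascontiguousarray(start.adjacency), actor,
                               phi, model.codes, model.acov, model.dcov,
                               True, dst, probs)
            expected -= probs @ dst
        np.testing.assert_allclose(score[1:], expected, atol=1e-12)


class TestMhSamplePath:
    def test_replayed_path_hits_end_network(self, rng, study_model,
                                            study_wave1):
        params = sh.true_parameters()
        end, _ = sh.simulate_period(study_model, study_wave1, params, 1.0, rng)
        path = mh_sample_path(study_model, study_wave1, end, params, 1.0,
                              rng, n_sweeps=300)
        np.testing.assert_array_equal(path.replay(study_wave1).adjacency,
                                      end.adjacency)

    def test_equal_endpoints_have_even_toggle_parity(self, rng):
        model = two_node_model()
        params = sh.SaomParameters(rates=[1.0], phi=[0.2, 0.4])
        start = two_node_net((1, 0))
        saw_empty = False
        for _ in range(40):
            path = mh_sample_path(model, start, start, params, 1.0, rng,
                                  n_sweeps=100)
            counts = {}
            for s in path.steps:
                if s.actor != s.target:
                    counts[(s.actor, s.target)] = counts.get(
                        (s.actor, s.target), 0) + 1
            pair_total = {}
            for (i, j), c in counts.items():
                key = frozenset((i, j))
                pair_total[key] = pair_total.get(key, 0) + c
            assert all(c % 2 == 0 for c in pair_total.values())
            saw_empty = saw_empty or path.n_steps == 0
        assert saw_empty  # the empty path is a valid, visited state

    def test_sampled_length_distribution_matches_enumeration(self, rng):
        """Conditional distribution of R given the endpoints, restricted
        to R <= 6, against exhaustive path enumeration."""
        model = two_node_model()
        phi = np.array([0.3, 0.5])
        rate, dt = 0.4, 1.0
        start, end_state = two_node_net((0, 0)), (1, 0)
        paths = enumerate_path_probs(model, start, phi, rate, dt, 6)
        mass = np.zeros(7)
        for seq, end, p in paths:
            if end == end_state:
                mass[len(seq)] += p
        exact = mass / mass.sum()

        params = sh.SaomParameters(rates=[rate], phi=phi)
        end_net = two_node_net(end_state)
        # one long chain, subsampled
        from saomhmm import _core
        from saomhmm.estimation import _direct_path_steps
        steps = _direct_path_steps(start.adjacency, end_net.adjacency, True,
                                   rng)
        hist = np.zeros(7)
        n_samples = 4000
        for _ in range(n_samples):
            steps, _ = _core.mh_path_update(
                np.ascontiguousarray(start.adjacency), steps, phi, rate, dt,
                model.codes, model.acov, model.dcov, True, 20, rng)
            if len(steps) <= 6:
                hist[len(steps)] += 1
        emp = hist / hist.sum()
        np.testing.assert_allclose(emp, exact, atol=0.05)


class TestFitContracts:
    def test_mom_seeded_reproducibility(self, rng, study_model, study_wave1):
        panel = sh.simulate_true_panel(study_model, study_wave1, rng)
        r1 = sh.fit_mom(panel, study_model, rng=np.random.default_rng(3))
        r2 = sh.fit_mom(panel, study_model, rng=np.random.default_rng(3))
        np.testing.assert_array_equal(r1.estimates, r2.estimates)

    def test_no_change_panel_flags_rate_boundary(self, study_wave1):
        model = sh.compile_effects([sh.EffectSpec("outdegree")], 10)
        panel = sh.NetworkPanel([study_wave1, study_wave1.copy(),
                                 study_wave1.copy()], [0, 1, 2])
        rep = sh.fit_mom(panel, model, rng=np.random.default_rng(0))
        assert rep.estimates[0] < 0.05 and rep.estimates[1] < 0.05
        assert any("boundary" in w for w in rep.warnings)

    def test_pooled_identical_series_match_single_series_target(
            self, rng, study_model, study_wave1):
        """Pooling H copies of one series solves the same moment
        equations as the single series; estimates agree within combined
        Monte Carlo error of the two stochastic fits."""
        panel = sh.simulate_true_panel(study_model, study_wave1, rng)
        r1 = sh.fit_mom(panel, study_model, rng=np.random.default_rng(10))
        r3 = sh.fit_mom([panel] * 3, study_model,
                        rng=np.random.default_rng(11))
        np.testing.assert_allclose(r1.estimates[3:], r3.estimates[3:],
                                   atol=1.2)

    def test_ml_mom_agreement_on_pooled_clean_series(self, rng, study_model,
                                                     study_wave1):
        """ML and MoM estimate the same SAOM; pooled over several clean
        series their effect estimates agree within Monte Carlo error."""
        panels = [sh.simulate_true_panel(study_model, study_wave1, rng)
                  for _ in range(4)]
        r_mom = sh.fit_mom(panels, study_model, rng=rng)
        r_ml = sh.fit_ml(panels, study_model, rng=rng)
        np.testing.assert_allclose(r_ml.estimates[3:], r_mom.estimates[3:],
                                   atol=1.5)

    def test_report_structure(self, rng, study_model, study_wave1):
        panel = sh.simulate_true_panel(study_model, study_wave1, rng)
        rep = sh.fit_mom(panel, study_model, rng=rng)
        assert rep.se is None and rep.t_ratios is None
        assert len(rep.labels) == len(rep.estimates) == 8
        assert rep.history.shape[1] == 8
        assert rep.method == "mom"
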