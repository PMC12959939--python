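"""Forward particle filter and ancestral-line sampling.

The 3-node, two-wave model is small enough (64 latent states) to compute
the wave-2 posterior by brute force: a Monte-Carlo estimate of the
one-period transition kernel from the first wave combined with the exact
emission density.
"""

import itertools

import numpy as np
import pytest

import saomhmm as sh
from saomhmm.particle import _resample


def three_node_setup():
    model = sh.compile_effects(
        [sh.EffectSpec("outdegree"), sh.EffectSpec("reciprocity")], 3)
    phi = np.array([-0.6, 1.2])
    params = sh.SaomParameters(rates=[1.0], phi=phi)
    u1 = np.zeros((3, 3), dtype=np.int8)
    u1[0, 1] = u1[1, 0] = 1
    y2 = np.zeros((3, 3), dtype=np.int8)
    y2[0, 1] = y2[2, 0] = 1
    meas = sh.MeasurementParameters(0.1, 0.2)
    panel = sh.NetworkPanel([sh.DirectedNetwork(u1), sh.DirectedNetwork(y2)],
                            [0.0, 1.0])
    return model, params, meas, panel


ALL_STATES = list(itertools.product((0, 1), repeat=6))


def state_index(u):
    cells = [(0, 1), (0, 2), (1, 0), (1, 2), (2, 0), (2, 1)]
    return ALL_STATES.index(tuple(int(u[i, j]) for i, j in cells))


def state_net(bits):
    cells = [(0, 1), (0, 2), (1, 0), (1, 2), (2, 0), (2, 1)]
    u = np.zeros((3, 3), dtype=np.int8)
    for (i, j), b in zip(cells, bits):
        u[i, j] = b
    return sh.DirectedNetwork(u)


class TestForwardFilter:
    def test_no_event_limit_keeps_first_wave(self, rng, study_model,
                                             study_wave1):
        panel = sh.NetworkPanel(
            [study_wave1, study_wave1.copy(), study_wave1.copy()], [0, 1, 2])
        params = sh.SaomParameters(rates=[1e-9], phi=sh.true_parameters().phi)
        meas = sh.MeasurementParameters(0.05, 0.05)
        ps = sh.forward_filter(panel, params, meas, study_model, 50, rng)
        for m in range(3):
            for k in range(ps.particles[m].shape[0]):
                np.testing.assert_array_equal(ps.particles[m][k],
                                              study_wave1.adjacency)

    def test_all_zero_weights_raise_with_hint(self, rng, study_model,
                                              study_wave1):
        other = study_wave1.adjacency.copy()
        other[0, 1] = 1 - other[0, 1]
        panel = sh.NetworkPanel(
            [study_wave1, sh.DirectedNetwork(other), study_wave1.copy()],
            [0, 1, 2])
        params = sh.SaomParameters(rates=[1e-9], phi=sh.true_parameters().phi)
        meas = sh.MeasurementParameters(0.0, 0.0)  # no noise allowed at all
        with pytest.raises(RuntimeError, match="floor"):
            sh.forward_filter(panel, params, meas, study_model, 20, rng)

    @staticmethod
    def _dyad_marginals(dist):
        """Per-dyad edge probabilities of a distribution over the 64
        states (the marginals of the wave-2 latent network)."""
        out = np.zeros(6)
        for s, bits in enumerate(ALL_STATES):
            out += dist[s] * np.array(bits)
        return out

    def test_wave2_particles_distributed_as_prior_by_default(self, rng):
        """Default weight timing: the final wave is never reweighted,
        so at M=2 the sampled lines' second wave follows the one-period
        transition kernel (the prior), not the posterior."""
        model, params, meas, panel = three_node_setup()
        kernel = self._mc_kernel(model, params, panel, rng, 60_000)
        ps = sh.forward_filter(panel, params, meas, model, 6000, rng)
        lines = sh.sample_ancestral_lines(ps, 6000, rng, weight_final=False)
        emp = np.zeros(64)
        for h in range(6000):
            emp[state_index(lines.lines[h, 1])] += 1
        emp /= emp.sum()
        np.testing.assert_allclose(self._dyad_marginals(emp),
                                   self._dyad_marginals(kernel), atol=0.03)

    def test_wave2_lines_match_enumerated_posterior_with_final_weight(
            self, rng):
        """With terminal reweighting the sampled lines' second wave
        matches the brute-force posterior: MC-estimated transition kernel
        times the exact emission density, normalized over all 64 states."""
        model, params, meas, panel = three_node_setup()
        kernel = self._mc_kernel(model, params, panel, rng, 60_000)
        emis = np.array([
            np.exp(sh.emission_log_probability(panel.networks[1],
                                               state_net(bits), meas))
            for bits in ALL_STATES])
        posterior = kernel * emis
        posterior /= posterior.sum()

        ps = sh.forward_filter(panel, params, meas, model, 6000, rng)
        lines = sh.sample_ancestral_lines(ps, 6000, rng, weight_final=True)
        emp = np.zeros(64)
        for h in range(6000):
            emp[state_index(lines.lines[h, 1])] += 1
        emp /= emp.sum()
        np.testing.assert_allclose(self._dyad_marginals(emp),
                                   self._dyad_marginals(posterior), atol=0.03)
        # the posterior and prior genuinely differ here; the filter must
        # track the former, not the latter
        assert np.abs(self._dyad_marginals(posterior)
                      - self._dyad_marginals(kernel)).max() > 0.06

    @staticmethod
    def _mc_kernel(model, params, panel, rng, n_sim):
        from saomhmm import _core
        counts = np.zeros(64)
        dst = np.empty((3, 2))
        probs = np.empty(3)
        u1 = np.ascontiguousarray(panel.networks[0].adjacency)
        for _ in range(n_sim):
            u = u1.copy()
            _core.evolve_period(u, params.phi, 1.0, 1.0, model.codes,
                                model.acov, model.dcov, True, rng, dst, probs)
            counts[state_index(u)] += 1
        return counts / counts.sum()


class TestAncestralLines:
    def test_parent_child_consistency(self, rng, study_model, study_wave1):
        panel = sh.simulate_true_panel(study_model, study_wave1, rng)
        noisy = sh.corrupt_panel(panel, sh.MeasurementParameters(0.05, 0.15),
                                 rng)
        params = sh.true_parameters()
        meas = sh.MeasurementParameters(0.05, 0.15)
        ps = sh.forward_filter(noisy, params, meas, study_model, 300, rng)
        sample = sh.sample_ancestral_lines(ps, 25, rng)
        for h in range(25):
            for m in range(4):
                z = sample.indices[h, m]
                np.testing.assert_array_equal(sample.lines[h, m],
                                              ps.particles[m][z])
            for m in range(3):
                assert ps.ancestors[m][sample.indices[h, m + 1]] == \
                    sample.indices[h, m]

    def test_single_particle_filter_gives_identical_lines(self, rng,
                                                          study_model,
                                                          study_wave1):
        panel = sh.simulate_true_panel(study_model, study_wave1, rng)
        params = sh.true_parameters()
        meas = sh.MeasurementParameters(0.1, 0.1)
        ps = sh.forward_filter(panel, params, meas, study_model, 1, rng)
        sample = sh.sample_ancestral_lines(ps, 10, rng)
        for h in range(1, 10):
            np.testing.assert_array_equal(sample.lines[h], sample.lines[0])

    def test_first_wave_is_always_the_observed_network(self, rng,
                                                       study_model,
                                                       study_wave1):
        panel = sh.simulate_true_panel(study_model, study_wave1, rng)
        params = sh.true_parameters()
        meas = sh.MeasurementParameters(0.1, 0.1)
        ps = sh.forward_filter(panel, params, meas, study_model, 40, rng)
        sample = sh.sample_ancestral_lines(ps, 5, rng)
        for h in range(5):
            np.testing.assert_array_equal(sample.lines[h, 0],
                                          study_wave1.adjacency)


class TestResampling:
    def test_multinomial_offspring_unbiased(self, rng):
        log_w = np.log(np.array([0.5, 0.3, 0.15, 0.05]))
        K = 4
        counts = np.zeros(4)
        n_draws = 5000
        for _ in range(n_draws):
            idx = _resample(log_w, K, rng, systematic=False)
            counts += np.bincount(idx, minlength=4)
        expected = K * np.exp(log_w)
        np.testing.assert_allclose(counts / n_draws, expected, rtol=0.05)

    def test_systematic_offspring_unbiased(self, rng):
        log_w = np.log(np.array([0.4, 0.3, 0.2, 0.1]))
        counts = np.zeros(4)
        for _ in range(3000):
            idx = _resample(log_w, 4, rng, systematic=True)
            counts += np.bincount(idx, minlength=4)
        np.testing.assert_allclose(counts / 3000, 4 * np.exp(log_w),
                                   rtol=0.05)

    def test_finite_weights_never_abort(self, rng, study_model, study_wave1):
        panel = sh.simulate_true_panel(study_model, study_wave1, rng)
        noisy = sh.corrupt_panel(panel, sh.MeasurementParameters(0.3, 0.4),
                                 rng)
        params = sh.true_parameters()
        meas = sh.MeasurementParameters(0.01, 0.01)
        ps = sh.forward_filter(noisy, params, meas, study_model, 100, rng)
        for lw in ps.log_weights:
            assert np.isfinite(lw).all()
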