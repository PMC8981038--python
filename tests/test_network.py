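"""Spiking substrate: neurons, synapses, connectivity, microcircuit."""

import math

import numpy as np
import pytest

from boldsim.network import (FS_2007, RS_2007, RS_SIMPLE, IzhikevichSimpleParams,
                             Network, PoissonPopulation, Projection, RateWindow,
                             SpikingPopulation, build_microcircuit,
                             izhikevich_step, microcircuit_counts, poisson_step,
                             sample_fixed_indegree, sample_lognormal_weights,
                             synapse_step)

#: the eight reference microcircuit sizes and their counts
TABLE_SIZES = {
    250: (450, 5_500),
    500: (900, 11_000),
    1_000: (1_800, 22_000),
    2_000: (3_600, 44_000),
    4_000: (7_200, 88_000),
    8_000: (14_400, 176_000),
    16_000: (28_800, 352_000),
    32_000: (57_600, 704_000),
}


class TestPoisson:
    def test_zero_rate_never_spikes(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            assert not poisson_step(np.zeros(50), 0.1, rng).any()

    def test_count_statistics(self):
        # 10 Hz for 100 s at dt = 0.1 ms: ~1000 spikes +- 4 sigma
        rng = np.random.default_rng(1)
        rates = np.full(1, 10.0)
        count = sum(poisson_step(rates, 0.1, rng)[0]
                    for _ in range(1_000_000))
        assert abs(count - 1000) < 4 * math.sqrt(1000)

    def test_multiplier_scales_rate(self):
        rng = np.random.default_rng(2)
        rates = np.full(200, 20.0)
        base = sum(poisson_step(rates, 1.0, rng).sum() for _ in range(2000))
        stim = sum(poisson_step(rates, 1.0, rng, multiplier=5.0).sum()
                   for _ in range(2000))
        ratio = stim / base
        assert 4.5 < ratio < 5.5

    def test_too_coarse_grid_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError, match="probability"):
            poisson_step(np.full(3, 2000.0), 1.0, rng)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            poisson_step(np.array([-1.0]), 0.1, np.random.default_rng(0))


class TestIzhikevich:
    def test_simple_form_fixed_point(self):
        # (v, u) = (-70, -14): 0.04*4900 - 350 + 140 + 14 = 0 and bv = u
        v, u, spk = izhikevich_step(
            RS_SIMPLE, np.array([-70.0]), np.array([-14.0]),
            np.array([0.0]), 1.0)
        assert v[0] == pytest.approx(-70.0, abs=1e-12)
        assert u[0] == pytest.approx(-14.0, abs=1e-12)
        assert not spk[0]

    def test_reset_contract(self):
        v, u, spk = izhikevich_step(
            RS_SIMPLE, np.array([29.999]), np.array([0.0]),
            np.array([500.0]), 1.0)
        assert spk[0]
        assert v[0] == RS_SIMPLE.c
        assert u[0] > 0.0    # incremented by d

    def test_simple_hand_euler_step(self):
        # one Euler step from (v, u) = (-60, -10), I = 7, dt = 0.5 ms
        v0, u0, I, dt = -60.0, -10.0, 7.0, 0.5
        dv = 0.04 * v0 ** 2 + 5 * v0 + 140 - u0 + I
        du = RS_SIMPLE.a * (RS_SIMPLE.b * v0 - u0)
        v, u, _ = izhikevich_step(RS_SIMPLE, np.array([v0]), np.array([u0]),
                                  np.array([I]), dt)
        assert v[0] == pytest.approx(v0 + dt * dv, abs=1e-12)
        assert u[0] == pytest.approx(u0 + dt * du, abs=1e-12)

    def test_2007_resting_state_is_stationary(self):
        v, u, spk = izhikevich_step(
            RS_2007, np.array([RS_2007.v_r]), np.array([0.0]),
            np.array([0.0]), 0.1)
        assert v[0] == RS_2007.v_r and u[0] == 0.0 and not spk[0]

    def test_fs_cubic_recovery_inactive_below_vb(self):
        u0 = 5.0
        v, u, _ = izhikevich_step(FS_2007, np.array([-60.0]), np.array([u0]),
                                  np.array([0.0]), 0.1)
        # below v_b the recovery target is 0: u decays toward 0
        assert u[0] == pytest.approx(u0 * (1 - 0.1 * FS_2007.a), abs=1e-12)

    def test_population_step_matches_functional_form(self):
        pop = SpikingPopulation("p", 40, RS_2007, 0.1,
                                rng=np.random.default_rng(0))
        pop.g_ampa[:] = np.linspace(0, 2, 40)
        v0, u0 = pop.v.copy(), pop.u.copy()
        g1 = pop.g_ampa * math.exp(-0.1 / 10.0)
        I = g1 * (0.0 - v0) + pop.g_gaba * (-90.0 - v0)
        v_ref, u_ref, _ = izhikevich_step(RS_2007, v0, u0, I, 0.1)
        pop.step()
        np.testing.assert_allclose(pop.v, v_ref, rtol=0, atol=1e-12)
        np.testing.assert_allclose(pop.u, u_ref, rtol=0, atol=1e-12)


class TestSynapses:
    def test_exponential_decay(self):
        g = np.array([1.0])
        for _ in range(100):
            g = synapse_step(g, 0.0, 0.1)    # 10 ms total
        assert g[0] == pytest.approx(math.exp(-1.0), rel=1e-12)

    def test_simultaneous_spikes_add(self):
        # increments land after the decay of the existing conductance
        g = synapse_step(np.array([1.0]), 0.2 + 0.3, 0.1)
        assert g[0] == pytest.approx(math.exp(-0.01) + 0.5, rel=1e-12)

    def test_current_signs_at_rest_potential(self):
        pop = SpikingPopulation("p", 2, RS_2007, 0.1,
                                rng=np.random.default_rng(0))
        pop.v[:] = -70.0
        pop.add_conductance("AMPA", np.array([1.0, 0.0]))
        pop.add_conductance("GABA", np.array([0.0, 1.0]))
        pop.step()
        # I = g (E_rev - v) with v = -70: AMPA +70 g, GABA -20 g
        assert pop._I_ampa[0] == pytest.approx(70.0)
        assert pop._I_gaba[1] == pytest.approx(-20.0)
        # magnitudes exposed as source variables
        assert pop.get_variable("I_GABA")[1] == pytest.approx(20.0)

    def test_conductances_stay_nonnegative(self):
        net = build_microcircuit(250, seed=5)
        for _ in range(2000):
            net.step()
            for name in ("corE", "corI"):
                pop = net.populations[name]
                assert (pop.g_ampa >= 0).all() and (pop.g_gaba >= 0).all()


class TestRateWindow:
    def test_counting(self):
        rw = RateWindow(1, window=100.0, dt=1.0)
        spikes = np.zeros(1, bool)
        for k in range(100):
            spikes[0] = k in (3, 50, 99)
            rw.update(spikes)
        assert rw.rate[0] == pytest.approx(30.0)   # 3 spikes / 100 ms

    def test_empty_window_rate_zero(self):
        rw = RateWindow(4, window=100.0, dt=0.1)
        rw.update(np.zeros(4, bool))
        assert (rw.rate == 0).all()

    def test_window_must_divide_grid(self):
        with pytest.raises(ValueError):
            RateWindow(1, window=100.0, dt=0.3)

    def test_incremental_equals_brute_force_recount(self):
        rng = np.random.default_rng(7)
        n, steps, wsteps = 8, 3000, 1000
        rw = RateWindow(n, window=100.0, dt=0.1)
        history = np.zeros((steps, n), bool)
        for k in range(steps):
            spikes = rng.random(n) < 0.02
            history[k] = spikes
            rw.update(spikes)
            lo = max(0, k + 1 - wsteps)
            brute = history[lo:k + 1].sum(axis=0) * (1000.0 / 100.0)
            np.testing.assert_array_equal(rw.rate, brute)


class TestWeightsAndWiring:
    def test_degenerate_sigma_gives_constant_weights(self):
        rng = np.random.default_rng(0)
        w = sample_lognormal_weights(mu=-1.0, sigma=0.0, scale=2.0, n=100,
                                     rng=rng)
        np.testing.assert_allclose(w, 2.0 * math.exp(-1.0))

    def test_seeded_draw_reproducible(self):
        a = sample_lognormal_weights(-1.5, 0.9, 1.0, 1000,
                                     np.random.default_rng(42))
        b = sample_lognormal_weights(-1.5, 0.9, 1.0, 1000,
                                     np.random.default_rng(42))
        np.testing.assert_array_equal(a, b)

    def test_median_matches_lognormal_theory(self):
        w = sample_lognormal_weights(-1.5, 0.93, 3.0, 100_000,
                                     np.random.default_rng(3))
        assert np.median(w) == pytest.approx(3.0 * math.exp(-1.5), rel=0.02)

    @pytest.mark.parametrize("n_pre", [10, 30, 200, 5000])
    def test_fixed_indegree_distinct(self, n_pre):
        idx = sample_fixed_indegree(n_pre, 77, 10, np.random.default_rng(0))
        assert idx.shape == (77, 10)
        assert idx.min() >= 0 and idx.max() < n_pre
        srt = np.sort(idx, axis=1)
        assert not (srt[:, 1:] == srt[:, :-1]).any()

    def test_indegree_larger_than_pre_rejected(self):
        with pytest.raises(ValueError):
            sample_fixed_indegree(5, 10, 10, np.random.default_rng(0))

    def test_projection_rejects_duplicate_indices(self):
        pre = SpikingPopulation("pre", 20, RS_2007, 0.1)
        post = SpikingPopulation("post", 4, RS_2007, 0.1)
        idx = np.zeros((4, 2), int)   # duplicated pre index 0
        with pytest.raises(ValueError, match="duplicate"):
            Projection(pre, post, "AMPA", idx, np.ones((4, 2)))

    def test_projection_delivers_previous_spikes(self):
        pre = SpikingPopulation("pre", 3, RS_2007, 0.1)
        post = SpikingPopulation("post", 2, RS_2007, 0.1)
        idx = np.array([[0, 1], [1, 2]])
        w = np.array([[0.5, 0.25], [1.0, 2.0]])
        proj = Projection(pre, post, "AMPA", idx, w)
        pre.spikes[:] = [True, True, False]
        pre.commit_spikes()
        proj.propagate()
        post.step()
        assert post.g_ampa[0] == pytest.approx(0.75)
        assert post.g_ampa[1] == pytest.approx(1.0)


class TestMicrocircuit:
    @pytest.mark.parametrize("n_recorded,expected", sorted(TABLE_SIZES.items()))
    def test_reference_counts_reproduced(self, n_recorded, expected):
        assert microcircuit_counts(n_recorded) == expected

    @pytest.mark.parametrize("n_recorded", [250, 1000])
    def test_built_network_matches_counts(self, n_recorded):
        net = build_microcircuit(n_recorded, seed=0)
        assert (net.total_neurons, net.total_connections) == \
            TABLE_SIZES[n_recorded]

    def test_structure(self):
        net = build_microcircuit(250, seed=0)
        assert net.populations["corE"].size == 200
        assert net.populations["corI"].size == 50
        assert net.populations["poisson"].size == 200
        names = {p.name for p in net.projections}
        assert names == {"poisson->corE", "poisson->corI", "corE->corI",
                         "corI->corE", "corI->corI"}
        kinds = {p.name: p.kind for p in net.projections}
        assert kinds["corI->corE"] == "GABA" and kinds["corE->corI"] == "AMPA"
        for proj in net.projections:
            assert proj.indegree == 10

    def test_afferent_counts(self):
        net = build_microcircuit(250, seed=0)
        assert net.populations["corE"].n_afferent == 20
        assert net.populations["corI"].n_afferent == 30

    def test_indivisible_size_rejected(self):
        with pytest.raises(ValueError, match="multiple of 5"):
            build_microcircuit(123)

    def test_same_seed_bit_identical_spike_trains(self):
        trains = []
        for _ in range(2):
            net = build_microcircuit(250, seed=11)
            spikes = []
            for _ in range(3000):
                net.step()
                spikes.append(net.populations["corE"].spikes.copy())
            trains.append(np.array(spikes))
        np.testing.assert_array_equal(trains[0], trains[1])

    def test_stimulus_multiplier_contract(self):
        # Poisson spikes during the window scale by the multiplier (3 sigma)
        net = build_microcircuit(250, seed=2)
        net.set_stimulus_schedule([(200.0, 400.0, 5.0)])
        pois = net.populations["poisson"]
        base = stim = 0
        while net.time < 600.0:
            in_stim = 200.0 <= net.time < 400.0
            net.step()
            if in_stim:
                stim += pois.spikes.sum()
            else:
                base += pois.spikes.sum()
        # equal total observation time in and out of the window
        lam = base / 2.0 * 5.0
        assert abs(stim - lam) < 3 * math.sqrt(lam) + 5

    def test_overlapping_stimulus_windows_rejected(self):
        net = build_microcircuit(250, seed=0)
        with pytest.raises(ValueError, match="overlap"):
            net.set_stimulus_schedule([(0.0, 100.0, 2.0), (50.0, 150.0, 3.0)])


class TestDerivedVariables:
    def test_syn_normalized_by_afferents(self):
        net = build_microcircuit(250, seed=0)
        pop = net.populations["corE"]
        pop.g_ampa[:] = 1.5
        pop.g_gaba[:] = 0.5
        assert pop.get_variable("syn")[0] == pytest.approx(2.0 / 20.0)

    def test_syn_zero_when_silent(self):
        net = build_microcircuit(250, seed=0)
        assert (net.populations["corE"].get_variable("syn") == 0).all()

    def test_syn_requires_afferents(self):
        lone = SpikingPopulation("p", 5, RS_2007, 0.1)
        with pytest.raises(ValueError, match="afferent"):
            lone.get_variable("syn")

    def test_registered_expression_evaluates_per_neuron(self):
        net = build_microcircuit(250, seed=0)
        pop = net.populations["corE"]
        pop.register_expression("drive", "I_AMPA + 1.5 * I_GABA")
        pop.register_expression("cbrt", "I_AMPA**(1/3)")
        net.run(50.0)
        ia = pop.get_variable("I_AMPA")
        ig = pop.get_variable("I_GABA")
        np.testing.assert_allclose(pop.get_variable("drive"), ia + 1.5 * ig)
        np.testing.assert_allclose(pop.get_variable("cbrt"), ia ** (1 / 3))

    def test_unknown_expression_symbol_rejected(self):
        pop = SpikingPopulation("p", 5, RS_2007, 0.1)
        with pytest.raises(Exception, match="bogus"):
            pop.register_expression("x", "bogus + 1")

    def test_unknown_variable_keyerror(self):
        pop = SpikingPopulation("p", 5, RS_2007, 0.1)
        with pytest.raises(KeyError):
            pop.get_variable("nope")
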