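"""Integrator contracts: exact gate decay, leak relaxation, refractoriness,
reproducibility, circulant-vs-dense equivalence, ring equivariance."""

from dataclasses import replace

import numpy as np
import pytest

import ringmem as rm
from ringmem.simulator import StimulusSpec, _RingConv, run_trials, trial_rng


def _silent_spec(quarter):
    """No external drive: only deterministic leak dynamics remain."""
    return replace(quarter,
                   excitatory=replace(quarter.excitatory, nu_ext=0.0),
                   inhibitory=replace(quarter.inhibitory, nu_ext=0.0))


def _no_serotonin():
    return rm.SerotoninSpec(baseline_5ht_nM=0.0)


class TestDeterministicDynamics:
    def test_leak_relaxation_matches_closed_form(self, quarter_net):
        """With all inputs off, V relaxes to E_L with tau = C_m/g_L ~ 18.2 ms."""
        spec = _silent_spec(quarter_net)
        proto = rm.TrialProtocol(periods=(("fixation", 100.0, None),
                                          ("cue", 10.0, "cue"),
                                          ("delay", 10.0, None)))
        batch = run_trials(spec, _no_serotonin(), proto, 123, 1,
                           stimulus=StimulusSpec(I_1=0.0),
                           keep_final_state=True)
        e = spec.excitatory
        rng = trial_rng(123, 0)
        v0_e = rng.uniform(e.E_L, e.V_th - 5.0, spec.pop.n_excitatory)
        tau = e.C_m / e.g_L * 1000.0  # nF/nS -> s, hence ms factor
        assert tau == pytest.approx(18.248, abs=0.01)
        T = 120.0
        expected = e.E_L + (v0_e - e.E_L) * np.exp(-T / tau)
        got = batch.final_state.V_e[0]
        assert np.allclose(got, expected, rtol=1e-3, atol=1e-3)

    def test_gate_trajectories_exactly_exponential(self, quarter_net, sero):
        """Reconstruct AMPA/GABA/x gates from spike times: exact decay sums."""
        proto = rm.TrialProtocol(periods=(("fixation", 30.0, None),
                                          ("cue", 150.0, "cue"),
                                          ("delay", 40.0, None)))
        batch = run_trials(quarter_net, sero, proto, 5, 1,
                           stimulus=StimulusSpec(I_1=1.5),
                           record_raster=True, keep_final_state=True)
        raster = batch.rasters[0]
        st = batch.final_state
        T = 220.0
        tE, iE = raster.select("E")
        assert len(tE) > 10, "stimulus failed to elicit spikes"
        for neuron in np.unique(iE)[:5]:
            ts = tE[iE == neuron]
            expect_ampa = np.sum(np.exp(-(T - ts) / 2.0))
            expect_x = expect_ampa  # same time constant
            assert st.s_ampa_rec[0, neuron] == pytest.approx(expect_ampa, rel=1e-10)
            assert st.x_nmda[0, neuron] == pytest.approx(expect_x, rel=1e-10)
        tI, iI = raster.select("I")
        for neuron in np.unique(iI)[:5]:
            ts = tI[iI == neuron]
            expect_gaba = np.sum(np.exp(-(T - ts) / 10.0))
            assert st.s_gaba[0, neuron] == pytest.approx(expect_gaba, rel=1e-10)

    def test_nmda_gate_saturates_below_one(self, quarter_net, sero):
        proto = rm.TrialProtocol(periods=(("fixation", 20.0, None),
                                          ("cue", 300.0, "cue"),
                                          ("delay", 20.0, None)))
        batch = run_trials(quarter_net, sero, proto, 5, 1,
                           stimulus=StimulusSpec(I_1=3.0),
                           keep_final_state=True)
        s = batch.final_state.s_nmda
        assert np.all(s >= 0.0) and np.all(s < 1.0)

    def test_mg_block_at_zero_mv(self, quarter_net):
        assert quarter_net.synapses.mg_block(0.0) == pytest.approx(0.7812, abs=2e-4)


class TestRefractoriness:
    def test_no_isi_below_tau_ref(self, quarter_net, sero):
        proto = rm.TrialProtocol(periods=(("fixation", 50.0, None),
                                          ("cue", 300.0, "cue"),
                                          ("delay", 50.0, None)))
        batch = run_trials(quarter_net, sero, proto, 9, 1,
                           stimulus=StimulusSpec(I_1=2.0), record_raster=True)
        raster = batch.rasters[0]
        for pop, tref in (("E", 2.0), ("I", 1.0)):
            ts, idx = raster.select(pop)
            for neuron in np.unique(idx):
                isi = np.diff(ts[idx == neuron])
                assert len(ts) == 0 or np.all(isi >= tref - 1e-9)


class TestReproducibility:
    def test_identical_seed_identical_raster(self, quarter_net, sero,
                                             short_protocol):
        b1 = run_trials(quarter_net, sero, short_protocol, 21, 2,
                        record_raster=True)
        b2 = run_trials(quarter_net, sero, short_protocol, 21, 2,
                        record_raster=True)
        for r1, r2 in zip(b1.rasters, b2.rasters):
            assert np.array_equal(r1.times, r2.times)
            assert np.array_equal(r1.neuron, r2.neuron)
            assert np.array_equal(r1.population, r2.population)

    def test_trial_independent_of_batch_composition(self, quarter_net, sero,
                                                    short_protocol):
        solo = run_trials(quarter_net, sero, short_protocol, 21, 1,
                          trial_indices=[3], record_raster=True)
        grouped = run_trials(quarter_net, sero, short_protocol, 21, 5,
                             record_raster=True)
        assert np.array_equal(solo.decode_counts[0], grouped.decode_counts[3])
        assert np.array_equal(solo.rasters[0].times, grouped.rasters[3].times)
        assert np.array_equal(solo.rasters[0].neuron, grouped.rasters[3].neuron)


class TestRingConv:
    def test_circulant_equals_dense(self, quarter_net, sero, short_protocol):
        """FFT and dense recurrent sums agree to tight tolerance end-to-end."""
        b1 = run_trials(quarter_net, sero, short_protocol, 3, 2,
                        conv_method="fft", keep_final_state=True)
        b2 = run_trials(quarter_net, sero, short_protocol, 3, 2,
                        conv_method="dense", keep_final_state=True)
        assert np.array_equal(b1.decode_counts, b2.decode_counts)
        assert np.allclose(b1.final_state.V_e, b2.final_state.V_e,
                           rtol=1e-10, atol=1e-10)

    def test_conv_sums_match_matrix_product(self, quarter_net):
        rng = np.random.default_rng(0)
        gates = rng.random((4, quarter_net.pop.n_excitatory))
        fft_conv = _RingConv(quarter_net, "fft")
        dense_conv = _RingConv(quarter_net, "dense")
        for a, b in zip(fft_conv.e_side(gates), dense_conv.e_side(gates)):
            assert np.allclose(a, b, rtol=1e-10, atol=1e-10)

    def test_one_hot_scalar_oracle(self, quarter_net):
        """Single presynaptic NMDA gate: conv equals W(d)*s by hand."""
        n = quarter_net.pop.n_excitatory
        gates = np.zeros((2, n))
        gates[1, 10] = 0.5
        s_ee, s_ei = _RingConv(quarter_net, "fft").e_side(gates)
        syn = quarter_net.synapses
        # onto itself: W(0) * 0.5; current at -55 mV includes the Mg block
        w0 = rm.kernel_value(quarter_net.kernel, 0.0, "EE")
        assert s_ee[1, 10] == pytest.approx(w0 * 0.5, rel=1e-9)
        i_hand = (w0 * syn.G_EE_NMDA * 0.5 * float(syn.mg_block(-55.0))
                  * (-55.0 - syn.V_exc)) * 1e-3
        i_code = (syn.G_EE_NMDA * s_ee[1, 10] * float(syn.mg_block(-55.0))
                  * (-55.0 - syn.V_exc)) * 1e-3
        assert i_code == pytest.approx(i_hand, rel=1e-9)
        # a distant neuron sees the kernel value at its angular distance
        d = quarter_net.pop.angles_e[60] - quarter_net.pop.angles_e[10]
        assert s_ee[1, 60] == pytest.approx(
            0.5 * rm.kernel_value(quarter_net.kernel, d, "EE"), rel=1e-9)


class TestEquivariance:
    def test_rotating_cue_and_noise_rotates_raster(self, quarter_net, sero,
                                                   short_protocol):
        """Ring homogeneity: a rotated world gives an exactly rotated raster."""
        k = 8  # grid steps; multiple of E/I ratio so the I grid rotates too
        step = 360.0 / quarter_net.pop.n_excitatory
        b0 = run_trials(quarter_net, sero, short_protocol, 13, 1,
                        stimulus=StimulusSpec(theta_s=0.0, I_1=0.8),
                        record_raster=True)
        b1 = run_trials(quarter_net, sero, short_protocol, 13, 1,
                        stimulus=StimulusSpec(theta_s=k * step, I_1=0.8),
                        drive_rotation=k, record_raster=True)
        r0, r1 = b0.rasters[0], b1.rasters[0]
        assert len(r0) > 0
        assert np.array_equal(r0.times, r1.times)
        for pop, n in (("E", quarter_net.pop.n_excitatory),
                       ("I", quarter_net.pop.n_inhibitory)):
            t0, i0 = r0.select(pop)
            t1, i1 = r1.select(pop)
            shift = k if pop == "E" else k * n // quarter_net.pop.n_excitatory
            assert np.array_equal((i0 + shift) % n, i1)


class TestValidation:
    def test_distractor_angle_contract(self, quarter_net, sero, short_protocol):
        with pytest.raises(ValueError):
            run_trials(quarter_net, sero, short_protocol, 1, 1, theta_d=90.0)
        proto_d = rm.TrialProtocol.distractor()
        with pytest.raises(ValueError):
            run_trials(quarter_net, sero, proto_d, 1, 1, theta_d=None)

    def test_dt_bounds(self, quarter_net, sero, short_protocol):
        for dt in (0.0, -0.01, 0.2):
            with pytest.raises(ValueError):
                run_trials(quarter_net, sero, short_protocol, 1, 1, dt=dt)

    def test_protocol_requires_one_cue(self):
        with pytest.raises(ValueError):
            rm.TrialProtocol(periods=(("fixation", 100.0, None),))
        with pytest.raises(ValueError):
            rm.TrialProtocol(periods=(("cue", 100.0, "cue"),
                                      ("cue2", 100.0, "cue")))
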