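"""Integration kernel: alpha PSPs, closed-form LIF rates, Poisson drive."""

import math

import numpy as np
import pytest

import bgsim
from bgsim import params as P
from bgsim.network import GABA, GLUT
from bgsim.simulate import (ALPHA_HALF_DECAY, alpha_kernel, events_from_times,
                            poisson_drive, tau_from_half_time)
from conftest import make_micro_net


class TestAlphaKernel:
    def test_peak_amplitude_at_tau(self):
        tau = tau_from_half_time(P.PSP_HALF_TIME["AMPA"])
        assert alpha_kernel(tau, "AMPA") == pytest.approx(1.0)

    def test_zero_at_time_zero(self):
        for receptor in P.RECEPTORS:
            assert alpha_kernel(0.0, receptor) == 0.0

    def test_gaba_is_hyperpolarizing(self):
        tau = tau_from_half_time(P.PSP_HALF_TIME["GABAA"])
        assert alpha_kernel(tau, "GABAA") == pytest.approx(-0.25)

    @pytest.mark.parametrize("receptor", ["AMPA", "NMDA", "GABAA"])
    def test_half_time_is_peak_to_half_decay(self, receptor):
        tau = tau_from_half_time(P.PSP_HALF_TIME[receptor])
        half_t = P.PSP_HALF_TIME[receptor]
        peak = alpha_kernel(tau, receptor)
        at_half = alpha_kernel(tau + half_t, receptor)
        assert at_half / peak == pytest.approx(0.5, rel=1e-2)

    def test_half_decay_constant_solves_transcendental(self):
        u = 1.0 + ALPHA_HALF_DECAY
        assert u * math.exp(1.0 - u) == pytest.approx(0.5, abs=1e-12)
        assert ALPHA_HALF_DECAY == pytest.approx(1.6783, abs=1e-4)

    def test_log2_reading_available(self):
        assert tau_from_half_time(5.0, "log2") == pytest.approx(5.0 / math.log(2))

    def test_superposition_of_kernels(self):
        t = np.linspace(0, 50, 500)
        single = alpha_kernel(t, "AMPA")
        shifted = alpha_kernel(t - 7.0, "AMPA")
        np.testing.assert_allclose(single + shifted,
                                   alpha_kernel(t, "AMPA") + alpha_kernel(t - 7.0, "AMPA"))

    def test_unknown_receptor_rejected(self):
        with pytest.raises(ValueError):
            alpha_kernel(1.0, "glycine")


class TestClosedFormLif:
    def test_no_input_no_spikes(self):
        net = make_micro_net(theta=10.0, v_c=0.0)
        rec = bgsim.run(net, duration=1000, warmup=0, dt=0.1, seed=0)
        assert rec.ids.size == 0

    def test_subthreshold_drive_never_fires(self):
        net = make_micro_net(theta=10.0, v_c=9.9)
        rec = bgsim.run(net, duration=2000, warmup=0, dt=0.1, seed=0)
        assert rec.ids.size == 0

    def test_constant_drive_rate_matches_closed_form(self):
        # ISI = t_ref + tau_m * ln(V_C / (V_C - theta)) = 2 + 14 ln 3 ~ 17.38 ms
        net = make_micro_net(theta=10.0, v_c=15.0, tau_m=14.0, t_ref=2.0)
        rec = bgsim.run(net, duration=10_000, warmup=1000, dt=0.1, seed=0)
        expected_isi = 2.0 + 14.0 * math.log(15.0 / 5.0)
        rate = bgsim.population_rate(rec, "GPi")
        assert rate == pytest.approx(1000.0 / expected_isi, rel=0.02)

    def test_no_isi_below_refractory_period(self, rest1):
        for neuron in np.unique(rest1.ids):
            isi = np.diff(np.sort(rest1.times[rest1.ids == neuron]))
            if isi.size:
                assert isi.min() >= rest1.meta.get("t_ref", 2.0) - 1e-9


class TestPspIntegration:
    def drive(self, net, times, duration=200.0):
        ev = events_from_times(times, [0] * len(times), duration, 0.1)
        rec = bgsim.run(net, duration=duration, warmup=0, dt=0.1, seed=0,
                        events=ev, watch=0)
        return rec.meta["v_watch"]

    def test_single_epsp_peaks_below_amplitude_and_decays(self):
        net = make_micro_net(theta=50.0, v_c=0.0, weight=1.0, kind=GLUT)
        v = self.drive(net, [20.0])
        assert 0.1 < v.max() < 1.1     # membrane filtering keeps V below A
        assert abs(v[-1]) < 0.05       # passive return toward rest
        assert np.all(v[:int(20 / 0.1)] == 0.0)

    def test_single_ipsp_is_negative(self):
        net = make_micro_net(theta=50.0, v_c=0.0, weight=1.0, kind=GABA)
        v = self.drive(net, [20.0])
        assert v.min() < -0.02
        assert v.max() <= 1e-12

    def test_subthreshold_superposition_is_exact(self):
        net = make_micro_net(theta=50.0, v_c=0.0, weight=1.0, kind=GLUT)
        v_a = self.drive(net, [20.0])
        v_b = self.drive(net, [60.0])
        v_ab = self.drive(net, [20.0, 60.0])
        np.testing.assert_allclose(v_ab, v_a + v_b, atol=1e-9)

    def test_half_time_mode_flag_changes_kinetics(self):
        net = make_micro_net(theta=50.0, v_c=0.0, weight=1.0, kind=GLUT)
        v_default = self.drive(net, [20.0])
        net.param.fixed.half_time_mode = "log2"
        v_log2 = self.drive(net, [20.0])
        assert not np.allclose(v_default, v_log2)

    def test_weight_scales_response_linearly(self):
        v1 = self.drive(make_micro_net(theta=50.0, weight=1.0, kind=GLUT), [20.0])
        v3 = self.drive(make_micro_net(theta=50.0, weight=3.0, kind=GLUT), [20.0])
        np.testing.assert_allclose(v3, 3.0 * v1, atol=1e-9)


class TestPoissonDrive:
    def test_total_count_matches_rate(self):
        net = make_micro_net(theta=1e9, n_inputs=1000, input_rate=4.0)
        rng = np.random.default_rng(1)
        ev_ptr, ev_src = poisson_drive(net, None, 10_000.0, 0.1, rng)
        expected = 1000 * 4.0 * 10.0
        assert ev_src.size == pytest.approx(expected, abs=3 * math.sqrt(expected))

    def test_zero_rate_is_silent(self):
        net = make_micro_net(theta=1e9, n_inputs=100, input_rate=0.0)
        rng = np.random.default_rng(1)
        _, ev_src = poisson_drive(net, None, 5000.0, 0.1, rng)
        assert ev_src.size == 0

    def test_schedule_step_changes_rate(self):
        net = make_micro_net(theta=1e9, n_inputs=500, input_rate=2.0)
        program = bgsim.StimulationProgram([
            bgsim.Activation(population="CMPf", channel=None, size=None,
                             schedule=[(1000.0, 2000.0, 20.0)])])
        rng = np.random.default_rng(2)
        ev_ptr, ev_src = poisson_drive(net, program, 2000.0, 0.1, rng)
        n_before = int(ev_ptr[10_000])
        n_after = ev_src.size - n_before
        for n, rate in ((n_before, 2.0), (n_after, 20.0)):
            expected = 500 * rate
            assert n == pytest.approx(expected, abs=3 * math.sqrt(expected))

    def test_oversized_subset_rejected(self):
        net = make_micro_net(theta=1e9, n_inputs=10, input_rate=2.0)
        program = bgsim.StimulationProgram([
            bgsim.Activation(population="CMPf", channel=None, size=11,
                             schedule=5.0)])
        with pytest.raises(ValueError):
            poisson_drive(net, program, 1000.0, 0.1, np.random.default_rng(0))


class TestReproducibility:
    def test_same_seed_identical_records(self, net1):
        a = bgsim.run(net1, duration=1200, warmup=600, dt=0.1, seed=9)
        b = bgsim.run(net1, duration=1200, warmup=600, dt=0.1, seed=9)
        np.testing.assert_array_equal(a.ids, b.ids)
        np.testing.assert_array_equal(a.times, b.times)

    def test_different_seeds_differ(self, net1):
        a = bgsim.run(net1, duration=1200, warmup=600, dt=0.1, seed=9)
        b = bgsim.run(net1, duration=1200, warmup=600, dt=0.1, seed=10)
        assert a.ids.size != b.ids.size or not np.array_equal(a.times, b.times)

    def test_empty_block_is_identity(self, net1):
        a = bgsim.run(net1, duration=1200, warmup=600, dt=0.1, seed=9)
        view = bgsim.block_receptors(net1, "GPi", ["AMPA"])
        view.blocks = []  # block nothing
        b = bgsim.run(view, duration=1200, warmup=600, dt=0.1, seed=9)
        np.testing.assert_array_equal(a.ids, b.ids)
        np.testing.assert_array_equal(a.times, b.times)

    def test_warmup_spikes_flagged_not_deleted(self, rest1):
        assert np.any(rest1.times < rest1.warmup_ms)
        _, analysed = rest1.spikes_of("GPi")
        assert np.all(analysed >= rest1.warmup_ms)


class TestBlockReceptors:
    def test_invalid_arguments(self, net1):
        with pytest.raises(ValueError):
            bgsim.block_receptors(net1, "GPx", ["AMPA"])
        with pytest.raises(ValueError):
            bgsim.block_receptors(net1, "GPi", [])
        with pytest.raises(ValueError):
            bgsim.block_receptors(net1, "GPi", ["glycine"])

    def test_gaba_block_disinhibits_gpi(self, net1, rest1):
        blocked = bgsim.block_receptors(net1, "GPi", ["GABAA"])
        rec = bgsim.run(blocked, duration=2000, warmup=1000, dt=0.1,
                        seed=rest1.seed)
        assert bgsim.population_rate(rec, "GPi") > \
            bgsim.population_rate(rest1, "GPi")


def test_dt_refinement_changes_rates_less_than_two_percent(net1):
    coarse = bgsim.run(net1, duration=3000, warmup=1000, dt=0.1, seed=11)
    fine = bgsim.run(net1, duration=3000, warmup=1000, dt=0.05, seed=11)
    for nucleus in ("FSI", "GPe", "GPi"):
        r0 = bgsim.population_rate(coarse, nucleus)
        r1 = bgsim.population_rate(fine, nucleus)
        assert abs(r1 - r0) / r0 < 0.02
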