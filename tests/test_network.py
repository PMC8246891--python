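"""Connectivity arithmetic, cable attenuation and network realization."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import bgsim
from bgsim.network import (Disruption, attenuation, electrotonic_length,
                           realized_in_degrees, source_neuron_count,
                           synapse_count)
from bgsim.params import expected_synapse_count


class TestSynapseCount:
    @pytest.mark.parametrize("args, expected", [
        ((1.0, 100, 100, 209.0), 209.0),               # identity case
        ((0.82, 10576, 56, 166.0), 25707.23),          # striato-pallidal
        ((1.0, 12000, 10576, 248.0), 281.39),          # cortico-striatal
    ])
    def test_arithmetic(self, args, expected):
        assert synapse_count(*args) == pytest.approx(expected, rel=1e-4)

    def test_zero_target_population_rejected(self):
        with pytest.raises(ValueError):
            synapse_count(1.0, 10, 0, 5.0)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            synapse_count(-0.1, 10, 10, 5.0)


class TestSourceNeuronCount:
    def test_integer_ratio_is_deterministic(self):
        rng = np.random.default_rng(0)
        assert all(source_neuron_count(12.0, 3.0, rng) == 4 for _ in range(50))

    def test_fsi_to_fsi_printed_count(self):
        # 117 synapses at redundancy 3 -> exactly 39 source interneurons
        rng = np.random.default_rng(0)
        assert all(source_neuron_count(117.0, 3.0, rng) == 39 for _ in range(50))

    def test_fractional_part_realized_as_probability(self):
        rng = np.random.default_rng(42)
        draws = np.array([source_neuron_count(14.1, 3.0, rng)
                          for _ in range(100_000)])
        assert set(np.unique(draws)) <= {4, 5}
        se = math.sqrt(0.7 * 0.3 / draws.size)
        assert draws.mean() == pytest.approx(4.7, abs=3 * se)

    def test_invalid_arguments(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            source_neuron_count(10.0, 0.5, rng)
        with pytest.raises(ValueError):
            source_neuron_count(-1.0, 3.0, rng)


class TestCable:
    def test_msn_electrotonic_length(self):
        # hand conversion: 619 um * sqrt((4 / 1e-4 cm) * (200/20000)) = 1.238
        assert electrotonic_length(619.0, 1.0, 200.0, 20000.0) == \
            pytest.approx(1.238, rel=1e-3)

    def test_zero_length_dendrite(self):
        assert electrotonic_length(0.0, 1.0, 200.0, 20000.0) == 0.0

    def test_quadrupling_diameter_halves_length(self):
        base = electrotonic_length(500.0, 1.0, 200.0, 20000.0)
        assert electrotonic_length(500.0, 4.0, 200.0, 20000.0) == \
            pytest.approx(base / 2.0, rel=1e-12)

    def test_somatic_contact_is_unattenuated(self):
        assert attenuation(2.5, 0.0) == pytest.approx(1.0)

    def test_distal_contact_closed_form(self):
        L = 1.7
        assert attenuation(L, 1.0) == pytest.approx(1.0 / math.cosh(L))

    def test_msn_example_attenuation(self):
        L = electrotonic_length(619.0, 1.0, 200.0, 20000.0)
        assert attenuation(L, 0.9) == pytest.approx(0.539, abs=1e-3)

    def test_bounds_and_monotonicity_over_sweep(self):
        ps = np.linspace(0.0, 1.0, 100)
        Ls = np.linspace(0.0, 4.0, 100)
        for L in (0.0, 0.5, 1.238, 3.0):
            gammas = [attenuation(L, p) for p in ps]
            assert all(0.0 < g <= 1.0 for g in gammas)
            assert np.all(np.diff(gammas) <= 1e-15)
        for p in (0.2, 0.9):
            gammas = [attenuation(L, p) for L in Ls]
            assert np.all(np.diff(gammas) <= 1e-15)
        assert all(attenuation(0.0, p) == 1.0 for p in ps)

    @given(L=st.floats(0.0, 6.0), p=st.floats(0.0, 1.0))
    @settings(max_examples=200, deadline=None)
    def test_attenuation_bounds_property(self, L, p):
        g = attenuation(L, p)
        assert 0.0 < g <= 1.0

    def test_invalid_location_rejected(self):
        with pytest.raises(ValueError):
            attenuation(1.0, 1.2)


class TestBuildNetwork:
    def test_rebuild_with_same_seed_is_bit_stable(self, param1):
        a = bgsim.build_network(param1, seed=5)
        b = bgsim.build_network(param1, seed=5)
        assert set(a.groups) == set(b.groups)
        for name in a.groups:
            np.testing.assert_array_equal(a.groups[name].pre, b.groups[name].pre)
            np.testing.assert_array_equal(a.groups[name].post, b.groups[name].post)

    def test_focused_projection_sources_share_channel(self, param3):
        net = bgsim.build_network(param3, seed=2)
        g = net.groups["MSN->GPi"]
        pre_ch = net.channel_of[g.pre]
        post_ch = net.channel_of[g.post]
        np.testing.assert_array_equal(pre_ch, post_ch)

    def test_no_self_synapses_within_population(self, param1):
        net = bgsim.build_network(param1, seed=3)
        for name in ("MSN->MSN", "FSI->FSI", "GPe->GPe"):
            g = net.groups[name]
            assert not np.any(g.pre == g.post)

    def test_diffuse_source_channels_uniform(self, param3):
        # flip the (large-pool) cortico-striatal projection to diffuse and
        # check the realized source-channel distribution is multinomial-flat
        net = bgsim.build_network(
            param3,
            disruptions=[Disruption(kind="make_diffuse", source="CSN",
                                    target="MSN")],
            seed=4)
        g = net.groups["CSN->MSN"]
        channels = net.inp_channel[g.pre]
        counts = np.bincount(channels, minlength=3)
        assert counts.sum() > 10_000
        chi2 = stats.chisquare(counts).pvalue
        assert chi2 > 1e-3

    def test_mean_in_degree_matches_expectation(self, net1):
        param = net1.param
        proj = param.projection("CSN", "MSN")
        nu = expected_synapse_count(param, proj)
        counts = realized_in_degrees(net1, "CSN", "MSN")
        ratio = nu / proj.rho
        frac = ratio - math.floor(ratio)
        se = math.sqrt(max(frac * (1 - frac), 1e-12) / counts.size)
        assert counts.mean() == pytest.approx(ratio, abs=max(3 * se, 1e-9))

    def test_weight_is_attenuation_times_redundancy(self, param1):
        net = bgsim.build_network(param1, seed=1)
        proj = param1.projection("MSN", "GPi")
        spec = param1.nucleus("GPi")
        L = electrotonic_length(spec.dendrite_length, spec.dendrite_diameter)
        expected = attenuation(L, proj.p) * proj.rho
        assert net.groups["MSN->GPi"].weight == pytest.approx(expected)

    def test_export_tables(self, net1, tmp_path):
        net1.export(tmp_path / "neurons.tsv", tmp_path / "synapses.tsv")
        header = (tmp_path / "neurons.tsv").read_text().splitlines()[0]
        assert header == f"# seed={net1.seed}"
        assert (tmp_path / "synapses.tsv").stat().st_size > 0


class TestDisruptions:
    def test_poissonify_preserves_synapse_count(self, param1):
        intact = bgsim.build_network(param1, seed=6)
        disrupted = bgsim.build_network(
            param1,
            disruptions=[Disruption(kind="poissonify_projection",
                                    source="MSN", target="MSN", rate=0.4)],
            seed=6)
        gi, gd = intact.groups["MSN->MSN"], disrupted.groups["MSN->MSN"]
        assert gd.pre.size == gi.pre.size
        assert gd.from_inputs
        np.testing.assert_array_equal(gd.post, gi.post)
        # each synapse got its own fresh generator at the requested rate
        assert np.unique(gd.pre).size == gd.pre.size
        assert np.all(disrupted.inp_rate[gd.pre] == 0.4)

    def test_make_focused_rewires_topology(self, param3):
        net = bgsim.build_network(
            param3,
            disruptions=[Disruption(kind="make_focused", source="STN",
                                    target="GPi")],
            seed=7)
        g = net.groups["STN->GPi"]
        np.testing.assert_array_equal(net.channel_of[g.pre],
                                      net.channel_of[g.post])

    def test_unknown_projection_rejected(self, param1):
        with pytest.raises(KeyError):
            bgsim.build_network(
                param1,
                disruptions=[Disruption(kind="poissonify_projection",
                                        source="GPi", target="MSN", rate=1.0)],
                seed=0)

    def test_malformed_disruption_rejected(self):
        with pytest.raises(ValueError):
            Disruption(kind="explode", source="MSN", target="MSN")
        with pytest.raises(ValueError):
            Disruption(kind="block_receptor", nucleus="GPi", receptors=())
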