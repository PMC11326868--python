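"""Compartmental model: morphology, assembly, holding, integration, metrics."""

import numpy as np
import pytest

from mocsyn.metrics import SuprathresholdError, detect_aps, measure_psp
from mocsyn.model import (
    ChannelSet,
    MocModel,
    PassiveProps,
    SimResult,
    SynapseSpec,
    biexp_peak_time,
    biexp_unit_peak,
    build_model,
)
from mocsyn.morphology import Morphology, Section, moc_fixture, read_swc, write_swc


class TestMorphology:
    def test_fixture_has_86_segments(self, fixture_morph):
        assert fixture_morph.total_nseg == 86

    def test_fixture_dimensions(self, fixture_morph):
        soma = fixture_morph.section("soma")
        assert (soma.length_um, soma.diam_um) == (33.6, 6.1)
        axon = fixture_morph.section("axon")
        assert (axon.length_um, axon.diam_um) == (180.0, 1.0)
        daughters = [s for s in fixture_morph.sections if "_d" in s.name]
        lengths = [s.length_um for s in daughters]
        diams = [s.diam_um for s in daughters]
        assert min(lengths) >= 1.5 and max(lengths) <= 31.4
        assert min(diams) >= 1.0 and max(diams) <= 2.0

    def test_zero_length_section_rejected(self):
        with pytest.raises(ValueError, match="length"):
            Section("bad", 0.0, 1.0)

    def test_disconnected_section_rejected(self):
        with pytest.raises(ValueError, match="disconnected|parent"):
            Morphology([
                Section("soma", 10, 5),
                Section("orphan", 10, 1, parent="ghost"),
            ])

    def test_multiple_roots_rejected(self):
        with pytest.raises(ValueError, match="root"):
            Morphology([Section("a", 10, 5), Section("b", 10, 5)])

    def test_swc_roundtrip(self, fixture_morph, tmp_path):
        path = tmp_path / "m.swc"
        write_swc(fixture_morph, path)
        back = read_swc(path, nseg_by_type={1: 1, 2: 8, 3: 1})
        assert back.total_nseg == 86
        # dimensions survive at the SWC file's 4-decimal precision
        assert back.total_area_um2 == pytest.approx(
            fixture_morph.total_area_um2, rel=1e-4
        )

    def test_shipped_swc_fixture(self):
        from importlib import resources

        with resources.as_file(
            resources.files("mocsyn.data").joinpath("moc_fixture.swc")
        ) as p:
            m = read_swc(p, nseg_by_type={1: 1, 2: 8, 3: 1})
        assert m.total_nseg == 86


class TestBuildModel:
    def test_soma_only_area_matches_cylinder(self, soma_only, passive_channels):
        m = build_model(soma_only, PassiveProps(), passive_channels)
        assert m.total_area_um2 == pytest.approx(np.pi * 6.1 * 33.6, rel=1e-3)

    def test_fixture_discretization(self, fixture_morph, passive_channels):
        m = build_model(fixture_morph, PassiveProps(), passive_channels)
        assert m.n_seg == 86
        assert m.total_area_um2 == pytest.approx(
            fixture_morph.total_area_um2, rel=1e-3
        )

    def test_invalid_passive_rejected(self):
        with pytest.raises(ValueError):
            PassiveProps(axial_resistivity=-1.0)


class TestSynapseSpec:
    def test_peak_conductance_equals_weight_analytic(self):
        """Unit-peak normalization: g at the analytic peak time equals the
        weight to 1e-6 relative error."""
        for tr, td in [(0.2, 6.0), (2.75, 3.64), (0.5, 1.0)]:
            tp = biexp_peak_time(tr, td)
            g = biexp_unit_peak(np.array([tp]), tr, td)[0]
            assert g == pytest.approx(1.0, rel=1e-6)
            # and it is the maximum on a fine grid
            t = np.arange(0, 10 * td, 1e-4)
            assert np.max(biexp_unit_peak(t, tr, td)) <= 1.0 + 1e-6

    def test_tau_swap_warns(self):
        with pytest.warns(UserWarning, match="swap"):
            s = SynapseSpec(tau_rise=3.64, tau_decay=2.75, weight=1e-3, reversal=0.0)
        assert s.tau_rise < s.tau_decay

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            SynapseSpec(tau_rise=0.2, tau_decay=6.0, weight=-1e-3, reversal=0.0)


class TestHolding:
    def test_passive_model_zero_bias(self, passive_soma_model):
        """Leak reversal at the target potential: holding needs ~no current."""
        assert passive_soma_model.holding["bias_nA"] == pytest.approx(0.0, abs=1e-3)

    def test_hcn_requires_hyperpolarizing_bias(self, soma_only):
        """HCN reverses at -38 mV, so holding -60 mV needs negative bias."""
        ch = ChannelSet(densities={"leak": {"all": 1e-4}, "hcn": {"all": 2e-4}},
                        e_leak=-60.0)
        m = build_model(soma_only, PassiveProps(), ch)
        assert m.set_holding(-60.0, settle_ms=1500.0) < 0

    def test_bias_monotone_in_target(self, soma_only):
        ch = ChannelSet(densities={"leak": {"all": 1e-4}}, e_leak=-60.0)
        m = build_model(soma_only, PassiveProps(), ch)
        b60 = m.set_holding(-60.0, settle_ms=500.0)
        b70 = m.set_holding(-70.0, settle_ms=500.0)
        assert b70 < b60

    def test_baseline_within_tolerance(self, calibrated_model):
        """Holding invariant on the full model: baseline within 1 mV of -60
        before any synaptic onset."""
        res = calibrated_model.run_protocol(duration=300.0, dt=0.1)
        assert np.all(np.abs(res.v_soma + 60.0) < 1.0)

    def test_no_synapse_drift_under_half_mV(self, calibrated_model):
        """Charge/steady-state sanity over a full second."""
        res = calibrated_model.run_protocol(duration=1000.0, dt=0.1)
        assert np.ptp(res.v_soma) < 0.5


class TestIntegration:
    def synapse(self, onset=10.0):
        return SynapseSpec(tau_rise=0.2, tau_decay=6.0, weight=0.0015,
                           reversal=0.0, onset=onset)

    def test_halving_dt_changes_psp_under_1pct(self, passive_soma_model):
        amps = []
        for dt in (0.025, 0.0125):
            res = passive_soma_model.run_protocol([self.synapse()],
                                                  duration=80.0, dt=dt)
            amps.append(measure_psp(res, 10.0).amplitude_mV)
        assert abs(amps[1] - amps[0]) / abs(amps[1]) < 0.01

    def test_crank_nicolson_agrees_with_backward_euler(self, passive_soma_model):
        amps = {}
        for method in ("be", "cn"):
            res = passive_soma_model.run_protocol([self.synapse()],
                                                  duration=80.0, dt=0.025,
                                                  method=method)
            amps[method] = measure_psp(res, 10.0).amplitude_mV
        assert amps["cn"] == pytest.approx(amps["be"], rel=5e-3)

    def test_synaptic_current_zero_at_reversal(self, soma_only):
        """Driving-force invariant: clamped at the synapse reversal, the
        clamp current is unchanged by the synapse."""
        ch = ChannelSet(densities={"leak": {"all": 2e-4}}, e_leak=-60.0)
        m = build_model(soma_only, PassiveProps(), ch)
        syn = SynapseSpec(tau_rise=0.5, tau_decay=4.0, weight=0.002,
                          reversal=-20.0, onset=10.0)
        with_syn = m.simulate([syn], duration=40.0, dt=0.05,
                              clamp_soma_mV=-20.0)
        without = m.simulate([], duration=40.0, dt=0.05, clamp_soma_mV=-20.0)
        np.testing.assert_allclose(
            with_syn.syn_g["clamp_nA"], without.syn_g["clamp_nA"], atol=1e-9
        )

    def test_nan_result_raises_naming_time(self):
        t = np.arange(5) * 0.1
        v = np.array([-60.0, -60.0, np.nan, -60.0, -60.0])
        with pytest.raises(FloatingPointError, match="0.2"):
            SimResult(t=t, v_soma=v, dt=0.1)

    def test_spatial_convergence_of_fixture(self, passive_channels):
        """Doubling axon discretization changes the evoked PSP < 1%."""
        fine_sections = []
        for s in moc_fixture().sections:
            nseg = s.nseg * 2 if s.name == "axon" else s.nseg
            fine_sections.append(
                Section(s.name, s.length_um, s.diam_um, s.parent, nseg, s.swc_type)
            )
        amps = []
        for morph in (moc_fixture(), Morphology(fine_sections)):
            m = build_model(morph, PassiveProps(), passive_channels)
            m.set_holding(-60.0, settle_ms=300.0)
            res = m.run_protocol([self.synapse(20.0)], duration=80.0, dt=0.05)
            amps.append(measure_psp(res, 20.0).amplitude_mV)
        assert abs(amps[1] - amps[0]) / abs(amps[0]) < 0.01


class TestMetrics:
    def spike_trace(self, times, duration=120.0, dt=0.025):
        t = np.arange(int(duration / dt)) * dt
        v = np.full(t.size, -60.0)
        for ts in times:
            v[(t >= ts) & (t < ts + 1.0)] = 10.0
        return SimResult(t=t, v_soma=v, dt=dt)

    def test_subthreshold_trace_no_aps(self):
        res = self.spike_trace([])
        ap = detect_aps(res)
        assert ap.n_aps == 0
        assert ap.first_latency_ms is None

    def test_five_spikes_rate_100hz(self):
        """Hand-constructed train at 10 ms spacing: rate (N-1)/span = 100 Hz,
        latency equals the first spike time."""
        res = self.spike_trace([20.0, 30.0, 40.0, 50.0, 60.0])
        ap = detect_aps(res, reference_onset_ms=10.0)
        assert ap.n_aps == 5
        assert ap.rate_hz == pytest.approx(100.0, rel=1e-3)
        assert ap.first_latency_ms == pytest.approx(10.0, abs=0.05)

    def test_refractory_collapses_double_crossings(self):
        t = np.arange(0, 50, 0.025)
        v = np.full(t.size, -60.0)
        v[(t >= 20.0) & (t < 20.2)] = 0.0
        v[(t >= 20.5) & (t < 20.7)] = 0.0  # 0.3 ms later: same AP
        res = SimResult(t=t, v_soma=v, dt=0.025)
        assert detect_aps(res, refractory_ms=1.0).n_aps == 1

    def test_zero_weight_zero_amplitude(self, passive_soma_model):
        syn = SynapseSpec(tau_rise=0.2, tau_decay=6.0, weight=0.0,
                          reversal=0.0, onset=10.0)
        res = passive_soma_model.run_protocol([syn], duration=60.0, dt=0.05)
        assert measure_psp(res, 10.0).amplitude_mV == pytest.approx(0.0, abs=1e-6)

    def test_measure_psp_rejects_spiking_window(self):
        res = self.spike_trace([30.0])
        with pytest.raises(SuprathresholdError):
            measure_psp(res, onset=20.0)
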