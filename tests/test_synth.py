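"""Synthetic-data generators: determinism, ground truth, calibrated noise."""

import numpy as np
import pandas as pd
import pytest

from mocsyn.events import compute_rms_noise
from mocsyn.synth import (
    EXCITATORY_CLUSTER,
    INHIBITORY_CLUSTER,
    CalciumGenSpec,
    ClusterGenSpec,
    SweepGenSpec,
    driving_force_factor,
    generate_calcium_movie,
    generate_feature_table,
    generate_sweep_set,
)


def cluster(**kw):
    base = dict(
        label="excitatory", mean_onset_latency=2.0, onset_jitter_sd=0.2,
        probability=1.0, amplitude_mean=60.0, amplitude_sd=10.0,
        tau_rise=0.3, tau_decay=3.0,
    )
    base.update(kw)
    return ClusterGenSpec(**base)


class TestClusterGenSpec:
    @pytest.mark.parametrize(
        "bad",
        [
            dict(probability=1.2),
            dict(probability=-0.1),
            dict(tau_rise=3.0, tau_decay=0.3),
            dict(onset_jitter_sd=-1.0),
            dict(amplitude_mean=0.0),
            dict(label="mystery"),
        ],
    )
    def test_invalid_specs_rejected(self, bad):
        with pytest.raises(ValueError):
            cluster(**bad)

    def test_default_excitatory_kinetics_faster_than_inhibitory(self):
        assert EXCITATORY_CLUSTER.tau_rise < INHIBITORY_CLUSTER.tau_rise
        assert EXCITATORY_CLUSTER.tau_decay < INHIBITORY_CLUSTER.tau_decay


class TestGenerateSweepSet:
    def test_degenerate_noise_free_case(self):
        """probability=1, no jitter, no noise: identical sweeps, one event
        each at the stated latency."""
        spec = SweepGenSpec(
            n_sweeps=10, duration=40.0, stim_times=(10.0,),
            clusters=(cluster(onset_jitter_sd=0.0, amplitude_sd=0.0),),
            noise_rms=0.0, seed=0,
        )
        ss, truth = generate_sweep_set(spec)
        assert len(truth) == 10
        assert np.allclose(truth["latency"], 2.0)
        for i in range(1, 10):
            np.testing.assert_array_equal(ss.traces[i], ss.traces[0])
        # event onset at stim + mean latency: trace leaves zero there
        i_on = int(12.0 / ss.dt)
        assert np.all(ss.traces[0][: i_on - 1] == 0)
        assert ss.traces[0][i_on + 10] < 0  # inward at -60 mV

    def test_occurrence_probability_binomial(self):
        """Fraction of sweeps containing an event ~ cluster probability
        (oracle: direct count of ground-truth rows)."""
        spec = SweepGenSpec(
            n_sweeps=1000, duration=30.0, stim_times=(5.0,),
            clusters=(cluster(probability=0.45),), noise_rms=1.0, seed=7,
        )
        _, truth = generate_sweep_set(spec)
        frac = truth["sweep"].nunique() / 1000
        assert abs(frac - 0.45) <= 0.05

    def test_both_classes_inward_at_minus60(self):
        """E and I events share polarity at -60 mV (both inward)."""
        spec = SweepGenSpec(
            n_sweeps=50, duration=40.0, stim_times=(10.0,),
            clusters=(EXCITATORY_CLUSTER, INHIBITORY_CLUSTER),
            noise_rms=0.0, holding_potential=-60.0, seed=3,
        )
        _, truth = generate_sweep_set(spec)
        assert (truth["rendered_amplitude"] < 0).all()

    def test_inhibitory_polarity_by_holding(self):
        """I events vanish at their -20 mV reversal and invert at 0 mV."""
        assert driving_force_factor(-20.0, -20.0) == 0.0
        assert driving_force_factor(0.0, -20.0) < 0
        assert driving_force_factor(-60.0, -20.0) == 1.0
        spec0 = SweepGenSpec(
            n_sweeps=30, duration=40.0, stim_times=(10.0,),
            clusters=(EXCITATORY_CLUSTER, INHIBITORY_CLUSTER),
            noise_rms=0.0, holding_potential=0.0, seed=3,
        )
        _, truth0 = generate_sweep_set(spec0)
        e = truth0[truth0.label == "excitatory"]
        i = truth0[truth0.label == "inhibitory"]
        assert np.allclose(e["rendered_amplitude"], 0.0)
        assert (i["rendered_amplitude"] > 0).all()

    def test_determinism_and_event_count_conservation(self):
        spec = SweepGenSpec(
            n_sweeps=25, duration=60.0, stim_times=(10.0, 35.0),
            clusters=(EXCITATORY_CLUSTER, INHIBITORY_CLUSTER),
            noise_rms=4.0, seed=11,
        )
        ss1, t1 = generate_sweep_set(spec)
        ss2, t2 = generate_sweep_set(spec)
        np.testing.assert_array_equal(ss1.traces, ss2.traces)
        pd.testing.assert_frame_equal(t1, t2)
        # conservation: rendering the truth table alone reproduces the traces
        noise_only, _ = generate_sweep_set(
            SweepGenSpec(
                n_sweeps=25, duration=60.0, stim_times=(10.0, 35.0),
                clusters=(
                    cluster(probability=0.0),
                    ClusterGenSpec(**{**INHIBITORY_CLUSTER.__dict__, "probability": 0.0}),
                ),
                noise_rms=4.0, seed=11,
            )
        )
        from mocsyn.model import biexp_unit_peak

        rebuilt = noise_only.traces.copy()
        t = ss1.t
        for row in t1.itertuples():
            rebuilt[row.sweep] += row.rendered_amplitude * biexp_unit_peak(
                t - row.onset, row.tau_rise, row.tau_decay
            )
        np.testing.assert_allclose(rebuilt, ss1.traces, atol=1e-9)

    def test_noise_rms_calibration(self):
        """With no events, measured RMS is within 5% of noise_rms over >=1e5
        samples."""
        spec = SweepGenSpec(
            n_sweeps=2, duration=1200.0, stim_times=(1100.0,),
            clusters=(cluster(probability=0.0),), noise_rms=5.0, seed=21,
        )
        ss, truth = generate_sweep_set(spec)
        assert len(truth) == 0
        assert ss.n_samples >= 5e4
        rms = compute_rms_noise(ss.traces.ravel(), ss.dt, (0.0, 2 * 1090.0))
        assert abs(rms - 5.0) / 5.0 <= 0.05

    @pytest.mark.parametrize(
        "bad",
        [
            dict(stim_times=(50.0,), duration=40.0),
            dict(sampling_rate=15.0),   # <= 2 x bandwidth
            dict(n_sweeps=0),
        ],
    )
    def test_invalid_sweep_specs_rejected(self, bad):
        base = dict(n_sweeps=5, duration=40.0, stim_times=(10.0,))
        base.update(bad)
        with pytest.raises(ValueError):
            SweepGenSpec(**base)


class TestFeatureTable:
    def test_zero_rows_rejected(self):
        with pytest.raises(ValueError):
            generate_feature_table(0)

    def test_separable_classes_are_trivially_classifiable(self):
        """Class means 10 sigma apart: any reasonable classifier is perfect."""
        from mocsyn.classify import evaluate_classifier, train_ei_classifier

        params = {
            "excitatory": {"rise_time": (1.0, 0.1), "decay_tau": (2.0, 0.2),
                           "amplitude": (60.0, 5.0), "probability": (0.8, 0.05),
                           "onset_jitter": (0.2, 0.05), "peak_jitter": (0.3, 0.05)},
            "inhibitory": {"rise_time": (2.0, 0.1), "decay_tau": (2.0, 0.2),
                           "amplitude": (60.0, 5.0), "probability": (0.8, 0.05),
                           "onset_jitter": (0.2, 0.05), "peak_jitter": (0.3, 0.05)},
        }
        train = generate_feature_table(150, class_params=params, seed=1)
        test = generate_feature_table(80, class_params=params, seed=2)
        model = train_ei_classifier(train, n_trees=100, seed=0)
        acc, _, auc = evaluate_classifier(model, test)
        assert acc == 1.0
        assert auc == 1.0

    def test_medians_recover_class_params(self):
        """Published median kinetics fed in come back out within MC error."""
        df = generate_feature_table(600, seed=4)
        e = df[df.label == "excitatory"]
        i = df[df.label == "inhibitory"]
        assert e["rise_time"].median() == pytest.approx(0.63, abs=0.05)
        assert i["rise_time"].median() == pytest.approx(0.86, abs=0.05)
        assert e["decay_tau"].median() == pytest.approx(2.23, abs=0.15)
        assert i["decay_tau"].median() == pytest.approx(3.51, abs=0.25)

    def test_determinism(self):
        a = generate_feature_table(40, seed=9)
        b = generate_feature_table(40, seed=9)
        pd.testing.assert_frame_equal(a, b)


class TestCalciumMovie:
    def test_full_suppression_flattens_blocked_movie(self):
        spec = CalciumGenSpec(suppression_factor=1.0, noise_sd=0.0, seed=0)
        movie, polys, truth = generate_calcium_movie(spec, "blocked")
        from mocsyn.synth import rasterize_roi

        for poly in polys:
            mask = rasterize_roi(poly, spec.frame_shape)
            tr = movie[:, mask].mean(axis=1)
            np.testing.assert_allclose(tr, spec.baseline_f, rtol=1e-12)
        assert np.allclose(truth["true_dff"], 1.0)

    def test_zero_suppression_identity(self):
        spec = CalciumGenSpec(suppression_factor=0.0, seed=8)
        a, _, _ = generate_calcium_movie(spec, "control")
        b, _, _ = generate_calcium_movie(spec, "blocked")
        np.testing.assert_array_equal(a, b)

    def test_downstream_percent_suppression_recovery(self):
        """evoked 1.18 with blocked peak 1.06 -> ~66.7% suppression
        (hand oracle: (1.18-1.06)/(1.18-1))."""
        from mocsyn.calcium import (
            compute_dff,
            percent_suppression,
            roi_traces_from_movie,
        )

        sf = (1.18 - 1.06) / (1.18 - 1.0)
        ctrl_spec = CalciumGenSpec(evoked_dff=1.18, noise_sd=0.0, seed=2)
        blk_spec = CalciumGenSpec(evoked_dff=1.18, noise_sd=0.0,
                                  suppression_factor=sf, seed=2)
        mc, polys, _ = generate_calcium_movie(ctrl_spec, "control")
        mb, _, _ = generate_calcium_movie(blk_spec, "blocked")
        args = (ctrl_spec.frame_rate, ctrl_spec.baseline_frames,
                ctrl_spec.stim_bout_frames)
        dc = [compute_dff(t)[0] for t in roi_traces_from_movie(mc, polys, *args)]
        db = [compute_dff(t)[0] for t in roi_traces_from_movie(mb, polys, *args)]
        sup = [percent_suppression(c, b) for c, b in zip(dc, db)]
        assert np.median(sup) == pytest.approx(66.7, abs=0.5)

    @pytest.mark.parametrize(
        "bad",
        [
            dict(stim_bout_frames=(15, 30, 70)),      # outside frame range
            dict(stim_bout_frames=(15, 30)),          # not three bouts
            dict(suppression_factor=1.5),
            dict(baseline_frames=20),                 # after first bout
        ],
    )
    def test_invalid_calcium_specs_rejected(self, bad):
        with pytest.raises(ValueError):
            CalciumGenSpec(**bad)
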