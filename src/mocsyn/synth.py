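"""Synthetic-data generators for every pipeline in the package.

Three generators, all deterministic under a seed:

* PSC sweep sets: stimulus-locked events in latency clusters with Gaussian
  onset jitter, class-specific double-exponential kinetics, per-cluster
  occurrence probability, and band-limited Gaussian noise, plus a complete
  ground-truth table.
* Labeled feature tables for the E/I classifier, parameterized by per-class
  feature distributions (defaults follow the midline-stimulation medians).
* ROI fluorescence movies with stimulus-locked transients and a tunable
  pharmacological suppression factor.

Sign convention: cluster amplitudes are positive magnitudes; polarity is
applied at render time from the holding potential and the class reversal
(excitatory 0 mV, inhibitory -20 mV chloride), scaled by the driving-force
ratio relative to -60 mV.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal
from scipy.stats import truncnorm

from .events import SweepSet
from .model import biexp_unit_peak

__all__ = [
    "ClusterGenSpec",
    "SweepGenSpec",
    "CalciumGenSpec",
    "EXCITATORY_CLUSTER",
    "INHIBITORY_CLUSTER",
    "CLASS_FEATURE_PARAMS",
    "generate_sweep_set",
    "generate_feature_table",
    "generate_calcium_movie",
]

E_REVERSAL_MV = 0.0
I_REVERSAL_MV = -20.0   # chloride reversal with the high-Cl internal
REFERENCE_HOLDING_MV = -60.0


@dataclass(frozen=True)
class ClusterGenSpec:
    """One latency-defined PSC cluster to inject into sweeps."""

    label: str                    # excitatory | inhibitory
    mean_onset_latency: float     # ms after each stimulus
    onset_jitter_sd: float        # ms
    probability: float            # fraction of stimuli evoking an event
    amplitude_mean: float         # pA, positive magnitude
    amplitude_sd: float           # pA
    tau_rise: float               # ms
    tau_decay: float              # ms

    def __post_init__(self):
        if self.label not in ("excitatory", "inhibitory"):
            raise ValueError(f"label must be excitatory/inhibitory, got {self.label!r}")
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError("probability must be in [0, 1]")
        if self.tau_rise >= self.tau_decay:
            raise ValueError("tau_rise must be < tau_decay")
        if self.onset_jitter_sd < 0:
            raise ValueError("onset_jitter_sd must be >= 0")
        if self.amplitude_mean <= 0 or self.amplitude_sd < 0:
            raise ValueError("amplitude_mean must be > 0 and amplitude_sd >= 0")

    @property
    def reversal(self) -> float:
        return E_REVERSAL_MV if self.label == "excitatory" else I_REVERSAL_MV


# defaults follow the midline-stimulation cluster medians: E events are
# faster-rising/decaying, earlier, higher-probability and lower-jitter than I
EXCITATORY_CLUSTER = ClusterGenSpec(
    label="excitatory", mean_onset_latency=1.92, onset_jitter_sd=0.25,
    probability=0.80, amplitude_mean=66.95, amplitude_sd=15.0,
    tau_rise=0.29, tau_decay=2.23,
)
INHIBITORY_CLUSTER = ClusterGenSpec(
    label="inhibitory", mean_onset_latency=4.47, onset_jitter_sd=0.50,
    probability=0.45, amplitude_mean=55.39, amplitude_sd=12.0,
    tau_rise=0.39, tau_decay=3.51,
)


@dataclass(frozen=True)
class SweepGenSpec:
    """Parameters of one synthetic sweep set."""

    n_sweeps: int
    duration: float                       # ms
    stim_times: tuple = (10.0,)           # ms
    sampling_rate: float = 50.0           # kHz
    holding_potential: float = -60.0      # mV
    clusters: tuple = (EXCITATORY_CLUSTER, INHIBITORY_CLUSTER)
    noise_rms: float = 5.0                # pA
    noise_bandwidth: float = 10.0         # kHz
    seed: int = 0

    def __post_init__(self):
        if self.n_sweeps < 1:
            raise ValueError("n_sweeps must be >= 1")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if any(not 0 <= s < self.duration for s in self.stim_times):
            raise ValueError("stim_times must lie within [0, duration)")
        if self.sampling_rate <= 2.0 * self.noise_bandwidth:
            raise ValueError("sampling_rate must exceed 2 x noise_bandwidth")
        if self.noise_rms < 0:
            raise ValueError("noise_rms must be >= 0")

    @property
    def dt(self) -> float:
        return 1.0 / self.sampling_rate


def driving_force_factor(holding_mV: float, reversal_mV: float) -> float:
    """Rendered amplitude scale relative to the -60 mV reference.

    1 at -60 mV; 0 at the class reversal; negative (inverted polarity)
    beyond it (e.g. chloride events at 0 mV).
    """
    ref = REFERENCE_HOLDING_MV - reversal_mV
    return (holding_mV - reversal_mV) / ref


def _band_limited_noise(rng, shape, dt_ms, bandwidth_khz, rms):
    """Gaussian white noise low-pass filtered (4-pole Bessel) to a target RMS.

    The filter's variance gain is computed from its impulse response so the
    output RMS is statistically calibrated rather than renormalized per
    sweep.
    """
    white = rng.standard_normal(shape)
    if rms == 0:
        return np.zeros(shape)
    fs = 1.0 / dt_ms  # kHz
    b, a = signal.bessel(4, bandwidth_khz / (fs / 2.0), btype="low")
    impulse = np.zeros(4096)
    impulse[0] = 1.0
    h = signal.lfilter(b, a, impulse)
    gain = np.sqrt(np.sum(h**2))
    return signal.lfilter(b, a, white, axis=-1) * (rms / gain)


def generate_sweep_set(spec: SweepGenSpec) -> tuple[SweepSet, pd.DataFrame]:
    """Render a synthetic sweep set plus its ground-truth event table.

    Per sweep and stimulus, each cluster contributes an event with its
    occurrence probability (independent Bernoulli draws); events sum
    linearly (clamped-cell assumption) over band-limited Gaussian noise.
    """
    rng = np.random.default_rng(spec.seed)
    n_samples = int(round(spec.duration / spec.dt))
    t = np.arange(n_samples) * spec.dt
    traces = _band_limited_noise(
        rng, (spec.n_sweeps, n_samples), spec.dt, spec.noise_bandwidth, spec.noise_rms
    )

    truth_rows = []
    for si in range(spec.n_sweeps):
        for stim in spec.stim_times:
            for ci, cl in enumerate(spec.clusters):
                if rng.random() >= cl.probability:
                    continue
                onset = stim + rng.normal(cl.mean_onset_latency, cl.onset_jitter_sd)
                if cl.amplitude_sd > 0:
                    a = -cl.amplitude_mean / cl.amplitude_sd
                    amp = truncnorm.rvs(
                        a, np.inf, loc=cl.amplitude_mean, scale=cl.amplitude_sd,
                        random_state=rng,
                    )
                else:
                    amp = cl.amplitude_mean
                rendered = -amp * driving_force_factor(
                    spec.holding_potential, cl.reversal
                )
                traces[si] += rendered * biexp_unit_peak(
                    t - onset, cl.tau_rise, cl.tau_decay
                )
                truth_rows.append(
                    dict(sweep=si, cluster=ci, label=cl.label, stim_time=stim,
                         onset=onset, latency=onset - stim, amplitude=amp,
                         rendered_amplitude=rendered,
                         tau_rise=cl.tau_rise, tau_decay=cl.tau_decay)
                )

    truth = pd.DataFrame(
        truth_rows,
        columns=["sweep", "cluster", "label", "stim_time", "onset", "latency",
                 "amplitude", "rendered_amplitude", "tau_rise", "tau_decay"],
    )
    sweep_set = SweepSet(
        traces=traces,
        dt=spec.dt,
        holding_potential=spec.holding_potential,
        stim_times=np.asarray(spec.stim_times, dtype=float),
        metadata={"synthetic": True, "seed": spec.seed},
    )
    return sweep_set, truth


# ---------------------------------------------------------------------------
# labeled feature tables

#: per-class (mean, sd) of the classifier features; midline-stimulation
#: medians where printed, realistic spreads otherwise
CLASS_FEATURE_PARAMS = {
    "excitatory": {
        "rise_time": (0.63, 0.19), "decay_tau": (2.23, 0.52),
        "amplitude": (66.95, 15.0), "probability": (0.80, 0.19),
        "onset_jitter": (0.25, 0.13), "peak_jitter": (0.30, 0.15),
    },
    "inhibitory": {
        "rise_time": (0.86, 0.15), "decay_tau": (3.51, 0.93),
        "amplitude": (55.39, 12.0), "probability": (0.45, 0.15),
        "onset_jitter": (0.50, 0.17), "peak_jitter": (0.60, 0.20),
    },
}

AGE_CATEGORIES = (14, 15, 16, 17, 18, 19)   # postnatal days


def generate_feature_table(
    n_per_class: int,
    class_params: dict | None = None,
    seed: int = 0,
    ages=AGE_CATEGORIES,
) -> pd.DataFrame:
    """Labeled feature rows for classifier training/testing.

    Continuous features are truncated normals (positive support;
    probability additionally capped at 1); age is a uniform draw from
    ``ages`` and independent of class.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    params = class_params or CLASS_FEATURE_PARAMS
    rng = np.random.default_rng(seed)
    frames = []
    for label in sorted(params):
        cols = {}
        for feat, (mu, sd) in params[label].items():
            if sd > 0:
                a = (0.0 - mu) / sd
                vals = truncnorm.rvs(a, np.inf, loc=mu, scale=sd,
                                     size=n_per_class, random_state=rng)
            else:
                vals = np.full(n_per_class, mu)
            if feat == "probability":
                vals = np.clip(vals, 0.0, 1.0)
            cols[feat] = vals
        cols["age"] = rng.choice(ages, size=n_per_class)
        cols["label"] = label
        frames.append(pd.DataFrame(cols))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# calcium movies


@dataclass(frozen=True)
class CalciumGenSpec:
    """Parameters of a synthetic ROI fluorescence movie."""

    n_rois: int = 12
    frame_rate: float = 3.0               # Hz
    n_frames: int = 60                    # ~20 s
    baseline_frames: int = 15             # ~5 s pre-stimulus
    stim_bout_frames: tuple = (15, 30, 45)
    evoked_dff: float = 1.2               # peak F/F0 ratio in control
    suppression_factor: float = 0.0       # evoked fraction removed when blocked
    noise_sd: float = 0.3                 # fluorescence units on the ROI mean
                                          # (~0.3% of baseline: bright somatic
                                          # GCaMP ROIs averaged over ~50 px)
    baseline_f: float = 100.0             # baseline intensity
    decay_frames: float = 3.5             # transient decay (GCaMP6f-like, ~1.2 s)
    frame_shape: tuple = (48, 48)
    seed: int = 0

    def __post_init__(self):
        if self.n_rois < 1:
            raise ValueError("n_rois must be >= 1")
        if len(self.stim_bout_frames) != 3:
            raise ValueError("stim_bout_frames must give three bout onsets")
        if any(not 0 <= b < self.n_frames for b in self.stim_bout_frames):
            raise ValueError("stim_bout_frames must lie within the frame range")
        if self.baseline_frames > min(self.stim_bout_frames):
            raise ValueError("baseline_frames must precede the first bout onset")
        if not 0.0 <= self.suppression_factor <= 1.0:
            raise ValueError("suppression_factor must be in [0, 1]")
        if self.evoked_dff < 1.0:
            raise ValueError("evoked_dff is a peak F/F0 ratio and must be >= 1")


def _roi_polygons(spec: CalciumGenSpec) -> list[np.ndarray]:
    """Octagonal ROI outlines laid out on a grid."""
    h, w = spec.frame_shape
    cols = int(np.ceil(np.sqrt(spec.n_rois)))
    rows = int(np.ceil(spec.n_rois / cols))
    polys = []
    r = 0.35 * min(h / rows, w / cols)
    ang = np.arange(8) * (2 * np.pi / 8)
    for i in range(spec.n_rois):
        cy = (i // cols + 0.5) * h / rows
        cx = (i % cols + 0.5) * w / cols
        polys.append(np.column_stack([cx + r * np.cos(ang), cy + r * np.sin(ang)]))
    return polys


def rasterize_roi(polygon: np.ndarray, frame_shape: tuple) -> np.ndarray:
    """Boolean mask of pixels whose centers fall inside the polygon
    (even-odd rule)."""
    from matplotlib.path import Path

    h, w = frame_shape
    yy, xx = np.mgrid[0:h, 0:w]
    pts = np.column_stack([xx.ravel() + 0.5, yy.ravel() + 0.5])
    return Path(polygon).contains_points(pts).reshape(h, w)


def generate_calcium_movie(
    spec: CalciumGenSpec, condition: str = "control"
) -> tuple[np.ndarray, list[np.ndarray], pd.DataFrame]:
    """Render a movie (frames x H x W), ROI polygons, and ROI ground truth.

    Under ``blocked`` the evoked component above baseline is multiplied by
    (1 - suppression_factor).  Noise draws are identical across conditions
    for the same seed, so suppression_factor = 0 gives identical movies.
    """
    if condition not in ("control", "blocked"):
        raise ValueError(f"condition must be control/blocked, got {condition!r}")
    rng = np.random.default_rng(spec.seed)
    polys = _roi_polygons(spec)
    masks = [rasterize_roi(p, spec.frame_shape) for p in polys]
    npix = np.array([m.sum() for m in masks])

    # stimulus-locked transient kernel, unit peak at the frame after onset
    frames = np.arange(spec.n_frames, dtype=float)
    kernel = np.zeros(spec.n_frames)
    for b in spec.stim_bout_frames:
        s = frames - b
        resp = np.where(s >= 0, np.exp(-np.maximum(s - 1, 0) / spec.decay_frames)
                        * np.minimum(s, 1.0), 0.0)
        kernel = np.maximum(kernel, resp)

    scale = (spec.evoked_dff - 1.0) * (
        1.0 - (spec.suppression_factor if condition == "blocked" else 0.0)
    )
    trace = spec.baseline_f * (1.0 + scale * kernel)   # per-frame ROI mean, no noise

    movie = np.zeros((spec.n_frames,) + spec.frame_shape)
    movie += spec.baseline_f * 0.2   # dim neuropil background
    truth_rows = []
    for i, mask in enumerate(masks):
        # pixel noise sized so the ROI-mean noise has sd ~ noise_sd
        pix_sd = spec.noise_sd * np.sqrt(npix[i])
        noise = rng.standard_normal((spec.n_frames, int(npix[i]))) * pix_sd
        roi_pixels = trace[:, None] + noise
        movie[:, mask] = roi_pixels
        truth_rows.append(
            dict(roi_id=i, baseline_f=spec.baseline_f,
                 true_dff=1.0 + scale, n_pixels=int(npix[i]))
        )
    return movie, polys, pd.DataFrame(truth_rows)
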