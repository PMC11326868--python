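"""Derived measurements on simulated voltage traces: PSP and AP metrics."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fitting import fit_decay_tau
from .model import SimResult

__all__ = ["PSPMetrics", "APMetrics", "measure_psp", "detect_aps"]


@dataclass(frozen=True)
class PSPMetrics:
    amplitude_mV: float      # extremum of V - baseline after onset (signed)
    decay_tau_ms: float | None
    peak_time_ms: float
    baseline_mV: float


@dataclass(frozen=True)
class APMetrics:
    ap_times_ms: np.ndarray
    first_latency_ms: float | None   # from the reference onset
    rate_hz: float                   # (N-1)/span of spike times, N >= 2
    rate_per_window_hz: float        # N / analysis window

    @property
    def n_aps(self) -> int:
        return int(self.ap_times_ms.size)


class SuprathresholdError(RuntimeError):
    """Raised when a PSP measurement window contains an action potential."""


def measure_psp(
    result: SimResult,
    onset: float,
    window: float | None = None,
    ap_threshold_mV: float = -10.0,
) -> PSPMetrics:
    """Amplitude and decay tau of a (sub-threshold) PSP.

    Amplitude is the signed extremum of (V - baseline) after ``onset``;
    the decay tau is a single-exponential fit from the 90%-of-peak point on
    the relaxation.  Raises :class:`SuprathresholdError` if the window
    contains an AP (use :func:`detect_aps` instead).
    """
    t, v, dt = result.t, result.v_soma, result.dt
    i0 = int(np.searchsorted(t, onset))
    if i0 <= 0 or i0 >= t.size:
        raise ValueError("onset outside the simulated trace")
    i1 = t.size if window is None else min(t.size, int(np.searchsorted(t, onset + window)))
    baseline = float(np.mean(v[max(0, i0 - int(2.0 / dt)):i0]))
    seg = v[i0:i1] - baseline
    if np.max(v[i0:i1]) >= ap_threshold_mV:
        raise SuprathresholdError(
            "AP detected in the PSP window; use detect_aps for spiking traces"
        )
    ipk = int(np.argmax(np.abs(seg)))
    amp = float(seg[ipk])
    peak_time = float(t[i0 + ipk])

    tau = None
    if amp != 0.0:
        # fit from the point where the relaxation falls to 90% of peak
        post = seg[ipk:]
        rel = post / amp  # 1 at peak, decaying toward 0
        below = np.nonzero(rel <= 0.9)[0]
        start = below[0] if below.size else 0
        tau = fit_decay_tau(post[start:] * np.sign(amp), dt)
    return PSPMetrics(
        amplitude_mV=amp, decay_tau_ms=tau, peak_time_ms=peak_time, baseline_mV=baseline
    )


def detect_aps(
    result: SimResult,
    threshold_mV: float = -10.0,
    refractory_ms: float = 1.0,
    reference_onset_ms: float = 0.0,
    window_ms: float | None = None,
) -> APMetrics:
    """Action potentials as upward threshold crossings with a refractory gap.

    The first-AP latency is measured from ``reference_onset_ms`` (by
    convention, the onset of the first synaptic event).  Two rates are
    reported because the printed values do not disclose a formula: the
    primary (N-1)/(span of spike times) and N/(analysis window).
    """
    t, v = result.t, result.v_soma
    above = v >= threshold_mV
    crossings = np.nonzero(above[1:] & ~above[:-1])[0] + 1
    times = []
    last = -np.inf
    for i in crossings:
        # linear interpolation of the crossing time
        frac = (threshold_mV - v[i - 1]) / (v[i] - v[i - 1])
        tc = t[i - 1] + frac * (t[i] - t[i - 1])
        if tc - last >= refractory_ms:
            times.append(tc)
            last = tc
    times = np.array(times)
    window = window_ms if window_ms is not None else float(t[-1] - reference_onset_ms)
    n = times.size
    if n >= 2:
        rate = 1000.0 * (n - 1) / (times[-1] - times[0])
    else:
        rate = 0.0
    rate_window = 1000.0 * n / window if window > 0 else 0.0
    latency = float(times[0] - reference_onset_ms) if n else None
    return APMetrics(
        ap_times_ms=times,
        first_latency_ms=latency,
        rate_hz=float(rate),
        rate_per_window_hz=float(rate_window),
    )
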