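"""Shared curve-fitting helpers: single-exponential decay fits."""

from __future__ import annotations

import numpy as np
from scipy.optimize import curve_fit

__all__ = ["fit_decay_tau", "fit_exponential"]


def _exp_model(t, a, tau, c):
    return a * np.exp(-t / tau) + c


def fit_exponential(segment, dt):
    """Least-squares fit of A*exp(-t/tau) + C to a decaying segment.

    Returns (A, tau_ms, C) or None on failure (non-convergence, degenerate
    input, or a non-positive fitted tau).
    """
    y = np.asarray(segment, dtype=float)
    if y.size < 3 or not np.all(np.isfinite(y)) or dt <= 0:
        return None
    if np.ptp(y) == 0.0:
        return None
    t = np.arange(y.size) * dt
    c0 = y[-1]
    a0 = y[0] - c0
    if a0 == 0.0:
        a0 = np.ptp(y) or 1.0
    # crude tau guess: time to fall to 1/e of the initial deviation
    dev = np.abs(y - c0)
    below = np.nonzero(dev <= abs(a0) / np.e)[0]
    tau0 = t[below[0]] if below.size and below[0] > 0 else t[-1] / 3.0
    tau0 = max(tau0, dt)
    import warnings

    try:
        with np.errstate(over="ignore", invalid="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                _exp_model,
                t,
                y,
                p0=(a0, tau0, c0),
                maxfev=5000,
            )
    except (RuntimeError, ValueError):
        return None
    a, tau, c = popt
    if not np.isfinite(tau) or tau <= 0:
        return None
    # a tau far beyond the observed window is an unconstrained fit, not a decay
    if tau > 10.0 * t[-1]:
        return None
    return float(a), float(tau), float(c)


def fit_decay_tau(segment, dt):
    """Single-exponential decay time constant (ms) of a post-peak segment.

    Returns the fitted tau, or None when the fit fails (flagged upstream).
    """
    fit = fit_exponential(segment, dt)
    return None if fit is None else fit[1]
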