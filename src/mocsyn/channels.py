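"""Voltage-gated channel kinetics for the MOC neuron model.

The model uses the ventral-cochlear-nucleus channel family conventionally
paired with the mechanism names it was built from: a high-threshold
delayed-rectifier K+ (kht), a low-threshold dendrotoxin-sensitive K+ (klt),
a fast transient Na+ conductance, and an HCN (Ih) current.  Rate functions
follow the Rothman & Manis (2003) parameterization at 22 C; a Q10 of 3 on
rates scales them to the working temperature (35 C by default).

Every scheme exposes:
  gates()            -> names of its state variables
  inf_tau(V, phi)    -> dict gate -> (x_inf, tau_x_ms) arrays
  open_fraction(**x) -> product of gate variables entering the conductance
"""

from __future__ import annotations

import numpy as np

__all__ = ["CHANNEL_SCHEMES", "rate_scale", "KHT", "KLT", "NaFast", "HCN"]


def rate_scale(temperature_c: float, q10: float = 3.0, base_c: float = 22.0) -> float:
    """Multiplicative speed-up of gating rates at ``temperature_c``."""
    return q10 ** ((temperature_c - base_c) / 10.0)


def _exp(x):
    # clipped exp to keep extreme voltages finite
    return np.exp(np.clip(x, -50.0, 50.0))


class KHT:
    """High-threshold K+ (delayed rectifier): i = g (0.85 n^2 + 0.15 p) (V - EK)."""

    name = "kht"

    @staticmethod
    def gates():
        return ("n", "p")

    @staticmethod
    def inf_tau(v, phi=1.0):
        n_inf = (1.0 + _exp(-(v + 15.0) / 5.0)) ** -0.5
        tau_n = 100.0 / (11.0 * _exp((v + 60.0) / 24.0)
                         + 21.0 * _exp(-(v + 60.0) / 23.0)) + 0.7
        p_inf = 1.0 / (1.0 + _exp(-(v + 23.0) / 6.0))
        tau_p = 100.0 / (4.0 * _exp((v + 60.0) / 32.0)
                         + 5.0 * _exp(-(v + 60.0) / 22.0)) + 5.0
        return {"n": (n_inf, tau_n / phi), "p": (p_inf, tau_p / phi)}

    @staticmethod
    def open_fraction(n, p):
        return 0.85 * n**2 + 0.15 * p


class KLT:
    """Low-threshold K+ : i = g w^4 z (V - EK).

    ``rate_per_ms`` scales the activation-gate (w) rate; it is the model's
    named low-threshold auxiliary rate parameter (default 0.6 /ms), applied
    as tau_w -> tau_w / (rate_per_ms * 1 ms).
    """

    name = "klt"

    def __init__(self, rate_per_ms: float = 0.6, zeta: float = 0.5):
        self.rate_per_ms = float(rate_per_ms)
        self.zeta = float(zeta)

    @staticmethod
    def gates():
        return ("w", "z")

    def inf_tau(self, v, phi=1.0):
        w_inf = (1.0 + _exp(-(v + 48.0) / 6.0)) ** -0.25
        tau_w = 100.0 / (6.0 * _exp((v + 60.0) / 6.0)
                         + 16.0 * _exp(-(v + 60.0) / 45.0)) + 1.5
        tau_w = tau_w / max(self.rate_per_ms, 1e-9)
        z_inf = self.zeta + (1.0 - self.zeta) / (1.0 + _exp((v + 71.0) / 10.0))
        tau_z = 1000.0 / (_exp((v + 60.0) / 20.0)
                          + _exp(-(v + 60.0) / 8.0)) + 50.0
        return {"w": (w_inf, tau_w / phi), "z": (z_inf, tau_z / phi)}

    @staticmethod
    def open_fraction(w, z):
        return w**4 * z


class NaFast:
    """Fast transient Na+ : i = g m^3 h (V - ENa)."""

    name = "na"

    @staticmethod
    def gates():
        return ("m", "h")

    @staticmethod
    def inf_tau(v, phi=1.0):
        m_inf = 1.0 / (1.0 + _exp(-(v + 38.0) / 7.0))
        tau_m = 10.0 / (5.0 * _exp((v + 60.0) / 18.0)
                        + 36.0 * _exp(-(v + 60.0) / 25.0)) + 0.04
        h_inf = 1.0 / (1.0 + _exp((v + 65.0) / 6.0))
        tau_h = 100.0 / (7.0 * _exp((v + 60.0) / 11.0)
                         + 10.0 * _exp(-(v + 60.0) / 25.0)) + 0.6
        return {"m": (m_inf, tau_m / phi), "h": (h_inf, tau_h / phi)}

    @staticmethod
    def open_fraction(m, h):
        return m**3 * h


class HCN:
    """Hyperpolarization-activated cation current: i = g r (V - Eh)."""

    name = "hcn"

    @staticmethod
    def gates():
        return ("r",)

    @staticmethod
    def inf_tau(v, phi=1.0):
        r_inf = 1.0 / (1.0 + _exp((v + 76.0) / 7.0))
        tau_r = 1.0e5 / (237.0 * _exp((v + 60.0) / 12.0)
                         + 17.0 * _exp(-(v + 60.0) / 14.0)) + 25.0
        return {"r": (r_inf, tau_r / phi)}

    @staticmethod
    def open_fraction(r):
        return r


CHANNEL_SCHEMES = {"kht": KHT, "klt": KLT, "na": NaFast, "hcn": HCN}
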