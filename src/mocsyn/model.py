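"""Compartmental conductance-based MOC neuron model.

The cable equation is discretized over the segments of a
:class:`~mocsyn.morphology.Morphology` and integrated implicitly
(backward Euler by default, Crank-Nicolson optionally), with channel gates
advanced by exact exponential integration between voltage solves.  Synapses
are double-exponential conductances normalized so that the peak conductance
equals the synaptic weight (the Exp2Syn convention).

Units: mV, ms, uS, nA, nF; channel densities in S/cm2; lengths in um.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .channels import CHANNEL_SCHEMES, KLT, rate_scale
from .morphology import Morphology

__all__ = [
    "PassiveProps",
    "ChannelSet",
    "SynapseSpec",
    "SimResult",
    "MocModel",
    "build_model",
    "biexp_peak_time",
    "biexp_unit_peak",
]


@dataclass(frozen=True)
class PassiveProps:
    """Passive membrane and cytoplasm properties."""

    axial_resistivity: float = 210.0       # Ohm cm
    membrane_capacitance: float = 1.0      # uF/cm2
    temperature: float = 35.0              # C

    def __post_init__(self):
        for name in ("axial_resistivity", "membrane_capacitance", "temperature"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


#: compartment groups a density may address; "all" expands to every group
GROUPS = ("soma", "dend", "axon")


@dataclass
class ChannelSet:
    """Channel densities (S/cm2) per compartment group, plus reversals.

    ``densities`` maps channel name ("kht", "klt", "na", "hcn", "leak") to
    a dict of group -> density; the key "all" sets every group and is
    overridden by explicit group entries, mirroring the published table's
    "All" rows with axon overrides.
    """

    densities: dict = field(default_factory=dict)
    e_k: float = -90.0
    e_na: float = 55.0
    e_h: float = -38.0
    e_leak: float = -65.0
    klt_rate_per_ms: float = 0.6
    #: Q10 applied to gating rates between rate_base_c and the working
    #: temperature; 1.0 uses the scheme's published rates unscaled.  The
    #: source mechanisms name no temperature compensation, so this is a
    #: calibrated model choice (see docs/methods.md).
    gate_q10: float = 1.0
    rate_base_c: float = 22.0

    def density(self, channel: str, group: str) -> float:
        spec = self.densities.get(channel, {})
        val = spec.get(group, spec.get("all", 0.0))
        if val < 0:
            raise ValueError(f"negative density for {channel}/{group}")
        return float(val)

    def with_scaled(self, channel: str, factor: float) -> "ChannelSet":
        """A copy with every density of ``channel`` multiplied by ``factor``."""
        dens = {c: dict(g) for c, g in self.densities.items()}
        dens[channel] = {k: v * factor for k, v in dens.get(channel, {}).items()}
        return replace(self, densities=dens)


@dataclass
class SynapseSpec:
    """A double-exponential conductance event.

    ``weight`` is the peak conductance in uS; the biexponential
    g(t) = weight * N * (exp(-t/tau_decay) - exp(-t/tau_rise)) is normalized
    (N) so its peak equals ``weight``.
    """

    tau_rise: float
    tau_decay: float
    weight: float
    reversal: float
    onset: float = 0.0
    section: str = "soma"

    def __post_init__(self):
        if self.weight < 0:
            raise ValueError("synaptic weight must be >= 0")
        if self.tau_rise <= 0 or self.tau_decay <= 0:
            raise ValueError("synaptic time constants must be > 0")
        if self.tau_rise >= self.tau_decay:
            # the biexponential is symmetric under exchange (up to sign)
            warnings.warn(
                "tau_rise >= tau_decay; swapping to keep the waveform shape valid",
                stacklevel=2,
            )
            self.tau_rise, self.tau_decay = self.tau_decay, self.tau_rise


def biexp_peak_time(tau_rise: float, tau_decay: float) -> float:
    """Analytic time-to-peak of the double exponential."""
    return (tau_decay * tau_rise / (tau_decay - tau_rise)) * math.log(tau_decay / tau_rise)


def biexp_unit_peak(t: np.ndarray, tau_rise: float, tau_decay: float) -> np.ndarray:
    """Double-exponential waveform normalized to unit peak; zero for t < 0."""
    tp = biexp_peak_time(tau_rise, tau_decay)
    norm = math.exp(-tp / tau_decay) - math.exp(-tp / tau_rise)
    out = np.zeros_like(np.asarray(t, dtype=float))
    m = t >= 0
    out[m] = (np.exp(-t[m] / tau_decay) - np.exp(-t[m] / tau_rise)) / norm
    return out


@dataclass
class SimResult:
    """Somatic voltage trace plus optional extras from one simulation."""

    t: np.ndarray                 # ms
    v_soma: np.ndarray            # mV
    syn_g: dict | None = None     # synapse index -> conductance trace (uS)
    v_all: np.ndarray | None = None
    dt: float = 0.025

    def __post_init__(self):
        if not np.all(np.isfinite(self.v_soma)):
            bad = int(np.argmax(~np.isfinite(self.v_soma)))
            raise FloatingPointError(
                f"non-finite somatic voltage first at t = {self.t[bad]:.3f} ms"
            )


class MocModel:
    """Discretized cable with per-segment conductances."""

    def __init__(self, morph: Morphology, passive: PassiveProps, channels: ChannelSet):
        self.morph = morph
        self.passive = passive
        self.channels = channels
        self._phi = rate_scale(
            passive.temperature, q10=channels.gate_q10, base_c=channels.rate_base_c
        )
        self._build_segments()
        self._holding: dict | None = None

    # -- assembly -----------------------------------------------------------

    def _build_segments(self) -> None:
        morph, passive = self.morph, self.passive
        seg_parent: list[int] = []
        seg_area: list[float] = []        # cm2
        seg_half_r: list[float] = []      # Ohm, axial half-resistance
        seg_group: list[str] = []
        self.section_segs: dict[str, list[int]] = {}
        ra_ohm_um = passive.axial_resistivity * 1.0e4

        order = self._topo_order()
        for sec in order:
            idxs = []
            lseg = sec.length_um / sec.nseg
            cross = math.pi * (sec.diam_um / 2.0) ** 2
            half_r = ra_ohm_um * (lseg / 2.0) / cross
            for j in range(sec.nseg):
                i = len(seg_parent)
                if j == 0:
                    parent = (
                        -1 if sec.parent is None
                        else self.section_segs[sec.parent][-1]
                    )
                else:
                    parent = i - 1
                seg_parent.append(parent)
                seg_area.append(math.pi * sec.diam_um * lseg * 1.0e-8)
                seg_half_r.append(half_r)
                if sec.swc_type == 1:
                    seg_group.append("soma")
                elif sec.swc_type == 2:
                    seg_group.append("axon")
                else:
                    seg_group.append("dend")
                idxs.append(i)
            self.section_segs[sec.name] = idxs

        n = len(seg_parent)
        self.n_seg = n
        self.seg_parent = np.array(seg_parent)
        self.area_cm2 = np.array(seg_area)
        self.seg_group = np.array(seg_group)
        self.c_nF = passive.membrane_capacitance * self.area_cm2 * 1.0e3
        self.soma_index = self.section_segs[morph.root.name][0]

        # axial conductance matrix (uS), symmetric tree Laplacian
        G = np.zeros((n, n))
        for i, p in enumerate(self.seg_parent):
            if p < 0:
                continue
            g = 1.0e6 / (seg_half_r[i] + seg_half_r[p])
            G[i, i] += g
            G[p, p] += g
            G[i, p] -= g
            G[p, i] -= g
        self.g_axial = G

        # per-segment channel conductances (uS)
        self._klt = KLT(rate_per_ms=self.channels.klt_rate_per_ms)
        self._schemes = {
            "kht": CHANNEL_SCHEMES["kht"](),
            "klt": self._klt,
            "na": CHANNEL_SCHEMES["na"](),
            "hcn": CHANNEL_SCHEMES["hcn"](),
        }
        self.gbar = {}
        for name in self._schemes:
            dens = np.array(
                [self.channels.density(name, g) for g in self.seg_group]
            )
            self.gbar[name] = dens * self.area_cm2 * 1.0e6
        leak = np.array(
            [self.channels.density("leak", g) for g in self.seg_group]
        )
        self.g_leak = leak * self.area_cm2 * 1.0e6
        self.e_rev = {
            "kht": self.channels.e_k,
            "klt": self.channels.e_k,
            "na": self.channels.e_na,
            "hcn": self.channels.e_h,
        }

    def _topo_order(self):
        by_name = {s.name: s for s in self.morph.sections}
        order, seen = [], set()

        def visit(sec):
            if sec.name in seen:
                return
            if sec.parent is not None and sec.parent not in seen:
                visit(by_name[sec.parent])
            seen.add(sec.name)
            order.append(sec)

        for sec in self.morph.sections:
            visit(sec)
        return order

    @property
    def total_area_um2(self) -> float:
        return float(np.sum(self.area_cm2)) * 1.0e8

    # -- gating -------------------------------------------------------------

    def _gates_steady(self, v: np.ndarray) -> dict:
        gates = {}
        for name, scheme in self._schemes.items():
            it = scheme.inf_tau(v, self._phi)
            for gname, (x_inf, _) in it.items():
                gates[(name, gname)] = np.array(x_inf, dtype=float)
        return gates

    def _advance_gates(self, gates: dict, v: np.ndarray, dt: float) -> None:
        for name, scheme in self._schemes.items():
            it = scheme.inf_tau(v, self._phi)
            for gname, (x_inf, tau) in it.items():
                x = gates[(name, gname)]
                x += (x_inf - x) * (1.0 - np.exp(-dt / tau))

    def _membrane_g_b(self, gates: dict):
        """Per-segment dynamic conductance (uS) and conductance*reversal sums."""
        g = self.g_leak.copy()
        b = self.g_leak * self.channels.e_leak
        for name, scheme in self._schemes.items():
            xs = [gates[(name, gn)] for gn in scheme.gates()]
            gc = self.gbar[name] * scheme.open_fraction(*xs)
            g += gc
            b += gc * self.e_rev[name]
        return g, b

    # -- simulation ---------------------------------------------------------

    def _syn_traces(self, synapses, t):
        """Per-synapse conductance traces (uS) on the simulation time grid."""
        out = []
        for syn in synapses:
            s = t - syn.onset
            out.append(syn.weight * biexp_unit_peak(s, syn.tau_rise, syn.tau_decay))
        return out

    def simulate(
        self,
        synapses=(),
        duration: float = 200.0,
        dt: float = 0.025,
        bias_nA: float | None = None,
        v_init=None,
        gates_init: dict | None = None,
        clamp_soma_mV: float | None = None,
        method: str = "be",
        record_all: bool = False,
        record_syn_g: bool = False,
    ) -> SimResult:
        """Integrate the cable equation; deterministic.

        When ``clamp_soma_mV`` is given, the somatic voltage is held fixed and
        the clamp current is recorded in the returned result's ``syn_g`` slot
        under the key "clamp_nA".
        """
        if dt <= 0:
            raise ValueError("dt must be > 0")
        theta = {"be": 1.0, "cn": 0.5}[method]
        n = self.n_seg
        nt = int(round(duration / dt)) + 1
        t = np.arange(nt) * dt

        if v_init is None:
            v = np.full(n, -60.0)
        else:
            v = np.array(v_init, dtype=float) * np.ones(n)
        gates = (
            {k: g.copy() for k, g in gates_init.items()}
            if gates_init is not None
            else self._gates_steady(v)
        )
        bias = np.zeros(n)
        if bias_nA is not None:
            bias[self.soma_index] = bias_nA

        syn_tr = self._syn_traces(synapses, t)
        syn_seg = [self.section_segs[s.section][len(self.section_segs[s.section]) // 2]
                   for s in synapses]
        # pre-sum synaptic conductances by target segment for the step loop
        seg_ids = sorted(set(syn_seg))
        g_syn_t = np.zeros((nt, len(seg_ids)))
        gb_syn_t = np.zeros_like(g_syn_t)
        for j, syn in enumerate(synapses):
            col = seg_ids.index(syn_seg[j])
            g_syn_t[:, col] += syn_tr[j]
            gb_syn_t[:, col] += syn_tr[j] * syn.reversal
        seg_ids = np.asarray(seg_ids, dtype=int)

        c_dt = self.c_nF / dt
        v_soma = np.empty(nt)
        v_soma[0] = v[self.soma_index]
        v_rec = np.empty((nt, n)) if record_all else None
        if record_all:
            v_rec[0] = v
        clamp_i = np.zeros(nt) if clamp_soma_mV is not None else None
        si = self.soma_index
        eye_cdt = np.diag_indices(n)

        for k in range(1, nt):
            self._advance_gates(gates, v, dt)
            g_dyn, b = self._membrane_g_b(gates)
            if seg_ids.size:
                g_dyn[seg_ids] += g_syn_t[k]
                b[seg_ids] += gb_syn_t[k]
            rhs_cur = b + bias
            A = theta * self.g_axial.copy()
            A[eye_cdt] += c_dt + theta * g_dyn
            rhs = c_dt * v + rhs_cur - (1.0 - theta) * (self.g_axial @ v + g_dyn * v)
            if clamp_soma_mV is not None:
                A[si, :] = 0.0
                A[si, si] = 1.0
                rhs[si] = clamp_soma_mV
            v_new = np.linalg.solve(A, rhs)
            if clamp_soma_mV is not None:
                # current the clamp must inject to hold the soma
                clamp_i[k] = (
                    self.g_axial[si] @ v_new + g_dyn[si] * v_new[si] - rhs_cur[si]
                )
            v = v_new
            v_soma[k] = v[si]
            if record_all:
                v_rec[k] = v

        extras = {}
        if record_syn_g:
            extras = {j: syn_tr[j] for j in range(len(synapses))}
        if clamp_i is not None:
            extras["clamp_nA"] = clamp_i
        res = SimResult(t=t, v_soma=v_soma, syn_g=extras or None, v_all=v_rec, dt=dt)
        res._final_state = (v.copy(), {k_: g.copy() for k_, g in gates.items()})
        return res

    # -- holding ------------------------------------------------------------

    def set_holding(
        self,
        target_mV: float = -60.0,
        settle_ms: float = 4000.0,
        dt: float = 1.0,
        tol_mV: float = 0.1,
        max_iter: int = 40,
    ) -> float:
        """Find and store the constant somatic bias current holding the soma
        at ``target_mV``; returns the bias in nA.

        A somatic voltage clamp is settled to steady state (the slowest
        gates relax over hundreds of ms, hence the long window), the steady
        clamp current becomes the bias, and the fixed point is verified
        (and, if needed, refined by secant iteration) in free-running mode.
        The system state carries forward across iterations so residual gate
        relaxation completes during the refinement.
        """
        res = self.simulate(
            duration=settle_ms, dt=dt, clamp_soma_mV=target_mV
        )
        bias = float(res.syn_g["clamp_nA"][-1])
        v_state, gates_state = res._final_state

        prev = None
        v_end = target_mV
        for _ in range(max_iter):
            free = self.simulate(
                duration=300.0, dt=dt, bias_nA=bias,
                v_init=v_state, gates_init=gates_state,
            )
            v_state, gates_state = free._final_state
            v_end = float(free.v_soma[-1])
            drift = float(free.v_soma[-1] - free.v_soma[free.v_soma.size // 2])
            err = v_end - target_mV
            if abs(err) <= tol_mV and abs(drift) <= tol_mV / 2:
                self._holding = {
                    "bias_nA": bias,
                    "target_mV": target_mV,
                    "v": v_state,
                    "gates": gates_state,
                }
                return bias
            # secant step on bias vs achieved voltage
            if prev is None:
                d_bias = -err * 0.01  # ~100 MOhm guess
            else:
                b0, e0 = prev
                denom = err - e0
                d_bias = -err * (bias - b0) / denom if abs(denom) > 1e-12 else -err * 0.01
            prev = (bias, err)
            bias += np.clip(d_bias, -0.5, 0.5)
        raise RuntimeError(
            f"holding current did not converge in {max_iter} iterations; "
            f"achieved {v_end:.3f} mV for target {target_mV} mV"
        )

    @property
    def holding(self) -> dict:
        if self._holding is None:
            raise RuntimeError("call set_holding() first")
        return self._holding

    def run_protocol(
        self,
        synapses=(),
        duration: float = 200.0,
        dt: float = 0.025,
        method: str = "be",
        **kw,
    ) -> SimResult:
        """Simulate from the stored holding state with the holding bias."""
        h = self.holding
        return self.simulate(
            synapses=synapses,
            duration=duration,
            dt=dt,
            bias_nA=h["bias_nA"],
            v_init=h["v"],
            gates_init=h["gates"],
            method=method,
            **kw,
        )


def build_model(
    morphology: Morphology,
    passive: PassiveProps | None = None,
    channels: ChannelSet | None = None,
) -> MocModel:
    """Assemble the discretized model and sanity-check its membrane area."""
    passive = passive or PassiveProps()
    channels = channels or ChannelSet()
    model = MocModel(morphology, passive, channels)
    analytic = morphology.total_area_um2
    if abs(model.total_area_um2 - analytic) > 1.0e-3 * analytic:
        raise AssertionError("discretized membrane area deviates from analytic sum")
    return model
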