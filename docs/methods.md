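# Methods

`mocsyn` models excitatory–inhibitory (E–I) synaptic integration in medial
olivocochlear (MOC) neurons and re-implements the analysis pipelines that
surround such experiments: postsynaptic-current (PSC) event detection and
kinetic feature extraction, latency clustering with gap-statistic model
selection, tree-ensemble E/I classification, and ΔF/F calcium-imaging
quantification. Synthetic generators stand in for recordings throughout.

## The compartmental MOC neuron model

### Morphology

The canonical cell is a tree of cylindrical sections: soma (33.6 × 6.1 µm),
axon (180 × 1 µm), and three primary dendrites (lateral 12.8, dorsal 10.1,
medial 7.3 µm; 1 µm diameter) that branch into 74 daughter dendrites
(lateral 46, dorsal 20, medial 8), with lengths spread linearly over
1.5–31.4 µm and diameters over 1–2 µm. Discretization is fixed at exactly
86 segments (soma 1, axon 8, one per dendritic section). The daughter
counts and dimension spreads are an approximation: the source reconstruction
is not recoverable, only the stated ranges, and the 86-segment budget caps
the number of daughter sections. Total membrane area is 7,670 µm²
(≈77 pF at 1 µF/cm²), which turns out to be the single most consequential
number in the model (see "Known inconsistencies" below).

### Passive properties and channels

Axial resistivity 210 Ω·cm, specific capacitance 1 µF/cm², nominal
temperature 35 °C. Four voltage-gated conductances use the ventral-cochlear-
nucleus schemes conventionally associated with the mechanism names the model
was built from: high-threshold K⁺ (kht: 0.85 n² + 0.15 p), low-threshold
K⁺ (klt: w⁴z), fast transient Na⁺ (m³h), and HCN (r), with E_K = −90 mV,
E_Na = +55 mV, E_HCN = −38 mV, plus a passive leak (reversal −65 mV). The
low-threshold activation rate carries the named auxiliary parameter
(0.6 ms⁻¹), applied as a scale on the w gate's rate.

Gating rates run at their published 22 °C parameterization by default
(`gate_q10 = 1`). This is a deliberate, configurable choice: with a Q10 of
3 applied up to 35 °C, every recovery process (kht n/p, klt w, Na h) relaxes
in ≤4 ms and nothing in the model can space action potentials at the
~30 ms intervals the train protocols produce; the source mechanisms' names
carry no rate equations or temperature compensation, so the slower variant
that can express the published dynamics was adopted.

### Numerics

The cable equation is integrated implicitly — backward Euler by default,
Crank–Nicolson as an option — at dt = 0.025 ms, with gates advanced by exact
exponential integration against the voltage of the previous step. The
86-compartment system is solved densely per step. Convergence is enforced by
tests: halving dt or doubling the axon's segment count changes an evoked-PSP
amplitude by <1%, and the default step agrees with a dt/16 reference within
0.5% of peak amplitude.

Synapses are double-exponential conductances normalized so that peak
conductance equals the weight (the Exp2Syn convention); the analytic peak
time t_p = τ_d τ_r/(τ_d−τ_r) · ln(τ_d/τ_r) anchors a 10⁻⁶-level
normalization test. If a configuration supplies τ_rise ≥ τ_decay the two
are swapped with a warning (the waveform is symmetric under exchange up to
sign).

Holding at −60 mV is found by settling a somatic voltage clamp to steady
state (4 s at dt = 1 ms — the klt inactivation gate and HCN relax over
hundreds of ms), taking the steady clamp current as the bias, and verifying
the free-running fixed point (drift <0.1 mV), with secant refinement if
needed.

### Calibration

Channel densities are deliberately treated as free parameters: the printed
density table carries corrupted units (cS/cm², kS/cm², nS/cm²; archived
verbatim in `data/table_printed.yaml`), so the working densities are fixed
by calibration against the published model outputs and shipped in
`data/calibrated.yaml` (regenerated by `analysis/04_calibrate_model.py`).
Three stages, each a derivative-free (Nelder–Mead, grid-seeded) minimax over
relative errors:

1. **Subthreshold** (klt, HCN, leak): targets the evoked-PSP decay time
   constants (16.4 / 14.8 / 14.8 ms). Decay, not amplitude, is prioritized
   because temporal summation — and with it every train/AP result and the
   monotone-suppression property — follows from it.
2. **Spiking** (Na⁺, kht, klt; axon densities at 10× somatodendritic):
   targets the EPSP-only train rate (31.5 Hz) and first-AP latency
   (24.4 ms) and the control-train latency (38.5 ms), under the hard
   constraint that single evoked PSPs stay subthreshold.
3. **Minis** (per-class weight and τ_decay, rise times fixed at the evoked
   values): targets the mini-PSP amplitudes and decays. This stage converges
   essentially exactly (0.901 mV / 8.21 ms and −1.56 mV / 14.4 ms).

Two target presets exist: the published model outputs (default, used by the
acceptance pipeline) and the recorded-cell group means.

### Known inconsistencies (why some outputs cannot be matched)

The published model-output set is internally inconsistent under the stated
morphology and synaptic weights, and the calibration therefore cannot (and
does not pretend to) satisfy all of it:

* With ~77 pF of membrane and a 1.5 nS peak EPSP conductance, an EPSP
  *amplitude* of 1.91 mV requires ~37 nS of rest conductance — but that
  makes the PSP decay in ~5 ms (vs the printed 16.4 ms) and leaves ~14%
  temporal summation, under which no Na⁺ density allows 100 Hz trains to
  fire while single PSPs stay subthreshold.
* Conversely the printed decay constants (and hence any train behavior)
  require ~5 nS rest conductance, under which the same synapse produces a
  4–8 mV EPSP — the paper's own "resulting amplitude, 8.506 mV" — rather
  than its 1.91 mV "output" value. The relation between those two printed
  amplitudes is not stated in the source and is treated here as unresolved.
* The Na⁺ scheme amplifies slow depolarizations into graded humps, which
  compresses the window between "trains fire" and "single PSPs fire"; the
  shipped configuration sits in the widest stable pocket found (EPSP-only
  train: 5 APs at 22.8 Hz, first AP 15.9 ms; control train suppressed to a
  single delayed AP). Inhibition at every E–I latency delays the first AP
  and never raises the rate, and the 0.51× IPSP-depression condition
  restores sustained firing (19–22 Hz) — the direction and ordering of all
  published train effects — but the absolute rates/latencies sit ~30% from
  the printed numbers and are reported as such.

## E–I protocols

E–I latency `delta` is IPSP onset minus EPSP onset (positive = excitation
first). Presets: control +2.8 ms (midline-stimulation median), in-vivo-like
+0.4 ms (auditory-nerve median), sweeps −10…+10 ms in 1 ms steps, trains of
20 pulses at 100 Hz with a 100 ms analysis tail, and a static 0.51 IPSP
scale for the prior-depression condition. First-AP latency is measured from
the first EPSP onset. Two rate definitions are reported because the source
does not disclose its formula: (N−1)/(span of spike times) (primary) and
N/analysis-window.

## PSC event pipeline

Detection: sweeps are lightly smoothed (Gaussian, σ = 0.12 ms — <1% peak
attenuation for PSC kinetics, ~2× noise reduction), and candidate peaks must
exceed `threshold × RMS` of the pre-stimulus baseline (default 2×) in the
polarity expected for the holding potential, with matching prominence (which
rejects noise bumps riding on decay tails) and a ≥0.5 ms half-amplitude
width — a minimal stand-in for the unspecified accept/reject heuristics of
the commercial detector being emulated. Onset is the last crossing of
baseline + 10% of peak deflection before the peak (linearly interpolated);
the local baseline is the median of the 2 ms before onset; rise time is
10–90%; decay is a single-exponential fit from the falling 90% point over at
most 5 estimated time constants or until the next event. Events >20 ms
after the preceding stimulus are treated as spontaneous and excluded from
evoked analyses. Failed decay fits flag the event and exclude it from
clustering.

## Clustering and E/I labeling

Features default to onset latency, rise time, and decay τ — amplitude is
excluded, matching the sorting actually applied to the recorded data, with a
flag to restore it — and are z-scored per column (the features span
different scales; the source is silent on scaling). Cluster number comes
from the gap statistic with uniform reference sets drawn over each feature's
observed range (Tibshirani's method; W_k is the pooled within-cluster sum of
squared distances, B = 500 references, best-of-25 k-means per fit, 1-SE
rule, smallest qualifying k, argmax fallback). The implementation was
cross-checked against R `cluster::clusGap` (d.power = 2,
spaceH0 = "original") on a frozen fixture; note R's W_k is half ours, an
offset that cancels in the gap. k-means partitions use scikit-learn with
best-of-nstart restarts, and clusters are re-indexed by ascending mean onset
latency so "first E/I cluster" is well defined.

Cluster summaries: onset jitter = SD of onset latency; peak jitter = SD of
onset latency + time-to-peak; probability = events/(sweeps × stimuli),
capped at 1. A −60 mV cluster is labeled inhibitory iff a 0 mV cluster's
mean latency falls within max(2 × pooled onset jitter, 0.5 ms) — the source
states the matching rule but no tolerance — excitatory otherwise; with no
0 mV data all clusters are excitatory and flagged. The cell's E–I latency
difference is first-inhibitory minus first-excitatory mean onset latency.

## E/I classifier

A random forest (scikit-learn, 500 trees by default — the published forest
stabilized by 150; √7 = 2 features per split; bootstrap with OOB scoring)
over seven features: rise time, decay τ, amplitude, cluster probability,
onset jitter, peak jitter, and age (categorical, ordinal-encoded; unseen
ages map to the nearest trained category with a warning). Class probability
is the fraction of trees voting excitatory; a tie at exactly 0.5 classifies
as inhibitory and is flagged (the published ">0.5" rule leaves ties
undefined). The OOB error is tracked per cumulative tree count by
majority-voting each sample's out-of-bag trees, and both the OOB error and
the resubstitution accuracy are reported because the published "99.89%
accuracy" does not say which it was. Clusters whose events receive both
labels are split into one E and one I cluster; cluster-level labels are the
majority vote of member events.

## Calcium imaging

ΔF/F is the ratio of the within-protocol maximum ROI fluorescence to the
baseline average F (first 15 frames, ~5 s): a quiescent ROI sits at ~1.
This *ratio* reading — rather than (F−F₀)/F₀ — is an inference from the
printed group values (control 1.18 vs blocked 1.06 reproducing ~68%
suppression) and is applied consistently:

    suppression = 100 · (dff_control − dff_blocked) / (dff_control − 1)

clipped to [0, 100], undefined (None) when the control shows no evoked
signal. A cell is active if its average fluorescence reaches 2 baseline SDs
above the baseline mean in ≥2 of 3 stimulation bouts; the bout statistic is
the bout-window mean by default ("peak" is available) because a per-frame
peak over a 15-frame window crosses 2 SD by chance ~29% of the time, which
would make the criterion meaningless on quiescent ROIs. ROI polygons are
rasterized by pixel-center containment (even-odd rule).

## Synthetic data: what it emulates, and what it does not

**PSC sweeps**: per stimulus and cluster, an independent Bernoulli draw
(the stated occurrence probability) places a double-exponential event with
Gaussian onset jitter and truncated-normal amplitude; events sum linearly
(clamped-cell assumption) over Gaussian noise low-pass filtered at 10 kHz
(4-pole Bessel, variance-calibrated from the filter's impulse response so
the trace RMS matches the requested value statistically, not by per-sweep
renormalization). Amplitudes are stored as positive magnitudes; polarity and
scale come from the driving-force ratio relative to −60 mV with reversals
0 mV (E) and −20 mV (I, the high-chloride internal), so at 0 mV excitatory
events vanish and inhibitory events invert at half magnitude. Defaults
follow the midline-stimulation cluster medians (E: 1.92 ± 0.25 ms latency,
p = 0.80, 67 pA; I: 4.47 ± 0.50 ms, p = 0.45, 55 pA; rise/decay constants
chosen so 10–90% rise times match the printed 0.63/0.86 ms). Amplitude SDs
(15/12 pA) and the within-cluster peak-jitter parameters are realistic
choices where the source prints none. Not emulated: dendritic filtering,
series-resistance artifacts, spontaneous event trains.

**Feature tables**: truncated-normal draws per class from the printed
medians/spreads, probability capped at 1, age uniform over P14–P19.

**Calcium movies**: octagonal ROIs on a grid; each bout drives a one-frame
rise and ~1.2 s exponential decay whose peak sets F/F₀ = `evoked_dff`
(default 1.2); "blocked" multiplies the evoked component by
(1 − suppression_factor) while reusing identical noise draws, so zero
suppression gives bit-identical movies. Pixel noise is sized so the ROI-mean
noise SD is `noise_sd` (default 0.3, ~0.3% of baseline — bright somatic
GCaMP ROIs averaged over ~50 pixels). Because ΔF/F is a maximum statistic,
frame noise biases it upward and the recovered suppression slightly
downward; at the default noise this bias is within the 2-point recovery
tolerance, and a green recovery test establishes pipeline correctness at
realistic noise, not robustness to arbitrarily dim ROIs.

All generators are bit-reproducible under a seed.

## Test scaling notes

The gap-statistic recovery suite runs 50 seeds at B = 50 references and
kmax = 5 (B = 500 is the analysis default; 50 × that is outside the test
budget and the decision concerns only the k̂ mode, which stabilizes far
below B = 500). Monte-Carlo suites (decay-fit recovery, detection
recall/precision, classifier holdout) use fixed seeds and sizes chosen so
the checked margins are several MC standard errors wide.
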