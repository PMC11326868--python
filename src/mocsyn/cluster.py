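"""Latency clustering of PSCs: gap statistic, k-means, and E/I labeling.

The number of clusters is chosen with the gap statistic (Tibshirani's
uniform-reference method, 1-SE rule), which can select one cluster where the
data are unimodal; events are then partitioned with best-of-nstart k-means
and summarized per cluster (onset/peak jitter, occurrence probability,
median kinetics).  Clusters recorded at -60 mV are labeled inhibitory when a
matching cluster exists at 0 mV and excitatory otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

__all__ = [
    "FeatureMatrix",
    "GapCurve",
    "PscCluster",
    "build_feature_matrix",
    "gap_select_k",
    "kmeans_cluster",
    "summarize_clusters",
    "label_clusters_by_holding",
    "ei_latency_difference",
]

DEFAULT_FEATURES = ("onset_latency", "rise_time", "decay_tau")


@dataclass
class FeatureMatrix:
    """Standardized event features of one cell at one holding potential."""

    values: np.ndarray              # (n_events, n_features), standardized
    feature_names: tuple
    raw: np.ndarray                 # same shape, original units
    event_index: np.ndarray         # row index into the source event table

    @property
    def n_events(self) -> int:
        return self.values.shape[0]


def build_feature_matrix(
    events: pd.DataFrame,
    features=DEFAULT_FEATURES,
    include_amplitude: bool = False,
    standardize: bool = True,
) -> FeatureMatrix:
    """Assemble (and by default z-score) the clustering features.

    The default feature set excludes amplitude, matching the sorting actually
    applied to recorded PSCs; ``include_amplitude`` restores it.  Rows with
    any null feature (e.g. failed decay fits) are dropped.
    """
    cols = list(features)
    if include_amplitude and "amplitude" not in cols:
        cols.append("amplitude")
    missing = [c for c in cols if c not in events.columns]
    if missing:
        raise KeyError(f"event table lacks feature columns {missing}")
    sub = events[cols].apply(pd.to_numeric, errors="coerce")
    keep = sub.notna().all(axis=1)
    raw = sub[keep].to_numpy(dtype=float)
    if raw.shape[0] < 2:
        raise ValueError("need at least 2 events with complete features to cluster")
    vals = raw.copy()
    if standardize:
        sd = vals.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        vals = (vals - vals.mean(axis=0)) / sd
    return FeatureMatrix(
        values=vals,
        feature_names=tuple(cols),
        raw=raw,
        event_index=np.asarray(events.index[keep]),
    )


@dataclass
class GapCurve:
    """Gap-statistic curve over k = 1..kmax."""

    ks: np.ndarray
    log_wk: np.ndarray
    ref_log_wk: np.ndarray     # E*[log W_k] over the B reference sets
    gap: np.ndarray
    sk: np.ndarray
    b: int

    def to_dict(self) -> dict:
        return {
            "k": self.ks.tolist(), "log_wk": self.log_wk.tolist(),
            "ref_log_wk": self.ref_log_wk.tolist(), "gap": self.gap.tolist(),
            "sk": self.sk.tolist(), "B": self.b,
        }


def _wk(x: np.ndarray, k: int, nstart: int, seed) -> float:
    """Pooled within-cluster sum of squares of the best-of-nstart solution."""
    if k == 1:
        mu = x.mean(axis=0)
        return float(np.sum((x - mu) ** 2))
    km = KMeans(n_clusters=k, n_init=nstart, random_state=seed).fit(x)
    return float(km.inertia_)


_LOG_FLOOR = 1e-12


def gap_select_k(
    features: FeatureMatrix | np.ndarray,
    kmax: int = 10,
    B: int = 500,
    nstart: int = 25,
    seed: int = 0,
    se_rule: float = 1.0,
) -> tuple[int, GapCurve]:
    """Optimal cluster number by the gap statistic.

    Gap(k) = mean_b log W*_kb - log W_k against B uniform reference sets
    drawn over each feature's observed range; k* is the smallest k with
    Gap(k) >= Gap(k+1) - se_rule * s_{k+1} (may be 1).  If no k qualifies,
    the argmax of Gap is returned.
    """
    x = features.values if isinstance(features, FeatureMatrix) else np.asarray(features)
    x = np.atleast_2d(x.astype(float))
    n = x.shape[0]
    if n < 2:
        raise ValueError("need at least 2 rows")
    if kmax < 1:
        raise ValueError("kmax must be >= 1")
    if kmax > n:
        warnings.warn(f"kmax={kmax} exceeds n={n}; clipping", stacklevel=2)
        kmax = n
    rng = np.random.default_rng(seed)
    lo, hi = x.min(axis=0), x.max(axis=0)

    ks = np.arange(1, kmax + 1)
    log_wk = np.array([
        np.log(max(_wk(x, k, nstart, int(rng.integers(2**31))), _LOG_FLOOR))
        for k in ks
    ])
    ref = np.empty((B, kmax))
    for b in range(B):
        xb = rng.uniform(lo, hi, size=x.shape)
        for j, k in enumerate(ks):
            ref[b, j] = np.log(
                max(_wk(xb, k, nstart, int(rng.integers(2**31))), _LOG_FLOOR)
            )
    ref_mean = ref.mean(axis=0)
    gap = ref_mean - log_wk
    sk = ref.std(axis=0, ddof=1 if B > 1 else 0) * np.sqrt(1.0 + 1.0 / B)

    k_star = None
    for j in range(kmax - 1):
        if gap[j] >= gap[j + 1] - se_rule * sk[j + 1]:
            k_star = int(ks[j])
            break
    if k_star is None:
        k_star = int(ks[np.argmax(gap)])
    return k_star, GapCurve(ks=ks, log_wk=log_wk, ref_log_wk=ref_mean,
                            gap=gap, sk=sk, b=B)


def kmeans_cluster(
    features: FeatureMatrix | np.ndarray,
    k: int,
    nstart: int = 25,
    seed: int = 0,
    order_by: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Best-of-nstart k-means partition; returns (assignments, W_k).

    Cluster ids are re-indexed by ascending mean of ``order_by`` (default:
    the first feature column, onset latency in the standard layout).
    """
    if isinstance(features, FeatureMatrix):
        x = features.values
        if order_by is None and "onset_latency" in features.feature_names:
            order_by = features.raw[:, features.feature_names.index("onset_latency")]
    else:
        x = np.atleast_2d(np.asarray(features, dtype=float))
    n = x.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds number of rows {n}")
    if k == 1:
        mu = x.mean(axis=0)
        return np.zeros(n, dtype=int), float(np.sum((x - mu) ** 2))
    km = KMeans(n_clusters=k, n_init=nstart, random_state=seed).fit(x)
    labels = km.labels_
    if order_by is None:
        order_by = x[:, 0]
    order_by = np.asarray(order_by, dtype=float)
    means = [order_by[labels == c].mean() for c in range(k)]
    remap = np.argsort(np.argsort(means))
    return remap[labels].astype(int), float(km.inertia_)


@dataclass
class PscCluster:
    """Summary of one latency-defined PSC cluster."""

    cluster_id: int
    event_ids: np.ndarray
    n: int
    mean_onset_latency: float
    median_onset_latency: float
    onset_jitter: float
    peak_jitter: float
    probability: float
    median_amplitude: float
    median_rise_time: float
    median_decay_tau: float
    label: str = "unknown"
    flags: list = field(default_factory=list)

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("cluster must contain at least one event")
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError("probability must be in [0, 1]")


def summarize_clusters(
    events: pd.DataFrame,
    assignments: np.ndarray,
    n_sweeps: int,
    n_stimuli: int = 1,
) -> list[PscCluster]:
    """Per-cluster metrics, ordered by cluster id (ascending latency).

    Onset jitter is the SD of onset latency within the cluster; peak jitter
    the SD of (onset latency + time to peak); probability the event count
    per stimulus per sweep, capped at 1.
    """
    assignments = np.asarray(assignments)
    if len(assignments) != len(events):
        raise ValueError("assignments must cover all events")
    out = []
    for cid in np.unique(assignments):
        sub = events.iloc[np.nonzero(assignments == cid)[0]]
        lat = sub["onset_latency"].to_numpy(dtype=float)
        peak_lat = lat + sub["time_to_peak"].to_numpy(dtype=float)
        decay = pd.to_numeric(sub["decay_tau"], errors="coerce")
        out.append(
            PscCluster(
                cluster_id=int(cid),
                event_ids=np.asarray(sub.index),
                n=len(sub),
                mean_onset_latency=float(lat.mean()),
                median_onset_latency=float(np.median(lat)),
                onset_jitter=float(lat.std(ddof=1)) if len(lat) > 1 else 0.0,
                peak_jitter=float(peak_lat.std(ddof=1)) if len(lat) > 1 else 0.0,
                probability=min(len(sub) / (n_sweeps * n_stimuli), 1.0),
                median_amplitude=float(sub["amplitude"].median()),
                median_rise_time=float(sub["rise_time"].median()),
                median_decay_tau=float(decay.median()),
            )
        )
    return sorted(out, key=lambda c: c.mean_onset_latency)


def label_clusters_by_holding(
    clusters_at_minus60: list[PscCluster],
    clusters_at_0mV: list[PscCluster],
    match_tolerance: float | None = None,
) -> list[PscCluster]:
    """Label -60 mV clusters E/I by latency correspondence with 0 mV clusters.

    A -60 mV cluster is inhibitory iff some 0 mV cluster's mean onset latency
    lies within the match tolerance (default: max of twice the pooled onset
    jitter of the pair and 0.5 ms); clusters at 0 mV are inhibitory by
    construction.  With no 0 mV data every cluster is excitatory and flagged.
    """
    for c0 in clusters_at_0mV:
        c0.label = "inhibitory"
    if not clusters_at_0mV:
        for c in clusters_at_minus60:
            c.label = "excitatory"
            if "no-0mV-data" not in c.flags:
                c.flags.append("no-0mV-data")
        return clusters_at_minus60
    for c in clusters_at_minus60:
        matched = False
        for c0 in clusters_at_0mV:
            if match_tolerance is None:
                pooled = np.sqrt((c.onset_jitter**2 + c0.onset_jitter**2) / 2.0)
                tol = max(2.0 * pooled, 0.5)
            else:
                tol = match_tolerance
            if abs(c.mean_onset_latency - c0.mean_onset_latency) <= tol:
                matched = True
                break
        c.label = "inhibitory" if matched else "excitatory"
    return clusters_at_minus60


def ei_latency_difference(
    clusters: list[PscCluster],
) -> float | None:
    """E-I latency difference of a cell: first-I minus first-E onset latency.

    Positive values mean excitation precedes inhibition.  Returns None when
    either class is absent.  "First" is the lowest-latency cluster of each
    label.
    """
    es = [c for c in clusters if c.label == "excitatory"]
    is_ = [c for c in clusters if c.label == "inhibitory"]
    if not es or not is_:
        return None
    first_e = min(es, key=lambda c: c.mean_onset_latency)
    first_i = min(is_, key=lambda c: c.mean_onset_latency)
    return float(first_i.mean_onset_latency - first_e.mean_onset_latency)
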