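"""Classification of simulated activity profiles into dynamic-behaviour classes.

Four classes describe the shapes seen across the pathway under an insulin
step: fast responses that plateau within a few minutes, fast overshooting
responses (early peak, later relaxation), slow responses, and slow
overshooting responses (peak after ~5 min, relaxation over tens of
minutes).  The classifier is deterministic and rule-based: it extracts
peak time, steady value, overshoot index and settling time from each
trace and applies fixed thresholds (all exposed in
:class:`ClassifierConfig`).  An optional unsupervised mode clusters
normalized traces into four groups for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional

import numpy as np


class BehaviourClass(str, Enum):
    FAST = "fast"
    FAST_OVERSHOOT = "fast_overshoot"
    SLOW = "slow"
    SLOW_OVERSHOOT = "slow_overshoot"


@dataclass(frozen=True)
class ClassifierConfig:
    overshoot_threshold: float = 0.05  # peak/steady - 1 above this = overshoot
    settling_band: float = 0.05        # fraction of steady value
    fast_cut_min: float = 5.0          # fast if settled (or peaked) by this time
    steady_tail_fraction: float = 0.1  # tail share of the window used as steady value


@dataclass(frozen=True)
class DynamicFeatures:
    peak_time: float
    peak_value: float
    steady_value: float
    overshoot_index: float
    settling_time: float
    settled: bool


def extract_dynamic_features(
    times: np.ndarray, trace: np.ndarray, config: ClassifierConfig = ClassifierConfig()
) -> DynamicFeatures:
    """Peak, steady state (tail mean), overshoot index and 5 % settling time.

    Monotone traces get overshoot index 0; an all-zero trace gets steady
    value 0 and overshoot 0.
    """
    times = np.asarray(times, dtype=float)
    trace = np.asarray(trace, dtype=float)
    if len(times) < 2 or times[-1] <= times[0]:
        raise ValueError("trace needs a positive-length time grid")
    n_tail = max(1, int(len(trace) * config.steady_tail_fraction))
    steady = float(trace[-n_tail:].mean())
    ipeak = int(np.argmax(trace))
    peak_t, peak_v = float(times[ipeak]), float(trace[ipeak])
    if steady <= 0:
        overshoot = 0.0 if peak_v <= 0 else float("inf")
    else:
        overshoot = max(0.0, peak_v / steady - 1.0)
    scale = max(abs(steady), 1e-12)
    outside = np.abs(trace - steady) / scale > config.settling_band
    if outside.any():
        last = int(np.where(outside)[0][-1])
        settled = last + 1 < len(times)
        settling = float(times[last + 1]) if settled else float(times[-1])
    else:
        settled = True
        settling = float(times[0])
    return DynamicFeatures(
        peak_time=peak_t,
        peak_value=peak_v,
        steady_value=steady,
        overshoot_index=overshoot,
        settling_time=settling,
        settled=settled,
    )


def classify_profile(
    features: DynamicFeatures, config: ClassifierConfig = ClassifierConfig()
) -> tuple[BehaviourClass, bool]:
    """Assign one of the four classes; the flag marks unsettled traces
    (classified by peak time alone)."""
    overshoot = features.overshoot_index > config.overshoot_threshold
    if not features.settled:
        fast = features.peak_time <= config.fast_cut_min
        cls = (
            (BehaviourClass.FAST_OVERSHOOT if overshoot else BehaviourClass.FAST)
            if fast
            else (BehaviourClass.SLOW_OVERSHOOT if overshoot else BehaviourClass.SLOW)
        )
        return cls, True
    arrival = features.peak_time if overshoot else features.settling_time
    fast = arrival <= config.fast_cut_min
    if overshoot:
        cls = BehaviourClass.FAST_OVERSHOOT if fast else BehaviourClass.SLOW_OVERSHOOT
    else:
        cls = BehaviourClass.FAST if fast else BehaviourClass.SLOW
    return cls, False


def classify_profiles(
    times: np.ndarray,
    traces: dict[str, np.ndarray],
    config: ClassifierConfig = ClassifierConfig(),
) -> "pd.DataFrame":
    """Classify a set of named traces; returns a tidy table
    (name, class, unsettled flag, features)."""
    import pandas as pd

    rows = []
    for name, trace in traces.items():
        f = extract_dynamic_features(times, trace, config)
        cls, unsettled = classify_profile(f, config)
        rows.append(
            {
                "name": name,
                "class": cls.value,
                "unsettled": unsettled,
                "peak_time": f.peak_time,
                "peak_value": f.peak_value,
                "steady_value": f.steady_value,
                "overshoot_index": f.overshoot_index,
                "settling_time": f.settling_time,
            }
        )
    return pd.DataFrame(rows)


def kmeans_cluster_profiles(
    traces: dict[str, np.ndarray],
    n_clusters: int = 4,
    n_iter: int = 100,
    seed: int = 0,
) -> dict[str, int]:
    """Unsupervised comparison mode: Lloyd k-means on min-max normalized
    traces with deterministic farthest-point initialization."""
    names = list(traces)
    X = []
    for name in names:
        y = np.asarray(traces[name], dtype=float)
        lo, hi = y.min(), y.max()
        X.append((y - lo) / (hi - lo) if hi > lo else np.zeros_like(y))
    X = np.array(X)
    rng = np.random.default_rng(seed)
    centers = [X[rng.integers(len(X))]]
    while len(centers) < min(n_clusters, len(X)):
        d = np.min([np.sum((X - c) ** 2, axis=1) for c in centers], axis=0)
        centers.append(X[int(np.argmax(d))])
    centers = np.array(centers)
    labels = np.zeros(len(X), dtype=int)
    for _ in range(n_iter):
        d = np.array([np.sum((X - c) ** 2, axis=1) for c in centers])
        new_labels = np.argmin(d, axis=0)
        if (new_labels == labels).all() and _ > 0:
            break
        labels = new_labels
        for k in range(len(centers)):
            members = X[labels == k]
            if len(members):
                centers[k] = members.mean(axis=0)
    return {name: int(lab) for name, lab in zip(names, labels)}
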