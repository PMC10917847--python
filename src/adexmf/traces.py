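"""Adaptation-indexed feature traces and their K-means classes.

For every fixed (S, E_L_i, E_L_e, T) combination, the sweep's records over
the adaptation axis form one trace of a connectivity feature versus b_e;
traces touching paroxysmal activity anywhere along the axis are excluded,
and the survivors are clustered as points in b_e-space.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

__all__ = [
    "FeatureTrace",
    "TraceClassModel",
    "build_traces",
    "cluster_traces",
    "class_distribution",
    "DEPOLARIZED_REGION",
    "HYPERPOLARIZED_REGION",
]

TRACE_KEY = ("S", "E_L_i", "E_L_e", "T")


def DEPOLARIZED_REGION(key: dict) -> bool:
    """Depolarized excitatory-leak band: -65 mV <= E_L_e <= -60 mV."""
    return -65.0 <= key["E_L_e"] <= -60.0


def HYPERPOLARIZED_REGION(key: dict) -> bool:
    """Hyperpolarized excitatory-leak band: -80 mV <= E_L_e <= -75 mV."""
    return -80.0 <= key["E_L_e"] <= -75.0


@dataclass
class FeatureTrace:
    """One feature-versus-adaptation trace at fixed (S, E_L_i, E_L_e, T)."""

    key: tuple
    b_e_values: np.ndarray
    values: np.ndarray
    valid: bool

    @property
    def key_dict(self) -> dict:
        return dict(zip(TRACE_KEY, self.key))


@dataclass
class TraceClassModel:
    """Fitted K-means classes over valid traces.

    Centroids are canonically ordered by their value at the first b_e, so
    labels are reproducible across runs regardless of K-means internals.
    ``labels`` maps each valid trace key to its class.
    """

    k: int
    centroids: np.ndarray
    labels: dict
    inertia: float
    seed: int
    b_e_values: np.ndarray = field(default_factory=lambda: np.empty(0))


def build_traces(table: pd.DataFrame, feature_name: str) -> list:
    """Group sweep records into per-(S, E_L_i, E_L_e, T) traces over b_e.

    A trace is invalid when any constituent record is paroxysmal or failed.
    Raises on an incomplete table (every trace must cover the same b_e
    axis), listing the gaps.
    """
    if feature_name not in table.columns:
        raise ValueError(f"unknown feature column {feature_name!r}")
    b_e_axis = np.sort(table["b_e"].unique())
    traces = []
    gaps = []
    for key, group in table.groupby(list(TRACE_KEY), sort=True):
        group = group.sort_values("b_e")
        if len(group) != len(b_e_axis) or not np.array_equal(
            group["b_e"].to_numpy(), b_e_axis
        ):
            gaps.append(key)
            continue
        ok = (group["status"] == "ok").all() if "status" in group else True
        valid = ok and not group["is_paroxysmal"].astype(bool).any()
        traces.append(
            FeatureTrace(
                key=tuple(float(x) for x in key),
                b_e_values=b_e_axis,
                values=group[feature_name].to_numpy(dtype=float),
                valid=bool(valid),
            )
        )
    if gaps:
        raise ValueError(
            f"incomplete sweep table: missing b_e records for {len(gaps)} "
            f"combinations, e.g. {gaps[:5]}"
        )
    return traces


def cluster_traces(traces: list, k: int = 6, seed: int = 0) -> TraceClassModel:
    """K-means over the valid traces as points in b_e-space.

    Plus-plus initialization with 10 restarts; the best-inertia solution is
    kept and the centroids re-ordered by their value at the first b_e.
    """
    valid = [t for t in traces if t.valid]
    if len(valid) < k:
        raise ValueError(f"need at least k={k} valid traces, got {len(valid)}")
    X = np.stack([t.values for t in valid])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(X)
    order = np.argsort(km.cluster_centers_[:, 0], kind="stable")
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    labels = {
        t.key: int(relabel[lab]) for t, lab in zip(valid, km.labels_)
    }
    return TraceClassModel(
        k=k,
        centroids=km.cluster_centers_[order],
        labels=labels,
        inertia=float(km.inertia_),
        seed=seed,
        b_e_values=valid[0].b_e_values,
    )


def class_distribution(
    model_a: TraceClassModel,
    model_b: TraceClassModel,
    region_filter=None,
) -> tuple:
    """Joint class-occupancy fractions of two trace classifications.

    Returns ``(joint, class_map)``: a ``k_a x k_b`` matrix of fractions
    summing to 1 over the filtered traces, and a DataFrame with one row per
    trace key and both labels.  An empty filter result yields an all-zero
    matrix and an empty map.
    """
    keys_a, keys_b = set(model_a.labels), set(model_b.labels)
    if keys_a != keys_b:
        raise ValueError("the two models were fitted on different trace sets")
    keys = sorted(keys_a)
    if region_filter is not None:
        keys = [key for key in keys if region_filter(dict(zip(TRACE_KEY, key)))]
    joint = np.zeros((model_a.k, model_b.k))
    records = []
    for key in keys:
        la, lb = model_a.labels[key], model_b.labels[key]
        joint[la, lb] += 1
        records.append(dict(zip(TRACE_KEY, key), class_a=la, class_b=lb))
    if keys:
        joint /= joint.sum()
    return joint, pd.DataFrame(records)
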