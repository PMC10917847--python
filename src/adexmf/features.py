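"""Regime features of a simulated rate series.

All features are computed from the excitatory rate on the post-transient
window: extreme/mean/dispersion statistics, Up-state durations, the
node-averaged power-spectrum peak, functional connectivity and its
correlation with the structural connectome, plus the paroxysm flag.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .connectome import Connectome
from .network import RateTimeSeries

__all__ = [
    "FeatureConfig",
    "FeatureSet",
    "detect_paroxysm",
    "basic_stats",
    "mean_up_duration",
    "psd_peak_frequency",
    "functional_connectivity",
    "corr_fc_sc",
    "extract_features",
]

#: names of the scalar features, in export order
FEATURE_NAMES = (
    "max_nu_e",
    "mean_nu_e",
    "mean_sd_nu_e",
    "mean_up_duration",
    "psd_peak_freq",
    "mean_FC",
    "corrFCSC",
)


@dataclass(frozen=True)
class FeatureConfig:
    """Conventions of the feature pipeline.

    The Up-state threshold is ``up_threshold_frac`` of each node's maximum
    rate, with epochs shorter than ``up_min_duration`` ms discarded; the
    spectral peak is the most prominent non-DC local maximum with prominence
    at least ``psd_prominence_frac`` of the spectrum maximum.
    """

    paroxysm_threshold: float = 175.0
    up_threshold_frac: float = 0.2
    up_min_duration: float = 20.0
    psd_prominence_frac: float = 0.05
    fc_include_diagonal: bool = True


@dataclass(frozen=True)
class FeatureSet:
    """The seven regime features plus the paroxysm flag."""

    max_nu_e: float
    mean_nu_e: float
    mean_sd_nu_e: float
    mean_up_duration: float
    psd_peak_freq: float
    mean_FC: float
    corrFCSC: float
    is_paroxysmal: bool

    def as_dict(self) -> dict:
        return {
            "max_nu_e": self.max_nu_e,
            "mean_nu_e": self.mean_nu_e,
            "mean_sd_nu_e": self.mean_sd_nu_e,
            "mean_up_duration": self.mean_up_duration,
            "psd_peak_freq": self.psd_peak_freq,
            "mean_FC": self.mean_FC,
            "corrFCSC": self.corrFCSC,
            "is_paroxysmal": self.is_paroxysmal,
        }


def detect_paroxysm(ts: RateTimeSeries, threshold: float = 175.0) -> bool:
    """True iff the excitatory rate strictly exceeds ``threshold`` Hz
    anywhere (any node, any time)."""
    if ts.nu_e.size == 0:
        raise ValueError("empty series")
    return bool(ts.nu_e.max() > threshold)


def basic_stats(ts: RateTimeSeries) -> tuple:
    """(max over nodes and time, grand mean, node-averaged temporal SD)."""
    if ts.nu_e.size == 0:
        raise ValueError("empty series")
    x = ts.nu_e
    return float(x.max()), float(x.mean()), float(x.std(axis=0).mean())


def _epoch_durations(mask: np.ndarray, dt: float) -> np.ndarray:
    """Durations (ms) of contiguous True runs in a boolean vector."""
    if not mask.any():
        return np.empty(0)
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    starts, ends = edges[::2], edges[1::2]
    return (ends - starts) * dt


def mean_up_duration(ts: RateTimeSeries, cfg: FeatureConfig | None = None) -> float:
    """Node-averaged mean duration (ms) of supra-threshold epochs.

    Per node, the threshold is ``up_threshold_frac`` of that node's maximum
    rate and epochs shorter than ``up_min_duration`` are discarded; nodes
    with no Up state contribute 0 to the node average.
    """
    if cfg is None:
        cfg = FeatureConfig()
    if ts.nu_e.size == 0:
        raise ValueError("empty series")
    per_node = []
    for k in range(ts.n_nodes):
        x = ts.nu_e[:, k]
        peak = x.max()
        if peak <= 0:
            per_node.append(0.0)
            continue
        durations = _epoch_durations(x > cfg.up_threshold_frac * peak, ts.dt)
        durations = durations[durations >= cfg.up_min_duration]
        per_node.append(float(durations.mean()) if durations.size else 0.0)
    return float(np.mean(per_node))


def psd_peak_frequency(ts: RateTimeSeries, cfg: FeatureConfig | None = None) -> float:
    """Frequency (Hz) of the most prominent peak of the node-averaged power
    spectrum of the mean-subtracted excitatory rate; 0 when no peak passes
    the prominence threshold (e.g. a flat spectrum)."""
    if cfg is None:
        cfg = FeatureConfig()
    x = ts.nu_e
    if x.shape[0] < 2:
        raise ValueError("need at least two samples")
    spectra = np.abs(np.fft.rfft(x - x.mean(axis=0), axis=0)) ** 2
    psd = spectra.mean(axis=1)
    freqs = np.fft.rfftfreq(x.shape[0], d=ts.dt * 1e-3)
    psd_ac = psd[1:]  # DC excluded from the peak search
    if psd_ac.max() <= 0:
        return 0.0
    peaks, props = find_peaks(psd_ac, prominence=cfg.psd_prominence_frac * psd_ac.max())
    if peaks.size == 0:
        return 0.0
    best = peaks[np.argmax(props["prominences"])]
    return float(freqs[1 + best])


def functional_connectivity(ts: RateTimeSeries) -> np.ndarray:
    """Pairwise Pearson correlation of the per-node excitatory rates.

    Zero-variance nodes correlate 0 with every other node and 1 with
    themselves, so a silent node cannot poison the mean with NaNs.  The
    result is symmetric with unit diagonal, clipped to [-1, 1].
    """
    x = ts.nu_e
    if x.shape[0] < 2:
        raise ValueError("need at least two samples")
    sd = x.std(axis=0)
    live = sd > 0
    n = x.shape[1]
    fc = np.zeros((n, n))
    if live.any():
        sub = np.corrcoef(x[:, live], rowvar=False)
        sub = np.atleast_2d(sub)
        fc[np.ix_(live, live)] = sub
    np.fill_diagonal(fc, 1.0)
    return np.clip(fc, -1.0, 1.0)


def corr_fc_sc(fc: np.ndarray, c: Connectome, include_diagonal: bool = True) -> float:
    """Pearson correlation between the flattened functional and structural
    connectivity matrices (diagonal included by default)."""
    w = c.weights
    if fc.shape != w.shape:
        raise ValueError(f"shape mismatch: FC {fc.shape} vs SC {w.shape}")
    if include_diagonal:
        a, b = fc.ravel(), w.ravel()
    else:
        off = ~np.eye(fc.shape[0], dtype=bool)
        a, b = fc[off], w[off]
    if a.std() == 0 or b.std() == 0:
        return 0.0
    r = float(np.corrcoef(a, b)[0, 1])
    return float(np.clip(r, -1.0, 1.0))


def extract_features(
    ts: RateTimeSeries,
    c: Connectome,
    cfg: FeatureConfig | None = None,
) -> FeatureSet:
    """Full feature pipeline on the post-transient window (deterministic)."""
    if cfg is None:
        cfg = FeatureConfig()
    mx, mean, sd = basic_stats(ts)
    fc = functional_connectivity(ts)
    mean_fc = float(fc.mean()) if cfg.fc_include_diagonal else float(
        fc[~np.eye(fc.shape[0], dtype=bool)].mean()
    )
    return FeatureSet(
        max_nu_e=mx,
        mean_nu_e=mean,
        mean_sd_nu_e=sd,
        mean_up_duration=mean_up_duration(ts, cfg),
        psd_peak_freq=psd_peak_frequency(ts, cfg),
        mean_FC=mean_fc,
        corrFCSC=corr_fc_sc(fc, c, cfg.fc_include_diagonal),
        is_paroxysmal=detect_paroxysm(ts, cfg.paroxysm_threshold),
    )
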