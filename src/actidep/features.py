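"""Feature engineering for per-minute activity windows.

Each one-day window is summarised into 13 activity features across four
families — time domain (mean, SD, skewness, kurtosis, IQR, lag-1
autocorrelation, histogram entropy), frequency domain (PSD mean, dominant
frequency, spectral entropy from a Welch averaged periodogram), circadian
(activity onset/offset of the primary daily activity period) and transition
structure (entropy rate of a discretised activity-state Markov chain) — and
joined with two demographics (age-band midpoint, gender code) to form the
15-column feature matrix.

Conventions for degenerate windows are explicit: a constant window has
SD 0, skewness/kurtosis 0, autocorrelation 0 and entropy 0; windows for
which a feature is genuinely undefined (flat day with no onset, all-zero
spectrum) are dropped and logged rather than imputed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import signal as sp_signal
from scipy import stats as sp_stats
from sklearn.preprocessing import StandardScaler

from .cohort_io import (
    ActivityWindow,
    Cohort,
    ValidationError,
    age_band_midpoint,
    assign_binary_label,
    assign_severity_label,
    window_recording,
)

__all__ = [
    "FeatureConfig",
    "FeatureMatrix",
    "ScalerParams",
    "FEATURE_NAMES",
    "time_domain_features",
    "frequency_domain_features",
    "circadian_features",
    "transition_entropy",
    "extract_window_features",
    "build_feature_matrix",
    "fit_scaler",
    "apply_scaler",
    "FeatureScaler",
]

ACTIVITY_FEATURES = (
    "mean", "sd", "skewness", "kurtosis", "iqr", "autocorr", "entropy",
    "psd_mean", "dominant_frequency", "spectral_entropy",
    "activity_onset", "activity_offset", "transition_entropy",
)
FEATURE_NAMES = ACTIVITY_FEATURES + ("age", "gender")


@dataclass
class FeatureConfig:
    """Estimator settings for the window summaries.

    autocorr_lag
        Lag (minutes) of the reported sample autocorrelation.
    entropy_bins
        Histogram bin count B for the time-domain entropy, normalised by
        log B so the feature lies in [0, 1].
    psd_segment_length
        Welch segment length in minutes (Hann taper, 50% overlap).
    onset_smooth / onset_threshold / onset_persistence
        Circadian detection: centred rolling-mean width, threshold as a
        multiple of the daily mean, and required consecutive minutes above
        threshold.
    transition_states
        Number of activity states k for the transition-entropy chain
        (per-window quantile discretisation, normalised by log k).
    """

    autocorr_lag: int = 1
    entropy_bins: int = 16
    psd_segment_length: int = 256
    onset_smooth: int = 60
    onset_threshold: float = 1.0
    onset_persistence: int = 30
    transition_states: int = 3
    window_length: int = 1440
    gap_tolerance: int = 2


def time_domain_features(
    window: ActivityWindow | np.ndarray, cfg: Optional[FeatureConfig] = None
) -> dict[str, float]:
    """Moments, IQR, lag-1 autocorrelation and normalised histogram entropy."""
    cfg = cfg or FeatureConfig()
    x = np.asarray(getattr(window, "counts", window), dtype=float)
    if x.size < 2:
        raise ValidationError("time-domain features need >= 2 samples")
    mean = float(np.mean(x))
    sd = float(np.std(x))  # population sigma, matching the z-score scaler
    if sd == 0.0:
        return {
            "mean": mean, "sd": 0.0, "skewness": 0.0, "kurtosis": 0.0,
            "iqr": 0.0, "autocorr": 0.0, "entropy": 0.0,
        }
    skew = float(sp_stats.skew(x, bias=False))
    kurt = float(sp_stats.kurtosis(x, fisher=True, bias=False))
    q75, q25 = np.percentile(x, [75, 25])
    lag = cfg.autocorr_lag
    xc = x - mean
    autocorr = float(np.dot(xc[:-lag], xc[lag:]) / np.dot(xc, xc))
    hist, _ = np.histogram(x, bins=cfg.entropy_bins)
    p = hist[hist > 0] / hist.sum()
    entropy = float(-(p * np.log(p)).sum() / np.log(cfg.entropy_bins))
    return {
        "mean": mean, "sd": sd, "skewness": skew, "kurtosis": kurt,
        "iqr": float(q75 - q25), "autocorr": autocorr, "entropy": entropy,
    }


def frequency_domain_features(
    window: ActivityWindow | np.ndarray, cfg: Optional[FeatureConfig] = None
) -> Optional[dict[str, float]]:
    """Welch-periodogram summaries; ``None`` for an all-zero window.

    The PSD is an averaged modified periodogram (Hann taper, 50% overlap,
    density scaling so that sum(psd) * df approximates the sample variance).
    The DC ordinate is excluded from all three summaries; frequencies are in
    cycles per minute.
    """
    cfg = cfg or FeatureConfig()
    x = np.asarray(getattr(window, "counts", window), dtype=float)
    nperseg = min(cfg.psd_segment_length, x.size)
    if x.size < 2 * nperseg:
        raise ValidationError(
            f"window of {x.size} samples is shorter than two PSD segments"
        )
    freqs, psd = sp_signal.welch(
        x, fs=1.0, window="hann", nperseg=nperseg,
        noverlap=nperseg // 2, detrend="constant", scaling="density",
    )
    freqs, psd = freqs[1:], psd[1:]  # drop DC
    total = psd.sum()
    if total <= 0.0 or not np.isfinite(total):
        return None
    p = psd / total
    p = p[p > 0]
    spectral_entropy = float(-(p * np.log(p)).sum() / np.log(psd.size))
    return {
        "psd_mean": float(psd.mean()),
        "dominant_frequency": float(freqs[int(np.argmax(psd))]),
        "spectral_entropy": spectral_entropy,
    }


def _sustained_runs(mask: np.ndarray, min_len: int) -> list[tuple[int, int]]:
    """[start, end) index pairs of True runs of at least ``min_len``."""
    runs: list[tuple[int, int]] = []
    start = None
    for i, m in enumerate(mask):
        if m and start is None:
            start = i
        elif not m and start is not None:
            if i - start >= min_len:
                runs.append((start, i))
            start = None
    if start is not None and len(mask) - start >= min_len:
        runs.append((start, len(mask)))
    return runs


def circadian_features(
    window: ActivityWindow | np.ndarray, cfg: Optional[FeatureConfig] = None
) -> Optional[dict[str, float]]:
    """Onset and offset (minutes into the window) of the main activity period.

    Counts are smoothed with a centred rolling mean, then compared against
    ``onset_threshold`` times the window mean; onset is the start of the first
    run of at least ``onset_persistence`` consecutive supra-threshold minutes
    and offset the end of the last such run. Returns ``None`` (drop the
    window) when no sustained crossing exists.
    """
    cfg = cfg or FeatureConfig()
    x = np.asarray(getattr(window, "counts", window), dtype=float)
    smoothed = (
        pd.Series(x).rolling(cfg.onset_smooth, center=True, min_periods=1)
        .mean().to_numpy()
    )
    level = cfg.onset_threshold * x.mean()
    if level <= 0.0:
        return None
    runs = _sustained_runs(smoothed > level, cfg.onset_persistence)
    if not runs:
        return None
    onset = float(runs[0][0])
    offset = float(runs[-1][1])
    return {"activity_onset": onset, "activity_offset": offset}


def transition_entropy(
    window: ActivityWindow | np.ndarray, cfg: Optional[FeatureConfig] = None
) -> float:
    """Entropy rate of the k-state discretised activity chain, in [0, 1].

    States are per-window quantile bins (tertiles for k=3); the statistic is
    H = -sum_i pi_i sum_j P_ij log P_ij normalised by log k, where P is the
    empirical transition matrix and pi the empirical state frequencies. A
    single occupied state (constant window) gives 0 by convention.
    """
    cfg = cfg or FeatureConfig()
    x = np.asarray(getattr(window, "counts", window), dtype=float)
    k = cfg.transition_states
    if x.size < k * k:
        warnings.warn(
            f"transition entropy on {x.size} < k^2 = {k * k} samples is "
            "poorly estimated", stacklevel=2,
        )
    # quantile binning via the mid-distribution function (rank - 0.5)/n:
    # robust to heavy ties, which plain quantile edges would merge or split
    ranks = sp_stats.rankdata(x, method="average")
    states = np.minimum(k - 1, ((ranks - 0.5) / x.size * k).astype(int))
    if np.unique(states).size < 2:
        return 0.0
    trans = np.zeros((k, k))
    np.add.at(trans, (states[:-1], states[1:]), 1.0)
    counts = np.bincount(states, minlength=k).astype(float)
    pi = counts / counts.sum()
    h = 0.0
    for i in range(k):
        row_total = trans[i].sum()
        if row_total == 0:
            continue
        p = trans[i][trans[i] > 0] / row_total
        h += pi[i] * float(-(p * np.log(p)).sum())
    return float(h / math.log(k))


def extract_window_features(
    window: ActivityWindow, cfg: Optional[FeatureConfig] = None
) -> tuple[Optional[dict[str, float]], Optional[str]]:
    """All 13 activity features for one window, or ``(None, reason)``."""
    cfg = cfg or FeatureConfig()
    feats = time_domain_features(window, cfg)
    if feats["sd"] == 0.0:
        return None, "constant window (undefined spectral/circadian features)"
    freq = frequency_domain_features(window, cfg)
    if freq is None:
        return None, "all-zero spectrum"
    circ = circadian_features(window, cfg)
    if circ is None:
        return None, "no sustained activity period (flat day)"
    feats.update(freq)
    feats.update(circ)
    feats["transition_entropy"] = transition_entropy(window, cfg)
    if not all(np.isfinite(v) for v in feats.values()):
        return None, "non-finite feature value"
    return feats, None


@dataclass
class FeatureMatrix:
    """Feature table with aligned labels and per-row participant ids."""

    frame: pd.DataFrame
    labels: np.ndarray
    participant_ids: np.ndarray
    drop_log: list[dict] = field(default_factory=list)

    @property
    def X(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)

    @property
    def feature_names(self) -> list[str]:
        return list(self.frame.columns)

    def __len__(self) -> int:
        return len(self.frame)


def build_feature_matrix(
    cohort: Cohort,
    cfg: Optional[FeatureConfig] = None,
    task: str = "binary",
    madrs_source: str = "madrs1",
) -> FeatureMatrix:
    """Window every recording and assemble the labelled feature matrix.

    ``task`` selects the label: ``"binary"`` (condition=1 / control=0) or
    ``"severity"`` (MADRS-banded 0/1/2, controls labelled from their score
    when present, else 0). Windows with undefined features are dropped and
    logged with their reason.
    """
    cfg = cfg or FeatureConfig()
    rows: list[dict] = []
    labels: list[int] = []
    pids: list[str] = []
    drop_log: list[dict] = []
    for member in cohort:
        meta = member.metadata
        if task == "binary":
            label = assign_binary_label(member.group)
        elif task == "severity":
            madrs = getattr(meta, madrs_source)
            if madrs is None:
                if member.group.value == "control":
                    label = 0
                else:
                    drop_log.append(
                        {"participant_id": meta.number,
                         "reason": f"missing {madrs_source} for severity label"}
                    )
                    continue
            else:
                label = assign_severity_label(madrs)
        else:
            raise ValueError(f"unknown task {task!r}")
        age = age_band_midpoint(meta.age_band)
        windows, gap_log = window_recording(
            member.recording, cfg.window_length, cfg.gap_tolerance
        )
        drop_log.extend(gap_log)
        for w in windows:
            feats, reason = extract_window_features(w, cfg)
            if feats is None:
                drop_log.append(
                    {"participant_id": meta.number, "start": str(w.start),
                     "reason": reason}
                )
                continue
            feats["age"] = age
            feats["gender"] = float(meta.gender)
            rows.append(feats)
            labels.append(label)
            pids.append(member.participant_id)
    if not rows:
        raise ValidationError("all windows were dropped during extraction")
    frame = pd.DataFrame(rows, columns=list(FEATURE_NAMES))
    return FeatureMatrix(
        frame=frame,
        labels=np.asarray(labels, dtype=int),
        participant_ids=np.asarray(pids, dtype=object),
        drop_log=drop_log,
    )


# ---------------------------------------------------------------------------
# z-score standardisation: z = (x - mu) / sigma per feature, population sigma


@dataclass
class ScalerParams:
    """Fitted per-feature mean and (population) standard deviation."""

    mu: np.ndarray
    sigma: np.ndarray
    feature_names: list[str]

    def to_dict(self) -> dict:
        return {
            "mu": self.mu.tolist(),
            "sigma": self.sigma.tolist(),
            "feature_names": self.feature_names,
        }


class FeatureScaler:
    """sklearn-style z-score scaler that preserves DataFrame column names.

    Wraps :class:`sklearn.preprocessing.StandardScaler` (population sigma);
    constant columns map to all-zeros with a warning rather than dividing
    by zero. Fit on training rows only.
    """

    def __init__(self) -> None:
        self._scaler: Optional[StandardScaler] = None
        self._names: Optional[list[str]] = None

    def fit(self, frame: pd.DataFrame) -> "FeatureScaler":
        self._scaler = StandardScaler().fit(frame.to_numpy(dtype=float))
        self._names = list(frame.columns)
        constant = [
            n for n, s in zip(self._names, np.sqrt(self._scaler.var_)) if s == 0.0
        ]
        if constant:
            warnings.warn(
                f"constant feature column(s) map to zeros: {', '.join(constant)}",
                stacklevel=2,
            )
        return self

    @property
    def params_(self) -> ScalerParams:
        if self._scaler is None:
            raise ValidationError("scaler has not been fitted")
        return ScalerParams(
            mu=self._scaler.mean_.copy(),
            sigma=np.sqrt(self._scaler.var_),
            feature_names=list(self._names),
        )

    def transform(self, frame: pd.DataFrame) -> pd.DataFrame:
        if self._scaler is None:
            raise ValidationError("scaler has not been fitted")
        if list(frame.columns) != self._names:
            raise ValidationError("feature columns differ from the fit set")
        z = self._scaler.transform(frame.to_numpy(dtype=float))
        return pd.DataFrame(z, columns=self._names, index=frame.index)

    def fit_transform(self, frame: pd.DataFrame) -> pd.DataFrame:
        return self.fit(frame).transform(frame)


def fit_scaler(train: pd.DataFrame | FeatureMatrix) -> FeatureScaler:
    frame = train.frame if isinstance(train, FeatureMatrix) else train
    return FeatureScaler().fit(frame)


def apply_scaler(
    scaler: FeatureScaler, matrix: pd.DataFrame | FeatureMatrix
) -> pd.DataFrame:
    frame = matrix.frame if isinstance(matrix, FeatureMatrix) else matrix
    return scaler.transform(frame)
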