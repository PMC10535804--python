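"""Windowing and the 33-feature vector for 1-second accelerometer windows.

Each preprocessed call is cut into 100-sample windows with 50% overlap and
summarised by 33 time-, frequency- and energy-domain features:

* 18 per-axis statistics — max, min, mean, population std, excess kurtosis,
  skewness for each of x, y, z;
* 1 zero-crossing rate of the mean-removed magnitude signal;
* 3 inter-axis Pearson correlations (xy, xz, yz);
* 9 spectral features of the mean-removed magnitude's power spectral
  density — max, mean, std of the PSD, spectral centroid, 85% rolloff,
  flatness, PSD-weighted skewness and excess kurtosis of frequency about
  the centroid, and Shannon spectral entropy;
* 2 energy features — total energy and signal magnitude area over all axes.

The order of `FEATURE_NAMES` is the canonical order and is part of the
classifier's input contract (the model consumes the vector as a length-33
sequence).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .io_preprocess import Recording, SubjectMeta

logger = logging.getLogger(__name__)

N_FEATURES = 33
PSD_EPS = 1e-12  # floor for log(psd) in flatness/entropy

_AXES = ("x", "y", "z")
_TIME_STATS = ("max", "min", "mean", "std", "kurtosis", "skewness")

FEATURE_NAMES: tuple[str, ...] = (
    tuple(f"{stat}_{ax}" for stat in _TIME_STATS for ax in _AXES)
    + ("zero_crossing_rate", "corr_xy", "corr_xz", "corr_yz")
    + (
        "psd_max",
        "psd_mean",
        "psd_std",
        "spectral_centroid",
        "spectral_rolloff",
        "spectral_flatness",
        "spectral_skewness",
        "spectral_kurtosis",
        "spectral_entropy",
    )
    + ("total_energy", "signal_magnitude_area")
)
assert len(FEATURE_NAMES) == N_FEATURES


@dataclass(frozen=True)
class WindowConfig:
    """window_size in samples (100 = 1 s at 100 Hz); overlap_fraction in [0, 1)."""

    window_size: int = 100
    overlap_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.window_size < 2:
            raise ValueError("window_size must be >= 2")
        if not 0.0 <= self.overlap_fraction < 1.0:
            raise ValueError("overlap_fraction must be in [0, 1)")
        if self.step < 1:
            raise ValueError("window step must be >= 1")

    @property
    def step(self) -> int:
        return int(round(self.window_size * (1.0 - self.overlap_fraction)))


@dataclass
class FeatureWindow:
    """One window's 33 features plus provenance and subject label."""

    subject_id: str
    call_id: str
    window_index: int
    features: np.ndarray
    label: int

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.shape != (N_FEATURES,):
            raise ValueError(f"features must have shape ({N_FEATURES},)")
        if not np.all(np.isfinite(self.features)):
            raise ValueError("features must be finite")


def make_windows(
    rec: Recording, cfg: WindowConfig | None = None
) -> list[tuple[int, np.ndarray]]:
    """Cut a recording into overlapping (window_index, (window_size, 3)) segments.

    Trailing samples that do not fill a window are discarded; a recording
    shorter than one window yields an empty list (logged).
    """
    cfg = cfg or WindowConfig()
    data = rec.xyz
    n = data.shape[0]
    if n < cfg.window_size:
        logger.info(
            "recording %s/%s has %d samples < window %d; no windows",
            rec.subject_id, rec.call_id, n, cfg.window_size,
        )
        return []
    starts = range(0, n - cfg.window_size + 1, cfg.step)
    return [(i, data[s : s + cfg.window_size]) for i, s in enumerate(starts)]


def _magnitude_centered(seg: np.ndarray) -> np.ndarray:
    mag = np.sqrt(np.sum(seg * seg, axis=1))
    return mag - mag.mean()


def _moments(v: np.ndarray) -> tuple[float, float, float]:
    """Population std, excess kurtosis, skewness; 0/0 conventions -> 0."""
    c = v - v.mean()
    m2 = float(np.mean(c**2))
    if m2 == 0.0:
        return 0.0, 0.0, 0.0
    m3 = float(np.mean(c**3))
    m4 = float(np.mean(c**4))
    return np.sqrt(m2), m4 / m2**2 - 3.0, m3 / m2**1.5


def _corr(a: np.ndarray, b: np.ndarray) -> float:
    ca, cb = a - a.mean(), b - b.mean()
    denom = np.sqrt(np.sum(ca**2) * np.sum(cb**2))
    if denom == 0.0:
        return 0.0  # correlation with a zero-variance axis
    return float(np.sum(ca * cb) / denom)


def time_features(seg: np.ndarray) -> np.ndarray:
    """The 22 time-domain features of a (N, 3) segment.

    18 per-axis statistics in stat-major order, then the zero-crossing rate
    of the mean-removed magnitude, then the three pairwise correlations.
    Degenerate (zero-variance) axes get kurtosis/skewness/correlation 0.
    """
    seg = np.asarray(seg, dtype=float)
    if seg.ndim != 2 or seg.shape[1] != 3 or seg.shape[0] < 2:
        raise ValueError("segment must be (N>=2, 3)")
    maxs = seg.max(axis=0)
    mins = seg.min(axis=0)
    means = seg.mean(axis=0)
    stds, kurts, skews = zip(*(_moments(seg[:, j]) for j in range(3)))

    mag = _magnitude_centered(seg)
    signs = mag[:-1] * mag[1:]
    zcr = float(np.count_nonzero(signs < 0)) / (len(mag) - 1)

    corrs = [_corr(seg[:, a], seg[:, b]) for a, b in ((0, 1), (0, 2), (1, 2))]
    return np.concatenate([maxs, mins, means, stds, kurts, skews, [zcr], corrs])


def periodogram_psd(
    v: np.ndarray, rate_hz: float, taper: str = "hann"
) -> tuple[np.ndarray, np.ndarray]:
    """One-sided PSD estimate of a 1-D signal (frequencies, psd)."""
    freqs, psd = sps.periodogram(v, fs=rate_hz, window=taper, detrend=False)
    return freqs, psd


def spectral_features(
    seg: np.ndarray, rate_hz: float, taper: str = "hann"
) -> np.ndarray:
    """The 9 spectral features of the mean-removed magnitude signal.

    PSD via a single Hann-tapered periodogram over the whole 1 s window (no
    sub-segment averaging — the window is too short for it). An all-zero
    spectrum returns a zero vector; zero PSD bins are floored at 1e-12
    inside the logs for flatness and entropy.
    """
    seg = np.asarray(seg, dtype=float)
    if seg.shape[0] < 8:
        raise ValueError("segment too short for spectral features (N >= 8)")
    freqs, psd = periodogram_psd(_magnitude_centered(seg), rate_hz, taper)
    total = float(psd.sum())
    if total == 0.0:
        return np.zeros(9)

    p = psd / total
    centroid = float(np.sum(freqs * p))
    cum = np.cumsum(psd)
    rolloff = float(freqs[np.searchsorted(cum, 0.85 * total)])
    flatness = float(np.exp(np.mean(np.log(np.maximum(psd, PSD_EPS)))) / psd.mean())
    var_f = float(np.sum(p * (freqs - centroid) ** 2))
    if var_f > 0.0:
        sd_f = np.sqrt(var_f)
        spec_skew = float(np.sum(p * ((freqs - centroid) / sd_f) ** 3))
        spec_kurt = float(np.sum(p * ((freqs - centroid) / sd_f) ** 4)) - 3.0
    else:
        spec_skew = 0.0
        spec_kurt = 0.0
    nz = p[p > 0]
    entropy = float(-np.sum(nz * np.log2(nz)))
    return np.array(
        [psd.max(), psd.mean(), psd.std(), centroid, rolloff, flatness,
         spec_skew, spec_kurt, entropy]
    )


def energy_features(seg: np.ndarray) -> np.ndarray:
    """Total energy Σ(x²+y²+z²) and signal magnitude area Σ(|x|+|y|+|z|)."""
    seg = np.asarray(seg, dtype=float)
    return np.array([float(np.sum(seg * seg)), float(np.sum(np.abs(seg)))])


def extract_features(seg: np.ndarray, rate_hz: float = 100.0) -> np.ndarray:
    """The full 33-vector [time(22), spectral(9), energy(2)] for one window."""
    vec = np.concatenate(
        [time_features(seg), spectral_features(seg, rate_hz), energy_features(seg)]
    )
    if not np.all(np.isfinite(vec)):  # conventions above should prevent this
        raise AssertionError("non-finite feature value")
    return vec


def build_feature_matrix(
    recordings: list[Recording],
    meta: list[SubjectMeta],
    wcfg: WindowConfig | None = None,
) -> list[FeatureWindow]:
    """One labelled FeatureWindow per window of every recording.

    Labels come from each subject's pd_status; a recording whose subject is
    missing from the metadata raises. Standardisation is done downstream at
    split time (train-set statistics only) via :func:`standardize`.
    """
    wcfg = wcfg or WindowConfig()
    labels = {m.subject_id: m.pd_status for m in meta}
    out: list[FeatureWindow] = []
    for rec in recordings:
        if rec.subject_id not in labels:
            raise KeyError(f"subject {rec.subject_id!r} has no metadata row")
        for idx, seg in make_windows(rec, wcfg):
            out.append(
                FeatureWindow(
                    subject_id=rec.subject_id,
                    call_id=rec.call_id,
                    window_index=idx,
                    features=extract_features(seg, rec.sample_rate_hz),
                    label=labels[rec.subject_id],
                )
            )
    return out


def standardize(
    X: np.ndarray, mean: np.ndarray | None = None, std: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-feature z-score. Fit on the training split only and reuse the
    returned (mean, std) for validation/test data. Zero-variance features
    are left centred but unscaled."""
    X = np.asarray(X, dtype=float)
    if mean is None:
        mean = X.mean(axis=0)
        std = X.std(axis=0)
    std_safe = np.where(std == 0.0, 1.0, std)
    return (X - mean) / std_safe, mean, std


def to_arrays(windows: list[FeatureWindow]) -> tuple[np.ndarray, np.ndarray]:
    """Stack FeatureWindows into (X: (n, 33), y: (n,))."""
    X = np.stack([w.features for w in windows])
    y = np.array([w.label for w in windows], dtype=int)
    return X, y


def to_dataframe(windows: list[FeatureWindow]):
    """Feature matrix as a pandas DataFrame (provenance + f columns + label)."""
    import pandas as pd

    rows = []
    for w in windows:
        row = {"subject_id": w.subject_id, "call_id": w.call_id,
               "window_index": w.window_index}
        row.update(dict(zip(FEATURE_NAMES, w.features)))
        row["label"] = w.label
        rows.append(row)
    return pd.DataFrame(rows)
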