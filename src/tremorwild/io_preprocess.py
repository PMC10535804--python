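"""Loading, cohort selection and signal conditioning for phone-call accelerometry.

Recordings are per-call triaxial acceleration traces (m/s²). The pipeline
selects subjects by self-reported tremor score (UPDRS item 16), regularises
each trace onto a uniform 100 Hz grid and low-pass filters it at 12 Hz —
the band that contains essentially all Parkinsonian-tremor information.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

logger = logging.getLogger(__name__)

METADATA_COLUMNS = ("subject_id", "pd_status", "updrs16", "updrs20", "updrs21")
SIGNAL_COLUMNS = ("timestamp", "x", "y", "z")

G_MSS = 9.80665  # standard gravity, for g -> m/s² conversion


class SchemaError(ValueError):
    """A data file does not match the expected column schema."""


@dataclass
class Recording:
    """One phone call's triaxial acceleration trace.

    timestamps are seconds (monotone increasing); x, y, z are accelerations
    in m/s², all the same length. sample_rate_hz is the nominal rate;
    ``uniform`` records whether the grid is uniform to 1e-9 s.
    """

    subject_id: str
    call_id: str
    timestamps: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    sample_rate_hz: float
    uniform: bool = True

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        n = len(self.timestamps)
        if not (len(self.x) == len(self.y) == len(self.z) == n):
            raise ValueError("timestamps, x, y, z must have equal length")
        if n >= 2 and not np.all(np.diff(self.timestamps) > 0):
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.timestamps)

    @property
    def xyz(self) -> np.ndarray:
        """(n, 3) array of the three axes."""
        return np.column_stack([self.x, self.y, self.z])

    @property
    def duration_s(self) -> float:
        return float(self.timestamps[-1] - self.timestamps[0])


@dataclass(frozen=True)
class SubjectMeta:
    subject_id: str
    pd_status: int
    updrs16: int
    updrs20: int
    updrs21: int

    def __post_init__(self) -> None:
        if self.pd_status not in (0, 1):
            raise ValueError(f"pd_status must be 0 or 1, got {self.pd_status}")


@dataclass(frozen=True)
class PreprocessConfig:
    """Signal-conditioning settings.

    target_rate_hz: uniform output rate (Hz). cutoff_hz: Butterworth low-pass
    cutoff (Hz); must sit below the output Nyquist. filter_order: Butterworth
    order (effective order doubles under zero-phase application).
    input_units: 'mss' (m/s², canonical) or 'g' (converted on load).
    """

    target_rate_hz: float = 100.0
    cutoff_hz: float = 12.0
    filter_order: int = 4
    zero_phase: bool = True
    input_units: str = "mss"

    def __post_init__(self) -> None:
        if self.cutoff_hz >= self.target_rate_hz / 2:
            raise ValueError(
                f"cutoff_hz={self.cutoff_hz} must be below the Nyquist "
                f"frequency {self.target_rate_hz / 2}"
            )
        if self.input_units not in ("mss", "g"):
            raise ValueError("input_units must be 'mss' or 'g'")


def read_metadata(metadata_path: str | Path) -> list[SubjectMeta]:
    """Read the subject metadata CSV (subject_id,pd_status,updrs16,updrs20,updrs21)."""
    df = pd.read_csv(metadata_path)
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{metadata_path}: missing metadata column(s): {', '.join(missing)}"
        )
    return [
        SubjectMeta(
            subject_id=str(row.subject_id),
            pd_status=int(row.pd_status),
            updrs16=int(row.updrs16),
            updrs20=int(row.updrs20),
            updrs21=int(row.updrs21),
        )
        for row in df.itertuples(index=False)
    ]


def _infer_rate(timestamps: np.ndarray) -> tuple[float, bool]:
    dt = np.diff(timestamps)
    med = float(np.median(dt))
    uniform = bool(np.all(np.abs(dt - med) < 1e-9))
    return 1.0 / med, uniform


def read_signal_file(path: str | Path, input_units: str = "mss") -> Recording:
    """Read one per-call signal CSV named ``<subject_id>__<call_id>.csv``.

    Columns: timestamp (s), x, y, z (acceleration). Raises SchemaError on a
    malformed header and ValueError on non-monotone timestamps.
    """
    path = Path(path)
    stem = path.stem
    if "__" in stem:
        subject_id, call_id = stem.split("__", 1)
    else:
        subject_id, call_id = stem, "call0"
    df = pd.read_csv(path)
    missing = [c for c in SIGNAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing signal column(s): {', '.join(missing)}")
    scale = G_MSS if input_units == "g" else 1.0
    ts = df["timestamp"].to_numpy(dtype=float)
    rate, uniform = _infer_rate(ts) if len(ts) >= 2 else (float("nan"), True)
    return Recording(
        subject_id=subject_id,
        call_id=call_id,
        timestamps=ts,
        x=df["x"].to_numpy(dtype=float) * scale,
        y=df["y"].to_numpy(dtype=float) * scale,
        z=df["z"].to_numpy(dtype=float) * scale,
        sample_rate_hz=rate,
        uniform=uniform,
    )


def load_dataset(
    signal_dir: str | Path,
    metadata_path: str | Path,
    input_units: str = "mss",
) -> tuple[list[Recording], list[SubjectMeta]]:
    """Load all per-call signal CSVs under ``signal_dir`` plus the metadata table.

    Recordings with non-monotone timestamps are rejected with a warning (not
    fatal); a recording whose subject is absent from the metadata raises.
    """
    meta = read_metadata(metadata_path)
    known = {m.subject_id for m in meta}
    recordings: list[Recording] = []
    for path in sorted(Path(signal_dir).glob("*.csv")):
        try:
            rec = read_signal_file(path, input_units=input_units)
        except SchemaError:
            raise
        except ValueError as exc:
            logger.warning("rejecting %s: %s", path.name, exc)
            continue
        if rec.subject_id not in known:
            raise KeyError(
                f"{path.name}: subject {rec.subject_id!r} not present in metadata"
            )
        recordings.append(rec)
    return recordings, meta


def filter_cohort(meta: list[SubjectMeta], max_updrs16: int = 1) -> list[SubjectMeta]:
    """Select subjects whose self-reported tremor score (UPDRS-16) is ≤ max_updrs16.

    max_updrs16=1 reproduces the main study cohort (minor or no self-reported
    tremor); max_updrs16=0 the tremor-unaware sub-cohort. Order preserved.
    """
    if max_updrs16 < 0:
        raise ValueError("max_updrs16 must be >= 0")
    return [m for m in meta if m.updrs16 <= max_updrs16]


def resample(rec: Recording, target_rate_hz: float = 100.0) -> Recording:
    """Resample a recording onto a uniform grid at ``target_rate_hz``.

    Uniformly sampled input is decimated/interpolated with polyphase
    filtering (anti-aliased); irregular timestamps are linearly interpolated
    onto the uniform grid. Duration is preserved to within one sample period.
    """
    if len(rec) < 2:
        raise ValueError("cannot resample a recording with fewer than 2 samples")
    t0 = rec.timestamps[0]
    if rec.uniform:
        ratio = Fraction(target_rate_hz / rec.sample_rate_hz).limit_denominator(1000)
        up, down = ratio.numerator, ratio.denominator
        if up == down:
            out = rec.xyz.copy()
        else:
            out = sps.resample_poly(rec.xyz, up, down, axis=0)
        n_out = out.shape[0]
    else:
        duration = rec.timestamps[-1] - t0
        n_out = int(math.floor(duration * target_rate_hz)) + 1
        grid = t0 + np.arange(n_out) / target_rate_hz
        out = np.column_stack(
            [np.interp(grid, rec.timestamps, a) for a in (rec.x, rec.y, rec.z)]
        )
    new_ts = t0 + np.arange(n_out) / target_rate_hz
    return replace(
        rec,
        timestamps=new_ts,
        x=out[:, 0],
        y=out[:, 1],
        z=out[:, 2],
        sample_rate_hz=float(target_rate_hz),
        uniform=True,
    )


def lowpass(rec: Recording, cfg: PreprocessConfig) -> Recording:
    """Butterworth low-pass each axis at cfg.cutoff_hz.

    Zero-phase (forward-backward) application by default so window
    alignment downstream is not phase-distorted; DC gain is exactly 1.
    """
    nyq = rec.sample_rate_hz / 2
    if cfg.cutoff_hz >= nyq:
        raise ValueError(
            f"cutoff {cfg.cutoff_hz} Hz >= Nyquist {nyq} Hz at rate "
            f"{rec.sample_rate_hz} Hz"
        )
    sos = sps.butter(
        cfg.filter_order, cfg.cutoff_hz, btype="low", fs=rec.sample_rate_hz, output="sos"
    )
    if cfg.zero_phase:
        out = sps.sosfiltfilt(sos, rec.xyz, axis=0)
    else:
        out = sps.sosfilt(sos, rec.xyz, axis=0)
    return replace(rec, x=out[:, 0], y=out[:, 1], z=out[:, 2])


def preprocess(rec: Recording, cfg: PreprocessConfig | None = None) -> Recording:
    """Full conditioning: regularise, low-pass at the native rate, then decimate.

    The low-pass is applied before decimation so the downsampling step cannot
    alias; since the cutoff sits below the output Nyquist the result is
    equivalent to filtering after downsampling, without the aliasing risk.
    """
    cfg = cfg or PreprocessConfig()
    if not rec.uniform:
        rec = resample(rec, rec.sample_rate_hz)  # regularise jittered clocks
    if rec.sample_rate_hz / 2 > cfg.cutoff_hz and rec.sample_rate_hz > cfg.target_rate_hz:
        rec = lowpass(rec, cfg)
        rec = resample(rec, cfg.target_rate_hz)
    else:
        rec = resample(rec, cfg.target_rate_hz)
        rec = lowpass(rec, cfg)
    return rec


def preprocess_dataset(
    recordings: list[Recording],
    cfg: PreprocessConfig | None = None,
    min_samples: int = 100,
) -> list[Recording]:
    """Preprocess every recording, dropping calls shorter than ``min_samples``."""
    cfg = cfg or PreprocessConfig()
    out: list[Recording] = []
    dropped = 0
    for rec in recordings:
        if len(rec) < 2:
            dropped += 1
            continue
        pp = preprocess(rec, cfg)
        if len(pp) < min_samples:
            dropped += 1
            continue
        out.append(pp)
    if dropped:
        logger.info("dropped %d recording(s) shorter than %d samples", dropped, min_samples)
    return out
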