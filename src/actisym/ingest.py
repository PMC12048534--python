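"""Raw actigraphy ingestion, calibration, and epoch-level reduction.

A recording is a uniformly sampled stream of tri-axial acceleration (g),
skin temperature (°C) and ambient light (lux).  This module validates and
calibrates the stream and reduces it to the epoch grids the downstream
detectors consume:

* a 1-minute grid carrying mean ENMO, ROCAM, smoothed temperature
  (5-minute rolling mean of minute means) and mean light;
* a 5-second grid carrying the z-axis elevation angle computed on
  per-epoch axis medians (used by sustained-inactivity sleep detection).

Conventions: all intervals are half-open ``[start, end)``; timestamps are
local civil time without DST adjustment; epoch grids are aligned to the
recording start.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

RAW_COLUMNS = ["timestamp", "ax_g", "ay_g", "az_g", "temp_c", "light_lux"]

__all__ = [
    "RAW_COLUMNS",
    "RawRecording",
    "CalibrationParams",
    "EpochFrame",
    "read_raw",
    "write_raw",
    "calibrate",
    "enmo",
    "rocam",
    "epochize",
]


@dataclass
class RawRecording:
    """A uniformly sampled tri-axial acceleration + temperature + light stream."""

    participant_id: str
    start_time: pd.Timestamp
    sample_rate: float  # Hz
    ax: np.ndarray  # g
    ay: np.ndarray
    az: np.ndarray
    temperature: np.ndarray  # °C
    light: np.ndarray  # lux
    wrist: str = "non-dominant"  # or "dominant"
    calibrated: bool = False

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        n = len(self.ax)
        for name in ("ay", "az", "temperature", "light"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"channel {name!r} length mismatch")

    @property
    def n_samples(self) -> int:
        return len(self.ax)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate

    def timestamps(self) -> pd.DatetimeIndex:
        step = pd.Timedelta(seconds=1.0 / self.sample_rate)
        return pd.date_range(self.start_time, periods=self.n_samples, freq=step)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "timestamp": self.timestamps(),
                "ax_g": self.ax,
                "ay_g": self.ay,
                "az_g": self.az,
                "temp_c": self.temperature,
                "light_lux": self.light,
            }
        )


@dataclass
class CalibrationParams:
    """Per-axis offsets (g) and gains applied as ``(value - offset) * gain``."""

    offset: tuple[float, float, float] = (0.0, 0.0, 0.0)
    gain: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        if not all(np.isfinite(self.offset)) or not all(np.isfinite(self.gain)):
            raise ValueError("calibration parameters must be finite")
        if any(g <= 0 for g in self.gain):
            raise ValueError("gains must be positive")


@dataclass
class EpochFrame:
    """Per-epoch derived series on the 1-minute and 5-second grids.

    ``minute`` columns: enmo (g), rocam (g per sample interval), t_smooth
    (°C), light_mean (lux), wear (filled by the non-wear module).
    ``five_sec`` columns: z_angle (degrees in [-90, 90]).
    """

    start_time: pd.Timestamp
    minute: pd.DataFrame
    five_sec: pd.DataFrame
    sample_rate: float

    @property
    def n_minutes(self) -> int:
        return len(self.minute)


def write_raw(recording: RawRecording, path: str | Path) -> None:
    """Write a recording to the raw CSV/Parquet schema (by extension)."""
    path = Path(path)
    df = recording.to_frame()
    if path.suffix == ".parquet":
        df.to_parquet(path, index=False)
    else:
        df.to_csv(path, index=False)


def read_raw(
    path: str | Path,
    *,
    participant_id: str | None = None,
    wrist: str = "non-dominant",
    rel_tol: float = 1e-3,
) -> RawRecording:
    """Read and validate a raw actigraphy file (CSV or Parquet).

    Timestamps must be strictly increasing and uniformly spaced within
    ``rel_tol`` of the modal interval; gaps larger than one sample are
    reported as warnings, non-monotone timestamps are rejected.
    """
    path = Path(path)
    if path.suffix == ".parquet":
        df = pd.read_parquet(path)
    else:
        df = pd.read_csv(path, parse_dates=["timestamp"])
    missing = [c for c in RAW_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"raw schema error: missing column(s) {', '.join(missing)}")
    ts = pd.to_datetime(df["timestamp"])
    if len(df) < 2:
        raise ValueError("recording must contain at least two samples")
    dt = np.diff(ts.to_numpy().astype("datetime64[ns]").astype("int64")) / 1e9
    if np.any(dt <= 0):
        raise ValueError("non-monotone timestamps")
    step = float(np.median(dt))
    gaps = np.nonzero(dt > step * (1 + rel_tol))[0]
    if gaps.size:
        warnings.warn(f"{gaps.size} sampling gap(s) larger than one sample interval")
    off_grid = np.abs(dt - step) > step * rel_tol
    if np.mean(off_grid) > 0.01:
        raise ValueError("non-uniform sampling beyond tolerance")
    return RawRecording(
        participant_id=participant_id or path.stem,
        start_time=pd.Timestamp(ts.iloc[0]),
        sample_rate=1.0 / step,
        ax=df["ax_g"].to_numpy(float),
        ay=df["ay_g"].to_numpy(float),
        az=df["az_g"].to_numpy(float),
        temperature=df["temp_c"].to_numpy(float),
        light=df["light_lux"].to_numpy(float),
        wrist=wrist,
    )


def calibrate(recording: RawRecording, params: CalibrationParams) -> RawRecording:
    """Apply per-axis offset/gain calibration: ``axis <- (axis - offset) * gain``."""
    if recording.calibrated:
        raise ValueError("recording is already calibrated")
    ox, oy, oz = params.offset
    gx, gy, gz = params.gain
    return replace(
        recording,
        ax=(recording.ax - ox) * gx,
        ay=(recording.ay - oy) * gy,
        az=(recording.az - oz) * gz,
        calibrated=True,
    )


def enmo(ax: np.ndarray, ay: np.ndarray, az: np.ndarray) -> np.ndarray:
    """Euclidean Norm Minus One with negative values truncated to zero (g)."""
    return np.maximum(np.sqrt(np.asarray(ax) ** 2 + np.asarray(ay) ** 2 + np.asarray(az) ** 2) - 1.0, 0.0)


def rocam(magnitude: np.ndarray) -> float:
    """Rate-of-change acceleration movement summary for one epoch.

    Convention adopted here: the mean absolute first difference of the
    acceleration vector magnitude across the epoch's samples (units: g per
    sample interval).  The statistic is zero for a frozen signal and scales
    linearly with the amplitude of within-epoch fluctuation.
    """
    m = np.asarray(magnitude, float)
    if m.size < 2:
        return float("nan")
    return float(np.mean(np.abs(np.diff(m))))


def _block_reduce(x: np.ndarray, block: int, fn) -> np.ndarray:
    n = (len(x) // block) * block
    return fn(x[:n].reshape(-1, block), axis=1)


def epochize(recording: RawRecording, *, smooth_minutes: int = 5) -> EpochFrame:
    """Reduce a calibrated recording to the 1-minute and 5-second epoch grids.

    Trailing partial epochs are dropped.  ``t_smooth`` is the centered
    ``smooth_minutes``-minute rolling mean of the minute-mean temperature.
    """
    rate = recording.sample_rate
    spm = rate * 60.0
    sp5 = rate * 5.0
    if abs(spm - round(spm)) > 1e-9 or abs(sp5 - round(sp5)) > 1e-9:
        raise ValueError("sample_rate must yield an integer number of samples per 5 s")
    spm, sp5 = int(round(spm)), int(round(sp5))
    if recording.n_samples < spm:
        warnings.warn("recording shorter than one minute; empty epoch frame")
    mag = np.sqrt(recording.ax**2 + recording.ay**2 + recording.az**2)
    e = np.maximum(mag - 1.0, 0.0)

    n_min = recording.n_samples // spm
    enmo_min = _block_reduce(e, spm, np.mean)
    mag_blocks = mag[: n_min * spm].reshape(-1, spm)
    rocam_min = np.abs(np.diff(mag_blocks, axis=1)).mean(axis=1) if spm >= 2 else np.full(n_min, np.nan)
    t_min = _block_reduce(recording.temperature, spm, np.mean)
    light_min = _block_reduce(recording.light, spm, np.mean)
    t_smooth = (
        pd.Series(t_min).rolling(smooth_minutes, center=True, min_periods=1).mean().to_numpy()
    )
    minute_index = pd.date_range(recording.start_time, periods=n_min, freq="1min")
    minute = pd.DataFrame(
        {
            "enmo": enmo_min,
            "rocam": rocam_min,
            "t_smooth": t_smooth,
            "light_mean": light_min,
            "wear": np.ones(n_min, dtype=bool),
        },
        index=minute_index,
    )

    ax5 = _block_reduce(recording.ax, sp5, np.median)
    ay5 = _block_reduce(recording.ay, sp5, np.median)
    az5 = _block_reduce(recording.az, sp5, np.median)
    with np.errstate(invalid="ignore"):
        z_angle = np.degrees(np.arctan2(az5, np.sqrt(ax5**2 + ay5**2)))
    five_index = pd.date_range(recording.start_time, periods=len(z_angle), freq="5s")
    five = pd.DataFrame({"z_angle": z_angle}, index=five_index)
    return EpochFrame(
        start_time=recording.start_time, minute=minute, five_sec=five, sample_rate=rate
    )
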