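"""Two-pass temperature + movement non-wear detection.

The device's skin-contact temperature sensor gives a clear wear signal:
on-wrist temperature sits near skin temperature (~31 °C) while off-wrist
it relaxes toward ambient.  The detector runs two passes over the
1-minute epoch grid:

Pass 1 (long non-wear, >= 90 min).  Candidate minutes are those where the
smoothed temperature is below a threshold T0 = max(26 °C, 5th percentile
of all readings) or the minute-to-minute temperature change is below
-0.5 °C.  Maximal candidate runs of at least 90 minutes whose mean ROCAM
is below 0.025 are non-wear, and two detected runs separated by fewer
than 15 minutes are fused together with the gap.

Pass 2 (short non-wear, 15-90 min).  A second threshold T1 is derived
from the pass-1 worn minutes: one standard deviation below the mean worn
temperature, capped at 24 °C; overridden by the 5th percentile of all
readings when that is larger; forced to 24 °C when fewer than 3 full
days were worn after pass 1.  Candidate runs outside pass-1 intervals of
length in [15, 90) minutes with mean ROCAM below 0.025 are kept only
when the mean smoothed temperature over the run's first 5 minutes
exceeds that over its last 5 minutes by at least 2 °C (the signature
sudden drop of a short removal).

All intervals are half-open minute index pairs ``[start, end)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from actisym.ingest import EpochFrame

__all__ = [
    "NonwearConfig",
    "WearMask",
    "compute_t0",
    "compute_t1",
    "detect_long_nonwear",
    "detect_short_nonwear",
    "wear_mask",
    "runs_of",
]


@dataclass
class NonwearConfig:
    t0_floor: float = 26.0  # °C
    t1_cap: float = 24.0  # °C
    t_drop_rate: float = -0.5  # °C per minute
    long_min: int = 90  # minutes
    short_min: int = 15
    short_max: int = 90  # exclusive; runs of exactly 90 min belong to pass 1
    merge_gap: int = 15
    rocam_thresh: float = 0.025
    short_temp_drop: float = 2.0  # °C
    min_worn_days_for_t1: int = 3  # full days = 1440 min each
    rocam_stat: Literal["mean", "median"] = "mean"

    def __post_init__(self) -> None:
        for name in ("long_min", "short_min", "short_max", "merge_gap"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class WearMask:
    """Minute-level wear mask with per-minute provenance.

    ``worn`` is a boolean array on the recording's minute grid;
    ``provenance`` holds '' for worn minutes and one of
    {'pass1', 'pass2', 'merged-gap'} for non-wear minutes.
    """

    index: pd.DatetimeIndex
    worn: np.ndarray
    provenance: np.ndarray
    pass1_intervals: list[tuple[int, int]] = field(default_factory=list)
    pass2_intervals: list[tuple[int, int]] = field(default_factory=list)

    def wear_fraction(self) -> float:
        return float(np.mean(self.worn)) if len(self.worn) else float("nan")

    def intervals_frame(self) -> pd.DataFrame:
        """Non-wear intervals as a table of (start, end, pass)."""
        rows = [
            {"start": self.index[a], "end": self.index[a] + pd.Timedelta(minutes=b - a), "pass": name}
            for ivals, name in ((self.pass1_intervals, "pass1"), (self.pass2_intervals, "pass2"))
            for a, b in ivals
        ]
        return pd.DataFrame(rows, columns=["start", "end", "pass"])


def runs_of(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True in a boolean array, as half-open index pairs."""
    m = np.asarray(mask, bool)
    if m.size == 0:
        return []
    edges = np.flatnonzero(np.diff(np.concatenate(([False], m, [False])).astype(np.int8)))
    return list(zip(edges[::2].tolist(), edges[1::2].tolist()))


def compute_t0(t_smooth: np.ndarray, config: NonwearConfig | None = None) -> float:
    """T0 = max(26 °C, 5th percentile of all smoothed temperature readings)."""
    config = config or NonwearConfig()
    t = np.asarray(t_smooth, float)
    t = t[np.isfinite(t)]
    if t.size == 0:
        raise ValueError("no valid temperature readings")
    return float(max(config.t0_floor, np.percentile(t, 5)))


def _candidate_minutes(t_smooth: np.ndarray, threshold: float, config: NonwearConfig) -> np.ndarray:
    t = np.asarray(t_smooth, float)
    dt = np.diff(t, prepend=np.nan)
    with np.errstate(invalid="ignore"):
        cand = (t < threshold) | (dt < config.t_drop_rate)
    return cand & np.isfinite(t)


def _rocam_stat(rocam: np.ndarray, a: int, b: int, config: NonwearConfig) -> float:
    seg = np.asarray(rocam, float)[a:b]
    seg = seg[np.isfinite(seg)]
    if seg.size == 0:
        return float("inf")
    return float(np.mean(seg) if config.rocam_stat == "mean" else np.median(seg))


def detect_long_nonwear(
    epochs: EpochFrame | pd.DataFrame,
    t0: float,
    config: NonwearConfig | None = None,
) -> list[tuple[int, int]]:
    """Pass-1 non-wear intervals (>= 90 min), fused across gaps < 15 min."""
    config = config or NonwearConfig()
    minute = epochs.minute if isinstance(epochs, EpochFrame) else epochs
    cand = _candidate_minutes(minute["t_smooth"].to_numpy(), t0, config)
    rocam = minute["rocam"].to_numpy()
    kept = [
        (a, b)
        for a, b in runs_of(cand)
        if b - a >= config.long_min and _rocam_stat(rocam, a, b, config) < config.rocam_thresh
    ]
    # fuse runs separated by less than merge_gap minutes, including the gap
    fused: list[tuple[int, int]] = []
    for a, b in kept:
        if fused and a - fused[-1][1] < config.merge_gap:
            fused[-1] = (fused[-1][0], b)
        else:
            fused.append((a, b))
    return fused


def compute_t1(
    t_smooth: np.ndarray,
    pass1_mask: np.ndarray,
    config: NonwearConfig | None = None,
) -> float:
    """Short-pass temperature threshold T1 from pass-1 worn minutes.

    T1 = min(mean_worn - sd_worn, 24 °C); if the 5th percentile of all
    readings exceeds it, that percentile is used instead; if fewer than
    3 full days were worn after pass 1, T1 = 24 °C.
    """
    config = config or NonwearConfig()
    t = np.asarray(t_smooth, float)
    worn = ~np.asarray(pass1_mask, bool) & np.isfinite(t)
    if not worn.any():
        raise ValueError("no worn minutes after pass 1")
    if worn.sum() < config.min_worn_days_for_t1 * 1440:
        return config.t1_cap
    t1 = min(float(t[worn].mean() - t[worn].std(ddof=0)), config.t1_cap)
    p5 = float(np.percentile(t[np.isfinite(t)], 5))
    if p5 > t1:
        t1 = p5
    return t1


def detect_short_nonwear(
    epochs: EpochFrame | pd.DataFrame,
    t1: float,
    pass1_intervals: list[tuple[int, int]],
    config: NonwearConfig | None = None,
) -> list[tuple[int, int]]:
    """Pass-2 non-wear intervals of [15, 90) min with the 2 °C drop filter."""
    config = config or NonwearConfig()
    minute = epochs.minute if isinstance(epochs, EpochFrame) else epochs
    t = minute["t_smooth"].to_numpy()
    rocam = minute["rocam"].to_numpy()
    cand = _candidate_minutes(t, t1, config)
    for a, b in pass1_intervals:
        cand[a:b] = False
    out = []
    for a, b in runs_of(cand):
        if not (config.short_min <= b - a < config.short_max):
            continue
        if _rocam_stat(rocam, a, b, config) >= config.rocam_thresh:
            continue
        head = np.nanmean(t[a : a + 5])
        tail = np.nanmean(t[max(a, b - 5) : b])
        if head - tail >= config.short_temp_drop:
            out.append((a, b))
    return out


def wear_mask(epochs: EpochFrame | pd.DataFrame, config: NonwearConfig | None = None) -> WearMask:
    """Run both detection passes and assemble the minute-level wear mask."""
    config = config or NonwearConfig()
    minute = epochs.minute if isinstance(epochs, EpochFrame) else epochs
    t = minute["t_smooth"].to_numpy()
    n = len(minute)

    t0 = compute_t0(t, config)
    cand = _candidate_minutes(t, t0, config)
    rocam = minute["rocam"].to_numpy()
    pre_merge = [
        (a, b)
        for a, b in runs_of(cand)
        if b - a >= config.long_min and _rocam_stat(rocam, a, b, config) < config.rocam_thresh
    ]
    pass1 = detect_long_nonwear(minute, t0, config)

    pass1_mask = np.zeros(n, bool)
    for a, b in pass1:
        pass1_mask[a:b] = True
    t1 = compute_t1(t, pass1_mask, config)
    pass2 = detect_short_nonwear(minute, t1, pass1, config)

    worn = np.ones(n, bool)
    provenance = np.full(n, "", dtype=object)
    pre_merge_mask = np.zeros(n, bool)
    for a, b in pre_merge:
        pre_merge_mask[a:b] = True
    for a, b in pass1:
        worn[a:b] = False
        seg = np.where(pre_merge_mask[a:b], "pass1", "merged-gap")
        provenance[a:b] = seg
    for a, b in pass2:
        worn[a:b] = False
        provenance[a:b] = "pass2"
    return WearMask(
        index=minute.index,
        worn=worn,
        provenance=provenance.astype(str),
        pass1_intervals=pass1,
        pass2_intervals=pass2,
    )
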