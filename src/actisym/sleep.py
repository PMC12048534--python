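"""Sleep detection: sustained inactivity, SPT window, WASO, SRI.

Sleep is inferred from arm-angle stability.  A 5-s epoch belongs to a
"sustained inactivity" period when it lies inside a maximal run of at
least 5 minutes over which every successive change in the z-axis angle
stays below 5 degrees.  The night's single main sleep interval (the
sleep period time, SPT, window) is found with a simplified heuristic:
inactivity runs of at least 30 minutes are candidate blocks, blocks
separated by less than 60 minutes are fused, and the longest fused block
wins (ties broken toward the block containing 03:00).  WASO is the time
inside the SPT window not classified as sustained inactivity.

Sleep days are anchored noon-to-noon.  The sleep regularity index (SRI)
compares 30-s sleep/wake states 24 h apart between consecutive days:
SRI = 200 * (fraction of agreeing epoch pairs) - 100, ranging from -100
to 100 with 100 for perfectly aligned sleep.  A day-pair SRI is reported
only when the fraction of jointly valid epochs exceeds 0.8.

Low-variation periods (a stillness measure independent of the angle
criterion) use the per-minute average over the three axes of the mean
absolute successive sample difference, sustained below a threshold for
at least 5 minutes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from actisym.ingest import EpochFrame, RawRecording, _block_reduce
from actisym.nonwear import WearMask, runs_of

EPOCH_5S_PER_MIN = 12
EPOCH_30S_PER_DAY = 2880

__all__ = [
    "SleepConfig",
    "SleepNight",
    "sustained_inactivity",
    "detect_spt",
    "sleep_metrics",
    "low_variation",
    "sleep_regularity",
    "states_30s",
    "sleep_nights",
]


@dataclass
class SleepConfig:
    angle_threshold: float = 5.0  # degrees
    inactivity_min: int = 5  # minutes a still run must last
    spt_block_min: int = 30  # minutes, minimum candidate block
    spt_fuse_gap: int = 60  # minutes, blocks closer than this are fused
    tie_hour: float = 3.0  # 03:00, tie-break anchor within the noon-noon night
    low_variation_threshold: float = 0.01  # g per sample interval, per-axis mean |diff|
    validity_min: float = 0.8  # joint-validity fraction required for SRI


@dataclass
class SleepNight:
    participant: str
    night_date: pd.Timestamp  # date of the noon anchoring the night (noon -> next noon)
    spt_start: pd.Timestamp | None
    spt_end: pd.Timestamp | None
    sleep_min: float
    waso_min: float
    efficiency: float
    sri: float
    validity: float


def sustained_inactivity(
    z_angle: np.ndarray,
    valid: np.ndarray | None = None,
    config: SleepConfig | None = None,
) -> np.ndarray:
    """Boolean 5-s series of sustained inactivity.

    An epoch is inactive when it lies in a maximal run of >= 5 minutes in
    which every successive |Δ z-angle| is below the 5° threshold.
    Invalid (non-worn) epochs break runs and are never inactive.
    """
    config = config or SleepConfig()
    a = np.asarray(z_angle, float)
    n = a.size
    if valid is None:
        valid = np.ones(n, bool)
    valid = np.asarray(valid, bool) & np.isfinite(a)
    with np.errstate(invalid="ignore"):
        small = np.abs(np.diff(a)) < config.angle_threshold
    # epoch i is "still" relative to its predecessor
    still = np.zeros(n, bool)
    still[1:] = small & valid[1:] & valid[:-1]
    min_epochs = config.inactivity_min * EPOCH_5S_PER_MIN
    inactive = np.zeros(n, bool)
    for a0, b0 in runs_of(still):
        # run of still diffs i..b0-1 covers epochs a0-1 .. b0-1
        start = a0 - 1
        if (b0 - start) >= min_epochs:
            inactive[start:b0] = True
    return inactive


def detect_spt(
    inactive: np.ndarray,
    index: pd.DatetimeIndex,
    config: SleepConfig | None = None,
) -> tuple[pd.Timestamp, pd.Timestamp] | None:
    """Most-likely sleep-period-time window within one noon-to-noon night.

    Returns half-open timestamps, or None when no candidate block exists.
    """
    config = config or SleepConfig()
    inactive = np.asarray(inactive, bool)
    blocks = [
        (a, b) for a, b in runs_of(inactive) if (b - a) >= config.spt_block_min * EPOCH_5S_PER_MIN
    ]
    if not blocks:
        return None
    fused: list[tuple[int, int]] = []
    gap = config.spt_fuse_gap * EPOCH_5S_PER_MIN
    for a, b in blocks:
        if fused and a - fused[-1][1] < gap:
            fused[-1] = (fused[-1][0], b)
        else:
            fused.append((a, b))
    lengths = [b - a for a, b in fused]
    best = max(lengths)
    winners = [iv for iv, ln in zip(fused, lengths) if ln == best]
    if len(winners) > 1:
        # tie: prefer the block containing 03:00 of the following morning
        night_start = index[0]
        anchor = night_start.normalize() + pd.Timedelta(days=1, hours=config.tie_hour)
        pos = int(np.clip((anchor - night_start) / pd.Timedelta(seconds=5), 0, len(index) - 1))
        containing = [iv for iv in winners if iv[0] <= pos < iv[1]]
        chosen = containing[0] if containing else winners[0]
    else:
        chosen = winners[0]
    a, b = chosen
    step = pd.Timedelta(seconds=5)
    return index[a], index[a] + step * (b - a)


def sleep_metrics(
    inactive: np.ndarray,
    index: pd.DatetimeIndex,
    spt: tuple[pd.Timestamp, pd.Timestamp] | None,
) -> tuple[float, float, float]:
    """(sleep_duration_min, waso_min, efficiency) within the SPT window."""
    if spt is None:
        return float("nan"), float("nan"), float("nan")
    a = int((spt[0] - index[0]) / pd.Timedelta(seconds=5))
    b = int((spt[1] - index[0]) / pd.Timedelta(seconds=5))
    window = np.asarray(inactive, bool)[a:b]
    spt_min = len(window) / EPOCH_5S_PER_MIN
    sleep_min = float(window.sum()) / EPOCH_5S_PER_MIN
    return sleep_min, spt_min - sleep_min, sleep_min / spt_min if spt_min else float("nan")


def low_variation(
    recording: RawRecording,
    threshold: float | None = None,
    config: SleepConfig | None = None,
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Minute-level low-variation flags and intervals.

    The per-minute statistic is the average over the three axes of the
    mean absolute successive sample difference; minutes below the (strict)
    threshold sustained for >= 5 minutes are low-variation.
    """
    config = config or SleepConfig()
    thr = config.low_variation_threshold if threshold is None else threshold
    spm = int(round(recording.sample_rate * 60))
    n_min = recording.n_samples // spm

    def per_axis(x: np.ndarray) -> np.ndarray:
        blocks = x[: n_min * spm].reshape(-1, spm)
        return np.abs(np.diff(blocks, axis=1)).mean(axis=1)

    stat = (per_axis(recording.ax) + per_axis(recording.ay) + per_axis(recording.az)) / 3.0
    below = stat < thr
    flags = np.zeros(n_min, bool)
    intervals = []
    for a, b in runs_of(below):
        if b - a >= config.inactivity_min:
            flags[a:b] = True
            intervals.append((a, b))
    return flags, intervals


def sleep_regularity(
    states_prev: np.ndarray,
    states_curr: np.ndarray,
    config: SleepConfig | None = None,
) -> float:
    """Day-pair sleep regularity index on 30-s states.

    States are coded 1 = sleep, 0 = wake, -1 = invalid.  Over epochs valid
    in both days, SRI = 200 * fraction agreeing - 100.  Returns NaN when
    the jointly valid fraction is <= 0.8 or no epochs are jointly valid.
    """
    config = config or SleepConfig()
    p = np.asarray(states_prev)
    c = np.asarray(states_curr)
    if p.shape != c.shape:
        raise ValueError("day-pair state series must have equal length")
    joint = (p >= 0) & (c >= 0)
    if joint.size == 0 or joint.mean() <= config.validity_min or not joint.any():
        return float("nan")
    agree = float(np.mean(p[joint] == c[joint]))
    return 200.0 * agree - 100.0


def states_30s(inactive_5s: np.ndarray, valid_5s: np.ndarray) -> np.ndarray:
    """Collapse 5-s inactivity flags to 30-s sleep/wake/invalid states.

    A 30-s epoch is invalid when at least half its 5-s epochs are invalid;
    otherwise sleep when at least half the valid 5-s epochs are inactive.
    """
    block = 6
    n = (len(inactive_5s) // block) * block
    inact = np.asarray(inactive_5s, bool)[:n].reshape(-1, block)
    val = np.asarray(valid_5s, bool)[:n].reshape(-1, block)
    nvalid = val.sum(axis=1)
    states = np.full(len(inact), -1, dtype=np.int8)
    ok = nvalid >= block / 2
    with np.errstate(invalid="ignore"):
        frac_sleep = np.where(nvalid > 0, (inact & val).sum(axis=1) / np.maximum(nvalid, 1), 0.0)
    states[ok] = (frac_sleep[ok] >= 0.5).astype(np.int8)
    return states


def sleep_nights(
    epochs: EpochFrame,
    mask: WearMask,
    participant: str = "",
    config: SleepConfig | None = None,
) -> pd.DataFrame:
    """Nightly sleep table over all complete noon-to-noon windows.

    Columns: participant, night_date, spt_start, spt_end, sleep_min,
    waso_min, efficiency, sri, validity.  The SRI on night k compares the
    30-s states of nights k-1 and k and is reported only when the joint
    validity exceeds 80%.
    """
    config = config or SleepConfig()
    five = epochs.five_sec
    valid_5s = np.repeat(mask.worn, EPOCH_5S_PER_MIN)[: len(five)]
    if len(valid_5s) < len(five):
        valid_5s = np.concatenate([valid_5s, np.zeros(len(five) - len(valid_5s), bool)])
    inactive = sustained_inactivity(five["z_angle"].to_numpy(), valid_5s, config)

    start = epochs.start_time
    first_noon = start.normalize() + pd.Timedelta(hours=12)
    if first_noon < start:
        first_noon += pd.Timedelta(days=1)
    end_time = five.index[-1] + pd.Timedelta(seconds=5)
    rows = []
    prev_states: np.ndarray | None = None
    noon = first_noon
    per_night = 24 * 60 * EPOCH_5S_PER_MIN
    while noon + pd.Timedelta(days=1) <= end_time:
        a = int((noon - start) / pd.Timedelta(seconds=5))
        b = a + per_night
        night_idx = five.index[a:b]
        night_inactive = inactive[a:b]
        night_valid = valid_5s[a:b]
        spt = detect_spt(night_inactive, night_idx, config)
        sleep_min, waso_min, eff = sleep_metrics(night_inactive, night_idx, spt)
        validity = float(np.mean(night_valid))
        states = states_30s(night_inactive, night_valid)
        sri = (
            sleep_regularity(prev_states, states, config)
            if prev_states is not None
            else float("nan")
        )
        rows.append(
            SleepNight(
                participant=participant,
                night_date=noon.normalize(),
                spt_start=spt[0] if spt else None,
                spt_end=spt[1] if spt else None,
                sleep_min=sleep_min,
                waso_min=waso_min,
                efficiency=eff,
                sri=sri,
                validity=validity,
            )
        )
        prev_states = states
        noon += pd.Timedelta(days=1)
    return pd.DataFrame([vars(r) for r in rows])
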