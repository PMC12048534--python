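"""Synthetic cohort generator with full ground-truth labels.

Emulates a longitudinal wearable study: each participant wears a wrist
device for one to three multi-week "smartwatch cycles" (tri-axial
acceleration, skin temperature, ambient light) while submitting daily
pain/fatigue diaries and an end-of-cycle EHP-30 questionnaire.

The generative model has two layers.

Latent daily layer.  Daily latent fatigue is baseline + a sinusoid with
the symptom period (menstrual-type cyclicity) + AR(1) noise + flare
impulses, shaped by the participant's phenotype (cyclical,
constant-severe, flare, post-surgical).  Latent pain is an affine
function of fatigue plus independent noise (within-person pain-fatigue
correlation ~0.67).  The daily activity level shares a controlled
correlation c with fatigue: activity_z = c * fatigue_z +
sqrt(1 - c^2) * noise, so the realized within-person fatigue-activity
correlation equals the configured coupling without calibration loops.
Diary items are ordinal discretizations (round + clamp) of the latent
scores; missingness is missing-completely-at-random by default.

Signal layer.  The raw stream realizes nightly sleep windows (stable arm
angle, low movement), a diurnal wake profile whose movement amplitude is
scaled by the day's latent activity level, wear temperature ~31 °C with
a mild diurnal rhythm, and injected non-wear (frozen orientation at the
sensor noise floor, temperature relaxing exponentially toward ambient).

Every random draw flows from ``numpy.random.default_rng([seed,
participant_index])``, so identical configurations reproduce identical
cohorts.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from actisym.ingest import RawRecording, write_raw

PHENOTYPES = ("cyclical", "constant-severe", "flare", "post-surgical")

__all__ = [
    "PHENOTYPES",
    "CohortConfig",
    "GroundTruth",
    "CohortBundle",
    "simulate_participant",
    "simulate_cohort",
    "inject_nonwear",
    "write_bundle",
]


@dataclass
class CohortConfig:
    """Study-design parameters for the synthetic cohort.

    Defaults mirror the emulated study: 68 participants, three 28-day
    smartwatch cycles, a 28-day symptom period, a within-person
    fatigue-activity coupling of -0.35 (the study's strong negative
    PA-fatigue association), ~20% daily-diary missingness (80% observed
    adherence), and a 1 Hz signal layer (10 Hz supported).
    """

    n_participants: int = 68
    days_per_cycle: int = 28
    n_cycles: int = 3
    sample_rate: float = 1.0
    phenotypes: str | Sequence[str] = "cyclical"
    symptom_period: float = 28.0
    coupling_fatigue_activity: float = -0.35
    prom_missing_rate: float = 0.2
    nonwear_events: list[tuple[float, float]] = field(default_factory=list)  # (start_min, duration_min)
    surgery_day: int | None = None
    seed: int = 0
    noise_scale: float = 1.0
    start_date: str = "2024-03-04"
    sleep_onset_jitter_min: float = 30.0

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.n_cycles not in (1, 2, 3):
            raise ValueError("n_cycles must be 1, 2, or 3")
        if not -1.0 <= self.coupling_fatigue_activity <= 1.0:
            raise ValueError("coupling must lie in [-1, 1]")
        if not 0.0 <= self.prom_missing_rate <= 1.0:
            raise ValueError("missing rate must lie in [0, 1]")
        phens = [self.phenotypes] if isinstance(self.phenotypes, str) else list(self.phenotypes)
        for p in phens:
            if p not in PHENOTYPES:
                raise ValueError(f"unknown phenotype {p!r}")

    @property
    def n_days(self) -> int:
        return self.days_per_cycle * self.n_cycles

    def phenotype_for(self, index: int) -> str:
        if isinstance(self.phenotypes, str):
            return self.phenotypes
        return self.phenotypes[index % len(self.phenotypes)]


@dataclass
class GroundTruth:
    """Truth labels accompanying one simulated participant."""

    wear_intervals: list[tuple[float, float]]  # seconds, half-open, merged
    sleep_intervals: list[tuple[float, float]]  # seconds from recording start
    daily: pd.DataFrame  # day, cycle, fatigue, pain, activity (latent, continuous)
    coupling: float


@dataclass
class CohortBundle:
    config: CohortConfig
    recordings: dict[str, RawRecording | None]
    proms: pd.DataFrame
    ehp30: pd.DataFrame
    truths: dict[str, GroundTruth]
    manifest: pd.DataFrame


def _phenotype_params(phenotype: str) -> dict:
    if phenotype == "constant-severe":
        return dict(baseline=7.0, cyc_amp=0.0, flare_rate=0.0, ar_sd=0.4)
    if phenotype == "flare":
        return dict(baseline=4.0, cyc_amp=0.5, flare_rate=1 / 14, ar_sd=0.5)
    if phenotype == "post-surgical":
        return dict(baseline=5.0, cyc_amp=1.0, flare_rate=0.0, ar_sd=0.5)
    return dict(baseline=4.5, cyc_amp=1.5, flare_rate=0.0, ar_sd=0.5)  # cyclical


def _simulate_latent(config: CohortConfig, phenotype: str, rng: np.random.Generator,
                     surgery_day: int | None) -> pd.DataFrame:
    n = config.n_days
    p = _phenotype_params(phenotype)
    days = np.arange(n)
    phase = rng.uniform(0, 2 * np.pi)
    fatigue = p["baseline"] + p["cyc_amp"] * np.sin(2 * np.pi * days / config.symptom_period + phase)
    # AR(1) day-to-day noise
    eps = rng.normal(0, p["ar_sd"] * config.noise_scale, n)
    ar = np.zeros(n)
    for i in range(1, n):
        ar[i] = 0.5 * ar[i - 1] + eps[i]
    fatigue = fatigue + ar
    # flare impulses: sudden jump decaying over ~4 days
    if p["flare_rate"] > 0:
        starts = np.nonzero(rng.random(n) < p["flare_rate"])[0]
        for s in starts:
            length = min(n - s, 6)
            fatigue[s : s + length] += 3.0 * np.exp(-np.arange(length) / 2.0)
    if surgery_day is not None:
        post = days - surgery_day
        spike = np.where(post >= 0, 2.5 * np.exp(-np.clip(post, 0, None) / 5.0), 0.0)
        fatigue = fatigue + spike

    sd = fatigue.std()
    f_z = (fatigue - fatigue.mean()) / sd if sd > 0 else np.zeros(n)
    c = config.coupling_fatigue_activity
    act_noise = rng.normal(0, 1, n) * (config.noise_scale if config.noise_scale > 0 else 0.0)
    if config.noise_scale == 0:
        act_z = c * f_z
    else:
        act_z = c * f_z + np.sqrt(1 - c**2) * act_noise
    act_base = 0.10 + rng.normal(0, 0.015)
    activity = np.clip(act_base + 0.02 * act_z, 0.01, None)
    if surgery_day is not None:
        post = days - surgery_day
        recovery = np.clip(post / 20.0, 0.0, 1.0)
        dip = np.where(post >= 0, 0.45 + 0.55 * recovery, 1.0)
        activity = activity * dip

    pain_noise = rng.normal(0, 1, n) * config.noise_scale
    pain_z = 0.67 * f_z + np.sqrt(1 - 0.67**2) * pain_noise
    pain = 4.5 + 1.6 * pain_z
    return pd.DataFrame(
        {
            "day": days,
            "cycle": days // config.days_per_cycle + 1,
            "fatigue": fatigue,
            "fatigue_z": f_z,
            "pain": pain,
            "activity": activity,
        }
    )


def _make_proms(latent: pd.DataFrame, config: CohortConfig, pid: str,
                rng: np.random.Generator) -> pd.DataFrame:
    n = len(latent)
    start = pd.Timestamp(config.start_date)
    f = latent["fatigue"].to_numpy()
    pain = latent["pain"].to_numpy()
    rows = []
    observed = rng.random(n) >= config.prom_missing_rate
    for i in range(n):
        if not observed[i]:
            continue
        date = start + pd.Timedelta(days=int(i))
        bfi_items = np.clip(np.round(f[i] + rng.normal(0, 0.5, 9) * config.noise_scale), 0, 10)
        pain_avg = float(np.clip(np.round(pain[i] + rng.normal(0, 0.3) * config.noise_scale), 1, 10))
        pain_worst = float(np.clip(pain_avg + round(abs(rng.normal(1.0, 0.5))), 1, 10))
        submitted = date + pd.Timedelta(hours=17) + pd.Timedelta(
            minutes=float(rng.uniform(0, 600))
        )
        row = {
            "participant": pid,
            "assoc_date": date,
            "submitted_at": submitted,
            "pain_avg": pain_avg,
            "pain_worst": pain_worst,
        }
        row.update({f"bfi_q{k+1}": float(bfi_items[k]) for k in range(9)})
        rows.append(row)
    cols = ["participant", "assoc_date", "submitted_at", "pain_avg", "pain_worst"] + [
        f"bfi_q{k}" for k in range(1, 10)
    ]
    return pd.DataFrame(rows, columns=cols)


def _make_ehp30(latent: pd.DataFrame, config: CohortConfig, pid: str,
                rng: np.random.Generator) -> pd.DataFrame:
    """End-of-cycle EHP-30 driven by the upper quartile of the cycle's latent symptoms."""
    rows = []
    for cyc, grp in latent.groupby("cycle"):
        pain_v = np.sort(grp["pain"].to_numpy())
        fat_v = np.sort(grp["fatigue"].to_numpy())
        k = max(1, int(np.ceil(len(grp) / 4)))
        sev_pain = np.clip(np.mean(pain_v[-k:]) / 10.0, 0, 1)
        sev_fat = np.clip(np.mean(fat_v[-k:]) / 10.0, 0, 1)
        items = {}
        for i in range(1, 31):
            sev = sev_pain if i <= 11 else sev_fat
            items[f"item_{i:02d}"] = float(
                np.clip(np.round(4 * sev + rng.normal(0, 0.4) * config.noise_scale), 0, 4)
            )
        rows.append({"participant": pid, "cycle": int(cyc), **items})
    return pd.DataFrame(rows)


def _diurnal_profile(seconds_of_day: np.ndarray) -> np.ndarray:
    """Smooth wake-activity envelope peaking mid-afternoon."""
    h = seconds_of_day / 3600.0
    return np.clip(np.sin(np.pi * (h - 8.0) / 14.0), 0.05, None)


def _synthesize_raw(config: CohortConfig, latent: pd.DataFrame, pid: str,
                    rng: np.random.Generator) -> tuple[RawRecording, list[tuple[float, float]]]:
    rate = config.sample_rate
    if abs(rate * 5 - round(rate * 5)) > 1e-9:
        raise ValueError("sample_rate must give an integer number of samples per 5 s")
    n_days = config.n_days
    n = int(round(n_days * 86400 * rate))
    t = np.arange(n) / rate  # seconds from midnight of day 0
    sod = t % 86400.0

    # nightly sleep windows: onset ~23:00 + jitter, offset ~07:00 + jitter (next day)
    sleep_mask = np.zeros(n, bool)
    sleep_intervals: list[tuple[float, float]] = []
    jit = config.sleep_onset_jitter_min * 60.0
    for d in range(n_days):
        onset = d * 86400 + 23 * 3600 + rng.normal(0, jit)
        offset = (d + 1) * 86400 + 7 * 3600 + rng.normal(0, jit)
        a, b = int(onset * rate), int(min(offset * rate, n))
        if a >= n:
            break
        sleep_mask[a:b] = True
        sleep_intervals.append((a / rate, b / rate))

    # orientation: z-angle stable at night, jumping per-minute random walk by day
    minutes = np.arange(int(np.ceil(n_days * 1440)))
    theta_min = np.empty(len(minutes))
    theta = rng.uniform(-30, 30)
    for i in range(len(minutes)):
        theta = np.clip(theta + rng.normal(0, 18), -75, 75)
        theta_min[i] = theta
    theta_s = np.repeat(theta_min, int(60 * rate))[:n]
    night_theta = rng.normal(30, 8, n_days + 1)
    night_of_sample = np.minimum((t / 86400.0 + 0.5).astype(int), n_days)
    theta_s = np.where(sleep_mask, night_theta[night_of_sample], theta_s)
    phi_s = np.where(sleep_mask, 0.3, rng.uniform(0, 2 * np.pi, n))

    # movement noise: scaled by the day's latent activity while awake
    day_idx = np.minimum((t / 86400.0).astype(int), n_days - 1)
    act = latent["activity"].to_numpy()[day_idx]
    active_minute = np.repeat(rng.random(len(minutes)) < 0.65, int(60 * rate))[:n]
    sigma = np.where(
        sleep_mask,
        0.0015,
        np.where(active_minute, 2.5 * act * _diurnal_profile(sod), 0.004),
    )
    th = np.radians(theta_s)
    gx = np.cos(th) * np.cos(phi_s)
    gy = np.cos(th) * np.sin(phi_s)
    gz = np.sin(th)
    noise = rng.normal(0, 1, (3, n)) * sigma
    ax, ay, az = gx + noise[0], gy + noise[1], gz + noise[2]

    # wear temperature: ~30.5 °C, peaking at night (distal skin temperature
    # rises during sleep), with a slow drift and sensor noise
    n_min_total = len(minutes)
    ou = np.zeros(n_min_total)
    a_ou = np.exp(-1.0 / 180.0)  # ~3 h correlation time on the minute grid
    ou_noise = rng.normal(0, 0.4 * np.sqrt(1 - a_ou**2), n_min_total)
    for i in range(1, n_min_total):
        ou[i] = a_ou * ou[i - 1] + ou_noise[i]
    drift = np.repeat(ou, int(60 * rate))[:n]
    temp = (
        30.5
        + 1.2 * np.cos(2 * np.pi * (sod / 3600 - 3) / 24.0)
        + drift
        + rng.normal(0, 0.05, n)
    )
    light = np.where((sod > 7 * 3600) & (sod < 22 * 3600), 200.0, 0.0) + rng.uniform(0, 5, n)

    start = pd.Timestamp(config.start_date)
    rec = RawRecording(
        participant_id=pid,
        start_time=start,
        sample_rate=rate,
        ax=ax, ay=ay, az=az,
        temperature=temp,
        light=np.clip(light, 0, 3000),
        calibrated=True,
    )
    return rec, sleep_intervals


def inject_nonwear(
    recording: RawRecording,
    intervals: list[tuple[float, float]],
    ambient: float = 21.0,
    tau_min: float = 5.0,
    rewarm_tau_min: float = 3.0,
    noise_floor: float = 0.002,
    rng: np.random.Generator | None = None,
) -> RawRecording:
    """Inject non-wear intervals (start_min, duration_min) into a recording.

    Inside each interval the acceleration freezes to the orientation at
    interval start plus the sensor noise floor, and temperature relaxes
    exponentially toward ``ambient`` with a 5-min time constant.  After
    re-wear it relaxes back toward the skin signal with a faster 3-min
    constant (conduction against skin warms the sensor quicker than air
    cools it).  The cooling constant must satisfy
    ``0.5 * tau <= t1_cap - ambient`` for the drop-rate and absolute
    temperature criteria of the short-pass detector to produce one
    contiguous candidate run; small wearable temperature sensors cool on
    this time scale.  Overlapping intervals are merged with a warning; an
    empty list returns the recording unchanged.
    """
    if not intervals:
        return recording
    rng = rng or np.random.default_rng(0)
    rate = recording.sample_rate
    n = recording.n_samples
    ivals = sorted((float(s), float(s) + float(d)) for s, d in intervals)
    merged: list[list[float]] = []
    for a, b in ivals:
        if merged and a < merged[-1][1]:
            warnings.warn("overlapping non-wear intervals merged")
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    for a, b in merged:
        if a < 0 or b * 60 * rate > n:
            raise ValueError("non-wear interval outside the recording span")
    ax, ay, az = recording.ax.copy(), recording.ay.copy(), recording.az.copy()
    temp = recording.temperature.copy()
    tau_s = tau_min * 60.0
    for a, b in merged:
        i0, i1 = int(a * 60 * rate), int(b * 60 * rate)
        k = i1 - i0
        ax[i0:i1] = ax[i0] + rng.normal(0, noise_floor, k)
        ay[i0:i1] = ay[i0] + rng.normal(0, noise_floor, k)
        az[i0:i1] = az[i0] + rng.normal(0, noise_floor, k)
        dt = np.arange(k) / rate
        temp[i0:i1] = ambient + (temp[i0] - ambient) * np.exp(-dt / tau_s)
        # re-warming back to the skin signal after the interval
        rew_s = rewarm_tau_min * 60.0
        k2 = min(n - i1, int(5 * rew_s * rate))
        if k2 > 0:
            dt2 = np.arange(k2) / rate
            temp[i1 : i1 + k2] = temp[i1 : i1 + k2] + (temp[i1 - 1] - temp[i1]) * np.exp(-dt2 / rew_s)
    return replace(recording, ax=ax, ay=ay, az=az, temperature=temp)


def nonwear_fixture_events(rng: np.random.Generator, days: int = 7) -> list[tuple[float, float]]:
    """Standard non-wear event schedule for detector evaluation.

    One long (5-6 h) removal plus near-daily daytime removals of
    15 min to 4 h, non-overlapping — about 8-11 h of non-wear per week,
    the realistic density (showers, charging, overnight removals) that
    places the detector's adaptive 5th-percentile temperature threshold
    in the non-wear range.
    """
    events = [
        (float(rng.integers(1, max(2, days - 1))) * 1440 + float(rng.uniform(0, 180)),
         float(rng.uniform(300, 360)))
    ]
    for d in range(days):
        if rng.random() < 0.85:
            events.append(
                (d * 1440 + float(rng.uniform(9 * 60, 18 * 60)),
                 float(rng.choice([15.0, 25.0, 45.0, 70.0, 120.0, 240.0])))
            )
    events.sort()
    clean = [events[0]]
    for s, d in events[1:]:
        if s > clean[-1][0] + clean[-1][1] + 30:
            clean.append((s, d))
    return clean


def _wear_truth(config: CohortConfig, n_seconds: float) -> list[tuple[float, float]]:
    nw = sorted((s * 60.0, (s + d) * 60.0) for s, d in config.nonwear_events)
    out = []
    cur = 0.0
    for a, b in nw:
        if a > cur:
            out.append((cur, a))
        cur = max(cur, b)
    if cur < n_seconds:
        out.append((cur, n_seconds))
    return out


def simulate_participant(
    config: CohortConfig,
    participant_index: int = 0,
    include_raw: bool = True,
) -> tuple[RawRecording | None, pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate one participant: (recording, diary, EHP-30, ground truth).

    With ``include_raw=False`` only the latent daily layer and the PROM
    tables are produced (cheap; used for large statistical experiments).
    """
    phenotype = config.phenotype_for(participant_index)
    surgery_day = config.surgery_day
    if phenotype == "post-surgical" and surgery_day is None:
        surgery_day = config.days_per_cycle  # first day of the second cycle
    if surgery_day is not None and not (0 <= surgery_day < config.n_days):
        raise ValueError(
            f"surgery_day {surgery_day} outside the recording span [0, {config.n_days})"
        )
    pid = f"P{participant_index + 1:02d}"
    rng = np.random.default_rng([config.seed, participant_index])
    latent = _simulate_latent(config, phenotype, rng, surgery_day)
    proms = _make_proms(latent, config, pid, rng)
    ehp30 = _make_ehp30(latent, config, pid, rng)
    recording = None
    sleep_intervals: list[tuple[float, float]] = []
    if include_raw:
        recording, sleep_intervals = _synthesize_raw(config, latent, pid, rng)
        if config.nonwear_events:
            recording = inject_nonwear(recording, config.nonwear_events, rng=rng)
    truth = GroundTruth(
        wear_intervals=_wear_truth(config, config.n_days * 86400.0),
        sleep_intervals=sleep_intervals,
        daily=latent,
        coupling=config.coupling_fatigue_activity,
    )
    return recording, proms, ehp30, truth


def simulate_cohort(config: CohortConfig, include_raw: bool = True) -> CohortBundle:
    """Simulate the full cohort plus a per-cycle manifest table."""
    if config.n_participants <= 0:
        raise ValueError("n_participants must be positive")
    recordings: dict[str, RawRecording | None] = {}
    truths: dict[str, GroundTruth] = {}
    prom_frames, ehp_frames, manifest_rows = [], [], []
    start = pd.Timestamp(config.start_date)
    for i in range(config.n_participants):
        rec, proms, ehp30, truth = simulate_participant(config, i, include_raw)
        pid = f"P{i + 1:02d}"
        recordings[pid] = rec
        truths[pid] = truth
        prom_frames.append(proms)
        ehp_frames.append(ehp30)
        phenotype = config.phenotype_for(i)
        surgery_day = config.surgery_day
        if phenotype == "post-surgical" and surgery_day is None:
            surgery_day = config.days_per_cycle
        for c in range(config.n_cycles):
            c_start = start + pd.Timedelta(days=c * config.days_per_cycle)
            manifest_rows.append(
                {
                    "participant": pid,
                    "cycle": c + 1,
                    "start_date": c_start,
                    "end_date": c_start + pd.Timedelta(days=config.days_per_cycle - 1),
                    "surgery_date": (
                        start + pd.Timedelta(days=int(surgery_day))
                        if surgery_day is not None else pd.NaT
                    ),
                    "wrist": "non-dominant" if i % 3 else "dominant",
                    "phenotype": phenotype,
                }
            )
    return CohortBundle(
        config=config,
        recordings=recordings,
        proms=pd.concat(prom_frames, ignore_index=True),
        ehp30=pd.concat(ehp_frames, ignore_index=True),
        truths=truths,
        manifest=pd.DataFrame(manifest_rows),
    )


def write_bundle(bundle: CohortBundle, out_dir: str | Path) -> None:
    """Write a cohort bundle to disk (CSV tables + JSON truth sidecars)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.proms.to_csv(out / "diary.csv", index=False)
    bundle.ehp30.to_csv(out / "ehp30.csv", index=False)
    bundle.manifest.to_csv(out / "manifest.csv", index=False)
    for pid, rec in bundle.recordings.items():
        if rec is not None:
            write_raw(rec, out / f"{pid}_raw.csv")
    for pid, truth in bundle.truths.items():
        sidecar = {
            "wear_intervals": truth.wear_intervals,
            "sleep_intervals": truth.sleep_intervals,
            "coupling": truth.coupling,
            "daily": truth.daily.to_dict(orient="list"),
        }
        (out / f"{pid}_truth.json").write_text(json.dumps(sidecar))
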