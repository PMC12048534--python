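"""Daily physical-activity and diurnal-rhythm features.

Physical-activity days are anchored midnight-to-midnight; a day is valid
for PA when the device was worn for at least 75% of that 24-h window
(sleep measures use the same rule on the noon-anchored window).  The
rest-activity rhythm features are:

* M10 / L5 — the mean minute activity over the most-active 10-h and
  least-active 5-h windows of the day (windows slide by one minute and
  stay inside the calendar day);
* RA — the relative amplitude (M10 - L5) / (M10 + L5);
* intensity minutes — worn minutes classified against acceleration
  cut-points (defaults 40/100/400 mg), with MVPA = moderate + vigorous;
* a 24-h cosinor fit of the smoothed skin temperature, giving mesor,
  amplitude and acrophase.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from actisym.ingest import EpochFrame
from actisym.nonwear import WearMask

MIN_PER_DAY = 1440

__all__ = [
    "CutPoints",
    "m10_l5_ra",
    "intensity_minutes",
    "temperature_rhythm",
    "assemble_daily",
]


@dataclass
class CutPoints:
    """Acceleration intensity cut-points in milli-g (lower-inclusive)."""

    light_lo: float = 40.0
    mod_lo: float = 100.0
    vig_lo: float = 400.0

    def __post_init__(self) -> None:
        if not (self.light_lo < self.mod_lo < self.vig_lo):
            raise ValueError("cut-points must satisfy light_lo < mod_lo < vig_lo")


def _window_means(x: np.ndarray, worn: np.ndarray, width: int, max_missing_frac: float = 0.25):
    """Mean of worn minutes over every sliding window of `width` minutes.

    Windows with more than `max_missing_frac` non-worn minutes are invalid
    (NaN).  Returns an array of length len(x) - width + 1.
    """
    w = np.asarray(worn, bool)
    vals = np.where(w, np.asarray(x, float), 0.0)
    cs = np.concatenate(([0.0], np.cumsum(vals)))
    cn = np.concatenate(([0], np.cumsum(w.astype(int))))
    sums = cs[width:] - cs[:-width]
    counts = cn[width:] - cn[:-width]
    out = np.full(len(sums), np.nan)
    ok = counts >= width * (1 - max_missing_frac)
    np.divide(sums, counts, out=out, where=ok & (counts > 0))
    out[~ok] = np.nan
    return out


def m10_l5_ra(
    minute_enmo: np.ndarray,
    worn: np.ndarray,
    *,
    m_hours: int = 10,
    l_hours: int = 5,
) -> tuple[float, float, float, float, float]:
    """(m10, m10_onset_hour, l5, l5_onset_hour, ra) for one midnight day.

    Windows are constrained within the 1440-minute day; ties broken by the
    earliest window start; non-worn minutes are excluded from window means
    and windows with more than 25% missing minutes are skipped.
    """
    x = np.asarray(minute_enmo, float)
    if x.size != MIN_PER_DAY:
        raise ValueError("expected a full 1440-minute day")
    nanv = (float("nan"),) * 5
    m_means = _window_means(x, worn, m_hours * 60)
    l_means = _window_means(x, worn, l_hours * 60)
    if np.all(np.isnan(m_means)) or np.all(np.isnan(l_means)):
        return nanv
    i_m = int(np.nanargmax(m_means))
    i_l = int(np.nanargmin(l_means))
    m10, l5 = float(m_means[i_m]), float(l_means[i_l])
    denom = m10 + l5
    ra = (m10 - l5) / denom if denom > 0 else float("nan")
    return m10, i_m / 60.0, l5, i_l / 60.0, ra


def intensity_minutes(
    minute_enmo: np.ndarray,
    worn: np.ndarray,
    cutpoints: CutPoints | None = None,
) -> dict[str, float]:
    """Worn minutes per intensity class plus MVPA (classes lower-inclusive)."""
    cp = cutpoints or CutPoints()
    e_mg = np.asarray(minute_enmo, float) * 1000.0
    w = np.asarray(worn, bool) & np.isfinite(e_mg)
    e = e_mg[w]
    inactive = float(np.sum(e < cp.light_lo))
    light = float(np.sum((e >= cp.light_lo) & (e < cp.mod_lo)))
    moderate = float(np.sum((e >= cp.mod_lo) & (e < cp.vig_lo)))
    vigorous = float(np.sum(e >= cp.vig_lo))
    return {
        "inactive_min": inactive,
        "light_min": light,
        "moderate_min": moderate,
        "vigorous_min": vigorous,
        "mvpa_min": moderate + vigorous,
    }


def temperature_rhythm(
    minute_t: np.ndarray,
    worn: np.ndarray,
    *,
    min_worn_frac: float = 0.5,
    amplitude_tol: float = 1e-9,
) -> tuple[float, float, float]:
    """24-h cosinor fit of minute temperature: (mesor °C, amplitude °C, acrophase h).

    Fits T(t) = M + A*cos(2*pi*(t - phi)/24) by linear least squares on
    worn minutes.  Degenerate (constant) input gives amplitude 0 and a
    missing acrophase.
    """
    t = np.asarray(minute_t, float)
    w = np.asarray(worn, bool) & np.isfinite(t)
    if w.mean() < min_worn_frac:
        return float("nan"), float("nan"), float("nan")
    hours = np.arange(t.size) / 60.0
    omega = 2 * np.pi / 24.0
    X = np.column_stack([np.ones(w.sum()), np.cos(omega * hours[w]), np.sin(omega * hours[w])])
    beta, *_ = np.linalg.lstsq(X, t[w], rcond=None)
    mesor, a, b = beta
    amplitude = float(np.hypot(a, b))
    if amplitude < amplitude_tol:
        return float(mesor), 0.0, float("nan")
    acrophase = float(np.arctan2(b, a) / omega % 24.0)
    return float(mesor), amplitude, acrophase


def assemble_daily(
    epochs: EpochFrame,
    mask: WearMask,
    nights: pd.DataFrame,
    participant: str = "",
    cycle: int = 1,
    cutpoints: CutPoints | None = None,
    pa_validity_min: float = 0.75,
) -> pd.DataFrame:
    """One row per participant-day with validity-rule masking.

    PA/rhythm fields are masked when the midnight-anchored wear fraction
    is below 0.75; sleep fields when the noon-anchored fraction is below
    0.75; the sleep-regularity index additionally requires its day-pair
    validity to exceed 0.8 (enforced upstream when the nightly table is
    built).
    """
    minute = epochs.minute
    enmo_min = minute["enmo"].to_numpy()
    t_min = minute["t_smooth"].to_numpy()
    worn = mask.worn
    start = epochs.start_time
    first_midnight = start.normalize()
    if first_midnight < start:
        first_midnight += pd.Timedelta(days=1)
    offset = int((first_midnight - start) / pd.Timedelta(minutes=1))
    n_days = (len(minute) - offset) // MIN_PER_DAY

    nights_by_date = {}
    if nights is not None and len(nights):
        nights_by_date = {pd.Timestamp(r.night_date).normalize(): r for r in nights.itertuples()}

    rows = []
    for d in range(n_days):
        a = offset + d * MIN_PER_DAY
        b = a + MIN_PER_DAY
        date = first_midnight + pd.Timedelta(days=d)
        day_worn = worn[a:b]
        wear_mid = float(np.mean(day_worn))
        noon_a, noon_b = a + 720, b + 720
        wear_noon = (
            float(np.mean(worn[noon_a:noon_b])) if noon_b <= len(worn) else float("nan")
        )
        row: dict = {
            "participant": participant,
            "cycle": cycle,
            "date": date,
            "wear_frac_midnight": wear_mid,
            "wear_frac_noon": wear_noon,
            "valid_pa": wear_mid >= pa_validity_min,
            "valid_sleep": bool(wear_noon >= pa_validity_min) if np.isfinite(wear_noon) else False,
        }
        pa_fields = dict.fromkeys(
            [
                "m10", "m10_onset", "l5", "l5_onset", "ra",
                "inactive_min", "light_min", "moderate_min", "vigorous_min", "mvpa_min",
                "mean_enmo", "mean_rocam",
                "temp_mesor", "temp_amplitude", "temp_acrophase",
            ],
            float("nan"),
        )
        if row["valid_pa"]:
            m10, m10_on, l5, l5_on, ra = m10_l5_ra(enmo_min[a:b], day_worn)
            pa_fields.update(m10=m10, m10_onset=m10_on, l5=l5, l5_onset=l5_on, ra=ra)
            pa_fields.update(intensity_minutes(enmo_min[a:b], day_worn, cutpoints))
            if day_worn.any():
                pa_fields["mean_enmo"] = float(np.mean(enmo_min[a:b][day_worn]))
                pa_fields["mean_rocam"] = float(np.nanmean(minute["rocam"].to_numpy()[a:b][day_worn]))
            mesor, amp, acro = temperature_rhythm(t_min[a:b], day_worn)
            pa_fields.update(temp_mesor=mesor, temp_amplitude=amp, temp_acrophase=acro)
        row.update(pa_fields)

        sleep_fields = dict.fromkeys(
            ["spt_start", "spt_end", "sleep_min", "waso_min", "efficiency", "sri"], float("nan")
        )
        night = nights_by_date.get(date.normalize())
        if night is not None and row["valid_sleep"]:
            sleep_fields.update(
                spt_start=night.spt_start,
                spt_end=night.spt_end,
                sleep_min=night.sleep_min,
                waso_min=night.waso_min,
                efficiency=night.efficiency,
                sri=night.sri,
            )
        row.update(sleep_fields)
        rows.append(row)
    df = pd.DataFrame(rows)
    if df.duplicated(subset=["participant", "date"]).any():
        raise ValueError("duplicate participant-day rows")
    return df
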