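"""Cycle-level summarization of daily series, variability measures, adherence.

A "cycle" is one 4-6-week wear-and-diary period.  For each daily
variable the summary carries the mean (requiring at least 10 non-missing
days), and the spread statistics — SD, skewness, IQR, quartiles, the
means of the upper and lower quartile of daily values — each requiring
at least 20 days.  Day-to-day variability is quantified with the
Teager-Kaiser energy operator and the root mean squared successive
differences, computed after linear interpolation of interior gaps of at
most three consecutive missing days:

    TKEO(x)  = (1/N) * sum_{i=2}^{N-1} (x_i^2 - x_{i-1} * x_{i+1})
    RMSSD(x) = sqrt( (1/N) * sum_{i=1}^{N-1} (x_{i+1} - x_i)^2 )

Both divide by N as printed in the source formulation even though the
sums run over N-2 and N-1 terms; ``conventional=True`` switches to the
textbook normalization.

Adherence is assessed over days 1-28 of each cycle: diary adherence is
the fraction of days with a submitted report, watch adherence the
fraction of days with more than 75% wear, with weekly (7-day) breakdowns.
A cycle is included when more than one diary entry was submitted in days
1-28 or any smartwatch data was returned.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "impute_series",
    "tkeo",
    "rmssd",
    "summarize_cycle",
    "adherence",
]


def impute_series(x: pd.Series | np.ndarray, max_gap: int = 3) -> pd.Series:
    """Linearly interpolate interior gaps of at most ``max_gap`` missing values.

    Longer interior gaps and leading/trailing gaps are left missing;
    non-missing values are never altered.  The input must be indexed by
    consecutive days (positional interpolation is used).
    """
    s = pd.Series(np.asarray(x, float)) if not isinstance(x, pd.Series) else x.astype(float)
    filled = s.reset_index(drop=True).interpolate(method="linear", limit_area="inside")
    isna = s.isna().to_numpy()
    # re-mask interior gaps longer than max_gap
    n = len(s)
    i = 0
    out = filled.to_numpy()
    while i < n:
        if isna[i]:
            j = i
            while j < n and isna[j]:
                j += 1
            if j - i > max_gap:
                out[i:j] = np.nan
            i = j
        else:
            i += 1
    return pd.Series(out, index=s.index)


def tkeo(x: np.ndarray, conventional: bool = False) -> float:
    """Teager-Kaiser energy operator of a daily series (NaN if N < 3)."""
    v = np.asarray(x, float)
    v = v[np.isfinite(v)]
    n = v.size
    if n < 3:
        return float("nan")
    core = float(np.sum(v[1:-1] ** 2 - v[:-2] * v[2:]))
    return core / (n - 2 if conventional else n)


def rmssd(x: np.ndarray, conventional: bool = False) -> float:
    """Root mean squared successive differences (NaN if N < 2)."""
    v = np.asarray(x, float)
    v = v[np.isfinite(v)]
    n = v.size
    if n < 2:
        return float("nan")
    ss = float(np.sum(np.diff(v) ** 2))
    return float(np.sqrt(ss / (n - 1 if conventional else n)))


def _upper_quartile_mean(v: np.ndarray, lower: bool = False) -> float:
    """Mean of the ceil(n/4) largest (or smallest) values."""
    k = int(np.ceil(v.size / 4))
    s = np.sort(v)
    return float(np.mean(s[:k] if lower else s[-k:]))


def summarize_cycle(
    daily: pd.DataFrame,
    variables: list[str],
    level: str = "cycle",
    min_n_mean: int = 10,
    min_n_other: int = 20,
    conventional_variability: bool = False,
) -> pd.DataFrame:
    """Long-format summary table of daily variables per cycle or participant.

    ``daily`` must carry participant, cycle, date and the variable
    columns; missing means no value that day.  Statistics honour the
    inclusion thresholds: the mean needs >= 10 non-missing days, all other
    statistics >= 20.  TKEO/RMSSD are computed on the gap-imputed series
    (residual missing removed).
    """
    keys = ["participant"] if level == "participant" else ["participant", "cycle"]
    rows = []
    for key_vals, grp in daily.groupby(keys):
        if not isinstance(key_vals, tuple):
            key_vals = (key_vals,)
        grp = grp.sort_values("date")
        # reindex to consecutive days so imputation sees true gaps
        dates = pd.date_range(grp["date"].min(), grp["date"].max(), freq="D")
        grp_full = grp.set_index("date").reindex(dates)
        for var in variables:
            series = grp_full[var].astype(float)
            v = series.dropna().to_numpy()
            n = v.size
            rec = dict(zip(keys, key_vals))
            rec.update({"variable": var, "n_nonmissing": n})
            rec["mean"] = float(np.mean(v)) if n >= min_n_mean else np.nan
            if n >= min_n_other:
                rec["sd"] = float(np.std(v, ddof=1))
                rec["skewness"] = float(sps.skew(v, bias=False))
                q25, q75 = np.percentile(v, [25, 75])
                rec["q25"], rec["q75"], rec["iqr"] = float(q25), float(q75), float(q75 - q25)
                rec["mean_upper_quartile"] = _upper_quartile_mean(v)
                rec["mean_lower_quartile"] = _upper_quartile_mean(v, lower=True)
                imp = impute_series(series).dropna().to_numpy()
                rec["tkeo"] = tkeo(imp, conventional_variability)
                rec["rmssd"] = rmssd(imp, conventional_variability)
            else:
                for stat in (
                    "sd", "skewness", "q25", "q75", "iqr",
                    "mean_upper_quartile", "mean_lower_quartile", "tkeo", "rmssd",
                ):
                    rec[stat] = np.nan
            rows.append(rec)
    return pd.DataFrame(rows)


def adherence(
    diary: pd.DataFrame,
    daily_wear: pd.DataFrame,
    manifest: pd.DataFrame,
    window_days: int = 28,
    wear_threshold: float = 0.75,
) -> pd.DataFrame:
    """Per-(participant, cycle) diary and watch adherence over days 1-28.

    ``diary``: de-duplicated rows with participant, assoc_date.
    ``daily_wear``: participant, date, wear_frac_midnight.
    ``manifest``: participant, cycle, start_date (day 1), end_date.

    A watch-adherent day has wear fraction > 0.75.  Cycles where at most
    one diary entry fell in the window and no smartwatch data exists are
    excluded.  Cycles shorter than the window use the available days as
    denominator and are flagged.
    """
    diary = diary.copy()
    diary["assoc_date"] = pd.to_datetime(diary["assoc_date"]).dt.normalize()
    daily_wear = daily_wear.copy()
    daily_wear["date"] = pd.to_datetime(daily_wear["date"]).dt.normalize()
    rows = []
    for r in manifest.itertuples():
        start = pd.Timestamp(r.start_date).normalize()
        end = pd.Timestamp(r.end_date).normalize()
        n_days = min(window_days, (end - start).days + 1)
        window_end = start + pd.Timedelta(days=n_days)
        d = diary[(diary["participant"] == r.participant)
                  & (diary["assoc_date"] >= start) & (diary["assoc_date"] < window_end)]
        w = daily_wear[(daily_wear["participant"] == r.participant)
                       & (daily_wear["date"] >= start) & (daily_wear["date"] < window_end)]
        has_watch = len(w) > 0
        include = (len(d) > 1) or has_watch
        prom_frac = d["assoc_date"].nunique() / n_days
        watch_frac = (
            float((w["wear_frac_midnight"] > wear_threshold).sum()) / n_days if has_watch else np.nan
        )
        weekly_prom, weekly_watch = [], []
        for wk in range(4):
            wa = start + pd.Timedelta(days=7 * wk)
            wb = wa + pd.Timedelta(days=7)
            if wa >= window_end:
                weekly_prom.append(np.nan)
                weekly_watch.append(np.nan)
                continue
            denom = min(7, (window_end - wa).days)
            dk = d[(d["assoc_date"] >= wa) & (d["assoc_date"] < wb)]
            wkw = w[(w["date"] >= wa) & (w["date"] < wb)]
            weekly_prom.append(dk["assoc_date"].nunique() / denom)
            weekly_watch.append(
                float((wkw["wear_frac_midnight"] > wear_threshold).sum()) / denom
                if has_watch else np.nan
            )
        rows.append(
            {
                "participant": r.participant,
                "cycle": r.cycle,
                "included": include,
                "short_cycle": n_days < window_days,
                "prom_adherence": prom_frac,
                "watch_adherence": watch_frac,
                **{f"prom_week{k+1}": weekly_prom[k] for k in range(4)},
                **{f"watch_week{k+1}": weekly_watch[k] for k in range(4)},
            }
        )
    out = pd.DataFrame(rows)
    return out[out["included"]].reset_index(drop=True)
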