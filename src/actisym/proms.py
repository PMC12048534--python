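"""Daily symptom-diary and EHP-30 questionnaire scoring.

Daily diaries carry two pain items ("average pain today", "worst pain
today"; 1-10) and the nine-item Brief Fatigue Inventory (0-10 each).
Global scores are plain item means: global pain = mean of the two pain
items; global BFI = mean of the nine fatigue items (missing when fewer
than nine items are present).

Diary entries are de-duplicated per participant and associated date.
An entry submitted between 5 pm on the associated date and 5 am the next
morning is in the "correct" window; anything submitted on the associated
day or the following day is "feasible".  Correct-window entries are
preferred; among equals the earliest submission wins; entries outside
both windows are dropped.

The EHP-30 has 30 items on a 0 (Never) to 4 (Always) scale, grouped into
five subdomains (pain 11 items, control and powerlessness 6, emotional
well-being 6, social support 4, self-image 3).  Each scale score is
100 * sum(items) / (4 * n_items), so every score lies on 0-100.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

PAIN_ITEMS = ["pain_avg", "pain_worst"]
BFI_ITEMS = [f"bfi_q{i}" for i in range(1, 10)]

# Published instrument layout: items are 1-based positions in the 30-item form.
EHP30_SUBDOMAINS: dict[str, list[int]] = {
    "pain_ehp30": list(range(1, 12)),
    "control_ehp30": list(range(12, 18)),
    "emotion_ehp30": list(range(18, 24)),
    "social_ehp30": list(range(24, 28)),
    "self_ehp30": list(range(28, 31)),
}

__all__ = [
    "PAIN_ITEMS",
    "BFI_ITEMS",
    "EHP30_SUBDOMAINS",
    "classify_window",
    "deduplicate",
    "score_daily",
    "score_ehp30",
]


def classify_window(assoc_date: pd.Timestamp, submitted_at: pd.Timestamp) -> str:
    """'correct', 'feasible', or 'invalid' for one diary submission."""
    day = pd.Timestamp(assoc_date).normalize()
    t = pd.Timestamp(submitted_at)
    if day + pd.Timedelta(hours=17) <= t < day + pd.Timedelta(days=1, hours=5):
        return "correct"
    if day <= t < day + pd.Timedelta(days=2):
        return "feasible"
    return "invalid"


def deduplicate(diary: pd.DataFrame) -> pd.DataFrame:
    """One diary row per (participant, assoc_date).

    Correct-window entries beat feasible ones; ties go to the earliest
    submission; entries outside both windows are dropped.  Adds a
    ``window_class`` column.
    """
    df = diary.copy()
    df["assoc_date"] = pd.to_datetime(df["assoc_date"]).dt.normalize()
    df["submitted_at"] = pd.to_datetime(df["submitted_at"])
    df["window_class"] = [
        classify_window(d, t) for d, t in zip(df["assoc_date"], df["submitted_at"])
    ]
    df = df[df["window_class"] != "invalid"]
    rank = df["window_class"].map({"correct": 0, "feasible": 1})
    df = df.assign(_rank=rank).sort_values(["participant", "assoc_date", "_rank", "submitted_at"])
    out = df.groupby(["participant", "assoc_date"], as_index=False).first()
    return out.drop(columns="_rank")


def score_daily(diary: pd.DataFrame) -> pd.DataFrame:
    """Add global_pain and global_bfi columns to a de-duplicated diary.

    global_pain is the mean of the two pain items; global_bfi the mean of
    the nine BFI items, missing when any item is missing.  Out-of-range
    items raise a validation error naming the item.
    """
    df = diary.copy()
    for col in PAIN_ITEMS:
        bad = df[col].dropna()
        if ((bad < 1) | (bad > 10)).any():
            raise ValueError(f"item {col!r} outside its 1-10 scale")
    for col in BFI_ITEMS:
        bad = df[col].dropna()
        if ((bad < 0) | (bad > 10)).any():
            raise ValueError(f"item {col!r} outside its 0-10 scale")
    df["global_pain"] = df[PAIN_ITEMS].mean(axis=1, skipna=False)
    df["global_bfi"] = df[BFI_ITEMS].mean(axis=1, skipna=False)
    return df


def score_ehp30(
    responses: pd.DataFrame,
    subdomains: dict[str, list[int]] | None = None,
    max_missing: int = 0,
) -> pd.DataFrame:
    """Score EHP-30 responses (columns item_01..item_30, values 0-4).

    Returns one row per input row with the five subdomain scores and
    ehp30_overall, each normalized to 0-100.  A scale score is missing
    when more than ``max_missing`` of its items are missing; present
    scores use the mean over answered items scaled to 0-100.
    """
    subdomains = subdomains or EHP30_SUBDOMAINS
    items = [f"item_{i:02d}" for i in range(1, 31)]
    missing_cols = [c for c in items if c not in responses.columns]
    if missing_cols:
        raise ValueError(f"EHP-30 schema error: missing {missing_cols[0]}")
    vals = responses[items].to_numpy(float)
    if np.nanmin(vals, initial=0) < 0 or np.nanmax(vals, initial=0) > 4:
        raise ValueError("EHP-30 items must lie in 0-4")

    def scale(cols_1based: list[int]) -> np.ndarray:
        sub = vals[:, [i - 1 for i in cols_1based]]
        n_missing = np.isnan(sub).sum(axis=1)
        score = 100.0 * np.nanmean(sub, axis=1) / 4.0
        score[n_missing > max_missing] = np.nan
        return score

    out = responses.drop(columns=items).copy()
    with np.errstate(invalid="ignore"):
        for name, cols in subdomains.items():
            out[name] = scale(cols)
        out["ehp30_overall"] = scale(list(range(1, 31)))
    return out
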