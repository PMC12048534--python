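"""End-to-end orchestration: raw stream -> daily feature/symptom table.

``process_recording`` runs one recording through epoching, non-wear
detection, sleep detection and daily feature assembly.  ``run_cohort``
does this for a whole simulated or ingested cohort, joins the scored
diaries, and returns the merged daily table plus a JSON-serializable run
manifest (software version, configuration, seed) for reproducibility.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

import actisym
from actisym.features import CutPoints, assemble_daily
from actisym.ingest import RawRecording, epochize
from actisym.nonwear import NonwearConfig, wear_mask
from actisym.proms import deduplicate, score_daily
from actisym.sleep import SleepConfig, sleep_nights
from actisym.synthetic import CohortBundle

__all__ = ["process_recording", "run_cohort"]


def process_recording(
    recording: RawRecording,
    nonwear_config: NonwearConfig | None = None,
    sleep_config: SleepConfig | None = None,
    cutpoints: CutPoints | None = None,
    cycle_days: int | None = None,
) -> pd.DataFrame:
    """Daily feature table for one recording (one row per day)."""
    epochs = epochize(recording)
    mask = wear_mask(epochs, nonwear_config)
    nights = sleep_nights(epochs, mask, recording.participant_id, sleep_config)
    daily = assemble_daily(epochs, mask, nights, recording.participant_id, cutpoints=cutpoints)
    if cycle_days:
        day_index = (daily["date"] - daily["date"].min()).dt.days
        daily["cycle"] = (day_index // cycle_days + 1).astype(int)
    return daily


def run_cohort(
    bundle: CohortBundle,
    nonwear_config: NonwearConfig | None = None,
    sleep_config: SleepConfig | None = None,
    manifest_path: str | Path | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Process every recording in a bundle and join the scored diaries.

    Returns the merged participant-day table (actigraphy features plus
    global_pain/global_bfi where a diary exists) and the run manifest.
    """
    frames = []
    for pid, rec in bundle.recordings.items():
        if rec is None:
            continue
        frames.append(process_recording(rec, nonwear_config, sleep_config,
                                        cycle_days=bundle.config.days_per_cycle))
    daily = pd.concat(frames, ignore_index=True)
    diary = score_daily(deduplicate(bundle.proms))
    diary = diary.rename(columns={"assoc_date": "date"})
    merged = daily.merge(
        diary[["participant", "date", "global_pain", "global_bfi"]],
        on=["participant", "date"],
        how="left",
    )
    start = pd.Timestamp(bundle.config.start_date)
    merged["study_day"] = (merged["date"] - start).dt.days
    manifest = {
        "package": "actisym",
        "version": actisym.__version__,
        "seed": bundle.config.seed,
        "n_participants": bundle.config.n_participants,
        "days_per_cycle": bundle.config.days_per_cycle,
        "n_cycles": bundle.config.n_cycles,
        "sample_rate_hz": bundle.config.sample_rate,
        "n_daily_rows": int(len(merged)),
    }
    if manifest_path is not None:
        Path(manifest_path).write_text(json.dumps(manifest, indent=2))
    return merged, manifest
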