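"""Serialisation of designs, schedules and response logs.

Trial schedules go to CSV (one event per row), session designs to JSON,
response logs to the tidy event CSV used throughout.  Everything
round-trips exactly enough to rebuild the in-memory objects.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .timeline import NOISE_DUR_S, TONE_DUR_S, SessionDesign, make_trial

SCHEMA_VERSION = 1


def schedule_frame(design: SessionDesign) -> pd.DataFrame:
    """One event per row: trial_id, event_type, onset_s, duration_s,
    freq_hz, is_deviant."""
    rows = []
    for trial in design.trials:
        for trip in trial.triplets:
            for ev, onset in trip.events:
                rows.append({
                    "trial_id": trial.trial_id, "event_type": ev,
                    "onset_s": onset, "duration_s": TONE_DUR_S,
                    "freq_hz": trip.b_freq_hz if ev == "tone_B" else trip.a_freq_hz,
                    "is_deviant": trip.is_deviant,
                })
        for onset in trial.noise_onsets_s:
            rows.append({"trial_id": trial.trial_id, "event_type": "noise",
                         "onset_s": onset, "duration_s": NOISE_DUR_S,
                         "freq_hz": None, "is_deviant": False})
        if trial.switch_time_s is not None:
            rows.append({"trial_id": trial.trial_id, "event_type": "switch_cue",
                         "onset_s": trial.switch_time_s, "duration_s": 0.0,
                         "freq_hz": None, "is_deviant": False})
    return pd.DataFrame(rows).sort_values(["trial_id", "onset_s"],
                                          kind="stable").reset_index(drop=True)


def design_to_json(design: SessionDesign) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "stage": design.stage,
        "rng_seed": design.rng_seed,
        "trials": [
            {
                "trial_id": t.trial_id, "n_triplets": t.n_triplets,
                "delta_f": t.delta_f, "task": t.task,
                "deviant_config": list(t.deviant_config),
                "a_freq_hz": t.a_freq_hz, "seed": t.seed,
                "switch_time_s": t.switch_time_s,
            }
            for t in design.trials
        ],
    }


def design_from_json(obj: dict) -> SessionDesign:
    trials = tuple(
        make_trial(d["trial_id"], d["n_triplets"], d["delta_f"], d["task"],
                   tuple(d["deviant_config"]), d["a_freq_hz"], d["seed"])
        for d in obj["trials"]
    )
    return SessionDesign(stage=obj["stage"], trials=trials,
                         rng_seed=obj["rng_seed"])


def save_design(design: SessionDesign, path: str | Path) -> None:
    Path(path).write_text(json.dumps(design_to_json(design), indent=1))


def load_design(path: str | Path) -> SessionDesign:
    return design_from_json(json.loads(Path(path).read_text()))


def save_logs(event_frame: pd.DataFrame, path: str | Path) -> None:
    event_frame.to_csv(path, index=False)


def load_logs(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
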