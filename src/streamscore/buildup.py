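"""Build-up curves, first-report statistics and phase durations.

The reported percept is sampled at the start of each triplet; the
proportion-segregated at a grid point is the number of trials labelled
``two_streams`` divided by the number of trials with any report yet, and
is undefined where no trial has responded.  Curves can be aligned to the
sequence start or re-zeroed at the attention switch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .scoring import percept_at
from .timeline import TRIPLET_PERIOD_S, TrialSpec

#: group tests conventionally start at 2 s post-alignment; earlier points
#: are computed but flagged (see BuildupCurve.analysis_mask)
ANALYSIS_START_S = 2.0


@dataclass
class BuildupCurve:
    delta_f: int | None
    task: str | None
    alignment: str               # sequence_start | switch
    times_s: np.ndarray          # 0.5-s grid
    prop_seg: np.ndarray         # in [0,1], NaN where undefined
    n_responding: np.ndarray     # per-point denominator

    @property
    def analysis_mask(self) -> np.ndarray:
        """Points at or after the 2-s convention with a defined value."""
        return (self.times_s >= ANALYSIS_START_S) & ~np.isnan(self.prop_seg)


def sample_percept_grid(trial: TrialSpec, percept_reports) -> list[str]:
    """Label at each triplet onset: latest report at or before it,
    ``unreported`` before the first report."""
    reports = sorted(percept_reports)
    return [percept_at(t.onset_s, reports) for t in trial.triplets]


def proportion_segregated(
    label_grids: list[list[str]],
    times_s: np.ndarray | None = None,
    delta_f: int | None = None,
    task: str | None = None,
    alignment: str = "sequence_start",
    switch_time_s: float | None = None,
) -> BuildupCurve:
    """Pool per-trial label grids into one build-up curve.

    ``label_grids`` may be ragged (different sequence lengths); each grid
    is assumed to start at time 0 on the 0.5-s triplet grid.  With
    ``alignment='switch'`` times are re-zeroed at ``switch_time_s`` and
    pre-switch points dropped.
    """
    if not label_grids:
        raise ValueError("at least one trial required")
    n_max = max(len(g) for g in label_grids)
    if times_s is None:
        times_s = np.arange(n_max) * TRIPLET_PERIOD_S
    seg = np.zeros(n_max)
    n_resp = np.zeros(n_max)
    for grid in label_grids:
        for k, lab in enumerate(grid):
            if lab != "unreported":
                n_resp[k] += 1
                if lab == "two_streams":
                    seg[k] += 1
    prop = np.where(n_resp >= 1, seg / np.maximum(n_resp, 1), np.nan)
    if alignment == "switch":
        if switch_time_s is None:
            raise ValueError("switch alignment requires switch_time_s")
        keep = times_s >= switch_time_s - 1e-9
        times_s = times_s[keep] - switch_time_s
        prop, n_resp = prop[keep], n_resp[keep]
    return BuildupCurve(delta_f, task, alignment, np.asarray(times_s, float),
                        prop, n_resp)


def first_report_stats(
    trial_reports: list[list],
    alignment_zero_s: float = 0.0,
    qualify_within_s: float = 6.0,
) -> dict:
    """First-report summary for one condition.

    Returns the proportion of trials whose first report is ``two_streams``
    and the mean time (from ``alignment_zero_s``) to the first
    ``two_streams`` report, over trials where it occurs within
    ``qualify_within_s``; NaN if no trial qualifies.
    """
    first_labels = []
    first_seg_times = []
    for reports in trial_reports:
        reports = [(t, lab) for t, lab in sorted(reports) if t >= alignment_zero_s]
        if not reports:
            continue
        first_labels.append(reports[0][1])
        seg = [t for t, lab in reports if lab == "two_streams"]
        if seg and seg[0] - alignment_zero_s <= qualify_within_s:
            first_seg_times.append(seg[0] - alignment_zero_s)
    prop_seg_first = (np.mean([lab == "two_streams" for lab in first_labels])
                      if first_labels else np.nan)
    mean_t = float(np.mean(first_seg_times)) if first_seg_times else np.nan
    return {
        "prop_first_two_streams": float(prop_seg_first),
        "mean_time_to_first_two_streams_s": mean_t,
        "n_trials_reporting": len(first_labels),
        "n_trials_qualifying": len(first_seg_times),
    }


def phase_durations(percept_reports, sequence_end_s: float) -> pd.DataFrame:
    """Natural-log durations of completed perceptual phases.

    A phase runs from one report to the next alternation; the final phase,
    cut off by the end of the sequence, is censored and excluded.
    """
    reports = sorted(percept_reports)
    if not reports:
        raise ValueError("at least one report required")
    rows = []
    for (t0, lab0), (t1, _) in zip(reports[:-1], reports[1:]):
        dur = t1 - t0
        if dur <= 0:
            raise ValueError("non-positive phase duration; reports must alternate in time")
        rows.append({"percept": lab0, "duration_s": dur, "ln_duration": np.log(dur)})
    return pd.DataFrame(rows, columns=["percept", "duration_s", "ln_duration"])


def session_curves(
    session: pd.DataFrame,
    design_trials: dict,
    alignment: str = "sequence_start",
) -> pd.DataFrame:
    """Tidy per-subject build-up curves from a simulated session frame.

    Returns columns: subject, delta_f, task, alignment, time_s, prop_seg,
    n_responding.  Switch-aligned curves are built from switch trials only.
    """
    rows = []
    for (subj, df, task), grp in session.groupby(["subject", "delta_f", "task"]):
        if alignment == "switch" and task != "switch":
            continue
        grids, switch_t = [], None
        for _, r in grp.iterrows():
            trial = design_trials[r.trial_id]
            grids.append(sample_percept_grid(trial, r.log.percept_reports))
            if trial.switch_time_s is not None:
                switch_t = trial.switch_time_s
        curve = proportion_segregated(
            grids, delta_f=df, task=task, alignment=alignment,
            switch_time_s=switch_t,
        )
        for t, p, nr in zip(curve.times_s, curve.prop_seg, curve.n_responding):
            rows.append({"subject": subj, "delta_f": df, "task": task,
                         "alignment": alignment, "time_s": t,
                         "prop_seg": p, "n_responding": nr})
    return pd.DataFrame(rows)
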