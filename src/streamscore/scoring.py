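"""Deviant-detection scoring: hit windows, sectioned false alarms,
rate corrections, d-prime and criterion.

A press within the hit window after the start of a deviant's additional
silence is a hit (first press only); every other press is a false alarm,
labelled early/middle/late by fixed section boundaries.  The false-alarm
"trial" count for a section is its duration divided by the hit window,
reduced by one when the section contains a deviant.  Rates pooled over a
cell are corrected by 0.5 counts when exactly 0 or 1 so the normal
quantiles are finite; d' = z(H) - z(F) and c = -(z(H) + z(F)) / 2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .timeline import TRIPLET_PERIOD_S, TrialSpec, DEVIANT_POSITIONS

log = logging.getLogger(__name__)

DEFAULT_HIT_WINDOW_S = 1.147
LATE_SECTION_S = 6.0
RESPONSE_SLACK_S = 1.5   # presses accepted up to this long after sequence end


class ScoringError(ValueError):
    pass


@dataclass(frozen=True)
class ScoringConfig:
    hit_window_s: float = DEFAULT_HIT_WINDOW_S
    rate_correction: float = 0.5
    #: in switch trials, score only the post-switch (late) section
    switch_post_only: bool = True

    def __post_init__(self):
        if self.hit_window_s <= 0:
            raise ScoringError("hit_window_s must be positive")

    def section_boundaries(self, n_triplets: int) -> tuple[float, float, float]:
        """(end_early, end_middle, end_late) for one sequence length.

        The late section is always 6 s; the early and middle sections split
        the remainder equally (6.25/12.5/18.5 s for 37 triplets).
        """
        total = n_triplets * TRIPLET_PERIOD_S
        em = (total - LATE_SECTION_S) / 2.0
        return (em, 2 * em, total)

    def section_durations(self, n_triplets: int) -> dict[str, float]:
        e, m, l = self.section_boundaries(n_triplets)
        return {"early": e, "middle": m - e, "late": l - m}


@dataclass
class DetectionScore:
    labels: dict
    n_hits: int
    n_deviants: int
    n_fa: int
    n_nonsignal_trials: float
    hit_rate: float = field(init=False)
    fa_rate: float = field(init=False)
    dprime: float = field(init=False)
    criterion: float = field(init=False)

    def __post_init__(self):
        if self.n_hits > self.n_deviants:
            raise ScoringError("more hits than deviants")
        if self.n_nonsignal_trials < 1:
            raise ScoringError("nonsignal trial count below 1")
        self.hit_rate = _corrected_rate(self.n_hits, self.n_deviants)
        self.fa_rate = _corrected_rate(self.n_fa, self.n_nonsignal_trials)
        zh, zf = norm.ppf(self.hit_rate), norm.ppf(self.fa_rate)
        self.dprime = zh - zf
        self.criterion = -(zh + zf) / 2.0


def _corrected_rate(numer: float, denom: float, correction: float = 0.5) -> float:
    """Rate with the 0.5-count adjustment applied only at exactly 0 or 1."""
    if denom <= 0:
        raise ScoringError("rate denominator must be positive")
    rate = numer / denom
    if rate == 0.0:
        rate = correction / denom
    elif rate == 1.0:
        rate = (numer - correction) / denom
    return rate


def compute_hit_window(latencies) -> float:
    """95th percentile (linear interpolation) of deviant-locked latencies,
    pooled across conditions and subjects."""
    lat = np.asarray(list(latencies), dtype=float)
    if lat.size == 0:
        raise ScoringError("no latencies supplied")
    return float(np.percentile(lat, 95))


def match_presses(
    deviant_silences, presses, hit_window_s: float, duration_s: float,
    slack_s: float = RESPONSE_SLACK_S,
) -> list[tuple[float, str, int | None]]:
    """Core press-deviant matcher.

    Presses are processed in time order; a press falling in the window of
    the earliest not-yet-hit deviant is that deviant's hit, any other
    in-range press is a false alarm, and presses outside
    [0, duration + slack] are dropped.  Returns (press_time, kind,
    deviant_index) triples, kind in {hit, fa, dropped}, with
    deviant_index into the sorted deviant list for hits.
    """
    devs = sorted(float(d) for d in deviant_silences)
    taken = [False] * len(devs)
    out = []
    for p in sorted(float(p) for p in presses):
        if p < 0 or p > duration_s + slack_s:
            out.append((p, "dropped", None))
            continue
        hit_idx = None
        for i, d in enumerate(devs):
            if not taken[i] and 0.0 <= p - d <= hit_window_s:
                hit_idx = i
                break
        if hit_idx is None:
            out.append((p, "fa", None))
        else:
            taken[hit_idx] = True
            out.append((p, "hit", hit_idx))
    return out


def classify_responses(
    trial: TrialSpec, presses, config: ScoringConfig | None = None
) -> pd.DataFrame:
    """Classify each press of a trial as hit / fa / dropped.

    Returns one row per press with columns ``time_s``, ``kind``
    (hit|fa|dropped), ``position`` (deviant position for hits, containing
    section for FAs), ``deviant_pos`` and ``latency_s`` for hits.
    """
    config = config or ScoringConfig()
    silence = trial.deviant_silence_onsets()   # position -> time
    dev_items = sorted(silence.items(), key=lambda kv: kv[1])
    matched = match_presses([t for _, t in dev_items], presses,
                            config.hit_window_s, trial.duration_s)
    e, m, l = config.section_boundaries(trial.n_triplets)
    rows = []
    for p, kind, idx in matched:
        if kind == "dropped":
            log.warning("press at %.3f s outside trial %s; dropped",
                        p, trial.trial_id)
            rows.append({"time_s": p, "kind": kind, "position": None,
                         "deviant_pos": None, "latency_s": np.nan})
        elif kind == "hit":
            pos = dev_items[idx][0]
            rows.append({"time_s": p, "kind": kind, "position": pos,
                         "deviant_pos": pos, "latency_s": p - silence[pos]})
        else:
            section = "early" if p < e else ("middle" if p < m else "late")
            rows.append({"time_s": p, "kind": kind, "position": section,
                         "deviant_pos": None, "latency_s": np.nan})
    return pd.DataFrame(
        rows, columns=["time_s", "kind", "position", "deviant_pos", "latency_s"]
    )


def count_nonsignal_trials(
    section_duration_s: float, n_deviants_in_section: int,
    config: ScoringConfig | None = None,
) -> float:
    """Normalised nonsignal "trial" count for one section of one sequence."""
    config = config or ScoringConfig()
    if section_duration_s <= 0:
        raise ScoringError("section duration must be positive")
    if n_deviants_in_section not in (0, 1):
        raise ScoringError("a section holds at most one deviant")
    out = section_duration_s / config.hit_window_s - n_deviants_in_section
    if out <= 0:
        raise ScoringError("nonsignal trial count must be positive")
    return out


def percept_at(time_s: float, percept_reports) -> str:
    """Percept label holding at ``time_s``: the latest report at or before
    it, or ``unreported`` if none has been made yet."""
    label = "unreported"
    for t, lab in percept_reports:
        if t <= time_s:
            label = lab
        else:
            break
    return label


def score_trial(
    trial: TrialSpec,
    detection_presses,
    config: ScoringConfig | None = None,
    percept_reports=None,
) -> pd.DataFrame:
    """Per-(section x deviant) counts for one trial, tidy long format.

    One row per deviant position plus one row per section's false alarms
    and nonsignal-trial count.  For switch trials with
    ``config.switch_post_only`` only the late section is scored.
    """
    config = config or ScoringConfig()
    cls = classify_responses(trial, detection_presses, config)
    durations = config.section_durations(trial.n_triplets)
    positions = list(DEVIANT_POSITIONS)
    if trial.task == "switch" and config.switch_post_only:
        positions = ["late"]
    silence = trial.deviant_silence_onsets()
    onsets = trial.deviant_onsets()
    rows = []
    for pos in positions:
        has_dev = pos in trial.deviant_config
        hit = int(((cls.kind == "hit") & (cls.position == pos)).sum()) if has_dev else 0
        n_fa = int(((cls.kind == "fa") & (cls.position == pos)).sum())
        percept = None
        subposition = None
        if has_dev:
            subposition = onsets[pos]
            if percept_reports is not None:
                percept = percept_at(silence[pos], percept_reports)
        rows.append({
            "trial_id": trial.trial_id,
            "delta_f": trial.delta_f,
            "task": trial.task,
            "position": pos,
            "n_deviants": int(has_dev),
            "n_hits": hit,
            "n_fa": n_fa,
            "n_nonsignal": count_nonsignal_trials(durations[pos], int(has_dev), config),
            "percept": percept,
            "subposition": subposition,
        })
    out = pd.DataFrame(rows)
    out["percept"] = out["percept"].astype(object)
    out["subposition"] = out["subposition"].astype(float)
    return out


def _time_in_labels(percept_reports, t_end: float) -> dict[str, float]:
    """Seconds spent in each percept label over [0, t_end]."""
    out = {"unreported": 0.0, "one_stream": 0.0, "two_streams": 0.0}
    reports = [(t, lab) for t, lab in percept_reports if t <= t_end]
    prev_t, prev_lab = 0.0, "unreported"
    for t, lab in reports:
        out[prev_lab] += t - prev_t
        prev_t, prev_lab = t, lab
    out[prev_lab] += t_end - prev_t
    return out


def score_trial_by_percept(
    trial: TrialSpec,
    detection_presses,
    percept_reports,
    config: ScoringConfig | None = None,
) -> pd.DataFrame:
    """Percept-conditioned counts for one trial, collapsed over sections.

    Deviants are assigned the percept holding at their additional-silence
    onset; false alarms the percept at the press; the nonsignal "trial"
    denominator is the time spent under each percept divided by the hit
    window, reduced by the number of deviants under that percept.  Deviants
    occurring before any report (unreported) are excluded.
    """
    config = config or ScoringConfig()
    cls = classify_responses(trial, detection_presses, config)
    silence = trial.deviant_silence_onsets()
    labels = ("one_stream", "two_streams")
    time_in = _time_in_labels(percept_reports, trial.duration_s)
    rows = []
    for lab in labels:
        dev_here = [pos for pos in trial.deviant_config
                    if percept_at(silence[pos], percept_reports) == lab]
        hits = int(cls[(cls.kind == "hit")
                       & cls.deviant_pos.isin(dev_here)].shape[0])
        fas = int(sum(
            1 for _, r in cls[cls.kind == "fa"].iterrows()
            if percept_at(r.time_s, percept_reports) == lab
        ))
        n_ns = time_in[lab] / config.hit_window_s - len(dev_here)
        rows.append({
            "trial_id": trial.trial_id,
            "delta_f": trial.delta_f,
            "task": trial.task,
            "percept": lab,
            "n_deviants": len(dev_here),
            "n_hits": hits,
            "n_fa": fas,
            "n_nonsignal": max(n_ns, 0.0),
        })
    return pd.DataFrame(rows)


def aggregate_dprime(
    cells: pd.DataFrame,
    by=("delta_f", "position", "task"),
    config: ScoringConfig | None = None,
) -> pd.DataFrame:
    """Pool per-trial counts over ``by`` keys and compute d' and criterion.

    ``cells`` is the long table from :func:`score_trial` (optionally
    concatenated over trials and subjects, with extra key columns such as
    ``subject``, ``percept`` or ``subposition`` added to ``by``).
    """
    config = config or ScoringConfig()
    by = list(by)
    out = []
    for keys, grp in cells.groupby(by, dropna=False):
        keys = keys if isinstance(keys, tuple) else (keys,)
        n_dev = int(grp.n_deviants.sum())
        n_hit = int(grp.n_hits.sum())
        n_fa = int(grp.n_fa.sum())
        n_ns = float(grp.n_nonsignal.sum())
        if n_ns < 1:
            raise ScoringError("pooled nonsignal count below 1")
        labels = dict(zip(by, keys))
        rec = dict(labels)
        rec.update(n_hits=n_hit, n_deviants=n_dev, n_fa=n_fa, n_nonsignal=n_ns)
        if n_dev > 0:
            score = DetectionScore(labels, n_hit, n_dev, n_fa, n_ns)
            rec.update(hit_rate=score.hit_rate, fa_rate=score.fa_rate,
                       dprime=score.dprime, criterion=score.criterion)
        else:
            fa_rate = _corrected_rate(n_fa, n_ns)
            rec.update(hit_rate=np.nan, fa_rate=fa_rate,
                       dprime=np.nan, criterion=np.nan)
        out.append(rec)
    return pd.DataFrame(out)
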