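"""Synthetic listener: percept trajectories and keypress logs.

The generator plants known structure so every downstream stage can be
validated without experimental data.  Perception is a two-state chain
(integrated / segregated) stepped once per 0.5-s triplet.  The
integrated-to-segregated hazard in a window is ``1 - exp(-rate * e * dt)``
where ``e`` is effective listening time: it accrues at 1 s/s while the
tones are attended, at ``rho`` s/s while the competing noise task is
performed, and is multiplied by ``kappa`` at the attention switch.  The
three attention hypotheses are corners of this parameterisation: no
automatic streaming (rho=0), full automaticity (rho=1, kappa=1), and
partial reset (intermediate kappa).

Detection presses arise from a logistic hit model over (delta-f, position,
percept) covariates plus a subject intercept, with lognormal latencies;
false alarms follow an inhomogeneous Poisson process whose rate depends on
the current percept (more conservative while segregated).  Percept-change
reports are emitted with a lognormal motor delay; nothing is reported, and
no detection presses occur, while the listener is attending the noises.
"""

from __future__ import annotations

from dataclasses import dataclass

import math

import numpy as np
import pandas as pd

from .timeline import TRIPLET_PERIOD_S, SessionDesign, TrialSpec

INTEGRATED, SEGREGATED = "one_stream", "two_streams"


@dataclass(frozen=True)
class ListenerParams:
    subj_intercept: float = 0.0            # logits, added to hit model
    buildup_rate_4: float = 0.0025         # hazard slope, 1/s per s of effective time
    buildup_rate_8: float = 0.0060
    unattended_gain: float = 0.5           # rho: build-up accrual while unattended
    reset_fraction: float = 0.5            # kappa: effective time kept at the switch
    seg_to_int_hazard: float = 0.02        # per-triplet S->I probability
    hit_coefs: tuple = (2.2, -1.2, -0.8, 1.5)  # intercept, df8, position, integrated
    fa_rate_int: float = 0.02              # false alarms / s while integrated
    fa_rate_seg: float = 0.01              # must be <= fa_rate_int
    latency_meanlog: float = math.log(0.55)
    latency_sdlog: float = 0.45            # 95th pct ~ 1.15 s, near the 1.147-s window
    report_delay_meanlog: float = math.log(0.6)
    report_delay_sdlog: float = 0.35
    noise_task_acc: float = 0.92

    def __post_init__(self):
        if not (0.0 <= self.unattended_gain <= 1.0):
            raise ValueError("unattended_gain must lie in [0, 1]")
        if not (0.0 <= self.reset_fraction <= 1.0):
            raise ValueError("reset_fraction must lie in [0, 1]")
        if not (0.0 <= self.noise_task_acc <= 1.0):
            raise ValueError("noise_task_acc must lie in [0, 1]")
        if self.fa_rate_seg > self.fa_rate_int:
            raise ValueError("fa_rate_seg must not exceed fa_rate_int")
        if min(self.buildup_rate_4, self.buildup_rate_8,
               self.seg_to_int_hazard, self.fa_rate_int, self.fa_rate_seg) < 0:
            raise ValueError("hazards and rates must be nonnegative")

    def buildup_rate(self, delta_f: int) -> float:
        return self.buildup_rate_4 if delta_f == 4 else self.buildup_rate_8


@dataclass
class ResponseLog:
    trial_id: int
    percept_reports: list   # (time_s, label)
    detection_presses: list  # time_s
    noise_labels: list       # (time_s, label in {approach, depart})


@dataclass
class TrialTruth:
    trial_id: int
    latent: list            # percept state per triplet (INTEGRATED/SEGREGATED)
    effective_time: list    # e(t) at each triplet onset


def default_cohort(n_subjects: int = 12, seed: int = 0) -> list[ListenerParams]:
    """Per-subject parameters with modest individual differences.

    Noise-task accuracy is drawn around the group mean of 0.92 (sd 0.04)
    and clipped to [0.82, 0.98]; build-up rates and the hit-model intercept
    get mild lognormal / normal jitter.
    """
    rng = np.random.default_rng(seed)
    cohort = []
    for _ in range(n_subjects):
        gain = float(np.exp(rng.normal(0.0, 0.25)))
        cohort.append(ListenerParams(
            subj_intercept=float(rng.normal(0.0, 0.5)),
            buildup_rate_4=0.0025 * gain,
            buildup_rate_8=0.0060 * gain,
            noise_task_acc=float(np.clip(rng.normal(0.92, 0.04), 0.82, 0.98)),
        ))
    return cohort


def _attended_mask(trial: TrialSpec) -> np.ndarray:
    """Per-triplet flag: is the listener attending the tones in this window?"""
    onsets = np.array([t.onset_s for t in trial.triplets])
    if trial.task == "switch":
        return onsets >= trial.switch_time_s
    return np.ones_like(onsets, dtype=bool)


def simulate_percept_trajectory(
    trial: TrialSpec, params: ListenerParams, seed: int
) -> tuple[TrialTruth, list]:
    """Sample the latent percept chain and the emitted percept reports.

    Returns (truth, percept_reports).  Reports are emitted at state
    changes, plus an initial report, each delayed by a lognormal motor
    time; in switch trials nothing is reported before the switch.
    """
    rng = np.random.default_rng(seed)
    rate = params.buildup_rate(trial.delta_f)
    attended = _attended_mask(trial)
    dt = TRIPLET_PERIOD_S
    state = INTEGRATED
    e = 0.0
    latent, e_trace = [], []
    switched = False
    for k, trip in enumerate(trial.triplets):
        if (trial.task == "switch" and not switched
                and trip.onset_s >= trial.switch_time_s):
            e *= params.reset_fraction
            switched = True
        latent.append(state)
        e_trace.append(e)
        if state == INTEGRATED:
            p = 1.0 - math.exp(-rate * e * dt)
            if rng.random() < p:
                state = SEGREGATED
        else:
            if rng.random() < params.seg_to_int_hazard:
                state = INTEGRATED
        e += dt * (1.0 if attended[k] else params.unattended_gain)
    truth = TrialTruth(trial.trial_id, latent, e_trace)

    reports = []
    report_start = trial.switch_time_s if trial.task == "switch" else 0.0
    prev_label = None
    onsets = [t.onset_s for t in trial.triplets]
    for k, t0 in enumerate(onsets):
        if t0 < report_start:
            continue
        lab = latent[k]
        first = prev_label is None
        if first or lab != prev_label:
            delay = float(rng.lognormal(params.report_delay_meanlog,
                                        params.report_delay_sdlog))
            t_rep = t0 + delay
            if reports:
                t_rep = max(t_rep, reports[-1][0] + 0.05)
            if t_rep <= trial.duration_s + 1.5:
                reports.append((t_rep, lab))
                prev_label = lab
    return truth, reports


def simulate_detection_responses(
    trial: TrialSpec, truth: TrialTruth, params: ListenerParams, seed: int
) -> list:
    """Detection keypresses: probabilistic hits at deviants plus
    percept-dependent Poisson false alarms; silent while attending noises."""
    rng = np.random.default_rng(seed)
    attended = _attended_mask(trial)
    onsets = np.array([t.onset_s for t in trial.triplets])
    presses = []
    b0, b_df, b_pos, b_int = params.hit_coefs
    pos_code = {"early": 0, "middle": 1, "late": 2}
    silence = trial.deviant_silence_onsets()
    for pos, t_sil in silence.items():
        k = int(np.searchsorted(onsets, t_sil, side="right") - 1)
        if not attended[k]:
            continue
        integrated = truth.latent[k] == INTEGRATED
        eta = (b0 + params.subj_intercept
               + b_df * (trial.delta_f == 8)
               + b_pos * pos_code[pos]
               + b_int * integrated)
        if math.isinf(eta):
            p_hit = 1.0 if eta > 0 else 0.0
        else:
            p_hit = 1.0 / (1.0 + math.exp(-eta))
        if rng.random() < p_hit:
            lat = float(rng.lognormal(params.latency_meanlog, params.latency_sdlog))
            t = t_sil + lat
            if t <= trial.duration_s + 1.5:
                presses.append(t)
    # false alarms: piecewise-constant rate per triplet window
    for k, t0 in enumerate(onsets):
        if not attended[k]:
            continue
        rate = (params.fa_rate_int if truth.latent[k] == INTEGRATED
                else params.fa_rate_seg)
        n = rng.poisson(rate * TRIPLET_PERIOD_S)
        for _ in range(n):
            presses.append(float(t0 + rng.uniform(0, TRIPLET_PERIOD_S)))
    return sorted(presses)


def simulate_noise_labels(
    trial: TrialSpec, params: ListenerParams, seed: int
) -> tuple[list, list]:
    """(true_kinds, labelled responses); each burst is approach/depart with
    equal probability and is labelled correctly with ``noise_task_acc``."""
    rng = np.random.default_rng(seed)
    if trial.task == "attend":
        return [], []
    kinds = ["approach" if rng.random() < 0.5 else "depart"
             for _ in trial.noise_onsets_s]
    labels = []
    if trial.task == "switch":
        for onset, kind in zip(trial.noise_onsets_s, kinds):
            correct = rng.random() < params.noise_task_acc
            resp = kind if correct else ("depart" if kind == "approach" else "approach")
            labels.append((onset + 0.4 + float(rng.lognormal(math.log(0.5), 0.3)), resp))
    return kinds, labels


def simulate_trial(
    trial: TrialSpec, params: ListenerParams, seed: int, stage: str = "exp2"
) -> tuple[ResponseLog, TrialTruth, list]:
    """Simulate one trial.  The stage fixes which response streams exist:
    the objective stage yields detection presses only, the subjective stage
    percept reports only, and the dual-task experiment both."""
    truth, reports = simulate_percept_trajectory(trial, params, seed)
    report_percept = stage in ("exp1_subjective", "exp2")
    detect_deviants = stage in ("exp1_objective", "exp2")
    detect = (simulate_detection_responses(trial, truth, params, seed + 1)
              if detect_deviants else [])
    kinds, labels = simulate_noise_labels(trial, params, seed + 2)
    log = ResponseLog(trial.trial_id, reports if report_percept else [],
                      detect, labels)
    return log, truth, kinds


def simulate_session(
    design: SessionDesign,
    cohort: list[ListenerParams],
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate every trial for every subject.

    Returns a tidy frame with one row per (subject, trial) holding the
    ResponseLog and ground truth objects, plus flat condition columns.
    """
    rows = []
    for s_idx, params in enumerate(cohort):
        for trial in design.trials:
            trial_seed = (seed * 1_000_003 + s_idx * 7919 + trial.trial_id * 13) % (2**31)
            log, truth, kinds = simulate_trial(trial, params, trial_seed, design.stage)
            rows.append({
                "subject": s_idx,
                "trial_id": trial.trial_id,
                "delta_f": trial.delta_f,
                "task": trial.task,
                "n_triplets": trial.n_triplets,
                "log": log,
                "truth": truth,
                "noise_kinds": kinds,
            })
    return pd.DataFrame(rows)


def logs_to_frame(session: pd.DataFrame) -> pd.DataFrame:
    """Flatten simulated logs to the serialisable event CSV schema:
    subject, trial_id, stream in {percept, detect, noise}, time_s, value."""
    rows = []
    for _, r in session.iterrows():
        log: ResponseLog = r.log
        for t, lab in log.percept_reports:
            rows.append((r.subject, r.trial_id, "percept", t, lab))
        for t in log.detection_presses:
            rows.append((r.subject, r.trial_id, "detect", t, "yes"))
        for t, lab in log.noise_labels:
            rows.append((r.subject, r.trial_id, "noise", t, lab))
    return pd.DataFrame(rows, columns=["subject", "trial_id", "stream", "time_s", "value"])
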