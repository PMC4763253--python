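"""End-to-end orchestration: design -> simulate -> score -> analyse.

``run_experiment1`` reproduces the two-stage design: an objective stage
(deviant detection in attend and switch trials) scored to d' per cell,
and a subjective stage (continuous percept report) turned into build-up
curves, first-report statistics and the covert-attention q scan with SPM
cluster inference.  ``run_experiment2`` runs the dual-task design and the
percept-conditioned analyses: the logistic mixed-model ladder, the
adjusted count pseudo-R2 and the criterion contrast.  All randomness
flows from named seeds in the run configuration.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import buildup, covert, glmm, io, listener, scoring, spm, timeline

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    design_seed: int = 1
    listener_seed: int = 2
    permutation_seed: int = 3
    n_subjects: int = 12
    alpha: float = 0.05
    q_step: float = 0.001
    hit_window_mode: str = "auto"      # auto | fixed
    hit_window_s: float = scoring.DEFAULT_HIT_WINDOW_S
    switch_post_only: bool = True
    exclude_early_deviants: bool = False
    spm_method: str = "rft"            # rft | perm
    n_perm: int = 1000
    out_dir: str | None = None

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls(**json.loads(text))


def _trial_index(design: timeline.SessionDesign) -> dict:
    return {t.trial_id: t for t in design.trials}


def detection_latencies(session: pd.DataFrame, design: timeline.SessionDesign,
                        config: scoring.ScoringConfig,
                        attribution_window_s: float = 2.5) -> np.ndarray:
    """Deviant-locked response latencies pooled over subjects and conditions.

    Presses are attributed to deviants with a deliberately generous
    window, so the 95th-percentile hit window derived from these
    latencies is not censored by the scoring window it will define.
    """
    trials = _trial_index(design)
    wide = scoring.ScoringConfig(hit_window_s=attribution_window_s,
                                 switch_post_only=config.switch_post_only)
    lats = []
    for _, r in session.iterrows():
        cls = scoring.classify_responses(trials[r.trial_id],
                                         r.log.detection_presses, wide)
        lats.extend(cls.loc[cls.kind == "hit", "latency_s"].tolist())
    return np.asarray(lats, dtype=float)


def score_session(session: pd.DataFrame, design: timeline.SessionDesign,
                  config: scoring.ScoringConfig,
                  with_percept: bool = False) -> pd.DataFrame:
    """Per-trial per-section counts for every subject (long format)."""
    trials = _trial_index(design)
    frames = []
    for _, r in session.iterrows():
        reports = r.log.percept_reports if with_percept else None
        frame = scoring.score_trial(trials[r.trial_id],
                                    r.log.detection_presses, config, reports)
        frame.insert(0, "subject", r.subject)
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def percept_score_session(session: pd.DataFrame, design: timeline.SessionDesign,
                          config: scoring.ScoringConfig) -> pd.DataFrame:
    trials = _trial_index(design)
    frames = []
    for _, r in session.iterrows():
        frame = scoring.score_trial_by_percept(
            trials[r.trial_id], r.log.detection_presses,
            r.log.percept_reports, config)
        frame.insert(0, "subject", r.subject)
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def deviant_outcome_table(session: pd.DataFrame, design: timeline.SessionDesign,
                          config: scoring.ScoringConfig) -> pd.DataFrame:
    """One row per presented deviant: subject, delta_f, position,
    subposition, percept at the deviant, hit (0/1)."""
    trials = _trial_index(design)
    rows = []
    for _, r in session.iterrows():
        trial = trials[r.trial_id]
        cls = scoring.classify_responses(trial, r.log.detection_presses, config)
        hits = set(cls.loc[cls.kind == "hit", "deviant_pos"])
        silence = trial.deviant_silence_onsets()
        onsets = trial.deviant_onsets()
        for pos in trial.deviant_config:
            rows.append({
                "subject": r.subject, "trial_id": r.trial_id,
                "delta_f": trial.delta_f, "position": pos,
                "subposition": onsets[pos],
                "percept": scoring.percept_at(silence[pos],
                                              r.log.percept_reports),
                "hit": int(pos in hits),
            })
    return pd.DataFrame(rows)


def subject_curve_matrices(curves: pd.DataFrame, delta_f: int, task: str,
                           alignment: str) -> tuple[np.ndarray, np.ndarray]:
    """(subjects x time) matrix and the time grid for one condition."""
    sub = curves[(curves.delta_f == delta_f) & (curves.task == task)
                 & (curves.alignment == alignment)]
    piv = sub.pivot_table(index="subject", columns="time_s",
                          values="prop_seg", dropna=False)
    return piv.to_numpy(), piv.columns.to_numpy(dtype=float)


@dataclass
class Experiment1Result:
    objective_design: timeline.SessionDesign
    subjective_design: timeline.SessionDesign
    hit_window_s: float
    scores: pd.DataFrame
    curves_start: pd.DataFrame
    curves_switch: pd.DataFrame
    first_reports: pd.DataFrame
    qscan: dict                     # delta_f -> covert.QScanResult


def run_experiment1(config: RunConfig | None = None,
                    cohort=None) -> Experiment1Result:
    config = config or RunConfig()
    t0 = time.time()
    obj_design = timeline.make_session("exp1_objective", config.design_seed)
    subj_design = timeline.make_session("exp1_subjective", config.design_seed + 1)
    cohort = cohort or listener.default_cohort(config.n_subjects,
                                               config.listener_seed)
    obj_session = listener.simulate_session(obj_design, cohort,
                                            config.listener_seed)
    subj_session = listener.simulate_session(subj_design, cohort,
                                             config.listener_seed + 1)
    log.info("simulated %d + %d trials x %d subjects in %.1f s",
             len(obj_design.trials), len(subj_design.trials), len(cohort),
             time.time() - t0)

    sconfig = scoring.ScoringConfig(switch_post_only=config.switch_post_only)
    if config.hit_window_mode == "auto":
        lats = detection_latencies(obj_session, obj_design, sconfig)
        window = scoring.compute_hit_window(lats)
    else:
        window = config.hit_window_s
    sconfig = scoring.ScoringConfig(hit_window_s=window,
                                    switch_post_only=config.switch_post_only)

    cells = score_session(obj_session, obj_design, sconfig)
    scores = scoring.aggregate_dprime(cells, by=["subject", "delta_f",
                                                 "position", "task"],
                                      config=sconfig)

    trials = _trial_index(subj_design)
    curves_start = buildup.session_curves(subj_session, trials, "sequence_start")
    curves_switch = buildup.session_curves(subj_session, trials, "switch")

    fr_rows = []
    for (subj, df, task), grp in subj_session.groupby(
            ["subject", "delta_f", "task"]):
        align0 = timeline.SWITCH_TIME_S if task == "switch" else 0.0
        stats = buildup.first_report_stats(
            [r.log.percept_reports for _, r in grp.iterrows()], align0)
        stats.update(subject=subj, delta_f=df, task=task)
        fr_rows.append(stats)
    first_reports = pd.DataFrame(fr_rows)

    qscan = {}
    n_analysis_start = int(round(buildup.ANALYSIS_START_S
                                 / timeline.TRIPLET_PERIOD_S))
    q_grid = np.arange(0.0, 1.0 + 1e-12, config.q_step)
    for df in timeline.VALID_DELTA_F:
        A, _ = subject_curve_matrices(curves_start, df, "attend",
                                      "sequence_start")
        S, _ = subject_curve_matrices(curves_switch, df, "switch", "switch")
        qscan[df] = covert.scan_q(
            A, S, q_grid=q_grid, alpha=config.alpha,
            method=config.spm_method, n_perm=config.n_perm,
            seed=config.permutation_seed,
            analysis_start=n_analysis_start,
        )

    result = Experiment1Result(obj_design, subj_design, window, scores,
                               curves_start, curves_switch, first_reports,
                               qscan)
    if config.out_dir:
        _write_exp1(result, config)
    return result


@dataclass
class Experiment2Result:
    design: timeline.SessionDesign
    hit_window_s: float
    scores: pd.DataFrame
    percept_scores: pd.DataFrame
    criterion_contrast: pd.DataFrame
    outcomes: pd.DataFrame
    ladder: glmm.ModelComparison
    curves_start: pd.DataFrame


def run_experiment2(config: RunConfig | None = None,
                    cohort=None) -> Experiment2Result:
    config = config or RunConfig()
    design = timeline.make_session("exp2", config.design_seed + 2)
    cohort = cohort or listener.default_cohort(config.n_subjects,
                                               config.listener_seed)
    session = listener.simulate_session(design, cohort,
                                        config.listener_seed + 2)
    sconfig = scoring.ScoringConfig()
    if config.hit_window_mode == "auto":
        lats = detection_latencies(session, design, sconfig)
        sconfig = scoring.ScoringConfig(
            hit_window_s=scoring.compute_hit_window(lats))

    cells = score_session(session, design, sconfig, with_percept=True)
    scores = scoring.aggregate_dprime(cells, by=["subject", "delta_f",
                                                 "position", "task"],
                                      config=sconfig)
    pcells = percept_score_session(session, design, sconfig)
    percept_scores = scoring.aggregate_dprime(
        pcells, by=["subject", "percept"], config=sconfig)
    contrast = glmm.criterion_contrast(percept_scores)

    outcomes = deviant_outcome_table(session, design, sconfig)
    ladder_rows = outcomes[outcomes.percept != "unreported"]
    if config.exclude_early_deviants:
        ladder_rows = ladder_rows[ladder_rows.position != "early"]
    ladder = glmm.lr_ladder(ladder_rows, alpha=config.alpha)

    trials = _trial_index(design)
    curves = buildup.session_curves(session, trials, "sequence_start")

    result = Experiment2Result(design, sconfig.hit_window_s, scores,
                               percept_scores, contrast, outcomes, ladder,
                               curves)
    if config.out_dir:
        _write_exp2(result, config)
    return result


def _manifest(config: RunConfig, stage: str) -> dict:
    return {"stage": stage, "config": asdict(config),
            "schema_version": io.SCHEMA_VERSION}


def _write_exp1(result: Experiment1Result, config: RunConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    io.save_design(result.objective_design, out / "design_objective.json")
    io.save_design(result.subjective_design, out / "design_subjective.json")
    result.scores.to_csv(out / "scores.csv", index=False)
    result.curves_start.to_csv(out / "buildup_start.csv", index=False)
    result.curves_switch.to_csv(out / "buildup_switch.csv", index=False)
    result.first_reports.to_csv(out / "first_reports.csv", index=False)
    summary = {}
    for df, scan in result.qscan.items():
        summary[str(df)] = {"nonsignificant_intervals": scan.intervals()}
        pd.DataFrame({
            "q": scan.q_grid, "max_abs_t": scan.max_abs_t,
            "n_clusters": scan.n_clusters, "min_cluster_p": scan.min_cluster_p,
            "significant": scan.significant,
        }).to_csv(out / f"qscan_df{df}.csv", index=False)
    summary["hit_window_s"] = result.hit_window_s
    (out / "covert_attention.json").write_text(json.dumps(summary, indent=1))
    (out / "manifest_exp1.json").write_text(
        json.dumps(_manifest(config, "exp1"), indent=1))


def _write_exp2(result: Experiment2Result, config: RunConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    io.save_design(result.design, out / "design_exp2.json")
    result.scores.to_csv(out / "scores_exp2.csv", index=False)
    result.percept_scores.to_csv(out / "percept_scores.csv", index=False)
    result.criterion_contrast.to_csv(out / "criterion_contrast.csv", index=False)
    result.outcomes.to_csv(out / "deviant_outcomes.csv", index=False)
    ladder_json = {
        "steps": result.ladder.ladder,
        "winning_terms": result.ladder.winning_terms,
    }
    (out / "ladder.json").write_text(json.dumps(ladder_json, indent=1, default=float))
    (out / "manifest_exp2.json").write_text(
        json.dumps(_manifest(config, "exp2"), indent=1))


def dual_task_cost(exp1_scores: pd.DataFrame,
                   exp2_scores: pd.DataFrame) -> pd.DataFrame:
    """Per subject x delta_f x position d' difference (single minus dual
    task) over attend-condition cells: the inputs to the dual-task-cost
    comparison."""
    a = exp1_scores[exp1_scores.task == "attend"]
    b = exp2_scores[exp2_scores.task == "dual"]
    keys = ["subject", "delta_f", "position"]
    merged = a.merge(b, on=keys, suffixes=("_exp1", "_exp2"))
    merged["dprime_drop"] = merged.dprime_exp1 - merged.dprime_exp2
    return merged[keys + ["dprime_exp1", "dprime_exp2", "dprime_drop"]]
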