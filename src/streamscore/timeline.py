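"""Deterministic construction of ABA- trial schedules.

Sequences are built from ABA- triplets presented every 500 ms: a 50-ms A
tone, a 75-ms gap, a 50-ms B tone, a 75-ms gap, a second A tone, then a
200-ms inter-triplet gap.  In a rhythmically deviant triplet the B tone is
delayed by a further 50 ms.  A contralateral series of 400-ms noise bursts
carries the competing labelling task; in switch trials the bursts stop at
the attention-switch time, halfway between the mean middle and late deviant
onsets (12.5 s).

All times are seconds from sequence onset; triplet indices are 1-based;
intervals are half-open [onset, onset + duration).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import numpy as np

TRIPLET_PERIOD_S = 0.5
TONE_DUR_S = 0.050
B_OFFSET_S = 0.125          # B-tone onset within a standard triplet
B_OFFSET_DEVIANT_S = 0.175  # B-tone onset when the triplet is deviant
A2_OFFSET_S = 0.250         # second A tone
NOISE_DUR_S = 0.400
NOISE_GAP_MIN_S = 0.75
NOISE_GAP_MAX_S = 1.25
SWITCH_TIME_S = 12.5        # midpoint of mean middle (10 s) and late (15 s) onsets
A_FREQ_CENTER_HZ = 800.0

VALID_N_TRIPLETS = (35, 37, 39)
VALID_DELTA_F = (4, 8)
DEVIANT_POSITIONS = ("early", "middle", "late")
#: all 2^3 present/absent combinations of early/middle/late deviants
DEVIANT_CONFIGS = tuple(
    tuple(p for p, keep in zip(DEVIANT_POSITIONS, bits) if keep)
    for bits in itertools.product((False, True), repeat=3)
)

STAGES = ("exp1_objective", "exp1_subjective", "exp2")


class DesignError(ValueError):
    """Raised when a trial or session specification is invalid."""


@dataclass(frozen=True)
class TripletSpec:
    index: int          # 1-based ordinal
    onset_s: float      # (index - 1) * 0.5
    is_deviant: bool
    a_freq_hz: float
    b_freq_hz: float

    @property
    def b_onset_s(self) -> float:
        return self.onset_s + (B_OFFSET_DEVIANT_S if self.is_deviant else B_OFFSET_S)

    @property
    def events(self) -> list[tuple[str, float]]:
        """(event_type, onset_s) for the three tones of this triplet."""
        return [
            ("tone_A", self.onset_s),
            ("tone_B", self.b_onset_s),
            ("tone_A", self.onset_s + A2_OFFSET_S),
        ]


@dataclass(frozen=True)
class TrialSpec:
    trial_id: int
    n_triplets: int
    delta_f: int
    task: str                       # attend | switch | dual
    deviant_config: tuple[str, ...]
    triplets: tuple[TripletSpec, ...]
    noise_onsets_s: tuple[float, ...]
    switch_time_s: float | None = None   # present iff task == "switch"
    seed: int = 0

    @property
    def duration_s(self) -> float:
        return self.n_triplets * TRIPLET_PERIOD_S

    @property
    def a_freq_hz(self) -> float:
        return self.triplets[0].a_freq_hz

    def deviant_triplets(self) -> list[TripletSpec]:
        return [t for t in self.triplets if t.is_deviant]

    def deviant_onsets(self) -> dict[str, float]:
        """Map deviant position label -> triplet onset (s)."""
        idx = deviant_indices(self.n_triplets)
        return {
            pos: (idx[pos] - 1) * TRIPLET_PERIOD_S
            for pos in self.deviant_config
        }

    def deviant_silence_onsets(self) -> dict[str, float]:
        """Onset of the *additional* silence of each deviant.

        The extra 50 ms of silence starts where the standard B tone would
        have begun (triplet onset + 125 ms); the hit window is measured
        from this instant.
        """
        return {
            pos: on + B_OFFSET_S for pos, on in self.deviant_onsets().items()
        }


@dataclass(frozen=True)
class SessionDesign:
    stage: str
    trials: tuple[TrialSpec, ...]
    rng_seed: int


def deviant_indices(n_triplets: int) -> dict[str, int]:
    """1-based triplet indices of the three potential deviant positions.

    Early is the sixth triplet (onset 2.5 s); late is the seventh-from-last
    counted inclusively (onsets 14/15/16 s for lengths 35/37/39); middle is
    the seventeenth-from-last, which places it at 9/10/11 s, consistent with
    the stated onset times and the 12.5-s switch midpoint.
    """
    if n_triplets not in VALID_N_TRIPLETS:
        raise DesignError(f"n_triplets must be one of {VALID_N_TRIPLETS}, got {n_triplets}")
    return {
        "early": 6,
        "middle": n_triplets - 16,
        "late": n_triplets - 6,
    }


def b_freq_for(a_freq_hz: float, delta_f: int) -> float:
    return a_freq_hz * 2.0 ** (delta_f / 12.0)


def build_triplet_timeline(
    n_triplets: int, delta_f: int, a_freq_hz: float = A_FREQ_CENTER_HZ
) -> list[TripletSpec]:
    """Lay out ``n_triplets`` standard triplets on the 0.5-s grid."""
    if not isinstance(n_triplets, (int, np.integer)) or n_triplets < 1:
        raise DesignError(f"n_triplets must be a positive integer, got {n_triplets!r}")
    if delta_f not in VALID_DELTA_F:
        raise DesignError(f"delta_f must be one of {VALID_DELTA_F}, got {delta_f!r}")
    if a_freq_hz <= 0:
        raise DesignError(f"a_freq_hz must be positive, got {a_freq_hz!r}")
    b = b_freq_for(a_freq_hz, delta_f)
    return [
        TripletSpec(
            index=i,
            onset_s=(i - 1) * TRIPLET_PERIOD_S,
            is_deviant=False,
            a_freq_hz=a_freq_hz,
            b_freq_hz=b,
        )
        for i in range(1, int(n_triplets) + 1)
    ]


def place_deviants(
    timeline: list[TripletSpec],
    deviant_config: tuple[str, ...] | list[str],
    n_triplets: int | None = None,
) -> list[TripletSpec]:
    """Flag the triplets named by ``deviant_config`` as deviant."""
    n = len(timeline) if n_triplets is None else n_triplets
    config = tuple(deviant_config)
    for pos in config:
        if pos not in DEVIANT_POSITIONS:
            raise DesignError(f"unknown deviant position {pos!r}")
    if len(set(config)) != len(config):
        raise DesignError(f"duplicate positions in deviant config {config!r}")
    idx = deviant_indices(n) if n in VALID_N_TRIPLETS else {
        "early": 6, "middle": n - 16, "late": n - 6
    }
    targets = [idx[pos] for pos in config]
    if len(set(targets)) != len(targets) or any(t < 1 or t > n for t in targets):
        raise DesignError(
            f"deviant config {config!r} collides or falls outside a {n}-triplet sequence"
        )
    target_set = set(targets)
    return [
        replace(t, is_deviant=True) if t.index in target_set else t
        for t in timeline
    ]


def schedule_noises(switch_time_s: float, seed: int) -> list[float]:
    """Noise-burst onsets: first at 0, gaps uniform on [0.75, 1.25] s,
    truncated so every 400-ms burst ends by ``switch_time_s``."""
    if switch_time_s <= 0:
        raise DesignError(f"switch_time_s must be positive, got {switch_time_s!r}")
    rng = np.random.default_rng(seed)
    onsets = [0.0]
    while True:
        nxt = onsets[-1] + rng.uniform(NOISE_GAP_MIN_S, NOISE_GAP_MAX_S)
        if nxt + NOISE_DUR_S > switch_time_s:
            break
        onsets.append(float(nxt))
    return onsets


def make_trial(
    trial_id: int,
    n_triplets: int,
    delta_f: int,
    task: str,
    deviant_config: tuple[str, ...],
    a_freq_hz: float,
    seed: int,
) -> TrialSpec:
    timeline = build_triplet_timeline(n_triplets, delta_f, a_freq_hz)
    timeline = place_deviants(timeline, deviant_config, n_triplets)
    if task == "switch":
        switch = SWITCH_TIME_S
        noise_end = switch
    elif task in ("attend", "dual"):
        switch = None
        noise_end = n_triplets * TRIPLET_PERIOD_S
    else:
        raise DesignError(f"unknown task {task!r}")
    noises = schedule_noises(noise_end, seed)
    return TrialSpec(
        trial_id=trial_id,
        n_triplets=n_triplets,
        delta_f=delta_f,
        task=task,
        deviant_config=tuple(deviant_config),
        triplets=tuple(timeline),
        noise_onsets_s=tuple(noises),
        switch_time_s=switch,
        seed=seed,
    )


def _stage_cells(stage: str) -> list[tuple[int, tuple[str, ...], str, int]]:
    """(delta_f, deviant_config, task, n_triplets) factorial cells."""
    if stage == "exp1_objective":
        return [
            (df, cfg, task, n)
            for df in VALID_DELTA_F
            for cfg in DEVIANT_CONFIGS
            for task in ("attend", "switch")
            for n in VALID_N_TRIPLETS
        ]
    if stage == "exp1_subjective":
        return [
            (df, cfg, task, 37)
            for df in VALID_DELTA_F
            for cfg in DEVIANT_CONFIGS
            for task in ("attend", "switch")
        ]
    if stage == "exp2":
        return [
            (df, cfg, "dual", n)
            for df in VALID_DELTA_F
            for cfg in DEVIANT_CONFIGS
            for n in VALID_N_TRIPLETS
        ]
    raise DesignError(f"unknown stage {stage!r}; expected one of {STAGES}")


def make_session(stage: str, rng_seed: int) -> SessionDesign:
    """Build the full factorial trial set for one stage, order randomised.

    The A frequency is drawn per trial log-uniformly over one octave
    centred on 800 Hz.
    """
    cells = _stage_cells(stage)
    rng = np.random.default_rng(rng_seed)
    order = rng.permutation(len(cells))
    trials = []
    for tid, k in enumerate(order):
        df, cfg, task, n = cells[k]
        a_freq = float(A_FREQ_CENTER_HZ * 2.0 ** rng.uniform(-0.5, 0.5))
        trial_seed = int(rng.integers(0, 2**31 - 1))
        trials.append(make_trial(tid, n, df, task, cfg, a_freq, trial_seed))
    return SessionDesign(stage=stage, trials=tuple(trials), rng_seed=rng_seed)
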