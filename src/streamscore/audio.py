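"""Optional audio rendering of trial schedules.

Tones are 50-ms sinusoids with 10-ms linear onset/offset ramps; noise
bursts are 400-ms bandpass (2-3 kHz) tokens with asymmetric linear ramps
giving an impression of motion ("approach": 350-ms attack / 50-ms decay;
"depart": reversed).  Triplets and noises go to opposite channels.
Analyses operate on schedules; rendering exists for listening checks and
for the schedule round-trip test.
"""

from __future__ import annotations

import numpy as np
from scipy import signal
from scipy.io import wavfile

from .timeline import NOISE_DUR_S, TONE_DUR_S, TrialSpec, DesignError

DEFAULT_SR = 44_100
RAMP_S = 0.010
NOISE_BAND_HZ = (2000.0, 3000.0)


def _tone(freq_hz: float, sr: int) -> np.ndarray:
    n = int(round(TONE_DUR_S * sr))
    t = np.arange(n) / sr
    x = np.sin(2 * np.pi * freq_hz * t)
    nr = int(round(RAMP_S * sr))
    ramp = np.ones(n)
    ramp[:nr] = np.arange(nr) / nr
    ramp[-nr:] = np.minimum(ramp[-nr:], np.arange(nr, 0, -1) / nr)
    return x * ramp


def _noise_token(kind: str, sr: int, rng: np.random.Generator) -> np.ndarray:
    """400-ms bandpass noise with motion ramps, energy confined to the token."""
    n = int(round(NOISE_DUR_S * sr))
    white = rng.standard_normal(n)
    # high-order zero-phase bandpass; order chosen for >= 60 dB stopbands
    sos = signal.butter(8, NOISE_BAND_HZ, btype="bandpass", fs=sr, output="sos")
    x = signal.sosfiltfilt(sos, white)
    x = x / (np.max(np.abs(x)) + 1e-12)
    attack = 0.350 if kind == "approach" else 0.050
    decay = NOISE_DUR_S - attack
    na, nd = int(round(attack * sr)), int(round(decay * sr))
    ramp = np.ones(n)
    ramp[:na] = np.arange(na) / max(na, 1)
    ramp[n - nd:] = np.arange(nd, 0, -1) / max(nd, 1)
    return x * ramp


def render_audio(
    trial: TrialSpec,
    sample_rate: int = DEFAULT_SR,
    ear_assignment: str = "tones_left",
    noise_kinds: list[str] | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Render a trial to a (n_samples, 2) float waveform in [-1, 1].

    ``noise_kinds`` optionally fixes each burst's approach/depart identity;
    otherwise each is drawn at random with equal probability.
    """
    if sample_rate / 2 <= NOISE_BAND_HZ[1]:
        raise DesignError(
            f"sample rate {sample_rate} too low for {NOISE_BAND_HZ[1]:.0f} Hz content"
        )
    if ear_assignment not in ("tones_left", "tones_right"):
        raise DesignError(f"unknown ear assignment {ear_assignment!r}")
    rng = np.random.default_rng(seed)
    dur = trial.duration_s + 0.1
    n = int(round(dur * sample_rate))
    tones = np.zeros(n)
    noises = np.zeros(n)
    for trip in trial.triplets:
        for _, onset in trip.events:
            freq = trip.b_freq_hz if _ == "tone_B" else trip.a_freq_hz
            seg = _tone(freq, sample_rate)
            i = int(round(onset * sample_rate))
            tones[i:i + len(seg)] += seg
    if noise_kinds is None:
        noise_kinds = [
            "approach" if rng.random() < 0.5 else "depart"
            for _ in trial.noise_onsets_s
        ]
    for onset, kind in zip(trial.noise_onsets_s, noise_kinds):
        seg = _noise_token(kind, sample_rate, rng)
        i = int(round(onset * sample_rate))
        seg = seg[: max(0, n - i)]
        noises[i:i + len(seg)] += seg
    stereo = np.zeros((n, 2))
    left, right = (0, 1) if ear_assignment == "tones_left" else (1, 0)
    stereo[:, left] = 0.5 * tones
    stereo[:, right] = 0.5 * noises
    return stereo


def write_wav(path: str, waveform: np.ndarray, sample_rate: int = DEFAULT_SR) -> None:
    """Write 16-bit PCM stereo WAV."""
    pcm = np.clip(waveform, -1.0, 1.0)
    wavfile.write(path, sample_rate, (pcm * 32767).astype(np.int16))


def detect_onsets(channel: np.ndarray, sample_rate: int, eps: float = 1e-9,
                  min_gap_s: float = 0.002) -> list[float]:
    """Recover event onsets from one rendered channel.

    An event starts one sample before the first non-silent sample of a
    non-silent run (the linear ramp makes the onset sample itself zero).
    Runs separated by less than ``min_gap_s`` are merged, since a pure
    tone passes exactly through zero at isolated samples.
    """
    active = np.abs(channel) > eps
    idx = np.flatnonzero(active)
    if idx.size == 0:
        return []
    min_gap = max(int(round(min_gap_s * sample_rate)), 1)
    breaks = np.flatnonzero(np.diff(idx) > min_gap)
    starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    return [(max(int(i) - 1, 0)) / sample_rate for i in starts]
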