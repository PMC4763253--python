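"""Build a factorial session design and inspect one trial's schedule.

Sequences of 35/37/39 ABA- triplets (one per 500 ms) carry up to three
rhythmic deviants (B tone delayed 50 ms) at early/middle/late positions;
contralateral noise bursts carry the competing labelling task.
"""

from streamscore import io, timeline

design = timeline.make_session("exp1_objective", rng_seed=7)
print(f"stage: {design.stage}, trials: {len(design.trials)}")

trial = next(t for t in design.trials
             if t.task == "switch" and len(t.deviant_config) == 3)
print(f"\ntrial {trial.trial_id}: {trial.n_triplets} triplets "
      f"({trial.duration_s} s), delta-f {trial.delta_f} semitones, "
      f"A = {trial.a_freq_hz:.1f} Hz")
print(f"deviant onsets (s): {trial.deviant_onsets()}")
print(f"attention switch at {trial.switch_time_s} s; "
      f"{len(trial.noise_onsets_s)} noise bursts before it")

events = io.schedule_frame(design)
print("\nfirst events of this trial:")
print(events[events.trial_id == trial.trial_id].head(8).to_string(index=False))
# The deviant onsets land at 2.5 s and on the 9-11 / 14-16 s grids, and
# the switch sits exactly halfway between the mean middle and late onsets.
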