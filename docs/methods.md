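# Methods

`streamscore` re-implements, end to end, the analysis machinery of a
dual-measure auditory-streaming experiment: a *subjective* measure
(continuous reports of hearing one integrated "galloping" stream versus
two segregated streams) and an *objective* measure (detection of
rhythmically deviant triplets) collected on the same ABA- tone
sequences.  No behavioural data ship with the package; every stage is
driven and validated by a synthetic listener with planted structure.

## Stimulus design

A sequence is 35, 37 or 39 ABA- triplets presented every 500 ms.  Within
a triplet the A tone starts at 0 ms, the B tone at 125 ms and the second
A at 250 ms; all tones last 50 ms with 10-ms linear ramps.  The B
frequency sits Δf ∈ {4, 8} semitones above A (ratio 2^(Δf/12)); A is
drawn log-uniformly over one octave centred on 800 Hz per trial.  In a
*deviant* triplet the B tone is delayed 50 ms (onset 175 ms), creating
an extra stretch of silence whose start anchors the hit window.

Deviants occupy up to three positions.  Early is the sixth triplet
(onset 2.5 s).  Late is the seventh-from-last counted inclusively
(onsets 14/15/16 s for the three lengths).  Middle is placed at the
seventeenth-from-last, giving onsets 9/10/11 s; the alternative
eighteenth-from-last reading would put it at 8.5/9.5/10.5 s and
contradict both the stated onset times and the 12.5-s switch midpoint,
so the onset times are treated as authoritative.  The attention switch
in switch-task trials sits at 12.5 s, the midpoint of the mean middle
(10 s) and mean late (15 s) onsets, for every sequence length.

Contralateral 400-ms noise bursts (2-3 kHz bandpass; "approach" =
350/50-ms attack/decay ramps, "depart" reversed) start at 0 and recur
with gaps drawn i.i.d. uniform on [0.75, 1.25] s (a mean 1-s rate with
±250 ms rectangular jitter; per-gap independence is a choice, since a
cumulative-drift constraint would satisfy the same mean-rate
description).  Bursts are truncated so each ends by the switch time in
switch trials, or by the sequence end otherwise.

A stage design is the exact factorial crossing, order-randomised by
seed: 96 trials for the objective stage (2 Δf x 8 deviant configurations
x 2 tasks x 3 lengths), 32 for the subjective stage (all length 37) and
48 for the dual-task experiment.  Audio rendering (44.1 kHz, 16-bit
stereo WAV, tones and noises on opposite channels) is optional plumbing:
all analyses operate on schedules.  The noise bandpass uses an 8th-order
Butterworth applied forward-backward (zero phase), which comfortably
exceeds 60 dB stopband attenuation; the exact filter order is otherwise
unconstrained.

## Synthetic listener

The generator is the minimal mechanism that can express the three
attention hypotheses the analyses contrast, not a biophysical model.
Perception is a two-state chain (integrated/segregated) stepped per
0.5-s triplet window.  The integrated-to-segregated transition
probability in a window is `1 - exp(-r_Δf * e(t) * dt)`, where `e(t)` is
*effective listening time*: it accrues at 1 s/s while the tones are
attended and at ρ s/s while the competing noise task is performed, and
is multiplied by κ at the attention switch.  The corners of (ρ, κ) are
the hypotheses: ρ=0 means no streaming without attention; ρ=1, κ=1
means fully automatic streaming unaffected by the switch; intermediate
κ is partial resetting.  A constant per-triplet hazard returns
segregated to integrated, making perception bistable late in the
sequence.

Defaults (chosen once to produce curve shapes typical of intermediate
streaming, and then treated as the study conditions): r₄ = 0.0025,
r₈ = 0.006 s⁻² (build-up reaching roughly 0.3/0.6 proportion segregated
by 18.5 s), ρ = κ = 0.5, segregated-to-integrated hazard 0.02 per
triplet.  A cohort applies mild between-subject lognormal jitter (sd
0.25 log units) to the rates and a normal subject intercept (sd 0.5
logits) to the hit model.

Percept reports are emitted at state changes (plus an initial report)
with lognormal motor delay (meanlog ln 0.6 s, sdlog 0.35); nothing is
reported, and no detection presses occur, while the listener attends
the noises, since experience before the first report is unobservable.
Detection presses arise per deviant with probability
logistic(intercept + β_Δf·[Δf=8] + β_pos·position + β_percept·[integrated] +
subject intercept), defaults (2.2, -1.2, -0.8, +1.5) logits, and
lognormal latency meanlog ln 0.55 s, sdlog 0.45 — placing the 95th
latency percentile at 1.15 s, i.e. near the 1.147-s scoring window the
pipeline derives.  False alarms follow an inhomogeneous Poisson process
at 0.02/s while integrated and 0.01/s while segregated, encoding the
more conservative criterion during segregation.  Noise bursts are
labelled correctly with per-subject probability drawn around 0.92 (sd
0.04, clipped to [0.82, 0.98]).

What the generator deliberately omits: adaptation and neural dynamics,
percept-report hysteresis, attention lapses, learning across blocks,
and any fit of the generator itself to published group curves.  Passing
recovery tests therefore demonstrates that the *analysis machinery* is
correct and calibrated — not that real listeners obey the generative
model.

## Deviant-detection scoring

A press within the hit window after the start of a deviant's additional
silence is that deviant's hit; the first press in a window wins and any
further press is a false alarm (the matcher is equivalent to maximal
press-deviant matching for non-overlapping windows, verified against a
brute-force oracle).  The default window is 1.147 s; `auto` mode
recomputes it as the 95th percentile (linear-interpolation definition)
of deviant-locked latencies pooled over everything, collected with a
deliberately generous 2.5-s attribution window so the percentile is not
censored by the window it defines.

False alarms are labelled early/middle/late by fixed boundaries: the
late section is always the final 6 s and the early and middle sections
split the remainder equally (6.25/12.5/18.5 s for 37 triplets).  The
nonsignal "trial" count for a section is duration / window, minus one
per deviant in the section.  Counts are pooled over all instances of a
cell (Δf x position x task, optionally percept or subposition), and the
0.5-count correction applies only when a pooled rate is exactly 0 or 1.
Then d' = z(H) - z(F) and criterion c = -(z(H) + z(F))/2.  In switch
trials only the post-switch (late) section is scored, since the
listener neither attends nor presses earlier; a toggle restores
full-sequence scoring.  Percept-conditioned cells assign deviants the
percept at their silence onset and false alarms the percept at the
press, with the nonsignal denominator taken from time spent under each
percept; deviants before any report are excluded from percept cells but
kept in stimulus cells.

## Build-up curves

The reported percept is sampled at each triplet onset (a report at the
sampling instant counts its new label).  Proportion segregated at a
grid point divides "two streams" trials by trials with any report yet,
undefined where none has responded; switch alignment re-zeroes time at
12.5 s.  Group tests conventionally start 2 s post-alignment; earlier
points are computed and flagged.  Phase durations between alternations
are natural-log transformed; the final, censored phase is excluded (the
handling of the censored phase is a convention, not a claim).
Time-to-first-segregated-report statistics use only trials where that
report lands within 6 s of alignment zero.

## Covert-attention model and q scan

The model assumes attention is wholly on the tones or the noises in
each 0.5-s window, independently with probability q on the tones.  The
probability that attention has been continuously on the tones for
exactly k windows just before the switch is geometric, w_k = (1-q)q^k
for k < K and w_K = q^K, with K = 25 windows in the 12.5-s pre-switch
period.  The modelled switch curve is M(t) = Σ_k w_k A(t + k·0.5) with
A the attend curve as a function of time-since-attending, clamped at
its last defined value beyond its support (clamping is appropriate
because the attend curve is near-asymptotic late in the sequence;
linear extrapolation is available as a config switch) and interior
undefined points linearly interpolated.

The scan walks q over a 0.001-step grid (matching the three-decimal
precision the exclusion bounds are conventionally reported at).  For
each q the mixture is applied to *each subject's own* attend curve, the
per-subject difference against that subject's observed switch curve is
formed, and the SPM cluster test is run on the difference fields; q
survives if no cluster is significant.  Applying the mixture per
subject keeps the test paired — the group-level alternative (test the
group-mean curves) is not available to a subjects-random-effects SPM,
so the paired construction is the package's documented choice.  The
surviving set is reported as grid intervals; non-contiguity triggers a
warning rather than an error.

## One-dimensional SPM

The paired t statistic is computed pointwise (listwise NaN exclusion,
reported df is the minimum across points; zero-variance points go to
±∞ with a warning and are capped at the t(0.9999) quantile before
clustering).  Smoothness is estimated from the gradients of pointwise
unit-normalised residuals: FWHM = sqrt(4 ln 2) / RMS gradient, the
standard 1D random-field estimator (white noise → sqrt(2 ln 2) ≈ 1.18
grid units); resels = (L-1)/FWHM.  The family-wise threshold is the
smallest u whose expected Euler characteristic — survival function plus
resels times the 1D EC density of a t field — falls to α/2 per tail
(inference is two-tailed, since the hypothesis is "differed
significantly" without direction).  Cluster p-values use the standard
extent approximation: with E[m] expected clusters and E[N] expected
suprathreshold resels, P(extent ≥ k) = exp(-βk²),
β = (Γ(3/2)·E[m]/E[N])², and cluster-level
p = 1 - exp(-E[m]·P(extent ≥ k)).

The sign-flip permutation test is the assumption-free oracle: it uses
the same cluster-forming threshold (so cluster boundaries coincide with
the RFT route by construction) and builds the null distribution of the
maximum cluster mass (sum of |t| - u) over random sign flips of the
subject difference fields, identity flip included.  Monte Carlo
calibration on smooth Gaussian nulls (12 subjects, 101 points, FWHM 4)
puts both methods' family-wise error near the nominal .05 and their
decisions in ≥90% agreement.  Inside the q scan the RFT threshold is
cached on resels rounded to two decimals; the induced threshold error
is below 10⁻³ t units.

## Percept-conditioned logistic models

Hit/miss outcomes per deviant are modelled with a logistic
random-intercept model: covariates are Δf (indicator for 8 vs 4
semitones), position (ordered numeric 0/1/2 — single-df entries imply a
numeric coding, though a treatment coding with pooled df cannot be
ruled out), and percept (indicator for integrated).  The marginal
likelihood integrates the normal subject intercept by *adaptive*
Gauss-Hermite quadrature — order 20, nodes recentred at each subject's
posterior mode and rescaled by the local curvature.  Adaptivity matters:
with ~100+ observations per subject the integrand is far narrower than
the prior, and fixed-node quadrature of any practical order is
inaccurate there, while the adaptive rule is stable (the 20- vs 40-node
log-likelihood difference on default data is ~10⁻¹¹).  Optimisation is
quasi-Newton (L-BFGS-B) with warm starts along the ladder; standard
errors come from a central-difference observed-information matrix.
Random-slope candidates add an independent slope variance, integrated
on an adaptive 9x9 tensor grid.

The ladder starts from the subject-only baseline, adds Δf, position and
percept in turn, then their two-way interactions, then per-term random
slopes; each addition is kept only if the χ² test on twice the
log-likelihood gain (1 df) has p < .05.  Complete separation is flagged
as non-convergence (|coef| > 15 logits) and the candidate skipped.  The
percept decision is checked for invariance to entry order.  A config
flag reruns the ladder excluding early deviants (which almost always
fall in integrated phases).  The adjusted count pseudo-R² quantises
conditional fitted probabilities (empirical-Bayes posterior-mean random
effects) at 0.5 — ties count as misses — and reports
(correct - majority) / (n - majority); negative values are legal and
reported.

## Numerical and scale choices

Monte Carlo sizes are chosen to keep each unit-test check under a few
seconds while leaving the assertion bands generous relative to
simulation error (e.g. 2,000 white-noise fields for the smoothness
expectation, 800-4,000 trials for listener-level comparisons); the
end-to-end calibration checks use 5,000 null fields, 100-replicate
recovery runs and a 1,000-log scoring oracle sweep.  The full default
two-experiment pipeline (12 simulated subjects, 0.001 q grid,
1,000-flip oracle available) runs in a few minutes on one CPU.  All
randomness flows from named seeds; identical seeds give byte-identical
outputs.

## Known limitations

The q scan is an exclusion scan, not an estimator: no likelihood is
attached to q.  Cluster-extent p-values rely on an asymptotic
approximation that is rough for clusters a few points wide — the
permutation route is authoritative when they disagree.  The GLMM
supports one random slope at a time (sufficient for likelihood-ratio
screening; the winning model here has none) and no slope-intercept
correlation.  The generator's individual-differences distributions are
conventions; nothing in the package estimates them from data.
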