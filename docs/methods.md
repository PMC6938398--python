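# Methods

## Scope and model

The package analyzes dual-channel recordings of inspiratory rhythm: an
integrated population trace from the preBötzinger complex (preBötC) and a
simultaneous hypoglossal (XII) motor trace. Rhythmic preBötC events are
classified by cross-channel synchrony — events with a temporally
overlapping XII event are bursts, events without one are burstlets — and
two closely spaced bursts (or one long multi-peak event) form a doublet
that counts as a single rhythmic event. The two headline statistics are
the mean instantaneous frequency (mean of 1/interval over consecutive
onsets of all rhythmic events) and the burstlet fraction (burstlets over
all rhythmic events).

## Synthetic recordings

Because validation needs known labels, the generator renders recordings
with ground truth attached. It is phenomenological: no biophysical or
network (percolation) model is simulated.

**Event times.** A gamma renewal process with configurable interval CV
(packaged presets use 0.5), truncated below 1.5 s. The truncation
reflects the analysis convention that two events closer than the doublet
threshold are one doublet, so distinct rhythmic events never occur at
sub-threshold spacing; doublets are generated explicitly instead
(probability `doublet_prob` per burst, second component 0.35 ± 0.05 s
after the first). Because the reported frequency statistic is the mean of
1/interval — which for gamma intervals exceeds the reciprocal mean
interval — the gamma scale is calibrated numerically (Brent root find on
the truncated-gamma closed form) so that E[1/T | T ≥ 1.5 s] equals the
preset rate. A preset's `prebotc_rate` therefore is the mean
instantaneous frequency the condition exhibits, on the scale on which
such values are reported.

**Class assignment.** Burst/burstlet labels follow an evenly-spread quota
scheme (an accumulator advancing by 1 − burstlet_prob per event, random
phase): the long-run burstlet fraction is exact and bursts are regularly
interleaved. I.i.d. Bernoulli assignment was rejected because it places
consecutive bursts at adjacent events often enough that the short XII
intervals dominate the motor-channel mean instantaneous frequency
(≈ 0.14 Hz where ≈ 0.08 Hz is observed for a 0.23 Hz rhythm with
burstlet fraction 0.58); regular interleaving reproduces the jointly
observed triplet of frequency, fraction and motor-output frequency. The
interval CV of 0.5 was fixed by the same consistency argument.

**Waveforms.** Events are difference-of-exponentials envelopes; for
nominal duration D, bursts rise/decay with τ = D/8 and 3D/8, burstlets
(slower population recruitment) with D/4 and D/2. Amplitudes are normal
draws per class, clipped at 0.1 a.u. so every ground-truth event remains
detectable. Bursts — never burstlets — are mirrored on the XII channel
with gain `xii_gain` after a 10 ms conduction delay. In `raw` mode
(default) the trace is white Gaussian noise amplitude-modulated so that
rectification + low-pass recovers `noise_sd · √(2/π)` at baseline and the
event amplitude at peaks; `envelope` mode emits the envelope plus
additive noise directly. All randomness flows from one
`numpy.random.Generator` per recording: identical (preset, duration,
seed, mode) is bit-identical.

**What the generator does not emulate.** Electrode drift, movement and
line artifacts, slow excitability trends, amplitude correlations between
neighboring events, ECG/EMG crosstalk, and between-slice variance beyond
what across-seed variation provides (a preset carries one set of
condition means; replicates differ only by seed). Passing round-trip
tests therefore demonstrates correctness of the analysis chain under
clean, stationary rhythms — not robustness to every artifact of real
recordings.

**Photostimulation sessions.** 8–20 stimuli at uniform 3–6 s intervals;
each independently triggers a burst with probability `success_prob` at a
latency drawn from a normal distribution truncated to (0, 500) ms. No
endogenous rhythm is rendered, matching entrainment protocols that pace
slightly faster than the endogenous rhythm precisely to keep the 0.5 s
windows clear; `expected_false_success_prob` quantifies the confound for
a given endogenous rate.

**Dot counts.** Cells are assigned to the five transcript-abundance bins
with given probabilities and counts drawn uniformly within each bin's
range (0; 1–3; 4–9; 10–15; 16–40).

## Integration

Full-wave rectification followed by a Paynter-style third-order
critically damped low-pass: three identical real poles, each with time
constant tc/3 so the total averaging time equals the configured
`time_constant_ms` (default 50 ms, the midpoint of the 20–100 ms range
such hardware used). Discretized by the bilinear transform, normalized to
unit DC gain, and applied forward–backward (`filtfilt`). Zero-phase
filtering was chosen over a causal realization so that onset and latency
measurements carry no filter lag; the symmetric smearing it introduces is
handled in onset estimation (below). The hardware being emulated may have
been causal (phase-lagging); that choice is documented rather than
guessed, and the time constant is configurable.

## Event detection

Two-pass baseline: a robust median/MAD pass locates suprathreshold
regions; mean and SD are then re-estimated from event-free samples (0.5 s
guard bands around event-like runs; a minimum of `baseline_window` = 5 s
of event-free data is required). An event opens where the trace exceeds
baseline + 3 SD (`amp_threshold_k`), closes where it falls back below,
with runs shorter than half of `min_duration` discarded before gap
merging (`merge_gap` = 100 ms) and events shorter than `min_duration` =
50 ms discarded after. Two further criteria emulate the visual
confirmation step of semiautomated detection deterministically: the peak
must exceed baseline + 5 SD (`min_peak_k`; smoothed-noise excursions can
hold above 3 SD for > 50 ms a few times per 10 min, while true events sit
at > 30 SD), and the maximum rising slope must exceed 2 baseline SD per
100 ms. Runs touching the trace boundary are dropped (undefined
onset/offset, filter edge transients).

**Onset estimate.** The reported onset is the last upward crossing of
baseline + 0.3 × (peak − baseline) before the first prominent peak. Under
zero-phase filtering the low opening threshold is crossed ~100 ms before
the true envelope start; the fractional criterion was calibrated against
generator ground truth to < 5 ms median bias for the standard burst
shape. `n_peaks` counts local maxima above threshold with prominence ≥
max(3 SD, 15% of peak).

## Doublet threshold and classification

The doublet threshold is fit from motor-channel inter-onset intervals: if
the 0.25 s-bin histogram has a local maximum below 1.5 s, the sub-2-s
mass is ≥ 5% of intervals, and the mode is separated from the endogenous
interval mass (either it dominates the histogram or a ≥ 0.75 s valley at
≤ 50% of the mode count intervenes), a Gaussian is fit to the sub-2-s
intervals and the threshold set to mean + 2 SD, capped at 2 s. The mode
search stops at 1.5 s because at realistic event counts the left tail of
a fast rhythm's own interval distribution is statistically
indistinguishable from a doublet peak near 2 s, and a spurious fit fuses
genuine burst pairs; a true doublet mode between 1.5 and 2 s would be
missed (`peak_search_max` is configurable). With fewer than 10 motor
events the fit signals a fallback; the pipeline then fuses nothing.

Classification runs synchrony first (any non-empty interval intersection
with a XII event ⇒ burst), then doublet formation: consecutive bursts
with onset-to-onset interval below the fitted threshold are fused
pairwise, and single bursts with ≥ 2 peaks and duration > 1.2 × the
median burst duration are relabeled. The 1.2 multiplier (rather than a
larger one) reflects that threshold-crossing durations include the
filter-smeared tails on both sides, compressing the doublet/single
duration ratio to ~1.3 where the underlying envelopes differ by ~2×.
Classes partition the events; a doublet's onset is its first component's
and intra-doublet intervals never enter frequency statistics. Motor-
channel trains pass through the same fusion so a doublet counts once in
motor-output frequency.

## Metrics, stimulation scoring, H-score, statistics

Metrics are as defined in the README; undefined quantities (frequency
with < 2 events, latency with no successes) are NaN or raised errors,
never zeros. Stimulation trials use the half-open window (stim, stim +
0.5 s], earliest-burst matching with consumption (one burst cannot
satisfy two stimuli); burstlets never count. The statistics layer wraps
scipy/statsmodels: Shapiro-Wilk at α = 0.05 per group (on paired
differences when paired) gates t vs Mann-Whitney/Wilcoxon, with the gate
decision recorded in each result; the 3-SD outlier rule is single-pass
with the sample SD; repeated-measures ANOVA applies no sphericity
correction; ANCOVA homogeneity is the partial F-test of the interaction
model against the common-slope model (equivalent t for two groups), with
perfect-fit inputs short-circuited to p = 1. Zero-variance paired
differences return t = 0, p = 1 by definition rather than NaN.

## Condition presets

`presets.json` stores one entry per experimental condition (9/1.5 and 3/1
ACSF controls; 10/30 nM DAMGO in each; picrotoxin/strychnine, Cd²⁺ and
Substance P variants; four photostimulation conditions), with the group
means it should reproduce and, in a `reported` block, the published
group statistics used for side-by-side display by `reproduce_figures`.
Where a condition's burstlet amplitude or similar was not separately
reported, a value consistent with the neighboring conditions was chosen
once and kept. Default sampling rate is 2 kHz — the envelopes carry no
content above a few hundred Hz, so nothing is lost relative to a 10 kHz
acquisition while simulations stay fast.

## Problem sizes and numerical choices

Round-trip validation uses 6–8 replicates of 600–1200 s per condition
(the slower the rhythm, the longer the recording) and 20 seeds per preset
for the classification oracle at 200–320 s each; stimulation recovery
uses 5–6 sessions of 20 stimuli. Statistical calibration uses 10⁴
two-group null replicates and 10³ each for the correlation and ANCOVA
nulls. These sizes give standard errors comfortably below the tolerances
tested while keeping the whole suite under a minute of simulation.
Tolerances in tests combine 3 standard errors of the generator ground
truth with a small absolute floor for quantities near zero.

## Known limitations

- The detector assumes a stationary baseline; slow drift would inflate
  the baseline SD and desensitize detection.
- Doublet chains of three or more components are not modeled or fused
  (pairs only).
- The synchrony rule uses any non-empty overlap; with conduction delays
  much longer than event durations it would under-classify bursts.
- The doublet threshold fit requires a clearly separated sub-1.5-s mode;
  rhythms whose doublet spacing approaches their endogenous period defeat
  it (by design, see above).
- Amplitude statistics use the peak of the fused event; the second
  doublet component is not averaged separately.
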