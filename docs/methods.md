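# Methods

This note documents the models, conventions, and numerical choices behind
each pipeline stage, what the synthetic generators do and do not emulate,
and the design decisions taken where the analysis recipe left room.

## Conventions

All time is in seconds (float). Trial-relative time zero sits at cue onset
(or at airpuff onset for unpredicted-US trials); windows are half-open
`[start, end)`. The sample holding time `t` is `floor((t − t_start) ·
rate)`; a trial row spans `[event − pre_s, event + total_s − pre_s)` with
the cue-onset sample at index `round(pre_s · rate)`. Default trial windows:
5 s of pre-event baseline in a 15-s trial, at 5 Hz (imaging), 10 Hz
(behavior), or 100 Hz (photometry). On-disk text formats use 9 significant
digits; HDF5 stores native doubles.

The task structure is fixed by the conditioning design: 1-s auditory cues,
a 0.5-s airpuff following the CS+ offset after a 0.5-s delay (so airpuff
onset is 1.5 s after cue onset), inter-trial intervals uniform on
[30, 45] s; habituation sessions hold 30 CS+, 30 CS−, and 5 unpredicted
airpuffs in shuffled order, conditioning sessions 30 CS+ (all paired) and
30 CS−.

## Statistical tests

Rank comparisons use the two-sided Wilcoxon rank-sum (Mann–Whitney) test in
its asymptotic form with mid-rank tie correction and continuity correction
(`scipy.stats.mannwhitneyu`), applied to per-trial samples. The test is
unpaired by design even though baseline and response windows come from the
same trials; a paired signed-rank variant is available via
`AnalysisConfig(paired_test=True)`. When both samples are a single tied
constant the p-value is defined as 1. The significance level defaults to
α = 0.05 everywhere.

Degenerate cases: the modulation index of a silent neuron (both window
rates zero) is defined as 0 and flagged, keeping cohort tables total
instead of propagating NaN.

## Electrophysiology

Spontaneous statistics exclude the 1-s post-foot-shock windows: the
recording is segmented at those windows and ISIs are only formed within
segments, so a stimulus-locked burst cannot leak into the "spontaneous"
features. Firing rate is spike count over spontaneous duration; CV is the
population SD/mean of ISIs; burst index is the fraction of ISIs under
25 ms. The ISI histogram uses 100 bins of 10 ms (normalized over in-range
ISIs, so it sums to 1 whenever any ISI is ≤ 1 s); autocorrelograms use 1-ms
bins over positive lags 1–500 ms and 1–100 ms, normalized by spike count.

The embedding input is exactly 15 features: 4 principal components each of
the ISI histogram and of the two autocorrelogram ranges (PCA fitted on the
cohort, per block — the only reading that sums to 15 with the three scalar
features), plus rate, CV, and burst index, each z-scored across the cohort.
Rank-deficient blocks are padded with zero components and a warning. t-SNE
runs at perplexity min(30, (n−1)/3) with a fixed seed; coordinates are
deterministic given (features, seed).

Foot-shock classification requires strictly more than 20 stimulation
trials; per-trial spike counts in [onset − 1 s, onset) vs.
[onset, onset + 1 s) feed the rank test, and direction comes from the
window-mean rates.

## Synthetic spike cohorts

Baseline rates are log-normal (median 4 Hz, σ = 1 — a realistic span of
roughly 0.5–30 Hz for LHb units). Spontaneous spiking is a gamma-renewal
process (per-neuron shape uniform on [0.6, 1.8], so CV spans regular to
super-Poisson) simulated by time rescaling under a piecewise-constant rate,
plus burst riders: each spike seeds, with probability 0.15, 2–4 extra
spikes at cumulative 5–15 ms lags. Foot-shock responses are rate steps over
the 1-s post-onset window — the analysis window — multiplying the rate by
the effect ratio (excited), its inverse (inhibited), or 1.

Rate/modulation coupling is a Gaussian copula: (log-rate, modulation
propensity) are bivariate normal at correlation ρ ∈ [−1, 0], and the
propensity is thresholded into classes at the planted proportions (defaults
0.68/0.19/0.13 excited/inhibited/non-modulated, mirroring the recorded
class distribution). Discretizing attenuates the realized Pearson r between
log rate and true modulation index to `ρ · (φ(Φ⁻¹(1−f_e)) + φ(Φ⁻¹(f_i))) /
sqrt((f_e+f_i) − (f_e−f_i)²)` ≈ 0.79·ρ at the defaults; measuring
modulation from finite trial counts attenuates it further. The tests
assert the realized value against this closed form.

## Calcium imaging

ΔF/F0 uses per-trial F0 = mean raw fluorescence over the 3 s before cue
onset; non-positive F0 drops the trial. AUCs are trapezoidal integrals
with linear interpolation at the window boundaries, so a window always
contributes its full span even when its endpoints fall between samples
(at 5 Hz, a 1.5-s window covers 7.5 sample intervals). Baseline AUC is the
1.5 s immediately before cue onset (the recipe names a "1.5-s baseline"
without placing it); the anticipatory window is [0, 1.5) s; the airpuff
window is [1.5, 2.0) s on paired trials and [0, 0.5) s on unpredicted-US
trials. Classification needs at least 5 trials of the cue (configurable; no
minimum is prescribed). The phase-by-class contingency uses Pearson χ²
without continuity correction, dropping class columns empty in both phases.

Synthetic calcium transients are difference-of-exponentials kernels (50 ms
rise, 500 ms decay — GCaMP6f-like) at 5 Hz, with class-signed amplitudes of
2 % ΔF/F0 in habituation and 20 % in conditioning. The amplitude growth
across learning is what plants the plasticity, and the habituation value
deliberately sits near the 30-trial detection threshold (baseline AUC noise
is ≈1.6 %·s at 5 % sample noise, putting 2 % responses at roughly half
power) so that learning redistributes the *classified* response
distribution rather than saturating both phases. 30 %
airpuff responses sharing the neuron's sign, Gaussian sample noise of 5 %,
and a shared per-trial gain (SD 0.35 — calcium responses are strongly
trial-to-trial variable) that behavior can couple to. CS− trials carry no
planted response.

## Behavior

Eye-area traces are normalized per trial to percent of the 5-s pre-cue
baseline mean; trials with non-positive baselines are dropped, not
interpolated. CR amplitude is the plain mean of the normalized trace over
[0, 1.5) s. The discrimination score is CS− mean CR minus CS+ mean CR; the
learning contrast across phases uses a paired t-test over mice. Airpuff
epochs force a full blink in the generator but lie outside the CR window,
so they affect only plotting.

Synthetic eyeblink depth on CS+ trials is 0.05 (habituation) and 0.30
(conditioning) for learners with 0.05 blink noise; CS− depth is 0. With
coupling c and the calcium cohort's standardized trial gain a_t, depth is
`d·(1 + 0.35·c·a_t)` clipped to [0, 1], so c = 1 with zero blink noise
makes the per-trial CR a strictly monotone function of the shared neural
gain.

## Decoding

Blink labels come from session-wise CR percentiles with linear
interpolation: below P40 is one class, above P60 the other, the
overlapping middle band is excluded (a dead-band reading that yields
disjoint classes). The feature is the scalar cue-window AUC, standardized
on the training split only. "100-fold validation" is implemented as 100
stratified random train/test splits at test fraction 0.2, since literal
100-fold CV is impossible with ~60 trials; a k-fold mode is available.
Hyperparameters (C ∈ {0.1, 1, 10, 100}, γ ∈ {scale, 0.01, 0.1, 1}) are
chosen per split by grid search on the training data — by default scored on
a single stratified holdout third, because k-fold inner CV triples the cost
without changing the selected models on these one-dimensional features;
`inner_cv > 1` enables it. The shuffle null permutes the label vector once
(the decoder's target is the blink class) and reruns the identical
procedure; cohort-level separation uses an unpaired t-test of accuracy
versus shuffle accuracy. Decoding pools CS+ and CS− trials by default.

## Photometry

Counts are smoothed with a centered 10-sample running average with edge
truncation (a trailing mode exists); smoothing precedes alignment and
ΔF/F0. F0 is the 3 s before the event, anchored to airpuff onset on
unpredicted-US trials. The validity rule partitions the [0, 1.5)-s
response span of the habituation trial-averaged trace into consecutive
50-ms epochs and requires at least 3 epoch means (not necessarily
consecutive) outside baseline mean ± 2 SD, on any stimulus; a zero-SD
baseline is flagged degenerate and any deviating epoch counts. Peaks are
maxima of ΔF/F0 over [0, 1.5) s, averaged in consecutive 5-trial bins per
cue; the trailing partial bin is kept and flagged. The cue contrast is a
two-factor (cue × bin) ANOVA on binned peaks pooled across animals, with
the interaction term included when replicates leave residual degrees of
freedom; the cue main effect (type-II F) is reported.

Synthetic sensors emit Poisson counts at 50 photons/bin baseline with
multiplicative event-locked transients (rise 50 ms, decay 500 ms): stable
profiles keep CS amplitudes at 0.3 across learning; the potentiating
profile doubles the conditioning CS+ amplitude to 0.6. Airpuff amplitude
is 0.8. Sixty conditioning trials per cue are obtained from two
conditioning sessions per animal.

## What the generators do and do not emulate

The generators plant exactly the structure the analyses test for: class
proportions, rate coupling, amplitude growth across learning, behavioral
discrimination, and sensor potentiation, under stationary noise. They do
not model slow drift or bleaching, movement artifacts, kinetic subtypes of
foot-shock responses, sensor-specific kinetics, correlated noise across
neurons (beyond the shared response gain), or session-to-session
nonstationarity. Passing tests therefore demonstrate correctness and
calibration of the statistics under the planted model, not robustness to
every artifact of real recordings.

## Problem sizes

The regression benchmarks run null calibrations at 2000 neurons
(binomial 95 % band around α), recovery at 300 neurons, coupling at 200
neurons, decoding at 50 responsive neurons × 100 repeats, behavior at 10
mice, and photometry at 6 + 3×3 animals — sizes chosen to make the
planted effects decisive on a single CPU in minutes.

## Known limitations

- The unpaired rank test on paired windows is kept for fidelity to the
  named test; it is slightly conservative relative to the signed-rank
  variant offered behind the `paired_test` flag.
- The embedding is reproducible only for a fixed (cohort, seed); t-SNE
  coordinates have no meaning across cohorts.
- The ANOVA on binned peaks pools bins across animals without a
  within-animal error term; with few animals this is anticonservative for
  strongly animal-clustered data (the synthetic cohorts are exchangeable
  across animals by construction).
- Validity epochs are evaluated on the trial-averaged trace only; per-trial
  artifact rejection is out of scope.
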