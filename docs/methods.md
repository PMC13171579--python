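# Methods

`dbslfp` re-implements, as a tested pipeline on synthetic data, a
group-level analysis of how unilateral, bilateral and multi-target
deep-brain stimulation (DBS) modulates local field potential (LFP) band
power across a depression-related prefrontal network, and of whether
combined stimulation acts additively, sub-additively or
super-additively. This note records the models, the numerical choices,
and what the synthetic data can and cannot show.

## Study structure

Three subjects each contribute several recording sessions ("datasets").
Within a session, seven stimulation conditions — right SCC, left SCC,
right VC/VS, left VC/VS, bilateral SCC, bilateral VC/VS, and
simultaneous bilateral SCC + VC/VS ("ALL") — are delivered as 1 s
bursts, ten repetitions each, in random order. Depth electrodes record
monopolar voltages from twelve regions of interest (ACC, mPFC, OFC,
DLPFC, Amy/HC, TL; left and right), several contacts per region. Each
stimulation event defines a 3 s epoch: 1 s pre-stimulation, 1 s
stimulation, 1 s post-stimulation. Only the pre and post windows are
analysed; the stimulation window is carried but never enters inference.

## Preprocessing

Contacts are bipolar re-referenced against the adjacent contact of the
same lead, provided both contacts lie in the same ROI; cross-ROI
adjacent pairs are dropped, and a lead without a valid pair contributes
nothing (with a warning). Polarity is deeper-minus-shallower; since the
outcome is power, polarity is inconsequential. Differencing removes any
signal common to a lead's contacts (volume-conducted common mode)
exactly. Signals are then decimated to a 1 kHz working rate with a
zero-phase FIR anti-aliasing low-pass. An FIR design is used because
its flat passband preserves sub-100 Hz amplitudes to well under 1%,
whereas a zero-phase (squared) Chebyshev-I cascade loses ~2% at staged
large factors. Re-reference → decimate ordering is mathematically
immaterial for these linear operations. Epochs that would extend past
either end of a recording are skipped, never zero-padded.

## Spectral power and the outcome

Time–frequency power comes from a continuous wavelet transform with the
bump wavelet (analytic; Fourier-domain bump with the conventional
parameters mu = 5, sigma = 0.6), implemented in the frequency domain
with zero-padded FFTs. The frequency grid is geometric, 12 voices per
octave from 2 to 55 Hz, offset by half a voice so no grid frequency
sits exactly on a band edge; bands are closed intervals theta 4–8,
alpha 8–12, beta 13–35, gamma 36–50 Hz. Power is averaged linearly over
band rows and over the pre / post windows, excluding 100 ms at the end
of the pre window and 100 ms at the start of the post window, where
wavelet edge effects from the stimulation transition concentrate. The
outcome per (epoch, channel, band) is the relative power change

    delta_p = (P_post − P_pre) / P_pre .

Records with P_pre at or below 1e−12 a.u. are dropped with a logged
count.

**Small-sample ratio bias.** A 1 s window of a 4 Hz-wide band supplies
only ~7 spectral degrees of freedom, so the single-epoch P_pre has
relative variance ≈ 0.28 and the per-epoch ratio delta_p is biased
upward by roughly that amount (E[X/Y] > E[X]/E[Y]); the bias is ~+0.28
in theta, ~+0.26 in alpha, ~+0.08 in gamma, ~+0.02 in beta under a
Gaussian signal model. This is a property of the outcome definition,
not of any implementation. Averages of per-epoch ratios inherit it, so
effect-recovery checks use the ratio-of-means estimator
(`spectral.empirical_delta_p`), whose bias is O(1/n); the mixed model's
response remains the per-epoch delta_p, and its cell estimates in the
narrow bands carry the bias — which cancels only partially in the
interaction contrast. Interaction analyses on narrowband data should be
read with this in mind.

## Outlier screening

Epochs contaminated by stimulation-edge transients are detected by a
deterministic rule: the ratio of mean broadband wavelet power in the
two 100 ms windows flanking stimulation onset and offset to the mean
broadband power over the remaining pre + post interior. A stationary
epoch scores ≈ 1; the default threshold is 5.0, calibrated on null
simulations to a false-positive rate below 1% while scoring strong
injected artifacts at 10–20. All records of a flagged epoch are
removed and the decision trail is serialized as JSON. The screen's
scope is onset/offset edge energy only; it does not claim to detect
arbitrary artifact morphologies.

## Mixed-effects inference

delta_p is modelled with a linear mixed-effects model: fixed effects
for condition, ROI and band with all interactions — equivalently one
fixed effect per (condition, ROI, band) cell — and random intercepts
for recording channel and for trial nested in dataset nested in
subject, fitted by REML (statsmodels `MixedLM`, with method-of-moments
starting values and a bfgs→cg→powell fallback chain; boundary (zero)
variance estimates are accepted). Population-level predictions are the
fixed-effects-only cell estimates. The variance decomposition reports
the random-effect and residual standard deviations and each component's
share of total variance.

Significance uses a cluster bootstrap (default 999 resamples), not
parametric standard errors. Trial clusters are resampled with
replacement within (subject, dataset, condition) strata — conditioning
on condition keeps every grid cell populated in every replicate — and
channel clusters within ROI strata, so both dependence structures
propagate into the resampling distribution. Because the fixed-effect
structure is saturated and the design balanced, the GLS fixed-effect
refit on a resample equals the weighted cell mean, which each replicate
computes directly (a full mixed-model refit per replicate is available
via `refit="lme"` and agrees in location). Two-sided percentile
p-values use the add-one rule p = (2·min(#{b ≤ 0}, #{b ≥ 0}) + 1) /
(n_boot + 1), capped at 1, so the smallest attainable p with 999
resamples is 1/1000. Benjamini–Hochberg FDR correction is applied
across the full grid of one model (336 cells pooled; 144 per subset
model), and significance is declared at alpha = 0.05.

## Additivity analysis

The data are partitioned into three subsets, one per combination pair:
(rSCC, lSCC → bSCC), (rVCVS, lVCVS → bVCVS), (bSCC, bVCVS → ALL);
conditions shared between pairs appear in multiple subsets. Each
subset gets its own mixed model. The additive-scale interaction per
(ROI, band) is

    Interaction = delta_P_AB − (delta_P_A + delta_P_B),

computed per bootstrap replicate from the cell estimates; the median,
2.5/97.5 percentile interval and add-one p-value summarize the
replicates, with BH correction over the 48 (ROI × band) cells within
each pair. Classification: *additive* when q ≥ 0.05; otherwise
*super-additive* when the median interaction shares the sign of the
expected additive effect delta_P_A + delta_P_B and *sub-additive* when
it opposes it. When |expected| < 1e−9 the sign rule is undefined; a
significant interaction there is classified super-additive (an effect
emerging where none was expected exceeds the additive prediction in
magnitude) and flagged in the report.

## Interaction-class prediction

A decision tree predicts the interaction class from stimulation target
pair, ROI, band, and the mean pre-stimulation power of the ROI and band
during stimulation of each component target. Feature rows are
observation-level — one per (cell, subject, dataset, trial repetition)
— with the power features summarized at the recording-session level, so
replicate rows of a cell share their session's feature values. The
tree is unpruned (Gini, stable alphabetical integer coding of
categoricals, fixed seed) and trained on a stratified 70/30 split.

Because the label is a fixed function of the categorical cell and every
test row's exact feature vector also occurs in training with the same
label, the tree separates the classes perfectly: 100% train and test
accuracy and per-class F1 of 1 are properties of the construction
(label leakage by replication), not generalization claims; the
classifier report says so explicitly. Confusion-matrix metrics are
computed from first principles rather than delegated to a metrics
library.

## Synthetic data

The generator has two levels sharing one planted-effect specification.

*Signal level.* Each contact carries four band-limited Gaussian noise
streams (4th-order Butterworth band-pass of white noise, variance set
by a coarse 1/f baseline: 4/2/1/0.5 a.u. for theta/alpha/beta/gamma).
From stimulation onset to the end of the epoch the stream's amplitude
is scaled by sqrt(1 + delta_p_effective), making the planted value
exactly the relative band-power change; delta_p_effective adds the
planted cell effect, a per-epoch trial intercept, a per-contact channel
intercept and a per-record Gaussian residual. Rare draws that would
make power non-positive saturate at 1 + delta ≥ 0.02 (logged); a
*planted* delta ≤ −1 raises an error. A common-mode stream (2× a
contact's private amplitude) is added identically to all contacts of a
lead so bipolar referencing is exercised. The default synthesis rate
is 2 kHz; a 30 kHz fixture exercises decimation in tests. Stimulation
pulses themselves are not synthesized (the stimulation window never
enters analysis); pulse settings are carried as metadata only.
Injected edge artifacts are tapered 15–50 Hz noise bursts (unit rms,
amplitude × channel sd, independent per contact) in the two 100 ms
windows flanking onset and offset; mid-band bursts are the signature a
sharp edge transient leaves inside the analysis band, and they survive
both decimation and bipolar differencing.

*Model level.* `simulate_power_table` draws the post-spectral table
directly from the hierarchical model (cell effect + intercepts +
residual, lognormal jitter on baseline power), which is what the
inference-calibration tests and the acceptance script use: it realizes
the mixed model's assumed structure exactly and runs in milliseconds.

Noise defaults are anchored to the variance structure this kind of data
shows: the trial : channel : residual standard-deviation ratios
(0.232 : 0.561 : 3.18) scaled so a single record's delta_p standard
deviation is ≈ 0.3, giving sd_trial = 0.018, sd_channel = 0.045,
sd_residual = 0.25. Planted unilateral effects are 0.2–0.3 in theta,
tapering with frequency (×0.8/0.5/0.4 for alpha/beta/gamma);
interactions are ±0.3. The `mixed` scenario assigns per pair 33
additive, 11 sub-additive and 4 super-additive cells on a stride
pattern that places every class in every band (class balance ≈ 66/26/7%,
the balance combinatorial stimulation data tends to show). Scenarios
`null`, `all_additive`, `all_sub` and `all_super` cover calibration and
sign-rule checks. For combined conditions the additive identity
delta(AB) = delta(A) + delta(B) + interaction holds exactly by
construction, and the ground-truth class follows the sign rule
(additive iff the planted interaction is 0).

**What the generator does not emulate:** oscillatory bursting, 1/f
slope dynamics, evoked potentials, electrode geometry, volume
conduction beyond the single common-mode term, or real artifact
morphologies. Passing tests therefore demonstrate that the pipeline
recovers effects under its own statistical assumptions — not that those
assumptions hold in clinical recordings.

## Problem sizes and determinism

The default study size (3 subjects × 2 datasets × 70 epochs × 12 ROIs ×
1 bipolar channel × 4 bands ≈ 20k records) keeps a full signal-level
run with 999 bootstrap resamples in the low minutes on one core, and
the model-level acceptance computation under half a minute;
calibration test loops use 199 resamples (the add-one p floor is then
1/200, which the q-threshold analysis tolerates at the planted effect
sizes). Every stochastic stage takes an explicit seed; identical seeds
give bit-identical fixtures, bootstrap draws and reports, and the run
log records the seed of each stage.

## Known limitations

- The ratio bias of per-epoch delta_p (above) shifts narrowband cell
  estimates; at the default design size the signal-level path detects
  beta/gamma interactions much more reliably than theta/alpha ones.
- With only three subjects the bootstrap cannot resample the subject
  level; between-subject variance enters only through the planted
  intercepts.
- Channel intercepts in the signal-level generator attach to contacts;
  a bipolar channel's effective intercept is the mean of its two
  contacts' draws, so exact channel-variance recovery checks use the
  model-level generator.
- The edge-artifact screen and the injected artifacts are matched to
  the same physical signature (boundary-confined in-band energy); the
  measured sensitivity/specificity do not transfer to artifact types
  with different morphology.
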