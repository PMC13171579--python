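# dbslfp

Band-power modulation and additive-interaction analysis for multi-site
deep-brain-stimulation (DBS) local field potential (LFP) recordings.

When two DBS targets — here the subcallosal cingulate (SCC) and the
ventral capsule/ventral striatum (VC/VS), left and right — are
stimulated together, does the network respond with the sum of the
individual effects, with less (antagonism), or with more (synergy)?
`dbslfp` implements the full analysis chain that answers this on
epoch-structured intracranial recordings, together with a synthetic
data generator with planted ground truth, so every stage is testable
end to end. It is aimed at researchers analysing stimulation-evoked
band-power changes in sEEG/LFP data and at methodologists who want a
reproducible harness for additive-interaction inference on hierarchical
neural data.

## The analysis

For each 1 s stimulation burst, an epoch of 1 s pre / 1 s stim / 1 s
post is cut from bipolar re-referenced, 1 kHz-decimated signals.
Bump-wavelet power, averaged over theta (4–8), alpha (8–12), beta
(13–35) and gamma (36–50 Hz) and over the pre/post windows (excluding
100 ms on either side of the stimulation period), gives the outcome

    ΔP = (P_post − P_pre) / P_pre

per epoch, channel and band. Epochs with stimulation-edge artifacts
are removed by a deterministic edge-power screen. ΔP is modelled with
a linear mixed-effects model — fixed effects condition × ROI × band,
random intercepts for channel and for trial nested in dataset nested in
subject — and population-level predictions per cell get two-sided
percentile p-values from a cluster bootstrap (999 resamples) with
Benjamini–Hochberg FDR correction.

For each combination pair (bilateral SCC, bilateral VC/VS,
multi-target) the additive-scale interaction per (ROI, band) is

    Interaction = ΔP_AB − (ΔP_A + ΔP_B)

summarized by the bootstrap median and 95% interval, and classified:
**additive** (q ≥ 0.05), **super-additive** (q < 0.05, same sign as the
expected effect ΔP_A + ΔP_B) or **sub-additive** (q < 0.05, opposite
sign). Finally, an unpruned decision tree predicts the interaction
class from (target pair, ROI, band, pre-stimulation powers), with
confusion matrix, per-class precision/recall/F1 and impurity-based
feature importances.

## Worked example

```python
from dbslfp import (make_design, plant_effects, simulate_power_table,
                    analyze_additivity, VarianceDecomposition)

design = make_design({"subjects": 3, "trials_per_condition": 10,
                      "channels_per_roi": 2})
effects, truth = plant_effects(design, scenario="mixed")
table = simulate_power_table(design, effects, seed=0)
results = analyze_additivity(table, n_boot=999, seed=0)

merged = results.merge(truth, on=["pair", "roi", "band"])
print(merged[["pair", "roi", "band", "median_interaction", "q",
              "class", "class_true"]].head(6).to_string(index=False))
print("class recovery:", round((merged["class"] == merged["class_true"]).mean(), 3))
```

prints

```
         pair  roi  band  median_interaction        q          class     class_true
SCC_bilateral lACC theta            0.304984 0.004364 super-additive super-additive
SCC_bilateral lACC alpha           -0.353678 0.004364   sub-additive   sub-additive
SCC_bilateral lACC  beta            0.037362 0.859765       additive       additive
SCC_bilateral lACC gamma           -0.054275 0.841714       additive       additive
SCC_bilateral rACC theta           -0.038887 0.859765       additive       additive
SCC_bilateral rACC alpha           -0.368980 0.004364   sub-additive   sub-additive
class recovery: 0.972
```

The planted +0.3 theta interaction in left ACC is recovered as
super-additive (median 0.305, q = 0.004), the −0.3 alpha interactions
as sub-additive, and null cells as additive; over all 144 (pair, ROI,
band) cells 97% are classified to their planted ground-truth class at
this design size. Variance decomposition is plain arithmetic on the
fitted standard deviations — e.g. trial-level sd 0.232 against channel
0.561 and residual 3.18 puts 0.5% of total variance at the trial level:

```python
VarianceDecomposition.from_sds(0.232, 0.561, 3.18).share_subject_dataset_trial
# 0.00514 -> 0.5%
```

The full signal-level chain (voltage synthesis → bipolar referencing →
decimation → epoching → wavelet power → outlier screen → inference) is
one call:

```bash
dbslfp run-all --out artifacts/ --seed 1      # or: dbslfp simulate / fit / ...
```

which writes the fixture, the epoch manifest, the band-power table, the
outlier report, the marginal-prediction grid, the additivity heatmaps
and the classifier report to `artifacts/`, plus a `run.log` with every
stage's seed. See `docs/methods.md` for the model details, parameter
defaults and known limitations.

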