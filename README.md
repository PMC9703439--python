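# newstrf

Analysis pipeline for EEG recorded while people listen to affective news
broadcasts, built around word-onset **temporal response functions (TRFs)**,
and a detector of depressed individuals trained on the extracted EEG
features.  It is aimed at researchers studying attention and language
processing under natural speech, and at anyone who wants a fully testable
reference implementation of this analysis style without access to the
original recordings.

## What it computes

Continuous EEG r_ch(t) at channels Fpz, Cz, Pz is modeled as the
convolution of a binary content-word impulse train s(t) with a weight
curve w_ch(τ) over lags τ ∈ [−100, 800] ms:

    r_ch(t) = Σ_τ w_ch(τ) s(t − τ) + ε_ch(t)

estimated by ridge regression, with the penalty λ chosen per subject by
leave-one-trial-out CV over {2¹ … 2²¹} and a single population λ* (the
mode of per-subject winners) used for the final condition-wise TRFs.  From
the TRF curves the pipeline extracts N1 / P2 / N400 window amplitudes
([100,160] / [170,230] / [300,600] ms) and per-subject peak latencies by
dynamic-time-warping each subject's curve onto the grand average.  Group
(depressed / non-depressed by BDI-II ≥ 14) × news (negative / neutral /
positive) effects are tested with a mixed ANOVA (aligned rank transform
for ordinal ratings, Greenhouse–Geisser correction, Bonferroni
post-hocs), and a class-weighted squared-hinge linear SVM under
leave-one-subject-out CV — with in-fold standardization, recursive
feature elimination to 6 features, grid-searched cost and a
1000-randomization label-permutation test — detects the depressed group
from 12 EEG features, 6 rating features, or their combination.

Because no public recordings exist for this paradigm, the package ships a
synthetic-cohort generator (`newstrf.synthetic`) that embeds the assumed
statistical structure — word-onset-locked component kernels with
group × news latency/amplitude effects, 1/f background noise at a
configurable SNR, group-shifted ratings — plus a ground-truth sidecar, so
every stage is testable end to end.  See `docs/methods.md` for the full
model description.

## Worked example

The stages chain through a working directory, either from Python or via
the `newstrf` CLI (`simulate | preprocess | trf | components | stats |
classify | report`):

```python
import numpy as np
from newstrf import (CohortConfig, EffectPlan, PipelineConfig,
                     generate_cohort, preprocess_cohort,
                     estimate_cohort_trfs, compute_component_measures,
                     build_feature_table, loocv_classify)

cohort = CohortConfig(n_depressed=6, n_nondepressed=14,
                      trial_duration_s=(18, 22), fs_hz=200,
                      snr_db=0.0, effect_scale=3.0, seed=7)
cfg = PipelineConfig(bp1_order=600, bp2_order=400, seed=7,
                     feature_set="combination")

ds, truth = generate_cohort(cohort)
pre, _ = preprocess_cohort(ds, cfg)
trfs, diagnostics, lam = estimate_cohort_trfs(pre, cfg)
measures = compute_component_measures(trfs, cfg)
features = build_feature_table(measures, pre.ratings, pre.subjects)
folds, report = loocv_classify(features, cfg, rng=np.random.default_rng(7))
print(f"lambda* = {lam:g}; AUC = {report.auc:.3f}, "
      f"TPR = {report.tpr:.3f}, TNR = {report.tnr:.3f}")
```

which prints

```
lambda* = 2; AUC = 1.000, TPR = 1.000, TNR = 1.000
```

Read: on this 20-subject cohort with triple-strength injected effects and
low noise, the CV-selected ridge penalty sits at the bottom of the grid
(clean data need little shrinkage), the pooled decision scores order every
depressed subject above every non-depressed one (AUC 1.0), and the signed
decision threshold classifies every held-out subject correctly.  At
`effect_scale=0` the same pipeline gives chance-level AUC — that
calibration is part of the test suite.

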