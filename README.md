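# dcebrix

Analysis pipeline for predicting treatment response from dynamic
contrast-enhanced (DCE) MRI of head-and-neck squamous cell carcinoma.
Starting from lesion-mean signal-intensity time series acquired with a fast
perfusion sequence (one frame every 2.5 s), the pipeline

1. normalizes each curve to relative enhancement on a clock zeroed at bolus
   arrival (baseline = mean of the first five frames; arrival = first frame
   exceeding baseline by 5 %),
2. fits the modified Brix two-compartment model
   `E(t) = A·k_ep·(e^(−k_ep t) − e^(−k_el t))/(k_el − k_ep)`
   by deterministic multi-start damped least squares,
3. derives the semi-quantitative perfusion features — peak enhancement (PE),
   time to peak (TTP), initial area under the curve (AUC, 60 s), wash-in and
   wash-out (extrema of `dE/dt`),
4. compares groups (Mann–Whitney U, Kruskal–Wallis, per-parameter ROC with
   DeLong confidence intervals, intrarater ICC), and
5. trains and cross-validates a SMOTE-balanced random-forest classifier of
   pathologic complete response (pCR) vs residual tumor (ReTu), with
   sequential backward feature selection on cross-validated AUC.

Because clinical DCE data are rarely shareable, the package ships a
first-class synthetic cohort generator whose group-wise parameter
distributions are calibrated to published cohort medians and interquartile
ranges, so every stage is testable end-to-end without any download.  See
`docs/methods.md` for the model, the design choices and what the synthetic
cohorts do and do not emulate.

Audience: imaging scientists and biostatisticians working with
pharmacokinetic DCE-MRI features and small-cohort response prediction.

## Worked example

Run the whole pipeline on a simulated 22-patient cohort (15 pCR / 7 ReTu):

```bash
dcebrix run-all --seed 1 --out run1 --config fast.yaml
```

with `fast.yaml` containing `{n_repeats: 5, n_trees: 200, mtry: 4}` (the
library defaults are 10 repeats, 500 trees, tuned mtry).  The run writes
`curves.csv`, `normalized.csv`, `params.csv`, `features.csv`,
`table2_style.csv`, `model_result.csv`, `metrics.txt` and a seed/config
manifest, and prints:

```
"n_patients": 22,
"n_excluded": 0,
"auc_roc": 0.9998095238095239,
"sensitivity": 92.0,
"specificity": 100.0
```

`metrics.txt` holds the pooled cross-validation metrics with 95 % intervals:

```
AUC_ROC: 0.9998 (95% CI 0.9993-1.0000)
sensitivity_pct: 92.0 (95% CI 83.63-96.28)
specificity_pct: 100.0 (95% CI 90.11-100.00)
```

and `table2_style.csv` the per-parameter group comparison; the kinetic
features separate the groups the way the calibration intends — responders
show long TTP and positive wash-out (persistent enhancement), residual
tumors peak early (~100 s) and wash out:

```
parameter  median_pCR  median_ReTu  p_value  auc_roc
      kel   -0.000287     0.000394 0.003847 0.876190
      TTP  302.500000    99.206051 0.002328 0.914286
 wash_out    0.000702    -0.000724 0.003847 0.876190
      kep    0.051043     0.053464 0.836593 0.533333
```

The pooled AUC on synthetic cohorts is near 1 because every feature is drawn
from its group's published distribution independently — group-level
separation is the only structure the generator encodes, and the forest finds
all of it.  A label-permutation null on the same cohorts gives AUC ≈ 0.5
(see the test suite).

The library surface mirrors the stages: `dcebrix.preprocess_curve`,
`dcebrix.fit_brix`, `dcebrix.compute_features`,
`dcebrix.stats.group_comparison_table`,
`dcebrix.model.crossvalidate_parrf` / `backward_select`, and
`dcebrix.generate_cohort` for simulation.

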