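# mci-convert

Multimodal biomarker pipeline for predicting conversion from mild
cognitive impairment (MCI) to Alzheimer's disease (AD).

Only a fraction of MCI patients progress to AD, and identifying the
likely converters at baseline matters for prognosis and for enriching
clinical trials. This package implements a transfer-classification
study of that question: support-vector classifiers are trained on the
two extreme diagnostic groups — cognitively normal controls (NC) and AD
patients — and applied to MCI subjects, on the hypothesis that
imminent converters (MCIc) resemble AD at baseline while
non-converters (MCInc) resemble controls. Each MCI subject receives a
continuous predictive value f(x), the signed scaled distance from the
separating hyperplane; subjects with f(x) < 0 (the AD side) are
predicted to convert. It is aimed at biostatisticians and methods
researchers who want a tested, reproducible reference implementation of
the full procedure on simulated multimodal cohorts.

The pipeline:

1. **Cohort** — four groups (111 NC / 96 AD / 87 MCInc / 56 MCIc by
   default) with 323 MRI ROI morphometry features, 5 CSF biomarkers
   (t-tau, Aβ1–42, p-tau181p and the two tau/Aβ ratios) and 14
   neuropsychological/functional measures (NM). A synthetic generator
   emulates the published group structure with planted disease markers,
   so every stage is testable without access-controlled data.
2. **Feature selection** (NC vs AD only) — for MRI and CSF, mRMR
   ranking (greedy maximum-relevance / minimum-redundancy on mutual
   information, MID criterion) followed by an incremental RBF-SVM
   wrapper under 20×10 repeated stratified cross-validation; a feature
   is kept if it falls in the AUC-optimal top-k subset in more than 50%
   of the 200 runs. For NM, a dual-ranking filter keeps measures with
   MI relevance > 0.3 bits *and* single-feature CV AUC > 0.95.
3. **Classification** — RBF-SVM on the selected features, (C, γ) tuned
   by cross-validated AUC over the standard power-of-four grid, features
   min-max scaled to [0, 1] on training data only.
4. **Conversion-time analysis** — MCIc decision values stratified by
   conversion month (6/12/18/24) and early (≤12 months) vs late
   converters compared with a two-sample t-test.

## Worked example

```python
from mci_convert import (CohortConfig, generate_cohort, wrapper_select,
                         apply_frequency_threshold, nm_dual_filter, train_svm,
                         predict_cohort, evaluate, summarize_by_month,
                         compare_conversion_groups, SvmConfig)

cohort = generate_cohort(CohortConfig(seed=0))
train = cohort.subset(["NC", "AD"])
y = train.labels()

mri = wrapper_select(train.data.loc[:, cohort.mri_features], y, seed=0)
mri_selected = apply_frequency_threshold(mri)           # > 50% of 200 runs
nm = nm_dual_filter(train.data.loc[:, cohort.nm_features], y, seed=1)
csf = wrapper_select(train.data.loc[:, cohort.csf_features], y,
                     max_subset_size=5, seed=2)
features = nm.selected + apply_frequency_threshold(csf) + mri_selected

model = train_svm(train.data.loc[:, features], y, SvmConfig(seed=3))
records = predict_cohort(model, cohort)                 # MCI subjects only
metrics = evaluate(records)
summary = summarize_by_month(records)
test = compare_conversion_groups(summary)
```

Output of this exact script (about a minute, dominated by the 200-run
MRI wrapper):

```
selected MRI markers:
  100.0%  entorhinal_cortex_TA_L
  100.0%  middle_temporal_gyrus_TA_L
  100.0%  middle_temporal_gyrus_CV_R
  100.0%  inferior_parietal_cortex_TA_R
  100.0%  retrosplenial_cortex_TA_L
  100.0%  hippocampus_SV_L
  100.0%  hippocampus_SV_R
selected NM measures: ['lm_delayed_recall', 'lm_immediate_recall',
                       'avlt_trials_1_5', 'avlt_delayed_recall']
selected CSF measures: ['ptau181', 'abeta42', 'ttau_abeta42', 'ttau']
MCI transfer: accuracy 63.64%  sensitivity 98.21%  specificity 41.38%  AUC 0.977
   6 mo: n=15  -2.55 +/- 0.42
  12 mo: n=12  -2.19 +/- 0.43
  18 mo: n=18  -1.68 +/- 0.39
  24 mo: n=11  -0.93 +/- 0.48
early (-2.39) vs late (-1.39): p = 1.2e-09
```

Reading the numbers: the wrapper recovers exactly the seven planted
atrophy markers; transfer to the MCI groups shows the characteristic
high-sensitivity / low-specificity profile of this design (most MCIc
sit clearly on the AD side, MCInc straddle the boundary); and decision
values grade monotonically with conversion time — the earliest
converters are the most AD-like at baseline, and early vs late
converters differ strongly.

The same stages are available from the shell:

```sh
mci-convert simulate --seed 0 --out cohort.csv
mci-convert select --cohort cohort.csv --modality mri --seed 0 --out mri.json
mci-convert run --seed 0 --out-dir results/   # full study, all 7 modality combos
```

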