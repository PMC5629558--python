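# survstrat

Survival-optimal cut-off selection and statistically weighted voting risk
stratification for expression cohorts.

## The problem

Given a log2 expression matrix (features × samples, e.g. tumor miRNA
intensities) and censored overall-survival data (follow-up time *t*,
death indicator *e*), find the features — and small feature subsets —
that split patients into prognostically distinct risk groups, and turn
them into a reproducible stratification of the cohort into low-,
intermediate- and high-risk subgroups.  The package is written for
biostatisticians and computational biologists building prognostic
signatures from bulk expression cohorts.

## The method

For one feature *x*, every admissible cut-off *c* defines a binary Cox
proportional-hazards model on the indicator 1{x > c}; the scan returns

    c* = argmin_c  P_Wald( beta-hat(c) ),

the cut-off whose Wald P-value is smallest (Efron tie handling, both
groups ≥ 10% of the cohort).  sign(beta-hat) classifies the feature as
pro-oncogenic (high expression, high hazard) or tumor-suppressor-like.
Extensions: two cut-offs (the two strongest local maxima of the
−log10 P profile) give three risk groups; for a feature pair the scan
searches a 49×49 quantile grid of cut-off pairs crossed with the seven
distinct bipartitions of the four expression quadrants, and a pair is
*synergistic* when its joint model beats both single-feature models.

Fitted dichotomizations are combined by weighted voting: feature *j*
votes v_ij = ±1 for patient *i* (high/low risk) and the patient score

    s_i = Σ_j w_j v_ij / Σ_j w_j ,   w_j = −log10 P_j ,

is itself stratified with the same cut-off scans into k ∈ {2, 3}
ordered risk groups; forward selection keeps the smallest feature
subset whose stratification P is within one order of magnitude of the
best.  Supporting machinery: repeated ten-fold cross-validation of
cut-off stability (pass: significance in >99.7% of fold fits and <1%
coefficient of variation of the cut-off), robust consensus K-means
(Manhattan distance, 1000 runs, 100%/90% co-clustering thresholds),
an exponential + Generalized-Pareto mixture model of expression noise
with a precision-targeted signal cut-off, Mann-Whitney/fold-change
differential screening with BH-FDR, and signature construction by
intersecting the screens.  A seeded synthetic-cohort generator with
planted ground truth (486 samples × 167 features, ~54% events by
default) makes every stage testable without external data.

## Worked example

```python
import survstrat as ss

truth = ss.default_truth(seed=7)          # 486 x 167 synthetic cohort
expr, surv, record = ss.generate(truth)

m = ss.scan_1d(expr.feature("syn-mir-001"), surv, feature_id="syn-mir-001")
print(f"cutoff    {m.cutoff:.3f}")
print(f"hr        {m.wald.hr:.2f}")
print(f"wald p    {m.wald.p:.2e}")
print(f"phenotype {m.phenotype}")
print(f"groups    low-risk n={m.n_low}, high-risk n={m.n_high}")
```

prints

```
cutoff    4.575
hr        1.54
wald p    1.15e-03
phenotype pro-oncogenic
groups    low-risk n=195, high-risk n=291
```

The scan found the planted cut-off exactly (the generator placed it at
4.575, the feature's 40th percentile): patients with expression above
it have a 1.54-fold higher estimated hazard (the planted effect is
1.8), the association is significant at P ≈ 1e-3, and high expression
tracks high risk, so the feature is called pro-oncogenic.

The whole workflow — noise filtering, per-feature scans, CV stability,
the pairwise scan, weighted voting, consensus clustering and the
intersection signature — runs as one command and writes TSV/JSON
artifacts plus a `summary.json` of stage counts:

```sh
survstrat run --seed 17 --out results/run
```

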