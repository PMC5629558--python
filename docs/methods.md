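# Methods

## Scope and model

`survstrat` stratifies censored survival cohorts by expression features.
Throughout, a cohort is a log2 expression matrix `x` (features × samples)
with per-sample follow-up time `t` (years) and death indicator `e`.  All
survival modelling is proportional-hazards with binary covariates: a
candidate grouping of the cohort is scored by the Wald test of the Cox
partial likelihood (Efron tie correction), and groupings are compared by
the k-sample log-rank test.

### Optimal cut-off scans (DDSS)

For a single feature, the one-dimensional scan evaluates every admissible
observed value `c` as a strict dichotomization `x > c` and returns the
cut-off minimizing the Wald P-value.  Admissibility requires both induced
groups to hold at least `min_group_frac` (default 0.10) of the cohort,
which keeps the Cox fit estimable at every candidate for cohorts of a few
hundred samples.  The sign of the fitted log hazard ratio classifies the
feature: positive (high expression, high hazard) is *pro-oncogenic*,
negative is *tumor-suppressor-like*; an exactly zero coefficient is
flagged indeterminate.  Ties in the minimized P break toward the smallest
cut-off, which makes the scan deterministic and order-independent.

The two-cut-off variant reads the −log10 P profile of the single-cut-off
scan, median-smooths it (window 5 candidates, suppressing single-point
spikes) and picks the strongest pair of local maxima subject to two
constraints: the cut-offs must be separated by at least
`min_cutoff_gap_frac` (default 0.15) of the candidate value range, and the
middle expression interval must hold at least `min_group_frac` of the
cohort.  The resulting three groups are risk-ordered by their pairwise Cox
coefficients against the low-expression group and the model is *accepted*
when the overall three-group log-rank P < 0.005 and all three pairwise
Wald P < 0.05.  When fewer than two qualifying maxima exist the scan falls
back to the single-cut-off model with `accepted=False` and a recorded
reason.  A known limitation follows from the gap constraint: score or
expression distributions whose two true cut points lie closer than 15% of
the observed range cannot be resolved into three groups at the default
setting.

The paired scan crosses a quantile grid of cut-offs for both features
(default 49 evenly spaced levels per axis) with the seven distinct
bipartitions of the four expression quadrants.  Seven is a combinatorial
fact: of the 2⁴ − 2 proper nonempty quadrant labelings, each bipartition
appears twice under exchange of the risk labels; the canonical
representative of mask m is min(m, 15 − m), i.e. masks 1..7.  A pair is
*synergistic* when its best joint model has a smaller Wald P than either
feature's best single-cut-off model on the same quantile grid (the grids
must match for the comparison to be a genuine search-space nesting).

### Selection bias and the permutation option

The minimized P of any scan is the minimum over many correlated tests and
is therefore stochastically smaller than uniform under the null; raw
minimized values are reported because that is how such scans are
conventionally summarized, and a permutation option (`permutations=B`)
re-runs the scan on label-permuted cohorts and reports
`(1 + #{perm ≤ obs}) / (B + 1)`, which is near-uniform under the null.
The option is off by default.

### Statistically weighted voting (SWVg)

Each fitted dichotomization casts a vote per patient: +1 if the model
labels the patient high-risk, −1 otherwise.  With weights
`w = −log10(Wald P)` (P floored at 1e-300 to avoid infinite weights), the
patient score is the weight-normalized mean vote, hence in [−1, +1].  The
score is stratified into k ∈ {2, 3} groups with the same cut-off scans
used for single features, relabelled so a higher score always means higher
risk.  Forward selection adds features in weight order and keeps the
smallest subset whose stratification P is within one order of magnitude of
the best subset's P — beyond that point additional features barely move
the P-value.  The vote encoding and combination rule are this package's
reconstruction of the published method's outline; the rule is isolated in
`score_patients` so an alternative can be substituted without touching the
rest of the stack.

### Cross-validated cut-off stability

Each repeat draws a fresh ten-fold partition stratified by event status
(so every training split keeps events); the scan runs on each 9/10 split.
`confidence` is the fraction of completed fold fits with P < 0.05 and
`cutoff_cv` the percent coefficient of variation (sd/mean, sample sd) of
the fold cut-offs.  The dual pass criterion is confidence > 99.7% and
cut-off CV < 1%, evaluated at the default of 100 repeats (1000 fold
fits).  The criterion sharpens with the number of distinct partitions:
at a handful of repeats a few percent of pure-noise features can pass,
while at the default the null pass rate stays below 1%.  Fold fits that
violate scan preconditions are skipped and counted; more than 20% skipped
aborts the assessment.

### Consensus K-means

Repeated k = 2 K-means with the Manhattan (L1) distance; the centroid
update is the component-wise median, the minimizer consistent with L1.
Runs start from k distinct random samples; empty clusters are re-seeded;
runs not converged within 300 Lloyd iterations are discarded and the
co-assignment denominator adjusts.  Sample pairs co-clustered in 100% of
completed runs form the robust cores (connected components of the
frequency-1 graph, split greedily into cliques when necessary); feature
clusters use a softer > 90% threshold.  Working with co-assignment
frequencies avoids the label-switching problem entirely.  Samples and
features are clustered separately.

### Expression noise mixture

Pooled log2 intensities are modelled as
`(1 − w)·Exponential(rate, shifted to the data minimum) + w·GPD(μ, σ, ξ)`.
The fit is EM over component responsibilities with a closed-form
exponential M-step and a Nelder-Mead GPD M-step (location constrained
below the supported responsibilities), 60 outer iterations, relative
tolerance 1e-7, and 10 restarts (first split at the 40th percentile, the
rest at seeded random quantiles between the 5th and 75th — small noise
fractions need low splits).  The likelihood is non-decreasing across
iterations because the inner optimizer only accepts improvements.  The
signal cut-off is the smallest observed value whose posterior precision
P(signal | x ≥ t) reaches the target (default 0.85).  Degenerate fits are
flagged when one component absorbs nearly all mass (w outside
[0.02, 0.98]) **or** when the mixture fails to beat the best
single-component fit by a BIC margin (3 extra parameters); the cut-off
then falls back to the dominant component's 95th percentile.  On pools
dominated by signal the precision target can be met at the data minimum —
the reported cut-off is then simply the smallest value, which is the
honest reading of the rule.

### Feature filtering and differential screening

The expression filter keeps features whose median (switchable to mean)
across samples reaches `min_expr` (default 4.1 log2 units, the
conventional floor for this platform class) and whose variance reaches
`min_variance` (default 0).  The differential screen is a two-sided
Mann-Whitney test per feature with BH-FDR across features; fold change is
`2^(mean_high − mean_low)` of the log2 values, thresholded symmetrically
via max(FC, 1/FC) ≥ 1.5.

## Numerical engine

All scans funnel into one vectorized Newton solver for the
binary-covariate Efron partial likelihood.  For a 0/1 covariate the
likelihood depends on the data only through per-event-time at-risk and
death counts of the indicator-1 group, so a whole batch of candidate
columns is iterated at once (step clip ±2, tolerance 1e-11, |β| > 15
declared monotone/separated).  Threshold families (all cut-offs of one
feature) get their counts from cumulative histograms of the feature ranks
rather than per-column sums, and the paired scan builds joint 2-D rank
histograms per event time.  The score statistic at β = 0 decomposes into
per-event-time coefficients that are linear/quadratic in the quadrant
counts — and the death-dependent weights vanish wherever only one death
occurs at a time — so all 7 × grid² configurations are ranked from a
handful of precomputed Gram grids, and only the `refine` (default 128)
strongest per design are Newton-polished to their exact Wald P.  On the
cohorts exercised here the refined set always contains the global argmin
(verified against exhaustive evaluation in the tests); `refine=None`
forces the exhaustive path.

## Synthetic cohorts

The generator emulates a bulk tumor microarray cohort with planted ground
truth.  Defaults (the conditions every full-scale test and the acceptance
script run under): 486 samples × 167 features; 15 informative features
drawn from the GPD signal component with cut-offs at the 0.4/0.5/0.6
quantiles, hazard ratio 1.8 each and alternating phenotypes (moderate
single-marker effects of the size such cohorts report); two planted
interactions (high/high quadrant, hazard ratio 3, 60th-percentile
cut-offs) on otherwise-null feature pairs; 30 low-expression noise
features from the exponential+GPD mixture (signal share 0.4) that the 4.1
filter removes, leaving 137 expressed features; and a latent subtype
(35% of samples) over-expressing half of the expressed null features by
1.2 log2 units with its own hazard ratio 1.5, which gives the consensus
clustering a real two-block structure to find and makes a block of
features legitimately survival-associated, as in real tumor cohorts.
Survival is exponential with baseline median 2.4 years multiplied by every
planted effect; censoring is uniform on (0, c_max) with c_max solved by
root-finding (via `expm1`, avoiding cancellation) so the expected event
fraction is 54%.  Clinical columns (a stage-like ordinal tracking the
latent risk with 30% noise, a null grade) exercise the association
report.  The same seed reproduces the cohort byte-identically.

What the generator does not model: batch effects, probe-level artifacts,
correlated miRNA families beyond the planted subtype block, non-
proportional hazards, and informative censoring.  Passing tests therefore
demonstrate correctness of the algorithms under the stated model, not
robustness to those violations.

## Problem sizes used in tests and acceptance

Unit tests run on cohorts of 80-600 samples.  The acceptance suite uses:
50 seeded cohorts (n=400, HR 3) for 1D cut-off recovery; 12 seeded
cohorts for paired-design identification; 50 seeded cohorts (n=600) for
three-group score stratification; 500 null replicates (n=80, 199
permutations) for the permutation-P uniformity check; 500 null features
(n=200, screened 5-repeat then full 100-repeat CV) for the dual-criterion
null rate; 1000 K-means runs on two-blob data for consensus stability;
and the full default 486 × 167 pipeline executed twice for byte-identical
reproducibility.  The pairwise scan in the default pipeline covers all
4950 pairs of the top-100 features on the 49-level quantile grid.

## Design choices made where the design was open

- Efron tie handling (the common modern default) rather than Breslow.
- "High expression" means strictly greater than the cut-off.
- The summary statistic for the expression floor is the median.
- The intersection signature takes the cross-validation set passing the
  *confidence* criterion; requiring the <1% cut-off CV as well is exposed
  as an option (`pass_cutoff_cv` per feature) but not the default, since
  the CV criterion is far stricter and its pass set is unstable at small
  cohort sizes.
- Features entering the synergy set need at least `min_pairs` (default
  50) synergistic pairs at P < 0.05.
- Risk labels are always explicit strings (low / intermediate / high);
  numeric phenotype codes are never emitted.
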