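# Methods

`ocmetab` re-implements, as a tested library, a serum-metabolomics
biomarker-discovery workflow for early-stage epithelial ovarian cancer (EOC):
an LC-MS run table is curated into a sample matrix, a linear SVM "metabolic
score" classifier is built, a minimal diagnostic panel is selected by
recursive feature elimination under leave-one-out cross-validation, the
panel is independently validated by OPLS-DA with permutation testing, and
candidate panel features are annotated by adduct mass arithmetic. Because no
patient-level feature matrix is publicly available, the package ships a
synthetic study-emulation generator with planted ground truth; every
pipeline stage is exercised and tested against it.

## Curation model

The input is a runs × features peak-area table with acquisition metadata
(run order, sample id, replicate, role ∈ {study, pooled QC, blank}, class,
batch, site). Curation applies, in order:

1. **Presence filter** — drop features detected (area > 0, non-missing) in
   fewer than `min_runs` runs (default 40).
2. **Total-area (TIC) normalization** — divide each run by its own total
   peak area; every run then sums to 1. This removes run-level intensity
   factors (injection volume, source efficiency, common sensitivity drift).
3. **Pooled-QC drift filter** — per feature, an OLS line of pooled-QC area
   versus run order. Default rule: remove iff |slope| > SE(slope), i.e. the
   slope estimate is more than one of its own standard deviations from zero.
   This is the only dimensionally coherent reading of a "slope more than one
   SD from zero" rule; a `span_sd` alternative (fitted drift across the
   acquisition exceeding one SD of the QC areas) is selectable. Features
   observed in fewer than 3 QC runs cannot be assessed and are removed.
   A fitted relative drift below 1e-9 over the whole span is floating-point
   noise on an exactly stable feature and counts as zero slope.
4. **Blank-baseline filter** — baseline = per-feature maximum area over
   blank runs (a global-scalar mode is available). A feature is kept iff, in
   at least one of {all study samples, cancer, control}, at least 50% of
   samples reach 10× baseline. The threshold comparison is made on the
   *pre-normalization* scale: a blank's raw total is tiny, so after TIC
   normalization its entries are rescaled to sample-like magnitudes and a
   detection-limit comparison would be meaningless. `curate` therefore
   snapshots raw areas for this decision and applies the removals to the
   normalized table.
5. **Duplicate averaging** — mean of a sample's replicate injections per
   feature, with a peak missing in a replicate counted as 0 (gap filling is
   out of scope); QC and blank runs are excluded from the output matrix.

Note on the 1-SE drift rule: under i.i.d. per-feature QC noise the rule is
scale-free — |t| > 1 occurs for roughly a third of drift-free features no
matter how precise the instrument — so on real data it is an aggressive,
conservative purge, consistent with curation pipelines that cut thousands of
raw features down to a few hundred. The synthetic generator models QC
injections without per-feature technical noise (below), which makes the
filter's behaviour deterministic and testable.

## Classifier and panel selection

Classes are coded N (control) → −1, C (cancer) → +1. The classifier is a
soft-margin linear SVM (hinge loss, L2 penalty, unpenalized bias; libsvm via
scikit-learn, cost C = 1 by default — the source workflow does not state a
cost). The decision value w·x′ + b is the **metabolic score**: positive
predicts cancer, negative control; a score of exactly 0 is classified
control (conservative for a screening score) with a warning.

Features are autoscaled (mean 0, unit sample SD) before modelling. Two
scaling modes exist: `global` (default) scales the whole matrix once before
RFE — the conventional chemometrics workflow, but the held-out sample
contributes to the scaling statistics, so LOOCV estimates are optimistically
biased; `per_fold` recomputes scaling inside each training fold (no
leakage). Both are exposed and the leakage direction is tested (per-fold
accuracy ≤ global accuracy on null data, on average).

**RFE**: from the full feature set down to one feature, each step runs a
full LOOCV (n models on n−1 samples), averages each feature's signed weight
over the n fold models, records LOOCV accuracy/sensitivity/specificity, and
eliminates the feature with the smallest importance |mean fold weight|
(mean |weight| is available as an option). Ties break to the earliest
feature in column order, making reruns deterministic. With global scaling
the inner loop runs on a precomputed linear-kernel Gram matrix, rank-1
downdated after each elimination — algebraically identical to refitting on
the reduced matrix and verified against direct fits.

**Panel selection**: the smallest panel whose (accuracy, sensitivity,
specificity) triple is lexicographically maximal over the whole trace — the
"minimum number of features reaching the best metrics" rule.

## OPLS-DA validation

Single-y OPLS (one predictive component, `n_ortho` orthogonal components
extracted by successive deflation). Orthogonal score vectors are exactly
orthogonal to the predictive scores and carry zero class covariance by
construction; `n_ortho = 0` reduces to 1-component PLS-DA (verified against
scikit-learn's PLS as an independent oracle). When unspecified, `n_ortho`
is chosen to maximize leave-one-out Q² (capped at 3).

Q² = 1 − PRESS/TSS over held-out class codes under four schemes:
leave-one-out; venetian blinds (cyclic assignment by sample index, 10
splits); contiguous blocks (10 index ranges); random subsets (10 splits ×
10 seeded iterations, Q² averaged over iterations). Scaling is refit inside
each training fold. The permutation test refits under randomized labels and
reports the add-one empirical p: (1 + #{permuted Q² ≥ observed})/(n_perm+1).

## Univariate summaries and bias inspection

Per feature: class means of the curated areas, signed fold change
(+mean_C/mean_N when the cancer mean is at least the control mean, else
−mean_N/mean_C, so |fc| ≥ 1 always), and a two-sided Mann-Whitney U test
(exact for ≤ 8 per group without ties, tie-corrected normal approximation
otherwise; the reported U is min(U_C, U_N)). Significance tiers: p<0.05,
p<0.10, ns; no multiplicity correction is applied, matching the source
workflow. Experimental-bias inspection is PCA on the autoscaled matrix:
PC1/PC2 scores labelled by batch/site/day plus a pseudo-F association score
(between-group over within-group mean square of the 2-D scores; ≈1 under no
structure).

## Mass annotation

Monoisotopic masses use most-abundant-isotope atomic masses (CODATA/IUPAC,
embedded constants). Ion m/z = (M + gains − losses ± z·mₑ)/z with the
electron term off by default (the *H-atom convention*): reported
deprotonated m/z values in the annotation tables this reproduces match
M − m(H) exactly and differ from the electron-corrected convention by
~0.5 mDa per charge; a flag enables the exact convention. Presets:
[M−H]⁻, [M+Na−2H]⁻, [M−2H]²⁻ (also reachable under its common "[M−H]²⁻"
printing), and [M−CHO−H]⁻ encoded as the loss of CH₂O plus a proton — the
arithmetic consistent with the printed cortisone value; the label's literal
arithmetic is 1.008 Da lower, a discrepancy documented in the preset.
ppm errors are reported against the theoretical m/z rounded to 4 decimals,
the precision at which annotation tables print theoretical values (this is
what makes reported ppm columns reproducible to 0.1 ppm).

Elemental-composition search enumerates formulas within per-element bounds
and a mDa tolerance (default 10 mDa), sorted by |error|, with optional
ring/double-bond-equivalent and nitrogen-rule filters; bound sets above 10⁷
combinations are refused with guidance. The screening-PPV helper computes
sens·prev / (sens·prev + (1−spec)(1−prev)).

## Synthetic study emulation

The generator emits the run table a peak-picking tool would export for the
emulated design: 46 cancer + 49 control sera analysed in duplicate with
non-adjacent replicate injections (seeded constrained shuffle), a pooled-QC
injection after every 8 study runs plus bracketing QCs, 11 blank runs, 8
batches balanced by class, 255 features (~226 runs in total; the count is
emergent, not forced).

Signal model, per feature f: lognormal areas with base log-mean
μ_f ~ U(log 10³, log 10⁶) and biological log-SD σ_f ~ U(0.4, 0.8) (CVs of
roughly 40–90%, typical of untargeted serum features). A planted panel of
16 features shifts the cancer-class log-mean by d_f·σ_f with standardized
effects |d_f| ~ U(1.5, 2.5), mixed signs. Run areas multiply in a
per-(batch, feature) factor (log-SD 0.05), technical replicate noise
(CV 12%, within the 10–15% convention for duplicate injections), a per-run
intensity scalar (log-SD 0.2), and, on a random 10% of features, a linear
differential-drift trend (±15–30% over the acquisition span). Low peaks are
censored: a study-run peak is missing with logistic probability in its
log-area around the detection quantile (marginal rate 5%).

Deliberate idealizations, and what they imply:

- **QC injections carry no per-feature technical noise**: a QC run is the
  mean study composition times the run's intensity scalar and drift trend.
  This makes the 1-SE drift rule deterministic — drifting features are
  always removed, stable features always kept — so curation tests are
  exact. Real pooled-QC replicates have 5–15% feature-level RSDs, under
  which the rule also removes a large fraction of stable features (see
  above); passing tests therefore validate the *mechanics* of the filter,
  not its false-positive behaviour on noisy QCs.
- **Differential drift is net-zero**: drift slopes are recentred against
  the pooled composition (over pool-detectable features) so QC totals are
  drift-stable. The common (whole-signal) drift component is represented by
  the per-run intensity scalar, which TIC normalization removes; without
  the recentring, normalization converts any net drift into a smooth
  artefactual trend on *every* feature.
- **Planted features are drawn from reliably detected features** (above
  the bottom abundance quintile) and are disjoint from drift and
  blank-contaminated features — a biomarker panel confounded with
  instrument drift or solvent contamination would be removed by curation
  by design, and no recovery statement would be meaningful.
- Blank runs sit at 1% of a feature's mean abundance except for a random
  5% of "contaminated" features at 50%, which the baseline filter removes.
- No retention-time structure, isotope patterns, or raw chromatograms are
  simulated; feature ids are opaque labels.

Ground truth (planted ids and effects, drift ids and slopes, contaminated
ids, class labels, ages) is returned alongside the table and serialized as
a JSON sidecar.

## What the study-emulation results do and do not show

With the planted effect sizes above, the selected minimal panel reaches
100% LOOCV accuracy/sensitivity/specificity in essentially every seed, and
the all-feature model is strictly worse — the qualitative
feature-selection-improves-accuracy direction. The selected panel is
however typically *smaller* than the planted 16-feature panel (usually
3–6 features): a subset of standardized effects ≥ 1.5 at n = 95 already
separates the classes perfectly, and the minimal-panel rule then stops
early. Recovering the planted size exactly would require each planted
feature to be individually necessary, i.e. much weaker per-feature effects
— under which 100% accuracy is no longer reached. The acceptance suite
reports both quantities honestly rather than tuning the generator to force
a coincidence. For the same reason the all-feature model, while reliably
worse than the selected panel, occasionally ties it at 100% on this
simulation.

A related estimator property the null tests respect: LOOCV on balanced
null data is slightly *pessimistic* (mean accuracy a few points below 50%),
because the held-out sample's class is always the training minority and
the soft-margin SVM leans against it. Null checks therefore assert that
chance is never exceeded (the leakage direction) rather than exact 50%.

## Numerical choices and degenerate inputs

- SVM solver tolerance is libsvm's default (1e-3); antisymmetry and
  duplication invariances hold to that tolerance.
- Autoscaling uses the sample SD (ddof = 1); a zero-variance feature is an
  error naming the feature.
- LOOCV requires ≥ 2 samples per class; OPLS-DA rejects `n_ortho` at or
  above the informative rank; cross-validation rejects more splits than
  samples.
- A run with non-positive total area, a table with no blank or < 3 QC
  runs, duplicated run indices, negative areas, and curation that leaves
  no features all raise errors naming the offending run/feature.
- Elimination and selection ties break deterministically (earliest feature
  in column order; smallest panel).

## Problem sizes used in the test suite

Unit and property tests run on scaled-down emulations (typically 20–48
samples × 30–60 features) where each property's statistics are still
informative; the acceptance checks run the full default profile
(95 samples × 255 features, nested-LOOCV RFE ≈ 24,000 SVM fits per
replicate) over 20 seeds, which the precomputed-Gram inner loop keeps to
roughly 25 s per replicate.
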