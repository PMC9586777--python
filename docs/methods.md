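# Methods

## The problem

Diagnosing iron-deficiency anemia from a routine laboratory panel is a
binary classification task on a small tabular dataset that is simultaneously
affected by outliers (mismeasured or misrecorded analytes), strong
multicollinearity (hematocrit is nearly proportional to hemoglobin), class
imbalance (most referred cases are confirmed), and label noise (borderline
cases evaluated inconsistently). `idadx` treats these jointly: dataset
variants are produced by different outlier-removal backends, features are
screened once per variant, and imbalance/noise handling happens inside each
cross-validation training fold, never on evaluation data.

## Outlier detection

**Iterative Z-score.** Each column is standardized with the population sd
over the currently retained rows; any row with |z| ≥ threshold (default 3)
in any column is removed, and the procedure repeats until a round removes
nothing or `max_rounds` (default 100) is reached. The ≥ comparison (rather
than >) is deliberate: with population sd, a single spike among n
otherwise-identical values has z exactly √(n−1) — at n = 10 that is exactly
3.0, and the spike must be flagged, so the threshold is inclusive.
Constant columns are skipped within a round.

**RDOS.** For each instance the extended neighborhood S(xⱼ) is the union of
its k nearest neighbors, its reverse nearest neighbors (instances counting
xⱼ among their k nearest), and its shared nearest neighbors (instances with
at least one common k-neighbor). The density at xⱼ is a Gaussian-kernel
estimate over S(xⱼ) ∪ {xⱼ}, K(u) = (2π)^{−d/2}·exp(−‖u‖²/2) scaled by the
width h, and the score is the mean density of the S(xⱼ) members divided by
the density at xⱼ. Scores near 1 mean the instance is as dense as its
surroundings.

*Kernel width.* The default h is the **mean distance to the k-th nearest
neighbor** of the (standardized) data. A Silverman-style rule on the pooled
per-feature sd is offered (`h="silverman"`) but is inappropriate beyond a
few dimensions: the kernel argument is the full Euclidean distance, and with
d = 10 typical pairwise distances are ≈ √(2d) pooled sds, so a Silverman
width (~0.6 sd) drives every cross term to ~e^{−25}; all densities then
collapse to their self-kernel term divided by |S|+1 and the "ratio of
densities" degenerates into a neighborhood-size artifact that scores genuine
outliers *below* 1. Tying h to the k-neighbor distance keeps the kernel
responsive at the scale where "local" is defined, in any dimension.

*Other defaults.* k = 5; features are standardized before distance
computation (iron and ferritin are numerically 1–2 orders of magnitude
larger than red-cell counts and would otherwise own the metric); distance
ties break toward the lower instance index, which makes every neighbor set
bit-reproducible by a brute-force oracle.

**NOF.** Natural-neighbor searching expands the neighbor radius r = 1, 2, …,
crediting each instance's r-th neighbor with one reverse-neighbor count
(Rnb), and stops when the set {i : Rnb(i) = 0} is empty or unchanged between
rounds. Instances never adopted (Rnb = 0) are natural outliers. The natural
eigenvalue sup_k — the mean neighbor-list length at termination, which
equals the terminal round whenever n−1 ≥ r — sets k for a LOF-style score:
lrd(xⱼ) = |NNₖ(xⱼ)| / Σ_m reach-distₖ(xⱼ, x_m) with
reach-distₖ(xⱼ,x_m) = max{k-dist(x_m), d(xⱼ,x_m)}, and
NOF(xⱼ) = Σ_{q∈NIS(xⱼ)} lrd(q) / (|NIS(xⱼ)|·lrd(xⱼ)) over the Natural
Influence Space NIS = NNₖ ∪ RNNₖ. Degenerate duplicate-heavy neighborhoods
(infinite lrd on both sides) score 1; an infinite score from a
zero-reachability neighborhood is flagged outright.

**Thresholding relative scores.** RDOS/NOF scores are converted to removal
decisions by standardizing the scores (population sd) and flagging z ≥ 3 on
the high side only. This 3σ rule is not robust: when contamination
approaches 5% the flagged instances inflate the score mean and sd enough to
mask one another, and measured recall of magnitude-8 displacements falls to
~0.7 regardless of k and h, even though the raw scores separate cleanly
(displaced ≥ 4.7 vs. clean ≤ 1.6). The detection-power tests therefore
check threshold-based recall at 3% contamination and threshold-free rank
separation at 5%.

## Feature screening (Boruta)

max(p, 5) shadow columns — within-column permutations of the originals —
are appended; per run a random forest (default 500 trees, unrestricted
depth, mean-decrease-in-impurity importances; permutation importance
available) is fit and each still-undecided feature scores a hit when its
importance exceeds the best shadow (shadowMax). After run r, a feature with
binomial evidence of hitting more often than chance (one-sided p <
alpha/p, Bonferroni across the p features, alpha = 0.01) is confirmed;
significantly less often, rejected. The loop stops early once every feature
is decided; leftovers are tentative and are retained for modelling
(conservative: dropping an undecided feature risks discarding signal).

## Resampling strategies

**SMOTE (exact balance).** n_syn = n_neg − n_pos synthetic minority points;
each picks a minority donor x_i uniformly with replacement, one of its k = 5
nearest minority neighbors x̂_i, and an independent λ ~ U[0,1], yielding
x_i + λ(x̂_i − x_i). k is clipped to (minority − 1) in small folds. Every
synthetic point is by construction a convex combination of two minority
rows; the output classes are exactly equal.

**Ensemble filter.** One shared stratified k-fold partition (default 5
folds); each of m heterogeneous base learners — decision tree, 5-NN, linear
discriminant by default (Gaussian NB and logistic regression extend the
roster to m ≤ 5) — is trained out-of-fold and predicts every held-out
instance, so each instance is tested exactly m times. Instances wrong under
*all* m learners are removed. Both classes are eligible (removals are
logged per class); removing an entire class aborts with advice to reduce m.

**ef_smote** filters first, then balances the filtered set — oversampling
before filtering would let noisy minority instances spawn synthetic copies.

## Evaluation protocol

Repeated stratified k-fold CV (default 10 folds × 5 repeats). Per cell:
standardize on the training part (test transformed with train-fitted
parameters), apply the resampling plan to the training part only, fit
XGBoost (binary logistic objective, exact greedy tree construction,
remaining hyperparameters at library defaults), and score the untouched
test part. The exact tree method is used because the histogram sketch pins
split thresholds to bin edges at the class boundary, misranking margin
points even on separable data; exact splits mid-margin and matches what the
reference R implementation resolves to at these data sizes.

Positive = minority class, resolved per dataset after cleaning. The
confusion matrix uses a 0.5 probability threshold; AUC is threshold-free.
Metrics aggregate as unweighted mean ± sd over all fold×repeat cells.
A fold whose resampling fails is skipped; >20% skipped aborts. MCC with a
zero denominator factor is defined as 0; sensitivity/specificity with a
zero denominator are NaN and excluded from aggregation.

Grid search enumerates the full Cartesian grid — default
nrounds ∈ {25,…,150}, λ, α ∈ {0,…,1}, η ∈ {0.01, 0.1, 0.25}, 450 points —
on identical fold assignments and resampling draws (common random numbers),
maximizing mean MCC; ties break toward smaller nrounds, then smaller η.
Per-cell seeds derive from the root seed independently of the
hyperparameters.

## Synthetic study conditions

The generator draws two class-conditional multivariate normals with shared
correlation structure and unit within-class variances; `class_shift` and
`outlier_magnitude` are therefore in within-class sd units. The IDA-like
preset uses 10 analyte analogues with Hb–Hct correlated at 0.97, moderate
iron-panel correlations (Fe–UIBC −0.5, Fe–FERR 0.55, Hb/Hct–MCV 0.4), a
majority(diseased)/minority(healthy) ratio of 2.287, and downward shifts in
the diseased class on Fe (−2.6), FERR (−2.4), Hb (−2.0) and Hct (−1.94 —
hematocrit must track hemoglobin or the near-unit pair collapses in the
pooled data). The shift magnitudes were calibrated once so that a tuned
boosted classifier on clean preset data reaches cross-validated MCC ≈ 0.93
and ACC ≈ 0.97 — the performance scale clinical IDA panels actually
exhibit, ferritin being close to diagnostic on its own.

Outlier contamination displaces ⌈fraction·n⌉ rows by magnitude × per-feature
sd along a random unit direction (displacement-based so ground truth is
unambiguous, unlike distribution-tail definitions); label noise flips each
label independently. What the generator does **not** emulate: the skewed
marginals of ferritin, measurement units, age structure, or any
feature-dependent noise mechanism — passing tests demonstrate structural
correctness of the pipeline, not clinical validity on real panels.

## Problem sizes

The test suite and the acceptance script run at desk scale, chosen as the
smallest sizes at which each effect is comfortably measurable: n = 200–516
rows, 20 seeds for frequency claims in tests (5 in the acceptance script),
Boruta with 50–100 trees per run in the simulation studies (500 in the
pipeline default), CV at 4–5 folds × 1–2 repeats in simulations (10 × 5 in
the pipeline default), and reduced grids where the full 450-point grid is
not itself the object under test.

## Known limitations

- The 3σ score-thresholding rule masks at contamination ≳ 5% (see above);
  a robust variant (median/MAD) would detect more but is deliberately not
  the default, to keep the published cleaning protocol.
- Natural-neighbor searching is O(n²) in memory and time; fine for n ≈ 500,
  not for n ≫ 10⁴.
- The ensemble filter's consensus rule is conservative by design; with
  overlapping classes it leaves most noise in place (agreement of all m
  learners on a wrong prediction requires the instance to look genuinely
  mislabeled).
- Exact reproduction of any particular clinical dataset's outlier counts
  depends on unknowable preprocessing details (standardization, k, h);
  the package exposes all three.
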