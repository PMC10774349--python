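# Methods

## Problem setting

`refsig` discovers and validates compact microbial signatures for binary
case/control phenotypes from 16S rRNA amplicon-sequence-variant (ASV)
count tables. The unit of analysis is the ASV: an exact denoised amplicon
sequence, resolved to single-nucleotide differences. The workflow has two
phases. In the *discovery phase*, recursive ensemble feature selection
(REFS) reduces a full ASV table (thousands of features) to the small
subset that best discriminates cases from controls, and a panel of five
held-out classifiers quantifies that subset's cross-validated ROC-AUC. In
the *validation phase*, the signature is transferred into independent
cohorts — which, having been sequenced over different 16S regions at
different read lengths, contain different ASVs — by exact subsequence
matching, and the transferred signature is re-scored with the same
held-out panel.

## Recursive ensemble feature selection

The selection ensemble has eight scikit-learn classifiers: a stochastic
gradient descent linear classifier, a linear-kernel SVC, gradient
boosting, random forest, logistic regression, a passive-aggressive
classifier (PA-I, constructed through its exact `SGDClassifier`
parametrization: hinge loss, no penalty, `pa1` learning rate), a ridge
classifier, and bagged decision trees.

One *cycle* works on the currently retained features:

1. Stratified k-fold split (default k = 10). Fold assignment is keyed to
   the sorted sample ids, so results do not depend on the order of rows
   in the input files. If the minority class has fewer than k samples the
   fold count drops to that size with a logged warning; below 2 samples
   per class the run aborts.
2. Per fold and member: fit on the training split, record held-out
   accuracy and ROC-AUC, and extract a per-feature importance vector —
   |coefficient| for the five linear members, impurity importance for the
   tree/boosting members, the mean over base trees for bagging. Each
   vector is L1-normalized before aggregation so that no member dominates
   through the scale of its coefficients; the cycle's importance is the
   mean over all (fold × member) pairs and itself sums to one.
3. The 20% least important features are removed (at least one), i.e.
   `n → n − max(1, ⌊0.2·n⌋)` until one feature remains. Starting from
   2040 features this schedule passes through …, 39, 32, 26, 21, … —
   consistent with the published 26-ASV optimum this package mirrors.

The whole schedule is replicated over independent *runs* (default 30;
the scaled-down benchmark uses 5), each with a derived seed
(`master_seed + run_index`). Runs may execute concurrently via joblib but
are merged by run index, so the result is identical for any worker
count. A run's best cycle is the one with the highest mean held-out
accuracy over folds × members, ties going to fewer features; the best run
is the one whose best cycle scores highest, ties going to the lower run
index. The selected signature is that cycle's retained set, ranked by
descending ensemble importance. Both accuracy and AUC are recorded per
cycle; accuracy drives cycle selection, AUC is what the validation module
reports.

Normalization is a per-feature Z-score `(x − mean)/sd` (population sd;
constant features map to zero) fitted **on the full matrix before
cross-validation** — the procedure this package reproduces normalizes
once up front, which leaks fold statistics into training. The
`fold_safe_scaling` flag refits the scaler inside each training fold
instead; the default logs a warning naming the leak.

### Frozen hyperparameters

All member hyperparameters live in a versioned YAML shipped with the
package (`refsig --version` prints its hash). Most are scikit-learn
defaults. Deviations: gradient boosting uses 50 trees with
`max_features="sqrt"` and random forest 50 trees — default gradient
boosting scans every feature at every split, which makes a full
elimination run roughly three times slower while the aggregated rank
order at ensemble size eight is unchanged in practice; logistic
regression gets `max_iter=1000` to converge on z-scored counts; the MLP
of the validation panel gets `max_iter=500` for the same reason.

## Held-out validation

Five classifiers that take no part in selection — AdaBoost, Extra Trees,
K-nearest neighbours, a multi-layer perceptron, and LassoCV — are scored
by ROC-AUC in the same stratified ten-fold scheme on the
signature-restricted, Z-scored matrix. Scores are the positive-class
probability where available, otherwise the decision function; LassoCV is
a regression learner used as a ranker, so its continuous prediction is
the score directly and no threshold is ever chosen (AUC needs only a
ranking). Tables report the per-fold mean ± SD per classifier and the
five-classifier average; the SD is across folds. Figures use the ROC of
scores pooled across folds; the trapezoidal area under the reported ROC
points equals the Mann–Whitney concordant-pair statistic (ties half) to
numerical precision.

## Cross-cohort signature transfer

A discovery ASV is *present* in a validation cohort when its sequence
occurs verbatim inside a validation ASV sequence (case-insensitive,
forward strand; reverse-complement search is available behind a flag
because cohorts sequenced over different regions can differ in
orientation). The counts of all containing validation ASVs are summed and
treated as that signature feature's abundance. A validation ASV that
contains two distinct signature sequences contributes its counts to both
aggregated columns — aggregation is per signature feature — and such
shared containments are flagged in the match report. Unmatched signature
features are recorded and excluded from the reduced table. Matching is a
plain substring scan; at ASV scale (thousands of sequences of a few
hundred nt) no index is warranted.

## Differential abundance

Selected columns are standardized to zero mean and unit variance over all
samples. Each feature's direction label compares standardized group means
("ASD increased" when cases are higher; exact ties are labelled "tied"
rather than assigned arbitrarily). Structural absence — zero raw counts
in every sample of one group — is flagged separately, because a
standardized mean cannot distinguish rare from never-observed. The
heat-map export writes the standardized samples × features matrix as TSV
(the artifact of record, full precision, columns in signature rank order)
plus a rendered image for inspection.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes,
with known ground truth so that recovery is measurable.

*Count law.* Dirichlet-multinomial: a log-normal baseline profile
(σ = 1.5: few dominant taxa, a long rare tail) scaled to total
concentration `overdispersion` (default 50, in the range of
Dirichlet-multinomial fits to human stool 16S data; smaller = noisier);
library sizes are shifted-Poisson (default mean 20 000). Dirichlet draws
are element-wise Gamma draws, so zero concentrations give exact zeros.

*Planted signal.* `n_informative` ASVs (default 15 of 500) multiply their
concentration by `exp(±effect_size/2)` per group, so the expected
case/control relative-abundance ratio is ≈ `exp(effect_size)` (default
2.0). Informative ASVs are drawn among taxa of above-median baseline
abundance: a taxon observed in almost no sample cannot express a
log-fold effect at realistic sequencing depth, so planting signal in the
rare tail would make the ground truth vacuous. A fraction
(`frac_absent_in_one_group`, default 0.2) of the informative set is made
*structurally* absent (zero concentration, hence zero counts always) in
its depleted group, mirroring signature taxa never observed in one
phenotype; absence is assigned to the rarest informative taxa, because
the total absence of an abundant taxon from one group would be a perfect
single-feature biomarker — something the moderate AUCs of real
case/control microbiome studies rule out.

*Paired validation cohort.* An independent cohort under the same law with
longer reads (250 vs 150 nt). For each retained informative discovery
ASV, 1–3 validation ASVs are constructed whose sequences embed the
discovery sequence verbatim at a random offset, splitting its
concentration mass among them and carrying its group effect; a
`drop_fraction` of the informative set gets no containing ASV at all,
emulating signature members missing from a second cohort. The containment
map is self-verifying by substring scan.

*Determinism.* One RNG per operation, seeded from the config
(`seed` for the discovery cohort, `seed + 1` for the validation cohort),
with a documented draw order (counts before sequences); fixed seeds
reproduce every output bit-exactly.

*What the generator does not emulate.* Taxonomic structure and
phylogenetic correlation between ASVs, read-level error, chimeras,
batch/primer effects, and compositional correlation beyond what the
Dirichlet induces. Passing recovery tests therefore show that the
pipeline finds planted compositional signal under realistic
overdispersion — not that any real cohort contains such signal.

## Benchmark scale and numerical choices

The standard benchmark is 200 samples × 500 ASVs with 15 planted features
at effect 2.0, selected with 5 runs × 10 folds — large enough that
held-out scores do not saturate and small enough for routine laptop runs.
A known property of recursive elimination at this scale is parsimony
pressure: when a small subset already separates the groups nearly
perfectly, the best-performing cycle can sit below the planted-set size,
trading completeness for compactness. Because the cycle-score curve is
then nearly flat over a wide range of cycle sizes, the size of the
selected set — and with it the fraction of planted features recovered —
varies appreciably between master seeds, while its precision (selected
features that are truly planted) stays high.

Tie-breaks and degenerate inputs: feature ties in importance are broken
by current column order (stable sort); constant features z-score to zero
and therefore carry no importance for linear members; empty matches,
single-class inputs, and sub-minimum read lengths are hard errors. Fold
seeds derive from run seeds; all randomness flows from one master seed.

## Relation to the real study

The published numbers this package's structure mirrors (a 26-ASV
signature; discovery average AUC 0.816; validation averages 0.748/0.740;
best single classifiers 0.90/0.84) were obtained from three external raw
sequencing datasets that require download and DADA2 processing, and the
26 signature sequences were never published. Those numbers are therefore
not reproducible from the package alone; the packaged transcription of
the signature's taxonomy table, its taxon census, and the synthetic
benchmark surface above are what the test suite and acceptance script
compute.
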