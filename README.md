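# refsig

Recursive ensemble feature selection (REFS) and cross-cohort signature
validation for 16S rRNA amplicon-sequence-variant (ASV) count tables.

## The problem

Case/control microbiome studies rarely agree on which bacterial taxa
matter: cohorts differ in geography, diet, sequencing region and
processing, and univariate tests on compositional, overdispersed count
data are fragile. One way through is to treat signature discovery as a
multivariate feature-selection problem — find the smallest set of ASVs
that lets a classifier separate cases from controls — and then demand
that the signature *transfer*: that the same sequences, found again in
independent cohorts, still discriminate.

`refsig` implements that workflow for binary phenotypes:

1. **Select** — an ensemble of 8 heterogeneous classifiers (SGD, linear
   SVC, gradient boosting, random forest, logistic regression,
   passive-aggressive, ridge, bagged trees) ranks ASVs by aggregated,
   L1-normalized importance under stratified ten-fold cross-validation;
   each cycle removes the 20% least important features
   (`n → n − max(1, ⌊0.2·n⌋)`) down to one. The process is replicated
   over independent runs and the signature is the retained set of the
   best-scoring cycle of the best run.
2. **Validate** — five held-out classifiers (AdaBoost, Extra Trees,
   KNeighbors, MLP, LassoCV) score the signature by ROC-AUC in
   stratified ten-fold cross-validation; the headline number is the
   five-classifier mean AUC, `AUC = P(score_case > score_control)` with
   ties counted half.
3. **Transfer** — a discovery ASV counts as present in another cohort
   when its sequence occurs verbatim inside a (longer) validation ASV;
   abundances of all containing ASVs are summed and the reduced table is
   re-scored with the same five classifiers.
4. **Report** — standardized differential-abundance directions
   ("ASD increased/decreased"), structural-absence flags, heat-maps.

A Dirichlet-multinomial synthetic-cohort generator with planted
discriminative ASVs (and engineered sequence containment between a
150 nt discovery cohort and a 250 nt validation cohort) provides ground
truth for every stage; see `docs/methods.md` for the model and its
limits. The package also ships a transcription of the published 26-ASV
autism signature taxonomy table (taxonomy, abundance direction,
per-cohort presence; the nucleotide sequences were never published), via
`refsig.load_asd_signature()`.

## Worked example

Simulate a paired cohort, select a signature, and transfer it:

```bash
refsig simulate --out-dir demo --n-case 30 --n-control 30 --n-asv 120 \
    --n-informative 8 --seed 7
refsig select --counts demo/discovery_counts.tsv --fasta demo/discovery_asvs.fasta \
    --labels demo/discovery_labels.tsv --out-dir demo/select --runs 3 --folds 5 --seed 7
```

which prints

```
{
  "selected_n_features": 7,
  "discovery_average_auc": 0.9966666666666667
}
```

i.e. recursive elimination kept a 7-ASV signature whose held-out
five-classifier mean AUC on the discovery cohort is 0.997 (per-classifier
table in `demo/select/discovery_auc_table.tsv`, cycle-score curve in
`demo/select/cycle_scores.tsv`). Transfer it into the paired validation
cohort, whose ASVs are longer reads containing the discovery sequences:

```bash
refsig match --signature-fasta demo/select/signature.fasta \
    --counts demo/validation_counts.tsv --fasta demo/validation_asvs.fasta \
    --labels demo/validation_labels.tsv --out-dir demo/match
```

```
matched 5/7 signature ASVs
```

Five of the seven selected ASVs occur verbatim inside validation-cohort
sequences; `demo/match/reduced_counts.tsv` holds their aggregated
abundances and `demo/match/presence.tsv` the Yes/No presence flags. The
full pipeline (`refsig run --config pipeline.yaml`) chains these stages
and writes a manifest with the seed, resolved configuration, and a
SHA-256 hash of every artifact, so every emitted number can be
regenerated from the manifest alone.

The same operations are available as a library:

```python
from refsig import SyntheticConfig, generate_discovery, run_refs, crossval_auc

cfg = SyntheticConfig(n_case=30, n_control=30, n_asv=120, n_informative=8, seed=7)
table, truth = generate_discovery(cfg)
result = run_refs(table, n_runs=3, n_folds=5, seed=7)
report = crossval_auc(table, result.selected_asv_ids, n_folds=5, seed=7)
print(len(result.selected_asv_ids), round(report.ensemble_mean, 3))
# 7 0.997
```

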