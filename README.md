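# enhancerclass

Supervised prediction of active enhancer regions from two complementary
data types: **chromatin-mark signal** (windowed ChIP-Seq tracks for
histone modifications, PolII and TF occupancy) and **sequence-motif
content** (thermodynamic binding affinities for a panel of
transcription-factor motifs). The package is aimed at regulatory
genomicists who want to train region classifiers on a curated positive
set (e.g. tissue-specific CRMs), compare the mark-only (EPI),
motif-only (MOT) and combined (ALL) feature sets, validate on an
independent enhancer collection, and dissect which features carry the
signal.

## The model

Each candidate region is summarized by:

* **MOT features** — the TRAP expected occupancy of a motif with
  position probabilities *p(j,b)* over a sequence *S* of length *L*:

      A = Σ_strands Σ_{i=1..L−m+1}  R0·e^(−E_i) / (1 + R0·e^(−E_i)),
      E_i = (1/λ) Σ_{j=1..m} ln( p(j, b*_j) / p(j, S_{i+j}) ),

  with λ = 0.7 and R0 = exp(0.584·m − 5.66) for motif length *m*
  (b*_j is the consensus base). Windows containing N contribute zero.

* **EPI features** — the unweighted mean of every fixed 50-bp signal
  window the region overlaps, one feature per mark.

Labeled regions (positives plus length-matched random negatives drawn
from the rest of the genome with lengths ~ Normal(mean, sd) fitted to
the positive set) are classified by one of three backends: a random
forest (30 trees), an RBF SVM on standardized features, or a discrete
Bayesian classifier whose class-node parents (≤ 3) are chosen by
exhaustive Bayesian-Dirichlet-equivalent (BDe) scoring. Evaluation is
k-fold cross-validation (standard 9:1 and reversed 1:9 schemes) by
ROC AUC and classification error. Feature relevance is assessed with a
shadow-feature (Boruta-style) procedure extended by contrast
variables: permuted feature copies whose confirmation rate estimates
the expected number of false discoveries.

A fully parameterized synthetic generator (genome, motif panel,
planted driver-motif instances, per-mark effect sizes with Gaussian
noise, optional non-additive mark pairs, low-complexity tracts) makes
every stage testable end to end without external data.

## Worked example

```python
from enhancerclass import (
    SyntheticConfig, generate_dataset, build_feature_matrix,
    ModelSpec, CVSpec, cross_validate,
)
from enhancerclass.pipeline import assemble_training_set

ds = generate_dataset(SyntheticConfig(seed=1))          # 500 enhancers, 8 marks, 20 motifs
regions = assemble_training_set(ds, seed=2)             # + 500 length-matched negatives
data = build_feature_matrix(ds.genome, ds.tracks, ds.pwms, regions, "ALL")

for fs in ("EPI", "MOT", "ALL"):
    res = cross_validate(ModelSpec(kind="rf", seed=1), data.select(fs),
                         CVSpec(k=10, seed=1))
    print(res.summary())
```

prints

```
EPI/rf (10-fold, standard): AUC 1.000 +/- 0.000, error 0.0 +/- 0.0%
MOT/rf (10-fold, standard): AUC 0.919 +/- 0.038, error 13.6 +/- 4.6%
ALL/rf (10-fold, standard): AUC 1.000 +/- 0.000, error 0.0 +/- 0.0%
```

Marks separate the classes essentially perfectly under the default
(strong-effect) conditions, motifs alone are informative but weaker,
and the combined feature set is at least as good as either — the
qualitative pattern the method is designed to expose. The same
analysis runs from the shell:

```bash
enhancerclass run --seed 1 --out results/
enhancerclass simulate --seed 1 --out data/
enhancerclass crossval --features results/features_ALL.tsv --model rf --k 10
```

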