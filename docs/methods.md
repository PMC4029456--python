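# Methods

## Problem and model

The package treats enhancer identification as binary classification of
genomic intervals. A region is described by two feature families.

**Motif affinities (MOT).** For each position weight matrix the TRAP
occupancy model assigns every length-m window a mismatch energy
E = (1/λ)·Σ_j ln(p(j, b*_j)/p(j, b_j)) relative to the best-binding
word, and the region's feature is the expected number of bound
molecules, Σ R0·e^(−E)/(1+R0·e^(−E)), summed over both strands.
Defaults: λ = 0.7 (calibrated for natural-log energies in the original
TRAP work), R0 = exp(0.584·m − 5.66). Count matrices are regularized
with pseudocount 1 per cell before log-ratios; windows containing N
contribute zero occupancy (assemblies contain N; an error would be
unhelpful); sequences shorter than the motif score 0 with a warning.
Both strands are scanned because TF binding is strand-symmetric and
the both-strand variant is the TRAP default.

**Chromatin marks (EPI).** Signal is modelled as fixed-width windows
(default 50 bp). A region's feature per mark is the unweighted mean of
every window it overlaps — a window partially covered counts fully.
Windows missing from a track (or beyond its recorded extent) are
imputed as zero signal.

Feature provenance is carried in the column name ("EPI:", "MOT:") so
the EPI/MOT/ALL feature sets are pure name filters.

## Negative sampling

Negative regions are drawn uniformly from the genome: chromosome with
probability proportional to its length, start uniform over positions
where the region fits, length ~ Normal(mean, sd) fitted to the
positive set (sample mean, n−1 sd), rounded, redrawn below 20 bp (the
Gaussian has mass below 1 bp; 20 bp is the smallest region for which
features are meaningful). Candidates overlapping any exclusion set
(positives, repeat tracts, a training set) or — by default — any
previously drawn negative are rejected; candidates with >50% N are
rejected when a genome is supplied. The sampler either returns exactly
n regions or raises, naming the exclusion set that rejected the most
candidates. A long run of consecutive rejections with mutual exclusion
active discards the drawn set and restarts: sequential rejection
sampling can otherwise wedge when early draws block the only feasible
layout of a tight free space.

One practical caveat surfaced during development: rejection sampling
against exclusions accepts short candidates more readily than long
ones, so at high exclusion density the realized negative lengths are
biased short. At the ~3% occupancy of the default synthetic genome
(and of real genome-scale data) the bias is negligible (<1 bp), but on
small crowded toy genomes it reaches tens of base pairs and leaks
length signal into otherwise null comparisons. The synthetic defaults
were sized accordingly.

## Classifiers

* **rf** — scikit-learn random forest, 30 trees, seeded; score =
  fraction of trees voting positive (needed for ROC analysis).
* **svm** — RBF kernel, C = 1, kernel width 1/p, features standardized
  with training statistics; score = signed decision value.
* **bde** — features discretized into equal-frequency bins (default
  3); exhaustive search over feature subsets of size ≤ 3 as parents of
  the class variable, scored by the BDe marginal likelihood with a
  uniform Dirichlet prior (equivalent sample size 1, α_jk = ESS/(q·r));
  ties break toward smaller subsets, then lexicographic order, making
  the search deterministic. The conditional probability table is
  Dirichlet-smoothed; the score is the posterior probability of the
  positive class. Only the class node's parents are learned — the part
  of a Bayesian-network structure that affects classification. The
  subset search is budget-limited (default 200 000 subsets) and
  refuses wide feature sets, reflecting the method's poor scaling in p.

Decision thresholds for error rates: 0.5 vote fraction (rf), 0 margin
(svm), 0.5 posterior (bde).

## Evaluation

k-fold cross-validation over a seeded shuffle (unstratified by
default; stratification available). Standard scheme: train on k−1
folds, test on one; reversed scheme: train on one fold, test on the
remaining k−1, probing sensitivity to training-set size. Fold-wise AUC
(Mann–Whitney, ties ½) and error are reported as mean ± sd over folds;
fold AUC is recorded only where the test fold contains both classes
(undefined otherwise, e.g. leave-one-out), while fold error is always
recorded. Folds whose training part is single-class are skipped with a
warning. External validation rebuilds features for an independent
labeled region set with the training-time parameters and refuses
validation regions that overlap the training set.

## Feature importance

The shadow-feature procedure augments the design with a freshly
permuted copy of every active feature each iteration, fits a random
forest, and scores a "hit" for features whose permutation importance
exceeds the best shadow importance. Importance is measured on a
held-out 30% split as the drop in the forest's mean probability of the
true class after permuting one column — a soft mean-decrease-accuracy.
The 0/1-vote variant is quantized to 1/n_val at these validation sizes
and could not separate weak real features from shadows, so the
probability form is used. Hit counts are tested two-sided against
Binomial(iterations, ½) at α = 0.01; confirmed features stay in the
design, rejected features are removed, and the run stops early when
nothing is tentative (cap: 100 iterations by default). The per-feature
Z-score is (importance − mean shadow)/sd shadow averaged over
iterations (skipped when fewer than 5 shadows remain, where the sd
estimate is unusable).

The whole run is repeated (default 30×) after extending the data with
*contrast variables* — row-permuted copies of real features, cycled
over the originals so marginals are preserved. The mean number of
confirmed contrasts per repetition estimates the expected number of
false discoveries among the real features; the final decision per
feature is the majority across repetitions and the final Z the mean.

Ablation protocols: remove each mark singly, or the K most / least
important marks (K = 1..7) by a supplied ranking, retrain and
cross-validate, reporting error increase over the full model.
Iterative motif elimination removes ⌊0.8·count⌋ of the least important
motif features per step while count ≥ 5, then one at a time, re-ranking
at every step, recording the cross-validated error down to a single
motif.

## Synthetic data

The generator emulates the statistical structure of a real
enhancer-classification dataset, at reduced scale:

* **Genome** — i.i.d. bases, GC 0.43, two chromosomes of 2 Mb. The
  size keeps region occupancy near 3% so that rejection sampling of
  negatives is unbiased (see above). Optional low-complexity tracts
  (runs of a repeated 2-mer) can cover a configurable fraction.
* **Motif panel** — 20 PWMs, lengths 8–12, one dominant base per
  position with probability 0.85–0.95; panel members are redrawn until
  their consensus words share at most a 5-mer on either strand. The
  non-redundancy mirrors curated motif collections and keeps the
  planted-informative set well-defined: with similar PWMs, planted
  driver sites genuinely inform "unrelated" motif features.
* **Enhancers** — 500 non-overlapping regions, lengths ~
  Normal(270.47, 112) rounded (the empirical moments of the real
  positive set this design emulates), redrawn below twice the longest
  motif. Each enhancer receives Poisson(3) instances of the 2 driver
  motifs, sampled base-by-base from the PWM, random strand, uniform
  non-overlapping offsets, never straddling the boundary.
* **Tracks** — window value = δ_m·1[window overlaps an enhancer] +
  Normal(0, 1), with δ = 4, 3, 2 for the three informative marks
  (H3K4me1, H3K36me3, Mef2 — the marks the method's reduced model
  highlights) and δ = 0 for the other five. The optional non-additive
  pair routes the whole effect to exactly one of two marks per
  enhancer (fair coin), the simplest mechanism by which two marks are
  individually weak but jointly decisive.

What the generator does **not** emulate: read-count noise models
(Poisson/NB), fragment-size and nucleosome structure, mapping bias in
repeats, GC-dependent background, co-occurring motif grammar beyond
independent planting. Passing tests therefore demonstrate that the
pipeline recovers planted structure of the assumed form, not that the
classifiers meet any particular accuracy on real chromatin data.

## Problem sizes and numerical choices

Tests and the acceptance script run the default 500+500-region
conditions for classification checks; importance recovery uses 250
positives on a 2×150 kb genome with mark effects {2, 1.5, 1} and an
iteration cap of 25 (decisions converge well before the cap under
these effect sizes); the all-noise false-discovery check uses 75
positives with 4 marks and 3 motifs; ablation uses noise_sd 2 so that
mark removal has a visible cost (the default strong-effect regime is
saturated and insensitive to single removals). Equal-frequency bin
edges are right-closed quantiles; constant features collapse to one
bin with a warning; BDe scoring is done entirely in log space via
gammaln. All randomness flows from numpy Generators seeded per stage;
the pipeline fans one global seed out through a SeedSequence.

## Known limitations

* The BDe backend's exhaustive subset search is exponential in
  max_parents; it is budget-limited rather than heuristic.
* Contrast/shadow decisions across the 30 repetitions share the same
  dataset, so dataset-level spurious associations (finite-sample
  correlations of a feature with the labels) are confirmed
  consistently rather than averaged away; only fresh data can remove
  them.
* Fold-mean AUC at 1000 regions has sampling sd ≈ 0.02; chance-level
  checks against a ±0.05 band are correspondingly tight.
* External validation assumes the validation genome/tracks use the
  same window width and motif panel as training.
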