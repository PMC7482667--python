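# Methods

## Scope and design

`lfqnet` implements the computational core of a grade-stratified,
label-free quantitative (LFQ) proteomics study of meningioma: the
differential-abundance statistics chain, an artificial-neural-network
(ANN) interactome miner, a randomized single-feature concordance ranking
for grade discrimination, and in-silico design of selected-reaction-
monitoring (SRM) transitions. Because the study's raw LC-MS/MS data
require licensed search engines and are not reproducible at desk scale,
the package ships a first-class synthetic-cohort generator with planted
ground truth; every downstream stage is validated by recovering what was
planted.

## Synthetic cohorts

The generator emulates the structure of an LFQ tissue study without
claiming to be a faithful generative model of mass spectrometry — no such
model is available, and all distributional choices below are explicit
stand-ins.

For protein *i* in sample *s* the log2 abundance is

    x_is = b_i + d_i(g(s)) + sum_j w_ji * (x_js - mean_s x_js) + e_is

* `b_i ~ Uniform(24, 36)` — base levels bracketing the abundance range of
  typical LFQ log-scale exports (roughly 24–36 for tissue proteomes).
* `d_i(g)` — an additive log2 group effect for proteins in the planted
  differential set (default: 5 proteins, +1.5 log2 in the tumor grades).
  With zero noise, group mean differences recover the planted effects
  exactly.
* `w_ji` — signed weights of the planted directed network, |w| in
  [0.4, 0.9]. Regulator values are **mean-centered before propagation**,
  so edges create co-variation without shifting group means: the network
  truth and the differential truth stay orthogonal. Propagation follows a
  topological order, so the simulated network must be a DAG; the edge
  sampler offers `acyclic=True` for this. (The unconstrained sampler also
  exists — up to n(n−1) distinct directed edges — because the planted map
  is an analysis target, not a mechanistic claim; `simulate_abundance_matrix`
  refuses cyclic inputs with an instructive error.)
* `e_is ~ Normal(0, 0.25)` log2 units of measurement noise by default.

Missingness is missing-not-at-random in the left-censored sense:
an entry is masked with probability `logistic((m − x_is) * k)` with
midpoint `m = 25` and steepness `k = 1` by default (≈10% missing on the
default scale, concentrated at low abundance). Lowering a value never
decreases its missing probability.

Unique-peptide counts are drawn so that ~19% of proteins are
single-peptide identifications (mirroring the usual attrition when
filtering at ≥2 unique peptides); planted proteins are forced to ≥2 so
the confidence filter cannot silently delete the ground truth.

Default cohort sizes are 10 MGI + 11 MGII tumors and 4 dura + 4 arachnoid
controls, the design of the motivating study.

Carrier FASTA records embed each target peptide exactly once, preceded by
K/R and not followed by P, so complete tryptic digestion releases it
intact; peptides with internal tryptic sites are rejected. Decoy records
contain no target peptide. The synthetic spectral library assigns
log-normal intensities to every y fragment (n ≥ 2, charges 1–2); it
emulates only the *shape* of a spectral-library table, not fragmentation
physics.

What passing tests on these cohorts show: that each algorithm recovers
known structure under additive Gaussian noise and logistic left-censoring
at realistic scales. What they do not show: robustness to batch effects,
non-Gaussian heavy tails, correlated missingness, shared-peptide protein
inference, or search-engine FDR behavior — none of which the generator
models.

## Statistics chain

Fixed, logged order: unique-peptide filter (≥2) → total-intensity
normalization → log2 → imputation → tests. The source description of the
normalization/imputation order parses both ways, so the driver also
supports imputing first (`normalize_before_impute=False`); the default is
normalize-first because normalization factors estimated on observed
totals are not distorted by imputed values.

* **Normalization** rescales every sample's observed total to the grand
  mean of totals; it conserves the grand total of observed intensity.
* **Imputation** draws each missing entry from
  `Normal(mean_s − 1.8·SD_s, 0.3·SD_s)` per sample — the down-shifted
  Gaussian that is the field-standard model for left-censored LFQ
  missingness. Shift and width are parameters; defaults 1.8 and 0.3.
* **ANOVA screen**: one-way fixed-effects F across all groups per
  protein; Benjamini–Hochberg q-values over the tested set (BH is applied
  within each contrast's tested set, never across contrasts). Zero
  within-group variance is reported as p = 1 with a `degenerate` flag
  rather than raising, so screens on synthetic edge cases complete.
* **Pairwise test**: Welch (unequal-variance) t; the unequal-variance
  default is the robust choice when no variance model is stated.
* **Volcano rule**: UP iff log2FC ≥ 1.2 and p < 0.05 (boundary fold
  change inclusive), DOWN symmetric. The 1.2 cutoff is read on the log2
  axis. Note that effects planted *exactly at* the cutoff are classified
  UP only ~50% of the time, since the estimated fold change is symmetric
  around the truth; sensitivity statements about the volcano rule are
  only meaningful for effects strictly beyond the cutoff.
* **Clustering/PCA**: Ward linkage on Euclidean distances over samples;
  PCA on centered data with components ordered by explained variance.
* **ΔΔCt**: `2^−[(Ct_t,trt − Ct_ref,trt) − (Ct_t,ctl − Ct_ref,ctl)]`, with
  the reference Ct taken as the housekeeping-panel mean.

## ANN interactome

Per target protein *t*, a three-layer perceptron (inputs → 2 sigmoid
hidden units → 1 sigmoid output) is trained to predict *t* from all other
proteins, on rows min-max scaled to [0, 1] (constant rows map to 0.5).
Training is per-sample (online) backpropagation on squared error with
learning rate 0.1, momentum 0.5, 300 epochs, order reshuffled each epoch,
weights initialized Uniform(−0.1, 0.1). "Parsimonious" is fixed at 2
hidden units by default and exposed as a parameter.

The directed interaction score is the summed connection weight from input
*i* to the output, `score(i) = Σ_h W1[i,h]·w2[h]`, **averaged** over 50
Monte-Carlo cross-validation splits (random 80% train subsets). Averaging
rather than summing keeps the score scale independent of the split count.
Scores are absolute summed weights, not deltas from initialization; on
data with no signal the split-averaged initialization noise leaves a
residue of order 1e-3, far below data-driven scores.

Each (target, split) pair derives its RNG from (seed, target index,
split), which makes the result bitwise reproducible and independent of
the order in which targets are evaluated.

Edges are then filtered on the Pearson correlation of the underlying
abundance pair at |r| ≥ 0.7 (boundary inclusive). The absolute value is
used so inhibitory (negative-weight) interactions survive. The filter is
applied to the data correlation, not to score reproducibility across
splits — of the two readings of the published procedure this is the one
that matches "removing the least significant interaction scores" by the
strength of the underlying association. Export is SIF plus a parallel
tab-separated attribute table, ordered by |score| descending with
lexicographic tie-breaks.

On the reference planted cohort (30 proteins, 40-edge DAG, 60 samples,
noise SD 0.25) the |score| ranking of all 870 ordered pairs recovers the
planted edges at AUROC ≈ 0.92; permuting the protein labels collapses
recovery to chance.

## Feature concordance

Each protein is scored alone: a 1-input perceptron (same trainer)
predicts the 0/1 group label, and the mean squared test error over MCCV
splits ranks proteins (ascending). Squared error of a regression-style
net is used instead of misclassification rate because it is smoother and
avoids mass ties at small test-set sizes. The ranking repeats over 20
randomized iterations (iteration seed = master seed + index); a protein's
concordance is the fraction of iterations in which it ranks in the top
k (default k = 10).

Within an iteration, split membership and weight initialization derive
from (iteration seed, split index) only — identical feature vectors
therefore receive identical errors and tie, and ties break
lexicographically by protein ID. An uninformative feature's error
approaches the Bernoulli variance of the class mix (0.25 when balanced).
With one planted feature always in the top k, the remaining n−1 null
features share exactly k−1 slots, so their mean concordance is
(k−1)/(n−1) by construction — slightly below k/n.

## SRM design

Monoisotopic masses from a 6-decimal residue table; water 18.0105647 Da,
proton 1.0072765 Da (hydrogen minus the electron — charging uses the
proton, matching monoisotopic mass settings). Fixed carbamidomethyl
(+57.021464 Da) on every cysteine; variable phospho (+79.966331 Da)
restricted to S/T/Y. All masses agree with an independent
atomic-composition calculation to ≤ 1e-4 Da.

Tryptic digestion cleaves C-terminal to K/R with Keil proline suppression
(no cleavage before P); the suppression is toggleable. With m missed
cleavages, all concatenations of up to m+1 adjacent fragments are
emitted, zero-miss fragments first, each tier in positional order.

Transitions: precursors at charge 2; candidate fragments y_n for
n = 2 … length−1 at charges 1 and 2 (y1 is excluded by default as a
low-specificity fragment); the top 3 by spectral-library intensity are
kept per precursor, ties preferring longer fragments then lower charge —
3 transitions per precursor is the community norm for SRM assays. Target
peptides must be proteotypic: found in the digest of exactly one supplied
protein, else the builder raises.

The curated marker panel covers five meningioma-associated proteins (VIM,
ANXA2, CKAP4, CLIC1, EIF4G1) with three proteotypic peptides each.

## Numerical and engineering notes

* The backprop inner loop is JIT-compiled with numba in plain float64;
  results are bitwise identical across runs and evaluation orders. All
  randomness flows through `numpy.random.Generator` seeded via
  `SeedSequence` mixing, with documented draw orders.
* Degenerate inputs are handled explicitly: constant rows scale to 0.5;
  zero-variance tests report p = 1 with a flag; samples with fewer than
  two observed values refuse imputation by name; empty edge lists export
  as empty files.
* Validation problem sizes (30-protein networks, 50-protein concordance
  cohorts, 2000-protein null screens) were chosen so each recovery
  statistic has small Monte-Carlo error while a full validation pass
  remains a desk-scale computation.

## Known limitations

* The MLP mirrors the published architecture class but cannot be
  bit-compared to the original compiled implementation; hidden-unit
  count, split count and train fraction are stated defaults, not
  published values.
* The generator's missingness and noise models are stand-ins; see above
  for what passing tests do and do not establish.
* Multi-class concordance contrasts, retention-time prediction,
  collision-energy optimization and protein inference from shared
  peptides are out of scope.
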