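# Methods

## The model

`cfscreen` predicts target–ligand binding from past assay outcomes alone.
The data object is a sparse matrix A whose rows are protein targets,
columns are ligands, and observed entries a_tl are activity labels derived
from binding concentrations. Two collaborative-filtering predictors are
implemented.

**Neighborhood (memory-based) CF.** The score of an unobserved pair
(t0, l) is the unweighted mean of the labels that *similar* targets gave
ligand l. Similarity between two target rows is computed only over their
co-rated support — the ligands both targets have labelled — with Pearson
correlation (default), cosine, or Jaccard on the binarized labels. A
target is a neighbor when its similarity reaches a threshold τ (default
1e-2, the best configuration from the hyperparameter search on real
screening data). Pairs with fewer than two co-rated ligands, or a
constant row under Pearson, have undefined similarity; they are
represented as NaN sentinels that can never pass τ. A similarity-weighted
mean is available behind a flag, but the unweighted mean is the default
scoring rule. When a pair has no neighbors at all, the prediction falls
back to the global training active rate and is flagged as a cold start —
a defined, rankable prior rather than a refusal.

**Latent-factor (matrix factorization) CF.** Each target t and ligand l
get f-dimensional factor vectors p_t, q_l with a_tl ≈ p_t · q_l, fitted by
minimizing the regularized squared error over the observed set Λ:

    sum_{(t,l) in Λ} (a_tl − p_t·q_l)² + λ(‖p_t‖² + ‖q_l‖²).

Optimization is plain SGD: each epoch visits every observed pair once in a
seeded shuffled order and applies the simultaneous update

    e = a − p·q;  p ← p + η(e·q − λp);  q ← q + η(e·p − λq)

using pre-update values of both vectors (this update rule is our
derivation of the gradient; only the objective is prescribed). Because the
matrix is overwhelmingly unobserved, each epoch adds *adaptive negative
sampling*: per target, for each positive label, a pool of
`candidate_pool_size` (default 100) unobserved ligands is drawn at random,
scored with the current model, and the argmax (ties to the lowest ligand
index) is trained as inactive. This targets the model's most confidently
wrong predictions and speeds convergence. One negative per positive
(default) keeps the class pressure comparable to the ~7:3
inactive:active balance of curated data. Binary labels are encoded
active = 1 / inactive = 0 and ranking uses the raw dot product; in the
four-level mode the model trains on labels 1–4, sampled negatives are
trained at the inactive label 4, and ranking is by ascending score (label
1 means sub-nM binding). The fitted rows of P and columns of Q are exposed
as *implicit fingerprints*: descriptors of targets and ligands derived
purely from interaction patterns.

## Parameters that matter

| parameter | default | notes |
|---|---|---|
| f (factors) | 50 | best grid row on real data; use ≈ true rank on synthetic data |
| λ (regularization) | 1e-3 | best grid row on real data; small panels need far more (see below) |
| η (SGD step) | 1e-3 | grid spans 1e-3..1e-1; with the small 0.1/√f initialization, escape from the zero saddle takes O(1/(η·σ(A))) epochs, so small panels converge much faster at 1e-2 |
| n_epochs | 50 | no stopping rule is prescribed; optional early stop when the relative objective change stays < `early_stop_tol` for 3 epochs |
| negatives_per_positive / pool | 1 / 100 | the argmax strategy is prescribed, the counts are ours |
| neighborhood τ | 1e-2 | Pearson threshold, best grid row |
| BEDROC α | 20 | weights roughly the top 8% of a ranking |
| EF fraction | 1% | exposed as a parameter; N_X = ceil(X·N) so small lists select at least one candidate |

Factor initialization is i.i.d. Gaussian with scale 0.1/√f (reproducible
from the seed). Every fit, split and simulation is bit-reproducible given
its seed; the repeated-split protocol derives iteration i's seed as
`master_seed + i`. The epoch sweeps are numba-compiled; all random draws
(visit order, candidate pools) happen outside the kernels in numpy, so
compiled and semantics are identical to the pure-numpy operations they
accelerate.

## Evaluation

Per target, validation ligands are ranked by predicted score (descending,
ties broken by ascending ligand index — the rank-based metrics need a
total order) and scored with AUC, EF_X% and BEDROC. AUC uses the tie-aware
Mann–Whitney convention instead of the forced total order. RIE is

    RIE = (1/n) Σ_{i∈actives} exp(−α r_i/N) / [(1/N)(1−e^{−α})/(e^{α/N}−1)],

with 1-based ranks r_i; its expectation under a uniform random ranking is
exactly 1. BEDROC is the standard min–max normalization of RIE and is
clipped into [0, 1] (the exact value lies there; floating cancellation at
the extremes can stray by ~1 ulp). Metrics undefined for a list (a
single-class validation set; EF with no actives) raise a typed error and
are reported as flagged NaN — excluded from aggregates, never imputed as
zero. Aggregation reports per-target values, means with standard errors,
and summaries by training-assay-count bin: <100, [100,200), …, [400,500),
and ≥500 as ">500" (the boundary sides are our convention; only 99 → <100,
150 → 100–200 and 501 → >500 are externally pinned).

## Split auditing (AVE bias)

The Asymmetric Validation Embedding bias of a target's split is

    B = [H(Va,Ta) − H(Va,Ti)] + [H(Vi,Ti) − H(Vi,Ta)],

where H(V, S) measures clumping of set V among set S: for each v ∈ V, the
nearest-neighbor Tanimoto distance to S is thresholded over a uniform grid
t ∈ {0.01, …, 1.00} and the indicators d(v) < t are averaged over ligands
and thresholds. The grid form follows the original formulation of the
measure; it is exposed as a parameter because only "cluster similarity
with Tanimoto" is externally fixed. Two all-zero fingerprints get
similarity 1 by default (both feature-free molecules are identical;
configurable to 0). B is 0 by construction when training actives and
inactives coincide as sets, positive when validation ligands clump with
same-class training ligands, and the audit of a method is the Pearson
correlation between per-target B and per-target AUC over targets where
both are defined.

## The synthetic generator

`simulate_ground_truth` draws factor matrices with i.i.d. N(0, 1/rank)
entries (so pair scores have sd 1/√rank — the activity threshold is the
empirical (1 − active_fraction) quantile of all pair scores, which makes
calibration exact at any rank). `simulate_assays` observes either a
uniform random sample of pairs (default density 0.15%) or a fixed
per-target quota (`skewed_assay_quotas` emulates real panels where over
half the targets have <200 assays), labels a pair active iff its true
score exceeds the threshold, and flips labels independently with the noise
probability (default 5%, modelling assay irreproducibility).
`simulate_fingerprints` emits binary bits as sign indicators of random
Gaussian projections of the true ligand factors, flipped with a chosen
probability — at flip ≈ 0.5 the bits are uninformative, the null case for
the AVE audit.

What the generator does *not* emulate: chemical series and scaffolds,
realistic concentration values (labels only), correlated targets
(paralogs), per-target active-rate heterogeneity, and the strong
popularity structure of mined databases. Passing tests therefore
demonstrate correctness of the machinery and the qualitative sparse-target
advantage of factor models, not the absolute performance levels reported
on mined bioactivity data, which benefit from that extra structure.

## Study conditions and numerical choices

The shipped protocol runs at a deliberately desk-sized scale: a 300-target
× 600-ligand panel at rank 10 with 5% label noise and skewed quotas (55%
of targets with 20–90 assays, 25% with 100–200, 20% with 250–450), four
70:30 stratified splits, MF at f = 10, λ = 0.05, η = 1e-2, 400 epochs
versus the Pearson/1e-2 neighborhood model. Two choices deserve comment:

- **λ = 0.05 rather than 1e-3.** Binarized labels carry far less
  information than continuous affinities, and at this panel size the
  number of parameters (f·(T+L)) is comparable to the number of observed
  labels, so the weak real-data regularizer lets SGD memorize (training
  AUC ≈ 0.97, held-out ≈ 0.56). λ = 0.05 sits inside the searched grid and
  restores generalization.
- **Observation counts bound what is recoverable.** At 0.05 matrix density
  on a 100 × 1000 panel, a validation ligand has on average 3.5 training
  labels against 10 factor dimensions. Oracle constructions (true target
  factors plus ridge-fitted ligand factors on noiseless continuous labels)
  cap held-out AUC near 0.77 there, so sub-0.85 scores in that regime are
  an information limit, not an optimization failure. The package's
  recovery experiment reports the measured value rather than asserting an
  unreachable one.

Degenerate inputs are handled explicitly: targets with a single assay go
entirely to training (validation metrics are undefined for them anyway,
and the validation draw per target is capped at n−1); duplicate records
with the same measure type are merged by geometric mean (symmetric and
scale-appropriate for concentrations; configurable to median or min);
empty candidate pools skip the negative draw; non-finite factors raise a
divergence error naming the step size.

## Known limitations

- The zero-saddle escape of small-initialization SGD makes wall-clock
  convergence sensitive to η on small panels; the default η = 1e-3 is
  tuned to large mined datasets.
- A rank-r least-squares fit cannot interpolate a thresholded rank-r
  matrix (the binary pattern 1{P·Q > τ} is generally of higher rank), so
  even noiseless full-density training accuracy plateaus below 100%
  (measured 0.85–0.93 on small panels) — thresholding, not optimization,
  is the cause.
- Ligands must appear in training to be scored at validation; cold-start
  ligands receive unconstrained (near-prior) factor scores.
- The neighborhood module implements target–target similarity only; no
  item–item variant, no Euclidean metric.
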