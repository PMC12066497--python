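# Methods

## Problem

Given a heterogeneous biological network over drugs, proteins and
diseases — several relation-specific subgraphs ("views") such as
drug–drug chemical similarity, protein–protein sequence similarity,
drug–disease and protein–disease associations, and the known
drug–protein interactions — predict which unobserved drug–protein pairs
interact. The emphasis is on (a) fusing topology-aware information from
many views and (b) using prior attributes (molecular fingerprints,
protein sequences) so that *cold-start* entities — drugs or proteins
with no interaction in the training fold — can still be placed.

## Model

One forward pass, in order:

1. **Initial node features.** Every node owns a learned free embedding
   in the working dimension d. Drugs add a learned linear projection of
   their fingerprint bit-vector; proteins add a projection of their
   k-mer composition; diseases (context nodes, never scored) keep only
   the free embedding. Attribute matrices are column-standardized
   before projection: k-mer frequencies are O(1/L) while fingerprint
   bits are O(1), and without standardization the protein attribute
   signal is numerically buried.
2. **Per-view graph attention.** For each view, a stack of layers
   (default 2) computes a_ij = softmax_{j in N(i)} (Q_i · K_j) and
   h_i' = ReLU( sum_j a_ij W h_j ), with view-specific W, Q, K
   parameters (relations have different semantics) and the node always
   included in its own neighborhood, so isolated nodes reduce to
   ReLU(W h_i) and the softmax is always defined. The dot-product
   attention is unscaled by default; a 1/sqrt(d) scaling flag exists.
   Multiple heads split the output dimension. The *uniform* variant
   (the no-attention ablation, a plain GCN step) fixes a_ij = 1/|N(i)|;
   forcing the Q/K maps to zero reproduces it bit for bit.
3. **View fusion.** z = sum_v alpha_v h_v with alpha = softmax over one
   free logit per view — a strictly convex combination at all times.
4. **Pair scoring.** score(d, p) = sigmoid( MLP([z_d ; z_p ; f_prior]) )
   where f_prior = [f_chem(d) ; f_seq(p)] is the pair-level attribute
   prior. The MLP (1–4 layers, default 2) applies its first layer
   block-wise over the four input segments, which is algebraically the
   same as concatenation but lets per-entity attribute projections be
   computed once per pass. The final sigmoid keeps scores strictly in
   (0, 1). Both attribute uses (node features and pair prior) are
   switched off together by the attribute ablation; shapes never change
   (the prior is effectively zeroed).

Training minimizes binary cross-entropy with Adam (default learning
rate 1e-3; the reference experiments use 3e-3), full-batch by default,
early-stopping on validation ROC-AUC and restoring the best-validation
parameters. Gradients come from a small reverse-mode autodiff engine
(`dtigat.autodiff`) written for exactly the dense operations this model
needs; the end-to-end gradient was verified against central finite
differences.

## Evaluation protocol

Known positives are shuffled once (seeded) and split into 2k
half-blocks; fold f tests on half-block 2f, validates on 2f+1 and
trains on the rest — 80/10/10 at k=5, with held-out blocks disjoint
across folds and test+validation together covering each positive
exactly once. (Test blocks alone cannot cover all positives at 10%
each and five folds; the rotation above is the consistent reading of
an 80/10/10 five-fold protocol.)

Negatives are drawn per fold, uniformly without replacement from the
complement of the *entire* positive set — a sampled "negative" is never
a held-out positive — at ratio 1:1 per split, disjoint across splits.
The known-interaction view of each fold's graph contains only that
fold's training positives; this is hard-asserted before training
(leakage guard). A test pair is cold-start iff its drug or protein has
zero training positives in that fold.

Threshold metrics (accuracy, sensitivity, specificity, precision, MCC)
use the threshold maximizing Youden's J on the validation split; a
zero-denominator metric reports 0 with a flag instead of raising, so
tiny cold-start subsets never crash a report. ROC-AUC is the
Mann–Whitney rank statistic with mid-rank ties; AUPR integrates the
step-wise precision–recall curve without linear interpolation. Both are
property-tested against brute-force oracles.

## Synthetic worlds

The generator plants a latent-factor ground truth: every entity gets a
latent vector with per-coordinate scale latent_scale · latent_dim^-1/4,
so latent dot products u·v have standard deviation latent_scale² —
3.24 at the default 1.8. A drug–protein pair is positive with
probability logistic(u·v + interaction_bias); at the default bias −5.5
this gives ≈6% density and a Bayes-optimal ranking AUC ≈0.96 for the
true probabilities, i.e. a "strong-signal" world is one in which a
perfect method could reach the operating range reported for real
drug–target corpora. The scale was calibrated against that closed-form
oracle, not against the model.

Similarity views are latent cosines plus Gaussian noise
(view_noise_sd), sparsified by mutual k-nearest-neighbour (default
k=10); association views are Bernoulli draws from latent affinity; the
interaction view carries training positives only. Fifteen views by
default: 4 drug–drug, 4 protein–protein, 3 drug–disease, 3
protein–disease, 1 drug–protein — the view count is what matters, the
partition is a documented stand-in. Attributes are coupled to the
latents by `attribute_informativeness` in [0, 1]: fingerprints
threshold a mix of a standardized latent projection (weight a) and
independent noise (weight 1−a); sequences are drawn from residue
distributions softmax(a · loadings · v). At a=0 attributes are pure
noise; at a=1 fingerprints are a deterministic function of the latents.
All randomness flows from one seed through named SeedSequence children
(entities, fingerprints, sequences, interactions, one per view), so
identical configs give byte-identical fixtures.

What the generator does **not** emulate: real chemistry (no SMILES, no
substructure logic), sequence homology beyond composition bias,
disease ontologies, and the heavy-tailed degree distributions of
curated interaction databases. Passing tests therefore demonstrate that
the implementation recovers planted multi-view latent structure under
controlled noise — not performance on real corpora.

## Reference experiments (`dtigat.protocols`)

Model for all protocols: embedding 32, 2 layers, 2 heads, unscaled
attention, 2-layer MLP with 192 hidden units, Adam 3e-3 — the package's
desk-scale configuration (library defaults are 64/64; the paper-scale
732-dimensional embedding remains available via config).

* **Signal recovery** — the default 200×200×40 world, full 5-fold CV
  per seed. Mean held-out AUC ≈0.87 across seeds (Bayes ceiling ≈0.96).
* **Null calibration** — 150×150 world with orthogonal drug/protein
  latents (u·v = 0 exactly, so every pair shares one true probability)
  and uninformative attributes; mean AUC sits at chance (≈0.5), showing
  the pipeline manufactures no signal.
* **Cold-start contrast** — sparse interactions (bias −8.0, median drug
  degree 1–3, so cold-start pairs arise naturally) and noisy similarity
  views (view_noise_sd = 1.0). The noise matters: with near-noiseless
  cosine views the graph itself carries the latent information and
  removing attributes costs cold pairs nothing. Full vs no-attributes
  is compared on the cold-start subset pooled over three folds.
* **Noise-view contrast** — a 5-view world whose only drug–drug view is
  pure noise, trained to convergence (patience 60): attention needs a
  longer horizon than the standard early-stopping to learn to ignore
  noise edges. Attention ≥ uniform aggregation in the majority of
  seeds. A mechanistic finding worth recording: in the *attention*
  model, fusion does **not** down-weight the noise view — attention
  learns to self-attend inside it, turning it into a clean self-echo
  channel. Fusion down-weighting of the noise view appears robustly in
  the uniform variant, where fusion is the only defense; the fusion
  property is therefore tested there.

`scripts/acceptance.py` reruns these protocols from scratch (seeds
derived from `--seed`) and writes the measured quantities as JSON.

## Numerical choices and limitations

* float32 model arithmetic by default (float64 available; the
  permutation-equivariance test runs in float64 with atol 1e-9, since
  reordering float reductions is not bitwise-neutral).
* Sequence similarity is normalized local alignment
  score(a,b)/sqrt(score(a,a)·score(b,b)) with BLOSUM62, gap open −11 /
  extend −1 — a self-contained stand-in for database-scale alignment
  scores, pluggable for precomputed similarity tables.
* Tanimoto of two all-zero fingerprints is defined as 0.
* Mutual top-k keeps edge (i,j) if either endpoint ranks the other in
  its top k; zero-weight edges are dropped by default.
* Negative sampling enumerates the full complement (exact uniform
  sampling without replacement); fine at desk scale, would need a
  rejection sampler for very large grids.
* Cold-start subsets are small by nature; their AUCs are reported
  pooled across folds and remain noisy at desk scale.
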