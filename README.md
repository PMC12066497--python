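# dtigat

Drug–target interaction (DTI) prediction with a multi-view
heterogeneous graph attention network, plus a synthetic-world generator
that makes the whole pipeline testable without any database downloads.

Intended for computational drug-discovery work: you have (or can
simulate) a heterogeneous network over drugs, proteins and diseases —
drug–drug chemical similarity, protein–protein sequence similarity,
drug/protein–disease associations, known drug–protein interactions —
plus per-entity attributes (fingerprint bit-vectors, protein
sequences), and you want calibrated scores for unobserved drug–protein
pairs, including *cold-start* pairs whose drug or protein has no known
interaction.

## Model

The heterogeneous graph G = (V, E) is kept as an ordered list of
relation views over a shared entity set. For each view, graph-attention
message passing

&nbsp;&nbsp;a_ij = softmax_{j ∈ N(i)} (Q_i · K_j),&nbsp;&nbsp;
h_i^{(l+1)} = ReLU( Σ_{j ∈ N(i)} a_ij W^{(l)} h_j^{(l)} )

produces one topology-aware embedding per view (a node is always in its
own neighborhood; the uniform a_ij = 1/|N(i)| variant is the GCN
ablation). Per-view embeddings are fused by a learned convex
combination

&nbsp;&nbsp;z = Σ_v α_v h_v,&nbsp;&nbsp;α = softmax(w),

and a pair is scored by an MLP on the concatenation of the two fused
embeddings and the attribute prior f_prior = [f_chem ; f_seq]
(fingerprint bits; k-mer composition):

&nbsp;&nbsp;ŷ_dp = σ( MLP([z_d ⊕ z_p ⊕ f_prior]) ).

Training is binary cross-entropy with Adam against 1:1 sampled
negatives, under a rotating 80/10/10 five-fold protocol with early
stopping on validation AUC, per-fold negative resampling, a hard
leakage guard (the interaction view of a fold's graph contains only
that fold's training positives) and cold-start flagging of test pairs.
The model and its gradients are implemented on a small reverse-mode
autodiff engine in `dtigat.autodiff`; see `docs/methods.md` for the
full model and protocol description.

## Worked example

Simulate a 120×120×24 drug–protein–disease world (15 views), run
5-fold cross-validation, and score a pair (about two minutes on one
CPU):

```
$ cat config.yaml
synthetic: {n_drugs: 120, n_proteins: 120, n_diseases: 24, seed: 7}
model:     {embed_dim: 32, mlp_hidden: 192, n_heads: 2}
train:     {lr: 0.003, max_epochs: 200, patience: 15, seed: 7}

$ dtigat simulate --config config.yaml --out fixtures
wrote 19 fixture files to fixtures

$ dtigat train --config config.yaml --data fixtures --out run --folds 5
Fold    Acc     Sen     Spec    Pre     MCC     AUC     AUPR
1       0.7800  0.8400  0.7200  0.7500  0.5641  0.8247  0.7771
2       0.7350  0.8000  0.6700  0.7080  0.4740  0.8103  0.8065
3       0.7550  0.7300  0.7800  0.7684  0.5106  0.8262  0.8183
4       0.7700  0.7300  0.8100  0.7935  0.5417  0.8460  0.8234
5       0.7525  0.7980  0.7071  0.7315  0.5072  0.8300  0.8075
Average 0.7585 ± 0.0173  0.7796 ± 0.0483  0.7374 ± 0.0567  0.7503 ± 0.0329  0.5195 ± 0.0346  0.8274 ± 0.0128  0.8066 ± 0.0180
# cold-start subset (pooled over folds): n=18, n_pos=5, AUC=0.7231, AUPR=0.6788
```

Per-fold rows list accuracy, sensitivity, specificity, precision,
Matthews correlation (threshold chosen on the validation split by
Youden's J), ROC-AUC and PR-AUC on that fold's held-out pairs; the
average row is mean ± SD across folds, and the cold-start line gives
the same ranking metrics on the pooled test pairs whose drug or protein
had no training interaction. Scoring a specific pair with a saved fold
model:

```
$ dtigat predict --model run/model_fold0.npz --data fixtures --pairs pairs.tsv
drug_id  protein_id  score
DR0003   PR0017      0.16119366881824382
```

The score is the model's interaction probability in (0, 1). Other
commands: `dtigat ablate` (full vs no-attention vs no-attributes under
identical folds), `dtigat sweep` (MLP depth / embedding-size grids),
`dtigat evaluate` (re-print a run's report). Every output directory
archives the exact resolved config and seed that produced it.

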