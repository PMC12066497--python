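"""Synthetic multi-relational drug-gene-disease network generator.

Every downstream stage (graph assembly, attention model, cross-validated
evaluation) is exercised on worlds produced here, so the generator plants
a known latent-factor interaction structure that the model can be tested
against:

* each drug, protein and disease gets a latent vector; a drug-protein
  pair is a true interaction with probability logistic(u_d . v_p + bias);
* similarity views are noisy cosines of the latents, sparsified by
  mutual-kNN; association views are Bernoulli draws from latent affinity;
* node attributes (fingerprint bits, residue sequences) are coupled to
  the latents with a dial ``attribute_informativeness`` in [0, 1], so the
  cold-start benefit of attributes is testable: at 0 attributes carry no
  signal, at 1 fingerprints are a deterministic function of the latents.

Per-coordinate latent scale is latent_dim**-0.25, so latent dot products
have unit variance regardless of latent_dim. All randomness flows from a
single seed through named SeedSequence children (entities, fingerprints,
sequences, interactions, then one per view), so each fixture is
individually reproducible and identical configs give byte-identical
outputs.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .graphs import (
    AMINO_ACIDS,
    ConfigurationError,
    EntitySet,
    ViewGraph,
    mutual_topk_edges,
)

RELATION_KINDS = ("drug-drug", "protein-protein", "drug-disease", "protein-disease")


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic world.

    Defaults are the desk-scale reference conditions: 200 drugs x 200
    proteins, latent dimension 8, similarity noise 0.1, attribute
    informativeness 0.8, and 15 views mirroring the heterogeneous
    drug-gene-disease network count the model is designed for.
    """

    n_drugs: int = 200
    n_proteins: int = 200
    n_diseases: int = 40
    latent_dim: int = 8
    n_views: int = 15
    latent_scale: float = 1.8
    interaction_bias: float = -5.5
    view_noise_sd: float = 0.1
    attribute_informativeness: float = 0.8
    fingerprint_bits: int = 256
    sequence_length: int = 200
    seed: int = 0
    # degenerate / ablation dials
    orthogonal_latents: bool = False
    noise_views: int = 0
    knn_k: int = 10
    association_bias: float = -2.0

    def __post_init__(self) -> None:
        for name in ("n_drugs", "n_proteins", "n_diseases", "latent_dim", "n_views",
                     "fingerprint_bits", "sequence_length", "knn_k"):
            if getattr(self, name) < 1 and not (name == "n_diseases" and self.n_diseases == 0):
                raise ConfigurationError(f"{name} must be >= 1, got {getattr(self, name)}")
        if self.view_noise_sd < 0:
            raise ConfigurationError("view_noise_sd must be >= 0")
        if self.latent_scale <= 0:
            raise ConfigurationError("latent_scale must be > 0")
        if not 0.0 <= self.attribute_informativeness <= 1.0:
            raise ConfigurationError("attribute_informativeness must be in [0, 1]")
        if self.orthogonal_latents and self.latent_dim < 2:
            raise ConfigurationError("orthogonal_latents requires latent_dim >= 2")
        if self.noise_views < 0:
            raise ConfigurationError("noise_views must be >= 0")


@dataclass
class SyntheticWorld:
    """Latent ground truth plus the emitted attribute payloads."""

    config: SyntheticConfig
    drug_ids: list[str]
    protein_ids: list[str]
    disease_ids: list[str]
    drug_latents: np.ndarray
    protein_latents: np.ndarray
    disease_latents: np.ndarray
    fingerprints: np.ndarray  # (n_drugs, fingerprint_bits) uint8
    sequences: list[str]
    true_prob: np.ndarray | None = None  # (n_drugs, n_proteins)
    positives: np.ndarray | None = None  # (m, 2) local (drug, protein) indices

    @property
    def all_ids(self) -> list[str]:
        return self.drug_ids + self.protein_ids + self.disease_ids

    @property
    def kinds(self) -> list[str]:
        return (
            ["drug"] * len(self.drug_ids)
            + ["protein"] * len(self.protein_ids)
            + ["disease"] * len(self.disease_ids)
        )

    def entity_set(self) -> EntitySet:
        es = EntitySet(ids=list(self.all_ids), kinds=list(self.kinds))
        for i, d in enumerate(self.drug_ids):
            es.fingerprints[d] = self.fingerprints[i]
        for i, p in enumerate(self.protein_ids):
            es.sequences[p] = self.sequences[i]
        return es


def _child_rngs(seed: int, n_views: int) -> list[np.random.Generator]:
    """Fixed seed-splitting scheme: entities, fingerprints, sequences,
    interactions, then one child per view."""
    children = np.random.SeedSequence(seed).spawn(4 + n_views)
    return [np.random.Generator(np.random.PCG64(c)) for c in children]


def _latents(rng: np.random.Generator, n: int, cfg: SyntheticConfig, kind: str) -> np.ndarray:
    # per-coordinate scale so SD(u . v) = latent_scale**2 regardless of latent_dim
    scale = cfg.latent_scale * cfg.latent_dim ** -0.25
    x = rng.normal(0.0, scale, size=(n, cfg.latent_dim))
    if cfg.orthogonal_latents:
        half = cfg.latent_dim // 2
        if kind == "drug":
            x[:, half:] = 0.0
        elif kind == "protein":
            x[:, :half] = 0.0
    return x


def generate_entities(config: SyntheticConfig) -> SyntheticWorld:
    """Latent vectors plus latent-coupled attributes for every entity.

    Fingerprints threshold a fixed random projection of
    a * latent_signal + (1 - a) * independent noise, a =
    attribute_informativeness; sequences are sampled from latent-biased
    residue frequencies (softmax over per-residue loadings).
    """
    cfg = config
    rng_ent, rng_fp, rng_seq, *_ = _child_rngs(cfg.seed, cfg.n_views)

    U = _latents(rng_ent, cfg.n_drugs, cfg, "drug")
    V = _latents(rng_ent, cfg.n_proteins, cfg, "protein")
    W = _latents(rng_ent, cfg.n_diseases, cfg, "disease")

    a = cfg.attribute_informativeness
    # fingerprints: latent signal standardized to unit variance, mixed with
    # unit noise, so the informativeness dial has a scale-free meaning
    proj = rng_fp.normal(size=(cfg.latent_dim, cfg.fingerprint_bits))
    signal = (U @ proj) / (cfg.latent_scale * cfg.latent_dim**0.25)
    noise = rng_fp.normal(size=signal.shape)
    fingerprints = ((a * signal + (1.0 - a) * noise) > 0).astype(np.uint8)

    # sequences: residue distribution softmax(a * loadings @ latent), with
    # the same standardization of the latent contribution
    loadings = rng_seq.normal(size=(len(AMINO_ACIDS), cfg.latent_dim))
    logits = a * (V @ loadings.T) / cfg.latent_scale
    logits -= logits.max(axis=1, keepdims=True)
    probs = np.exp(logits)
    probs /= probs.sum(axis=1, keepdims=True)
    residues = np.array(list(AMINO_ACIDS))
    sequences = []
    for i in range(cfg.n_proteins):
        draw = rng_seq.choice(len(residues), size=cfg.sequence_length, p=probs[i])
        sequences.append("".join(residues[draw]))

    return SyntheticWorld(
        config=cfg,
        drug_ids=[f"DR{i:04d}" for i in range(cfg.n_drugs)],
        protein_ids=[f"PR{i:04d}" for i in range(cfg.n_proteins)],
        disease_ids=[f"DZ{i:04d}" for i in range(cfg.n_diseases)],
        drug_latents=U,
        protein_latents=V,
        disease_latents=W,
        fingerprints=fingerprints,
        sequences=sequences,
    )


def generate_interactions(world: SyntheticWorld, config: SyntheticConfig | None = None) -> np.ndarray:
    """Sample the positive drug-protein pair set from the planted model.

    P(interaction) = logistic(u_d . v_p + interaction_bias); the true
    probabilities are recorded on the world (clipped into the open unit
    interval at float precision).
    """
    cfg = config or world.config
    rng = _child_rngs(cfg.seed, cfg.n_views)[3]
    logits = world.drug_latents @ world.protein_latents.T + cfg.interaction_bias
    prob = 1.0 / (1.0 + np.exp(-logits))
    eps = 1e-12
    world.true_prob = np.clip(prob, eps, 1.0 - eps)
    hit = rng.random(prob.shape) < world.true_prob
    d_idx, p_idx = np.nonzero(hit)
    world.positives = np.column_stack([d_idx, p_idx]).astype(int)
    return world.positives


def partition_views(n_views: int, has_diseases: bool) -> list[str]:
    """Relation kind for each of the n_views views, in recorded order.

    One drug-protein interaction view, the remainder distributed
    round-robin over drug-drug, protein-protein (and the two disease
    association kinds when diseases exist); default 15 views give
    4 drug-drug, 4 protein-protein, 3 drug-disease, 3 protein-disease
    and 1 drug-protein.
    """
    kinds = list(RELATION_KINDS) if has_diseases else ["drug-drug", "protein-protein"]
    if n_views < len(kinds) + 1:
        raise ConfigurationError(
            f"n_views={n_views} < {len(kinds) + 1} relation kinds requested"
        )
    counts = {k: 0 for k in kinds}
    for i in range(n_views - 1):
        counts[kinds[i % len(kinds)]] += 1
    order: list[str] = []
    for k in kinds:
        order.extend([k] * counts[k])
    order.append("drug-protein")
    return order


def _cosine(x: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(x, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return (x / norms) @ (x / norms).T


def generate_views(
    world: SyntheticWorld,
    config: SyntheticConfig | None = None,
    train_pairs: np.ndarray | None = None,
) -> list[ViewGraph]:
    """Emit the n_views relation views over the world's entity indexing.

    Similarity weights are latent cosines plus Gaussian(0, view_noise_sd)
    noise, sparsified by mutual top-k; association views are Bernoulli
    draws from latent affinity; the drug-protein view holds the known
    interactions — pass ``train_pairs`` so it is built only from training
    positives, never held-out edges. The first ``noise_views`` drug-drug
    views are pure noise (the attention-robustness condition).
    """
    cfg = config or world.config
    rngs = _child_rngs(cfg.seed, cfg.n_views)[4:]
    n_d, n_p = len(world.drug_ids), len(world.protein_ids)
    off_p = n_d
    off_z = n_d + n_p
    kinds = partition_views(cfg.n_views, len(world.disease_ids) > 0)

    base = {
        "drug-drug": _cosine(world.drug_latents),
        "protein-protein": _cosine(world.protein_latents),
    }
    counters = {k: 0 for k in RELATION_KINDS}
    views: list[ViewGraph] = []
    for v, kind in enumerate(kinds):
        rng = rngs[v]
        i = counters.get(kind, 0)
        counters[kind] = i + 1
        name = f"{kind.replace('-', '_')}_{i}"
        if kind in ("drug-drug", "protein-protein"):
            n = n_d if kind == "drug-drug" else n_p
            off = 0 if kind == "drug-drug" else off_p
            if kind == "drug-drug" and i < cfg.noise_views:
                sim = rng.normal(size=(n, n))
                sim = (sim + sim.T) / 2.0
                name = f"drug_drug_noise_{i}"
            else:
                noise = rng.normal(0.0, cfg.view_noise_sd, size=(n, n)) if cfg.view_noise_sd else 0.0
                sim = base[kind] + noise
            k = min(cfg.knn_k, n - 1)
            src, dst, w = mutual_topk_edges(sim, k)
            views.append(ViewGraph(name=name, relation=f"{kind}-similarity",
                                   src=src + off, dst=dst + off, weight=w))
        elif kind in ("drug-disease", "protein-disease"):
            ent_lat = world.drug_latents if kind == "drug-disease" else world.protein_latents
            off = 0 if kind == "drug-disease" else off_p
            logits = ent_lat @ world.disease_latents.T + cfg.association_bias
            prob = 1.0 / (1.0 + np.exp(-logits))
            hit = rng.random(prob.shape) < prob
            s, z = np.nonzero(hit)
            views.append(ViewGraph(name=name, relation=f"{kind}-association",
                                   src=s + off, dst=z + off_z,
                                   weight=np.ones(len(s))).symmetrized())
        else:  # drug-protein interaction view
            pairs = train_pairs if train_pairs is not None else world.positives
            if pairs is None:
                raise ConfigurationError("interactions not generated yet")
            pairs = np.asarray(pairs, dtype=int).reshape(-1, 2)
            views.append(ViewGraph(name="drug_protein_interactions",
                                   relation="drug-protein-interaction",
                                   src=pairs[:, 0], dst=pairs[:, 1] + off_p,
                                   weight=np.ones(len(pairs))).symmetrized())
    return views


def generate_world(config: SyntheticConfig) -> SyntheticWorld:
    """Entities + planted interactions in one call."""
    world = generate_entities(config)
    generate_interactions(world, config)
    return world


# ---------------------------------------------------------------------------
# Fixture output
# ---------------------------------------------------------------------------


def write_fixtures(
    world: SyntheticWorld,
    views: list[ViewGraph],
    outdir: str | Path,
) -> dict[str, str]:
    """Write the standard fixture files; returns {filename: sha256}.

    TSV with header row, UTF-8, LF line endings; FASTA wrapped at 60
    columns. All files reference entities by string id.
    """
    from .graphs import write_view_tsv

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    entities = world.entity_set()

    with open(out / "entities.tsv", "w", encoding="utf-8", newline="\n") as fh:
        fh.write("id\ttype\tname\n")
        for eid, kind in zip(entities.ids, entities.kinds):
            fh.write(f"{eid}\t{kind}\tsynthetic {kind} {eid}\n")

    with open(out / "proteins.fasta", "w", encoding="utf-8", newline="\n") as fh:
        for pid, seq in zip(world.protein_ids, world.sequences):
            fh.write(f">{pid}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")

    with open(out / "fingerprints.tsv", "w", encoding="utf-8", newline="\n") as fh:
        fh.write("id\tbitstring\n")
        for did, bits in zip(world.drug_ids, world.fingerprints):
            fh.write(did + "\t" + "".join(map(str, bits)) + "\n")

    if world.positives is None:
        raise ConfigurationError("interactions not generated yet")
    with open(out / "positives.tsv", "w", encoding="utf-8", newline="\n") as fh:
        fh.write("drug_id\tprotein_id\n")
        for d, p in world.positives:
            fh.write(f"{world.drug_ids[d]}\t{world.protein_ids[p]}\n")

    view_files = []
    for view in views:
        fname = f"edges_{view.name}.tsv"
        write_view_tsv(view, entities, out / fname)
        view_files.append(fname)

    manifest: dict[str, str] = {}
    for fname in ["entities.tsv", "proteins.fasta", "fingerprints.tsv", "positives.tsv"] + view_files:
        manifest[fname] = hashlib.sha256((out / fname).read_bytes()).hexdigest()
    return manifest
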