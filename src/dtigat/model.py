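"""Multi-view graph attention model for drug-target pair scoring.

Architecture, in the order a forward pass runs:

1. Initial node features: a learned free embedding per node, plus (when
   attributes are enabled) learned linear projections of the drug
   fingerprint and protein k-mer composition into the working dimension.
   Disease nodes carry only their free embedding.
2. Per view, a stack of attention message-passing layers:
   a_ij = softmax_j(Q_i . K_j) over the neighborhood N(i) (the node is
   always included in its own neighborhood so the softmax is defined for
   isolated nodes), then h_i' = ReLU(sum_j a_ij W h_j). The ablation
   variant replaces a_ij with the uniform 1/|N(i)| (a plain GCN step).
3. View fusion: z = sum_v alpha_v h_v with alpha = softmax over one
   learned logit per view — a convex combination at all times.
4. Pair scoring: an MLP on [z_drug ; z_target ; f_prior] with a final
   sigmoid, so scores live strictly in (0, 1).

The attention is dot-product as stated, without the transformer
1/sqrt(d) scaling by default; an optional scaling flag exists for
stability. Attention/transform parameters are view-specific (relations
have different semantics); the initial projections are shared.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .graphs import ConfigurationError, MultiViewGraph


@dataclass(frozen=True)
class ModelConfig:
    embed_dim: int = 64
    n_layers: int = 2
    n_heads: int = 1
    mlp_layers: int = 2
    mlp_hidden: int = 64
    use_attention: bool = True
    use_attributes: bool = True
    attention_scaling: bool = False
    dtype: str = "float32"

    def __post_init__(self) -> None:
        if not 1 <= self.mlp_layers <= 4:
            raise ConfigurationError("mlp_layers must be in 1..4")
        if self.n_layers < 1:
            raise ConfigurationError("n_layers must be >= 1")
        if self.embed_dim < 1 or self.n_heads < 1 or self.embed_dim % self.n_heads:
            raise ConfigurationError("embed_dim must be a positive multiple of n_heads")
        if self.dtype not in ("float32", "float64"):
            raise ConfigurationError("dtype must be float32 or float64")

    @property
    def np_dtype(self):
        return np.float32 if self.dtype == "float32" else np.float64


# ---------------------------------------------------------------------------
# Graph preparation: dense neighborhood masks per view
# ---------------------------------------------------------------------------


@dataclass
class ViewPack:
    """One view's neighborhoods: ``active`` nodes (those with at least one
    non-self edge) and their boolean adjacency with self-loops on the
    diagonal. Nodes outside ``active`` have self-only neighborhoods."""

    name: str
    active: np.ndarray
    mask: np.ndarray


@dataclass
class GraphPack:
    n_nodes: int
    views: list[ViewPack]
    drug_nodes: np.ndarray
    prot_nodes: np.ndarray
    chem: np.ndarray  # (n_drugs, chem_dim); zero-width if no attributes
    seq: np.ndarray  # (n_proteins, seq_dim)

    @property
    def n_views(self) -> int:
        return len(self.views)


def view_pack(name: str, src: np.ndarray, dst: np.ndarray, n: int) -> ViewPack:
    src = np.asarray(src, dtype=int)
    dst = np.asarray(dst, dtype=int)
    active = np.unique(np.concatenate([src, dst])) if len(src) else np.empty(0, int)
    pos = np.full(n, -1, dtype=int)
    pos[active] = np.arange(len(active))
    mask = np.zeros((len(active), len(active)), dtype=bool)
    if len(src):
        mask[pos[src], pos[dst]] = True
        mask[pos[dst], pos[src]] = True
    np.fill_diagonal(mask, True)
    return ViewPack(name=name, active=active, mask=mask)


def _standardize(x: np.ndarray) -> np.ndarray:
    """Column z-scores over the entity set; constant columns become 0.

    Fingerprint bits are O(1) while k-mer frequencies are O(1/length);
    standardizing puts the two attribute blocks on the same footing
    before the learned projections."""
    if x.size == 0:
        return x
    mu = x.mean(axis=0, keepdims=True)
    sd = x.std(axis=0, keepdims=True)
    sd[sd == 0] = 1.0
    return (x - mu) / sd


def prepare_graph(mvg: MultiViewGraph, standardize_attributes: bool = True) -> GraphPack:
    n = len(mvg.entities)
    views = [view_pack(v.name, v.src, v.dst, n) for v in mvg.views]
    drug_nodes = mvg.entities.indices_of_kind("drug")
    prot_nodes = mvg.entities.indices_of_kind("protein")
    if mvg.features is not None:
        chem = np.asarray(mvg.features.chem, dtype=float)
        seq = np.asarray(mvg.features.seq, dtype=float)
        if standardize_attributes:
            chem = _standardize(chem)
            seq = _standardize(seq)
    else:
        chem = np.zeros((len(drug_nodes), 0))
        seq = np.zeros((len(prot_nodes), 0))
    return GraphPack(n_nodes=n, views=views, drug_nodes=drug_nodes,
                     prot_nodes=prot_nodes, chem=chem, seq=seq)


# ---------------------------------------------------------------------------
# Functional building blocks (also the unit-test surface)
# ---------------------------------------------------------------------------


def attention_scores(
    node_feat: np.ndarray,
    neighbor_feats: np.ndarray,
    Wq: np.ndarray,
    Wk: np.ndarray,
    scaling: bool = False,
) -> np.ndarray:
    """Softmax-normalized dot-product attention of one node over its
    neighborhood: positive weights summing to 1."""
    q = np.asarray(node_feat, dtype=float) @ Wq
    k = np.asarray(neighbor_feats, dtype=float) @ Wk
    logits = k @ q
    if scaling:
        logits = logits / np.sqrt(q.shape[-1])
    return ad.softmax(logits)


def _layer_forward(
    h: ad.Tensor,
    view: ViewPack,
    W: ad.Tensor,
    Wq: list[ad.Tensor],
    Wk: list[ad.Tensor],
    use_attention: bool,
    scaling: bool,
) -> ad.Tensor:
    """One message-passing step h -> ReLU(sum_j a_ij W h_j) on one view."""
    hw = ad.matmul(h, W)
    if len(view.active) == 0:
        return ad.relu(hw)  # every neighborhood is the node itself
    sub = ad.gather_rows(hw, view.active)
    if use_attention:
        ha = ad.gather_rows(h, view.active)
        n_heads = len(Wq)
        head_dim = hw.shape[1] // n_heads
        parts = []
        for hd in range(n_heads):
            q = ad.matmul(ha, Wq[hd])
            k = ad.matmul(ha, Wk[hd])
            logits = ad.matmul_t(q, k)
            if scaling:
                logits = ad.scale(logits, 1.0 / np.sqrt(q.shape[1]))
            attn = ad.masked_softmax(logits, view.mask)
            block = sub if n_heads == 1 else ad.cols(sub, hd * head_dim, (hd + 1) * head_dim)
            parts.append(ad.matmul(attn, block))
        agg = parts[0] if n_heads == 1 else ad.concat_cols(parts)
    else:
        deg = view.mask.sum(axis=1, keepdims=True)
        uniform = ad.constant((view.mask / deg).astype(hw.data.dtype))
        agg = ad.matmul(uniform, sub)
    return ad.relu(ad.replace_rows(hw, view.active, agg))


def message_pass(
    features: np.ndarray,
    mask: np.ndarray,
    W: np.ndarray,
    Wq: np.ndarray,
    Wk: np.ndarray,
    scaling: bool = False,
) -> np.ndarray:
    """Forward-only attention message passing on a dense neighborhood mask
    (self-loops expected on the diagonal)."""
    n = len(features)
    vp = ViewPack("adhoc", np.arange(n), np.asarray(mask, dtype=bool))
    out = _layer_forward(
        ad.constant(np.asarray(features, dtype=float)),
        vp,
        ad.constant(np.asarray(W, dtype=float)),
        [ad.constant(np.asarray(Wq, dtype=float))],
        [ad.constant(np.asarray(Wk, dtype=float))],
        use_attention=True,
        scaling=scaling,
    )
    return out.data


def gcn_message_pass(features: np.ndarray, mask: np.ndarray, W: np.ndarray) -> np.ndarray:
    """The no-attention ablation: a_ij fixed to 1/|N(i)|."""
    n = len(features)
    vp = ViewPack("adhoc", np.arange(n), np.asarray(mask, dtype=bool))
    out = _layer_forward(
        ad.constant(np.asarray(features, dtype=float)),
        vp,
        ad.constant(np.asarray(W, dtype=float)),
        [], [],
        use_attention=False,
        scaling=False,
    )
    return out.data


def fuse_views(embeddings: list[np.ndarray], logits: np.ndarray) -> np.ndarray:
    """Forward-only convex fusion z = sum_v softmax(logits)_v h_v."""
    alpha = ad.fusion_weights(logits)
    return sum(alpha[i] * np.asarray(h, dtype=float) for i, h in enumerate(embeddings))


# ---------------------------------------------------------------------------
# The trainable model
# ---------------------------------------------------------------------------


class DTGModel:
    """Per-view attention stacks + convex fusion + MLP pair scorer.

    Parameter layout (all learned): free node embeddings; shared
    fingerprint / k-mer input projections; per view and layer a transform
    W and per head Q/K projections; one fusion logit per view; the MLP
    blocks, whose first layer is split over [z_drug | z_target | f_chem |
    f_seq] so the pair prior enters exactly as a concatenation.
    """

    def __init__(self, pack: GraphPack, config: ModelConfig, seed: int = 0):
        self.pack = pack
        self.config = config
        self.seed = seed
        d = config.embed_dim
        dt = config.np_dtype
        rng = np.random.default_rng(seed)

        def glorot(fan_in: int, fan_out: int) -> np.ndarray:
            lim = np.sqrt(6.0 / max(1, fan_in + fan_out))
            return rng.uniform(-lim, lim, size=(fan_in, fan_out)).astype(dt)

        p: dict[str, ad.Tensor] = {}
        p["node_emb"] = ad.parameter((rng.normal(0, 1.0 / np.sqrt(d), size=(pack.n_nodes, d))).astype(dt))
        cd, sd = pack.chem.shape[1], pack.seq.shape[1]
        if cd:
            p["proj_chem"] = ad.parameter(glorot(cd, d))
        if sd:
            p["proj_seq"] = ad.parameter(glorot(sd, d))
        head_dim = d // config.n_heads
        for v in range(pack.n_views):
            for l in range(config.n_layers):
                p[f"W_{v}_{l}"] = ad.parameter(glorot(d, d))
                for h in range(config.n_heads):
                    p[f"Wq_{v}_{l}_{h}"] = ad.parameter(glorot(d, head_dim))
                    p[f"Wk_{v}_{l}_{h}"] = ad.parameter(glorot(d, head_dim))
        p["fusion_logits"] = ad.parameter(np.zeros(pack.n_views, dtype=dt))
        m1 = 1 if config.mlp_layers == 1 else config.mlp_hidden
        p["mlp_W_zd"] = ad.parameter(glorot(d, m1))
        p["mlp_W_zp"] = ad.parameter(glorot(d, m1))
        if cd:
            p["mlp_W_chem"] = ad.parameter(glorot(cd, m1))
        if sd:
            p["mlp_W_seq"] = ad.parameter(glorot(sd, m1))
        p["mlp_b_0"] = ad.parameter(np.zeros(m1, dtype=dt))
        for i in range(1, config.mlp_layers - 1):
            p[f"mlp_W_{i}"] = ad.parameter(glorot(config.mlp_hidden, config.mlp_hidden))
            p[f"mlp_b_{i}"] = ad.parameter(np.zeros(config.mlp_hidden, dtype=dt))
        if config.mlp_layers > 1:
            p["mlp_W_out"] = ad.parameter(glorot(config.mlp_hidden, 1))
            p["mlp_b_out"] = ad.parameter(np.zeros(1, dtype=dt))
        self.params = p
        self._chem_const = ad.constant(pack.chem.astype(dt))
        self._seq_const = ad.constant(pack.seq.astype(dt))

    # -- forward ------------------------------------------------------------

    def parameters(self) -> list[ad.Tensor]:
        return list(self.params.values())

    def initial_features(self) -> ad.Tensor:
        h = self.params["node_emb"]
        if self.config.use_attributes:
            if "proj_chem" in self.params and self._chem_const.data.size:
                h = ad.add_rows(h, self.pack.drug_nodes,
                                ad.matmul(self._chem_const, self.params["proj_chem"]))
            if "proj_seq" in self.params and self._seq_const.data.size:
                h = ad.add_rows(h, self.pack.prot_nodes,
                                ad.matmul(self._seq_const, self.params["proj_seq"]))
        return h

    def encode_views(self) -> list[ad.Tensor]:
        """One topology-aware embedding matrix per view."""
        cfg = self.config
        h0 = self.initial_features()
        out = []
        for v, vp in enumerate(self.pack.views):
            h = h0
            for l in range(cfg.n_layers):
                h = _layer_forward(
                    h, vp,
                    self.params[f"W_{v}_{l}"],
                    [self.params[f"Wq_{v}_{l}_{hd}"] for hd in range(cfg.n_heads)],
                    [self.params[f"Wk_{v}_{l}_{hd}"] for hd in range(cfg.n_heads)],
                    use_attention=cfg.use_attention,
                    scaling=cfg.attention_scaling,
                )
            out.append(h)
        return out

    def encode(self) -> ad.Tensor:
        """Fused node embeddings z = sum_v alpha_v h_v."""
        return ad.fuse_weighted(self.encode_views(), self.params["fusion_logits"])

    def fusion_alpha(self) -> np.ndarray:
        return ad.fusion_weights(self.params["fusion_logits"].data)

    def pair_logits(self, z: ad.Tensor, pairs: np.ndarray) -> ad.Tensor:
        """MLP([z_drug ; z_target ; f_prior]) as raw logits for (m, 2)
        local (drug, protein) index pairs."""
        pairs = np.asarray(pairs, dtype=int).reshape(-1, 2)
        pd, pp = pairs[:, 0], pairs[:, 1]
        zd = ad.gather_rows(z, self.pack.drug_nodes[pd])
        zp = ad.gather_rows(z, self.pack.prot_nodes[pp])
        x = ad.add(ad.add(ad.matmul(zd, self.params["mlp_W_zd"]),
                          ad.matmul(zp, self.params["mlp_W_zp"])),
                   self.params["mlp_b_0"])
        if self.config.use_attributes:
            if "mlp_W_chem" in self.params and self._chem_const.data.size:
                x = ad.add(x, ad.gather_rows(
                    ad.matmul(self._chem_const, self.params["mlp_W_chem"]), pd))
            if "mlp_W_seq" in self.params and self._seq_const.data.size:
                x = ad.add(x, ad.gather_rows(
                    ad.matmul(self._seq_const, self.params["mlp_W_seq"]), pp))
        if self.config.mlp_layers == 1:
            return x
        h = ad.relu(x)
        for i in range(1, self.config.mlp_layers - 1):
            h = ad.relu(ad.add(ad.matmul(h, self.params[f"mlp_W_{i}"]),
                               self.params[f"mlp_b_{i}"]))
        return ad.add(ad.matmul(h, self.params["mlp_W_out"]), self.params["mlp_b_out"])

    def forward_scores(self, pairs: np.ndarray) -> np.ndarray:
        """Interaction scores in (0, 1) for (m, 2) local pairs."""
        logits = self.pair_logits(self.encode(), pairs)
        return ad.sigmoid(logits.data.astype(np.float64)).ravel()

    def loss(self, pairs: np.ndarray, labels: np.ndarray) -> ad.Tensor:
        logits = self.pair_logits(self.encode(), pairs)
        return ad.bce_with_logits(logits, np.asarray(labels, dtype=float).reshape(-1, 1))

    def predict_pair(self, drug_local: int, protein_local: int) -> float:
        return float(self.forward_scores(np.array([[drug_local, protein_local]]))[0])

    # -- state --------------------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, v in self.params.items():
            if k not in state:
                raise KeyError(f"missing parameter {k!r} in state")
            v.data = np.array(state[k], dtype=v.data.dtype, copy=True)

    def save(self, path: str | Path) -> None:
        """Versioned checkpoint: parameters plus config/seed snapshot."""
        meta = {"format": "dtigat-model-v1", "seed": self.seed, "config": asdict(self.config)}
        with open(path, "wb") as fh:
            np.savez(fh, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                     **self.state_dict())

    @classmethod
    def load(cls, path: str | Path, pack: GraphPack) -> "DTGModel":
        with np.load(path) as z:
            meta = json.loads(bytes(z["__meta__"]).decode())
            if meta.get("format") != "dtigat-model-v1":
                raise ValueError(f"unrecognized checkpoint format in {path}")
            state = {k: z[k] for k in z.files if k != "__meta__"}
        model = cls(pack, ModelConfig(**meta["config"]), seed=meta["seed"])
        model.load_state_dict(state)
        return model
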