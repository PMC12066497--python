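"""Fold construction, negative sampling, cold-start flagging and training.

Protocol: known positives are shuffled once (seeded) and split into 2k
half-blocks; fold f takes half-block 2f as test, half-block 2f+1 as
validation and the rest as training — 80/10/10 at k=5, rotating so the
held-out blocks are disjoint across folds and test+validation blocks
together cover every positive exactly once.

Negatives are drawn anew per fold, uniformly without replacement from the
complement of the FULL positive set (so a "negative" is never a held-out
positive), at the configured ratio for each of train/validation/test,
mutually disjoint within the fold.

A test pair is cold-start iff its drug or its protein has zero positive
training pairs in that fold.

Training minimizes binary cross-entropy with Adam and early-stops on
validation ROC-AUC; the known-interaction view of the training graph must
contain only that fold's training positives — asserted, hard error on
violation.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace as dc_replace

import numpy as np

from . import autodiff as ad
from .evaluation import roc_auc
from .features import build_prior_features
from .graphs import ConfigurationError, EntitySet, MultiViewGraph
from .model import DTGModel, ModelConfig, prepare_graph
from .synthetic import SyntheticConfig, SyntheticWorld, generate_views, generate_world


class SamplingError(ValueError):
    """Not enough non-interacting pairs for the requested negative count."""


class LeakageError(RuntimeError):
    """Held-out positives found in the training interaction view."""


@dataclass(frozen=True)
class TrainConfig:
    lr: float = 1e-3
    max_epochs: int = 200
    patience: int = 10
    negative_ratio: float = 1.0
    batch_size: int = 0  # 0 = full batch
    seed: int = 0
    use_attention: bool = True
    use_attributes: bool = True
    weight_decay: float = 0.0

    def __post_init__(self) -> None:
        if self.lr <= 0 or self.max_epochs < 1 or self.patience < 1:
            raise ConfigurationError("lr, max_epochs, patience must be positive")
        if self.negative_ratio <= 0:
            raise ConfigurationError("negative_ratio must be > 0")


def _pair_shape(entities) -> tuple[int, int]:
    if isinstance(entities, EntitySet):
        return len(entities.indices_of_kind("drug")), len(entities.indices_of_kind("protein"))
    n_d, n_p = entities
    return int(n_d), int(n_p)


def sample_negatives(
    positives: np.ndarray,
    entities,
    ratio: float = 1.0,
    seed: int = 0,
    count: int | None = None,
) -> np.ndarray:
    """Uniform sample without replacement from the non-interacting pairs.

    ``entities`` is an EntitySet or an (n_drugs, n_proteins) tuple; size is
    floor(ratio * |positives|) unless ``count`` overrides it. Deterministic
    given ``seed``.
    """
    n_d, n_p = _pair_shape(entities)
    pos = np.asarray(positives, dtype=int).reshape(-1, 2)
    codes = pos[:, 0] * n_p + pos[:, 1]
    complement = np.setdiff1d(np.arange(n_d * n_p), codes, assume_unique=False)
    want = int(ratio * len(pos)) if count is None else int(count)
    if want > len(complement):
        raise SamplingError(
            f"requested {want} negatives but only {len(complement)} "
            f"non-interacting pairs exist ({n_d}x{n_p} grid, {len(pos)} positives)"
        )
    rng = np.random.default_rng(seed)
    draw = rng.choice(complement, size=want, replace=False)
    return np.column_stack([draw // n_p, draw % n_p]).astype(int)


def make_folds(positives: np.ndarray, k: int, seed: int = 0) -> list[dict[str, np.ndarray]]:
    """k rotating folds of index arrays {train, val, test} into positives.

    Positives are shuffled once, split into 2k half-blocks; fold f tests on
    half-block 2f, validates on 2f+1, trains on the rest (80/10/10 at k=5).
    """
    n = len(np.asarray(positives).reshape(-1, 2))
    if k < 2:
        raise ConfigurationError("k must be >= 2")
    if k > n:
        raise ConfigurationError(f"k={k} exceeds number of positives ({n})")
    if n < 2 * k:
        raise ConfigurationError(f"need at least 2k={2 * k} positives, got {n}")
    perm = np.random.default_rng(seed).permutation(n)
    blocks = np.array_split(perm, 2 * k)
    folds = []
    for f in range(k):
        test = blocks[2 * f]
        val = blocks[2 * f + 1]
        train = np.concatenate([b for i, b in enumerate(blocks) if i not in (2 * f, 2 * f + 1)])
        folds.append({"train": np.sort(train), "val": np.sort(val), "test": np.sort(test)})
    return folds


def flag_cold_start(
    positives: np.ndarray,
    fold: dict[str, np.ndarray],
    pairs: np.ndarray | None = None,
) -> np.ndarray:
    """Cold-start flag per pair: drug OR protein has no training positive."""
    pos = np.asarray(positives, dtype=int).reshape(-1, 2)
    train_pos = pos[fold["train"]]
    warm_drugs = set(train_pos[:, 0].tolist())
    warm_prots = set(train_pos[:, 1].tolist())
    target = pos[fold["test"]] if pairs is None else np.asarray(pairs, dtype=int).reshape(-1, 2)
    return np.array(
        [(d not in warm_drugs) or (p not in warm_prots) for d, p in target], dtype=bool
    )


@dataclass
class FoldData:
    """Labeled pairs for one fold, with cold-start flags on the test split."""

    fold_index: int
    train_pos: np.ndarray
    train_pairs: np.ndarray
    train_labels: np.ndarray
    val_pairs: np.ndarray
    val_labels: np.ndarray
    test_pairs: np.ndarray
    test_labels: np.ndarray
    test_cold: np.ndarray
    heldout_pos: np.ndarray  # val + test positives, for the leakage guard


def build_fold_data(
    positives: np.ndarray,
    entities,
    k: int = 5,
    negative_ratio: float = 1.0,
    seed: int = 0,
) -> list[FoldData]:
    """Fold assignments plus per-fold negatives (sampled anew each fold)."""
    pos = np.asarray(positives, dtype=int).reshape(-1, 2)
    folds = make_folds(pos, k, seed)
    out = []
    for f, fold in enumerate(folds):
        tr, va, te = pos[fold["train"]], pos[fold["val"]], pos[fold["test"]]
        n_tr = int(negative_ratio * len(tr))
        n_va = int(negative_ratio * len(va))
        n_te = int(negative_ratio * len(te))
        negs = sample_negatives(pos, entities, seed=seed * 1000 + f,
                                count=n_tr + n_va + n_te)
        neg_tr, neg_va, neg_te = negs[:n_tr], negs[n_tr : n_tr + n_va], negs[n_tr + n_va :]
        test_pairs = np.vstack([te, neg_te])
        out.append(
            FoldData(
                fold_index=f,
                train_pos=tr,
                train_pairs=np.vstack([tr, neg_tr]),
                train_labels=np.concatenate([np.ones(len(tr)), np.zeros(len(neg_tr))]),
                val_pairs=np.vstack([va, neg_va]),
                val_labels=np.concatenate([np.ones(len(va)), np.zeros(len(neg_va))]),
                test_pairs=test_pairs,
                test_labels=np.concatenate([np.ones(len(te)), np.zeros(len(neg_te))]),
                test_cold=flag_cold_start(pos, fold, test_pairs),
                heldout_pos=np.vstack([va, te]),
            )
        )
    return out


@dataclass
class TrainedModel:
    """Learned parameters plus the training record for one fold."""

    model: DTGModel
    log: list[dict] = field(default_factory=list)
    best_val_auc: float = float("nan")
    best_epoch: int = -1


def _assert_no_leakage(graph: MultiViewGraph, heldout_pos: np.ndarray) -> None:
    entities = graph.entities
    drug_nodes = entities.indices_of_kind("drug")
    prot_nodes = entities.indices_of_kind("protein")
    dpos = {g: i for i, g in enumerate(drug_nodes)}
    ppos = {g: i for i, g in enumerate(prot_nodes)}
    held = {(int(d), int(p)) for d, p in np.asarray(heldout_pos, dtype=int).reshape(-1, 2)}
    for view in graph.views:
        if view.relation != "drug-protein-interaction":
            continue
        for s, t in zip(view.src, view.dst):
            a, b = int(s), int(t)
            if a in dpos and b in ppos:
                pair = (dpos[a], ppos[b])
            elif b in dpos and a in ppos:
                pair = (dpos[b], ppos[a])
            else:
                continue
            if pair in held:
                raise LeakageError(
                    f"view {view.name!r} contains held-out positive pair {pair}"
                )


def train_model(
    graph: MultiViewGraph,
    fold: FoldData,
    model_config: ModelConfig | None = None,
    train_config: TrainConfig | None = None,
) -> TrainedModel:
    """End-to-end optimization on one fold's training pairs.

    Binary cross-entropy, Adam, early stopping on validation ROC-AUC with
    the configured patience; the best-validation parameters are restored.
    """
    tc = train_config or TrainConfig()
    mc = model_config or ModelConfig()
    mc = dc_replace(mc, use_attention=tc.use_attention, use_attributes=tc.use_attributes)
    _assert_no_leakage(graph, fold.heldout_pos)

    pack = prepare_graph(graph)
    model = DTGModel(pack, mc, seed=tc.seed)
    opt = ad.Adam(model.parameters(), lr=tc.lr, weight_decay=tc.weight_decay)
    rng = np.random.default_rng(tc.seed + 1)

    trained = TrainedModel(model=model)
    best_state = model.state_dict()
    best_auc = -np.inf
    wait = 0
    n_train = len(fold.train_pairs)
    for epoch in range(tc.max_epochs):
        if tc.batch_size and tc.batch_size < n_train:
            order = rng.permutation(n_train)
            losses = []
            for start in range(0, n_train, tc.batch_size):
                sel = order[start : start + tc.batch_size]
                loss = model.loss(fold.train_pairs[sel], fold.train_labels[sel])
                if not np.isfinite(loss.data):
                    raise RuntimeError(f"non-finite loss at epoch {epoch}")
                opt.zero_grad()
                loss.backward()
                opt.step()
                losses.append(float(loss.data))
            epoch_loss = float(np.mean(losses))
        else:
            loss = model.loss(fold.train_pairs, fold.train_labels)
            if not np.isfinite(loss.data):
                raise RuntimeError(f"non-finite loss at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss = float(loss.data)

        val_scores = model.forward_scores(fold.val_pairs)
        val_auc = roc_auc(fold.val_labels, val_scores)
        trained.log.append({"epoch": epoch, "loss": epoch_loss, "val_auc": val_auc})
        if val_auc > best_auc:
            best_auc = val_auc
            best_state = model.state_dict()
            trained.best_epoch = epoch
            wait = 0
        else:
            wait += 1
            if wait >= tc.patience:
                break

    model.load_state_dict(best_state)
    trained.best_val_auc = float(best_auc)
    return trained


# ---------------------------------------------------------------------------
# End-to-end synthetic pipeline
# ---------------------------------------------------------------------------


def build_fold_graph(
    world: SyntheticWorld,
    cfg: SyntheticConfig,
    fold: FoldData,
    entities: EntitySet | None = None,
    features=None,
    kmer_k: int = 3,
) -> MultiViewGraph:
    """Multi-view graph for one fold: the interaction view holds only that
    fold's training positives."""
    entities = entities or world.entity_set()
    if features is None:
        features = build_prior_features(entities, k=kmer_k)
    views = generate_views(world, cfg, train_pairs=fold.train_pos)
    return MultiViewGraph(entities=entities, views=views, features=features)


@dataclass
class CVResult:
    world: SyntheticWorld
    folds: list[FoldData]
    trained: list[TrainedModel]
    view_names: list[str] = field(default_factory=list)


def run_cv(
    synth_config: SyntheticConfig,
    model_config: ModelConfig | None = None,
    train_config: TrainConfig | None = None,
    k: int = 5,
    fold_subset: list[int] | None = None,
    kmer_k: int = 3,
) -> CVResult:
    """Generate a world, build k folds, train one model per fold.

    ``fold_subset`` restricts training to selected folds (the fold split
    itself is always the full k-fold split).
    """
    tc = train_config or TrainConfig()
    world = generate_world(synth_config)
    entities = world.entity_set()
    features = build_prior_features(entities, k=kmer_k)
    folds = build_fold_data(
        world.positives, (synth_config.n_drugs, synth_config.n_proteins),
        k=k, negative_ratio=tc.negative_ratio, seed=tc.seed,
    )
    selected = folds if fold_subset is None else [folds[i] for i in fold_subset]
    trained = []
    view_names: list[str] = []
    for fold in selected:
        graph = build_fold_graph(world, synth_config, fold, entities, features, kmer_k)
        view_names = graph.view_names()
        trained.append(train_model(graph, fold, model_config, tc))
    return CVResult(world=world, folds=selected, trained=trained, view_names=view_names)
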