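"""Heterogeneous multi-view graph containers and similarity scorers.

The model's input is a multi-relational graph G=(V,E) over drugs, proteins
and diseases: a shared, ordered entity set plus an ordered list of named
relation *views* (drug-drug similarity, protein-protein similarity,
drug-disease / protein-disease association, and the known drug-protein
interaction view). Views are stored symmetrized with string entity ids on
disk and integer indices in memory; entity indexing is file order, so a
graph round-trips deterministically.
"""

from __future__ import annotations

import dataclasses
import functools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
ENTITY_KINDS = ("drug", "protein", "disease")

# Smith-Waterman defaults for the protein similarity stand-in: BLOSUM62
# with affine gaps, gap of length L scoring OPEN + (L-1)*EXTEND.
SW_MATRIX = "BLOSUM62"
SW_OPEN = -11.0
SW_EXTEND = -1.0


class InputError(ValueError):
    """Malformed user input (files, vectors, sequences)."""


class ReferentialIntegrityError(InputError):
    """An edge references an entity id that does not exist."""


class ConfigurationError(ValueError):
    """Inconsistent configuration (counts, view partitions, k values)."""


# ---------------------------------------------------------------------------
# Entity set
# ---------------------------------------------------------------------------


@dataclass
class EntitySet:
    """Ordered, typed entities with optional attribute payloads.

    ``ids`` fixes the node indexing (file order). Drugs may carry a binary
    fingerprint; proteins may carry a residue sequence.
    """

    ids: list[str]
    kinds: list[str]
    fingerprints: dict[str, np.ndarray] = field(default_factory=dict)
    sequences: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.kinds):
            raise InputError("ids and kinds must have equal length")
        if len(set(self.ids)) != len(self.ids):
            dupes = {i for i in self.ids if self.ids.count(i) > 1}
            raise InputError(f"duplicate entity ids: {sorted(dupes)[:5]}")
        unknown = set(self.kinds) - set(ENTITY_KINDS)
        if unknown:
            raise InputError(f"unknown entity kinds: {sorted(unknown)}")
        self.index = {eid: i for i, eid in enumerate(self.ids)}

    def __len__(self) -> int:
        return len(self.ids)

    def indices_of_kind(self, kind: str) -> np.ndarray:
        return np.array([i for i, k in enumerate(self.kinds) if k == kind], dtype=int)

    def ids_of_kind(self, kind: str) -> list[str]:
        return [e for e, k in zip(self.ids, self.kinds) if k == kind]

    @classmethod
    def from_files(
        cls,
        entities_tsv: str | Path,
        fasta: str | Path | None = None,
        fingerprints_tsv: str | Path | None = None,
    ) -> "EntitySet":
        df = pd.read_csv(entities_tsv, sep="\t", dtype=str)
        if "id" not in df.columns or "type" not in df.columns:
            raise InputError(f"{entities_tsv}: expected columns 'id' and 'type'")
        es = cls(ids=list(df["id"]), kinds=list(df["type"]))
        if fasta is not None:
            for rec in SeqIO.parse(str(fasta), "fasta"):
                if rec.id in es.index:
                    es.sequences[rec.id] = str(rec.seq)
        if fingerprints_tsv is not None:
            fp = pd.read_csv(fingerprints_tsv, sep="\t", dtype=str)
            for _, row in fp.iterrows():
                if row["id"] in es.index:
                    bits = np.frombuffer(row["bitstring"].encode(), dtype=np.uint8) - ord("0")
                    es.fingerprints[row["id"]] = bits.astype(np.uint8)
        return es

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"id": self.ids, "type": self.kinds})


# ---------------------------------------------------------------------------
# View graphs
# ---------------------------------------------------------------------------


@dataclass
class ViewGraph:
    """One weighted relation view: a named edge set over the entity index.

    Undirected views are stored symmetrized: (i, j, w) present iff
    (j, i, w) present. Self-edges are never stored; the model adds the
    self-connection itself.
    """

    name: str
    relation: str
    src: np.ndarray
    dst: np.ndarray
    weight: np.ndarray
    undirected: bool = True

    def __post_init__(self) -> None:
        self.src = np.asarray(self.src, dtype=int)
        self.dst = np.asarray(self.dst, dtype=int)
        self.weight = np.asarray(self.weight, dtype=float)
        if not (len(self.src) == len(self.dst) == len(self.weight)):
            raise InputError(f"view {self.name}: ragged edge arrays")
        if len(self.weight) and not np.all(np.isfinite(self.weight)):
            raise InputError(f"view {self.name}: non-finite edge weights")

    @property
    def n_edges(self) -> int:
        return len(self.src)

    def symmetrized(self) -> "ViewGraph":
        """Return a copy with both edge directions present, self-edges dropped.

        Idempotent: symmetrizing twice equals symmetrizing once.
        """
        keep = self.src != self.dst
        s, d, w = self.src[keep], self.dst[keep], self.weight[keep]
        pairs: dict[tuple[int, int], float] = {}
        for i, j, x in zip(s, d, w):
            pairs[(int(i), int(j))] = float(x)
            pairs[(int(j), int(i))] = float(x)
        if not pairs:
            return dataclasses.replace(
                self, src=np.empty(0, int), dst=np.empty(0, int), weight=np.empty(0, float)
            )
        keys = sorted(pairs)
        ss = np.array([k[0] for k in keys], dtype=int)
        dd = np.array([k[1] for k in keys], dtype=int)
        ww = np.array([pairs[k] for k in keys], dtype=float)
        return dataclasses.replace(self, src=ss, dst=dd, weight=ww)

    def validate(self, n_entities: int) -> None:
        if self.n_edges and (self.src.max() >= n_entities or self.dst.max() >= n_entities):
            raise ReferentialIntegrityError(
                f"view {self.name}: edge endpoint out of range (n={n_entities})"
            )
        if self.n_edges and (self.src.min() < 0 or self.dst.min() < 0):
            raise ReferentialIntegrityError(f"view {self.name}: negative edge index")


@dataclass
class MultiViewGraph:
    """Shared entity set plus an ordered list of views.

    View order is fixed and recorded; fusion weights are positional.
    ``features`` holds the prior attribute matrices (see
    :mod:`dtigat.features`), attached by :func:`assemble_multiview_graph`.
    """

    entities: EntitySet
    views: list[ViewGraph]
    features: object | None = None

    def __post_init__(self) -> None:
        for v in self.views:
            v.validate(len(self.entities))

    @property
    def n_views(self) -> int:
        return len(self.views)

    def view_names(self) -> list[str]:
        return [v.name for v in self.views]


# ---------------------------------------------------------------------------
# Similarity scorers
# ---------------------------------------------------------------------------


def tanimoto_similarity(fp_a: np.ndarray, fp_b: np.ndarray) -> float:
    """Jaccard similarity of two binary fingerprints: |a AND b| / |a OR b|.

    Returns 0.0 when both vectors are all-zero (documented convention).
    """
    a = np.asarray(fp_a).astype(bool)
    b = np.asarray(fp_b).astype(bool)
    if a.shape != b.shape:
        raise InputError(f"fingerprint length mismatch: {a.shape} vs {b.shape}")
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 0.0
    return float(np.logical_and(a, b).sum() / union)


@functools.lru_cache(maxsize=1)
def _aligner() -> PairwiseAligner:
    aln = PairwiseAligner()
    aln.mode = "local"
    aln.substitution_matrix = substitution_matrices.load(SW_MATRIX)
    aln.open_gap_score = SW_OPEN
    aln.extend_gap_score = SW_EXTEND
    return aln


def _check_sequence(seq: str, label: str) -> str:
    if not seq:
        raise InputError(f"{label}: empty sequence")
    seq = seq.upper()
    bad = set(seq) - set(AMINO_ACIDS)
    if bad:
        raise InputError(f"{label}: illegal residues {sorted(bad)}")
    return seq


def sequence_similarity(seq_a: str, seq_b: str) -> float:
    """Normalized local-alignment similarity in [0, 1].

    Smith-Waterman with BLOSUM62 and affine gaps (open -11, extend -1),
    normalized as score(a,b) / sqrt(score(a,a) * score(b,b)). Symmetric,
    and 1.0 for identical sequences.
    """
    a = _check_sequence(seq_a, "seq_a")
    b = _check_sequence(seq_b, "seq_b")
    aln = _aligner()
    sab = aln.score(a, b)
    saa = aln.score(a, a)
    sbb = aln.score(b, b)
    if saa <= 0 or sbb <= 0:  # cannot happen for standard residues, guard anyway
        return 0.0
    return float(min(1.0, max(0.0, sab / np.sqrt(saa * sbb))))


# ---------------------------------------------------------------------------
# Similarity-view construction
# ---------------------------------------------------------------------------


def mutual_topk_edges(sim: np.ndarray, k: int, drop_zero: bool = True):
    """Mutual-rank kNN sparsification of a symmetric similarity matrix.

    Keeps edge (i, j), i != j, iff j is among i's k most similar entities
    OR i is among j's. Returns sorted (src, dst, weight) arrays with both
    directions present.
    """
    sim = np.asarray(sim, dtype=float)
    n = sim.shape[0]
    if k < 1:
        raise ConfigurationError("k must be >= 1")
    if k >= n:
        raise ConfigurationError(f"k={k} must be < number of entities ({n})")
    s = (sim + sim.T) / 2.0
    np.fill_diagonal(s, -np.inf)
    # ranks: for each row, indices of the k largest entries
    order = np.argsort(-s, axis=1, kind="stable")[:, :k]
    keep = np.zeros((n, n), dtype=bool)
    rows = np.repeat(np.arange(n), k)
    keep[rows, order.ravel()] = True
    keep = keep | keep.T
    if drop_zero:
        keep &= s != 0
    keep &= np.isfinite(s)
    src, dst = np.nonzero(keep)
    return src, dst, s[src, dst]


def build_similarity_view(
    entities: EntitySet,
    kind: str,
    scorer: Callable[[str, str], float],
    k: int = 10,
    name: str | None = None,
    drop_zero: bool = True,
) -> ViewGraph:
    """Score all same-kind pairs with ``scorer`` and keep mutual top-k edges.

    ``scorer`` receives two entity ids and must return a similarity; it is
    pluggable so precomputed similarity tables can be supplied instead of
    Tanimoto / Smith-Waterman.
    """
    idx = entities.indices_of_kind(kind)
    n = len(idx)
    if k >= n:
        raise ConfigurationError(f"k={k} must be < number of {kind} entities ({n})")
    sim = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            sim[a, b] = sim[b, a] = scorer(entities.ids[idx[a]], entities.ids[idx[b]])
    src, dst, w = mutual_topk_edges(sim, k, drop_zero=drop_zero)
    return ViewGraph(
        name=name or f"{kind}_similarity",
        relation=f"{kind}-{kind}-similarity",
        src=idx[src],
        dst=idx[dst],
        weight=w,
    )


def fingerprint_scorer(entities: EntitySet) -> Callable[[str, str], float]:
    def score(a: str, b: str) -> float:
        return tanimoto_similarity(entities.fingerprints[a], entities.fingerprints[b])

    return score


def sequence_scorer(entities: EntitySet) -> Callable[[str, str], float]:
    def score(a: str, b: str) -> float:
        return sequence_similarity(entities.sequences[a], entities.sequences[b])

    return score


# ---------------------------------------------------------------------------
# Edge file I/O and assembly
# ---------------------------------------------------------------------------

EDGE_COLUMNS = ["source_id", "target_id", "weight", "relation"]


def write_view_tsv(view: ViewGraph, entities: EntitySet, path: str | Path) -> None:
    """Persist a view with string ids (never indices), one direction per
    undirected edge (i < j); full float precision."""
    if view.undirected:
        keep = view.src < view.dst
        src, dst, w = view.src[keep], view.dst[keep], view.weight[keep]
    else:
        src, dst, w = view.src, view.dst, view.weight
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(EDGE_COLUMNS) + "\n")
        for i, j, x in zip(src, dst, w):
            fh.write(
                f"{entities.ids[int(i)]}\t{entities.ids[int(j)]}\t{float(x)!r}\t{view.relation}\n"
            )


def read_view_tsv(path: str | Path, entities: EntitySet, name: str | None = None) -> ViewGraph:
    df = pd.read_csv(path, sep="\t", dtype={"source_id": str, "target_id": str})
    missing = [c for c in EDGE_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing columns {missing}")
    src, dst = [], []
    for row_no, (s, t) in enumerate(zip(df["source_id"], df["target_id"]), start=2):
        for eid in (s, t):
            if eid not in entities.index:
                raise ReferentialIntegrityError(f"{path}, line {row_no}: unknown entity id {eid!r}")
        src.append(entities.index[s])
        dst.append(entities.index[t])
    relation = str(df["relation"].iloc[0]) if len(df) else "unknown"
    view = ViewGraph(
        name=name or Path(path).stem.removeprefix("edges_"),
        relation=relation,
        src=np.array(src, dtype=int),
        dst=np.array(dst, dtype=int),
        weight=df["weight"].to_numpy(dtype=float),
    )
    return view.symmetrized()


def assemble_multiview_graph(
    entities_tsv: str | Path,
    view_files: Sequence[str | Path],
    fasta: str | Path | None = None,
    fingerprints_tsv: str | Path | None = None,
    kmer_k: int = 3,
) -> MultiViewGraph:
    """Read entity/edge/sequence/fingerprint files into a MultiViewGraph.

    View order follows ``view_files`` order and is recorded in the graph.
    Initial node features are attached from the prior-feature builder when
    attribute files are given.
    """
    from . import features as _features

    entities = EntitySet.from_files(entities_tsv, fasta=fasta, fingerprints_tsv=fingerprints_tsv)
    views = [read_view_tsv(p, entities) for p in view_files]
    prior = None
    if entities.fingerprints or entities.sequences:
        prior = _features.build_prior_features(entities, k=kmer_k)
    return MultiViewGraph(entities=entities, views=views, features=prior)


def positives_from_tsv(path: str | Path, entities: EntitySet) -> np.ndarray:
    """Read labeled (drug_id, protein_id) pairs into local (drug, protein)
    kind-index pairs."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    drug_ids = entities.ids_of_kind("drug")
    prot_ids = entities.ids_of_kind("protein")
    dpos = {eid: i for i, eid in enumerate(drug_ids)}
    ppos = {eid: i for i, eid in enumerate(prot_ids)}
    pairs = []
    for row_no, (d, p) in enumerate(zip(df["drug_id"], df["protein_id"]), start=2):
        if d not in dpos or p not in ppos:
            raise ReferentialIntegrityError(f"{path}, line {row_no}: unknown pair ({d!r}, {p!r})")
        pairs.append((dpos[d], ppos[p]))
    return np.array(pairs, dtype=int).reshape(-1, 2)
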