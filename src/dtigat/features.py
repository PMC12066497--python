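"""Prior attribute features for drugs and proteins.

Drugs contribute their fingerprint bits as a 0/1 real vector (f_chem);
proteins contribute a normalized k-mer composition over the 20-letter
amino-acid alphabet (f_seq). The pair-level prior is the concatenation
f_prior = [f_chem ; f_seq], chemical first. These attributes are used
twice by the model: projected into the initial node features, and
concatenated to the pair embedding at the MLP input; each use is
independently switchable for the attribute-ablation variant.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .graphs import AMINO_ACIDS, EntitySet, InputError


def drug_chem_features(fingerprint: np.ndarray, l2_normalize: bool = False) -> np.ndarray:
    """Cast a binary fingerprint to a real vector, optionally L2-normalized."""
    fp = np.asarray(fingerprint)
    if fp.size == 0:
        raise InputError("empty fingerprint")
    out = fp.astype(float).ravel()
    if l2_normalize:
        norm = np.linalg.norm(out)
        if norm > 0:
            out = out / norm
    return out


def kmer_index(kmer: str) -> int:
    """Lexicographic index of a k-mer over the amino-acid alphabet."""
    idx = 0
    for ch in kmer:
        idx = idx * 20 + AMINO_ACIDS.index(ch)
    return idx


def kmer_alphabet(k: int) -> list[str]:
    return ["".join(p) for p in itertools.product(AMINO_ACIDS, repeat=k)]


def protein_seq_features(sequence: str, k: int = 3) -> np.ndarray:
    """Normalized k-mer frequency vector over the 20**k alphabet.

    Entries are non-negative and sum to 1 for non-empty sequences;
    invariant to sequence case. k is limited to {1, 2, 3} (dimension
    20**k grows fast).
    """
    if k not in (1, 2, 3):
        raise InputError(f"k must be in {{1, 2, 3}}, got {k}")
    seq = sequence.upper()
    if len(seq) < k:
        raise InputError(f"sequence of length {len(seq)} shorter than k={k}")
    bad = set(seq) - set(AMINO_ACIDS)
    if bad:
        raise InputError(f"illegal residues {sorted(bad)}")
    vec = np.zeros(20**k)
    for i in range(len(seq) - k + 1):
        vec[kmer_index(seq[i : i + k])] += 1.0
    return vec / vec.sum()


@dataclass
class PriorFeatures:
    """Attribute matrices aligned with the drug / protein kind orderings.

    ``chem`` is (n_drugs, fingerprint_bits); ``seq`` is (n_proteins, 20**k).
    dim(f_prior) = chem_dim + seq_dim.
    """

    drug_ids: list[str]
    protein_ids: list[str]
    chem: np.ndarray
    seq: np.ndarray
    kmer_k: int

    def __post_init__(self) -> None:
        self._drug_row = {d: i for i, d in enumerate(self.drug_ids)}
        self._prot_row = {p: i for i, p in enumerate(self.protein_ids)}

    @property
    def chem_dim(self) -> int:
        return self.chem.shape[1]

    @property
    def seq_dim(self) -> int:
        return self.seq.shape[1]

    @property
    def prior_dim(self) -> int:
        return self.chem_dim + self.seq_dim

    def zeroed(self) -> "PriorFeatures":
        """Attribute-ablation mode: same shapes, all-zero content."""
        return PriorFeatures(
            drug_ids=self.drug_ids,
            protein_ids=self.protein_ids,
            chem=np.zeros_like(self.chem),
            seq=np.zeros_like(self.seq),
            kmer_k=self.kmer_k,
        )


def build_prior_features(entities: EntitySet, k: int = 3, l2_normalize: bool = False) -> PriorFeatures:
    """Assemble f_chem / f_seq matrices for every drug and protein.

    Every drug must have a fingerprint and every protein a sequence; a
    missing attribute is a lookup error (distinct from the ablation mode,
    which zeroes features while keeping shapes).
    """
    drug_ids = entities.ids_of_kind("drug")
    protein_ids = entities.ids_of_kind("protein")
    for d in drug_ids:
        if d not in entities.fingerprints:
            raise LookupError(f"drug {d!r} has no fingerprint")
    for p in protein_ids:
        if p not in entities.sequences:
            raise LookupError(f"protein {p!r} has no sequence")
    chem = np.stack(
        [drug_chem_features(entities.fingerprints[d], l2_normalize) for d in drug_ids]
    ) if drug_ids else np.zeros((0, 0))
    seq = np.stack(
        [protein_seq_features(entities.sequences[p], k) for p in protein_ids]
    ) if protein_ids else np.zeros((0, 20**k))
    return PriorFeatures(drug_ids=drug_ids, protein_ids=protein_ids, chem=chem, seq=seq, kmer_k=k)


def pair_prior(drug_id: str, protein_id: str, features: PriorFeatures) -> np.ndarray:
    """f_prior for one pair: [f_chem ; f_seq], chemical block first."""
    if drug_id not in features._drug_row:
        raise LookupError(f"no chemical features for drug {drug_id!r}")
    if protein_id not in features._prot_row:
        raise LookupError(f"no sequence features for protein {protein_id!r}")
    return np.concatenate(
        [features.chem[features._drug_row[drug_id]], features.seq[features._prot_row[protein_id]]]
    )
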