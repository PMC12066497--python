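"""Graph containers, similarity scorers and file round-trips."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from Bio.Align import substitution_matrices

import dtigat as dg
from dtigat.graphs import (
    AMINO_ACIDS,
    ConfigurationError,
    EntitySet,
    InputError,
    ReferentialIntegrityError,
    SW_EXTEND,
    SW_OPEN,
    ViewGraph,
    mutual_topk_edges,
)

# ---------------------------------------------------------------------------
# Tanimoto
# ---------------------------------------------------------------------------


def test_tanimoto_identity():
    fp = np.array([1, 0, 1, 1, 0])
    assert dg.tanimoto_similarity(fp, fp) == 1.0


def test_tanimoto_disjoint():
    assert dg.tanimoto_similarity(np.array([1, 1, 0, 0]), np.array([0, 0, 1, 1])) == 0.0


def test_tanimoto_hand_counted():
    # |a|=3, |b|=3, |intersection|=2 -> union=4 -> 2/4
    a = np.array([1, 1, 1, 0, 0])
    b = np.array([1, 1, 0, 1, 0])
    assert dg.tanimoto_similarity(a, b) == 0.5


def test_tanimoto_all_zero_convention():
    z = np.zeros(8)
    assert dg.tanimoto_similarity(z, z) == 0.0


def test_tanimoto_length_mismatch():
    with pytest.raises(InputError):
        dg.tanimoto_similarity(np.ones(4), np.ones(5))


# ---------------------------------------------------------------------------
# Smith-Waterman similarity vs an independent Gotoh DP oracle
# ---------------------------------------------------------------------------

_BLOSUM = substitution_matrices.load("BLOSUM62")


def gotoh_local_score(a: str, b: str) -> float:
    """Brute-force local affine-gap DP (gap of length L costs
    OPEN + (L-1)*EXTEND), independent of the library aligner."""
    n, m = len(a), len(b)
    NEG = -1e9
    H = np.zeros((n + 1, m + 1))
    Ix = np.full((n + 1, m + 1), NEG)
    Iy = np.full((n + 1, m + 1), NEG)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            Ix[i][j] = max(H[i - 1][j] + SW_OPEN, Ix[i - 1][j] + SW_EXTEND)
            Iy[i][j] = max(H[i][j - 1] + SW_OPEN, Iy[i][j - 1] + SW_EXTEND)
            H[i][j] = max(0.0, H[i - 1][j - 1] + _BLOSUM[a[i - 1], b[j - 1]],
                          Ix[i][j], Iy[i][j])
            best = max(best, H[i][j])
    return best


def oracle_similarity(a: str, b: str) -> float:
    sab = gotoh_local_score(a, b)
    return min(1.0, sab / np.sqrt(gotoh_local_score(a, a) * gotoh_local_score(b, b)))


def test_sequence_similarity_self_is_one():
    assert dg.sequence_similarity("MKTAYIAK", "MKTAYIAK") == pytest.approx(1.0)


def test_sequence_similarity_matches_dp_oracle_on_printed_pair():
    a, b = "HEAGAWGHEE", "PAWHEAE"
    got = dg.sequence_similarity(a, b)
    assert got == pytest.approx(oracle_similarity(a, b), abs=1e-12)
    # raw local score of this classic pair is 17 under BLOSUM62/-11/-1
    assert gotoh_local_score(a, b) == 17.0


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.data())
def test_sequence_similarity_symmetric_and_matches_oracle(data):
    seq = st.text(alphabet=AMINO_ACIDS, min_size=3, max_size=12)
    a, b = data.draw(seq), data.draw(seq)
    s_ab = dg.sequence_similarity(a, b)
    assert s_ab == pytest.approx(dg.sequence_similarity(b, a), abs=1e-12)
    assert s_ab == pytest.approx(oracle_similarity(a, b), abs=1e-9)
    assert 0.0 <= s_ab <= 1.0


def test_sequence_similarity_rejects_bad_input():
    with pytest.raises(InputError):
        dg.sequence_similarity("", "MKT")
    with pytest.raises(InputError):
        dg.sequence_similarity("MKX1", "MKT")


# ---------------------------------------------------------------------------
# Mutual top-k sparsification
# ---------------------------------------------------------------------------


def brute_force_mutual_topk(sim, k, drop_zero=True):
    s = (np.asarray(sim, float) + np.asarray(sim, float).T) / 2
    n = len(s)
    np.fill_diagonal(s, -np.inf)
    keep = set()
    for i in range(n):
        top = sorted(range(n), key=lambda j: (-s[i][j], j))[:k]
        for j in top:
            if i != j:
                keep.add((i, j))
                keep.add((j, i))
    edges = {(i, j) for (i, j) in keep if np.isfinite(s[i][j])}
    if drop_zero:
        edges = {(i, j) for (i, j) in edges if s[i][j] != 0}
    return edges


def test_three_entities_k2_complete_graph():
    sim = np.array([[0, .5, .2], [.5, 0, .9], [.2, .9, 0]])
    src, dst, _ = mutual_topk_edges(sim, 2)
    assert set(zip(src.tolist(), dst.tolist())) == {
        (0, 1), (1, 0), (0, 2), (2, 0), (1, 2), (2, 1)}


def test_all_zero_similarities_give_empty_edge_set():
    src, dst, w = mutual_topk_edges(np.zeros((4, 4)), 2, drop_zero=True)
    assert len(src) == 0


def test_k1_matches_keep_max_per_row_oracle():
    sim = np.array([
        [0.0, 0.9, 0.1, 0.2, 0.3],
        [0.9, 0.0, 0.4, 0.1, 0.2],
        [0.1, 0.4, 0.0, 0.8, 0.5],
        [0.2, 0.1, 0.8, 0.0, 0.6],
        [0.3, 0.2, 0.5, 0.6, 0.0],
    ])
    src, dst, _ = mutual_topk_edges(sim, 1)
    assert set(zip(src.tolist(), dst.tolist())) == brute_force_mutual_topk(sim, 1)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(n=st.integers(3, 8), k=st.integers(1, 6), seed=st.integers(0, 10_000))
def test_mutual_topk_matches_exhaustive_oracle(n, k, seed):
    if k >= n:
        return
    sim = np.random.default_rng(seed).random((n, n))
    src, dst, w = mutual_topk_edges(sim, k)
    got = set(zip(src.tolist(), dst.tolist()))
    assert got == brute_force_mutual_topk(sim, k)
    s = (sim + sim.T) / 2
    assert np.allclose(w, [s[i, j] for i, j in zip(src, dst)])


def test_k_out_of_range_rejected():
    with pytest.raises(ConfigurationError):
        mutual_topk_edges(np.zeros((3, 3)), 3)


def test_build_similarity_view_uses_pluggable_scorer():
    es = EntitySet(ids=["d0", "d1", "d2", "p0"], kinds=["drug"] * 3 + ["protein"])
    table = {("d0", "d1"): 0.9, ("d0", "d2"): 0.1, ("d1", "d2"): 0.4}

    def scorer(a, b):
        return table.get((a, b), table.get((b, a), 0.0))

    view = dg.build_similarity_view(es, "drug", scorer, k=1, name="dd")
    pairs = set(zip(view.src.tolist(), view.dst.tolist()))
    assert pairs == {(0, 1), (1, 0), (1, 2), (2, 1)}


# ---------------------------------------------------------------------------
# Symmetrization and I/O round-trips
# ---------------------------------------------------------------------------


@settings(max_examples=30, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000), n_edges=st.integers(0, 20))
def test_symmetrization_idempotent(seed, n_edges):
    rng = np.random.default_rng(seed)
    v = ViewGraph("v", "r", rng.integers(0, 6, n_edges),
                  rng.integers(0, 6, n_edges), rng.random(n_edges))
    once = v.symmetrized()
    twice = once.symmetrized()
    assert np.array_equal(once.src, twice.src)
    assert np.array_equal(once.dst, twice.dst)
    assert np.array_equal(once.weight, twice.weight)


def test_view_roundtrip_preserves_edges_exactly(tmp_path):
    es = EntitySet(ids=["a", "b", "c"], kinds=["drug"] * 3)
    v = ViewGraph("sim", "drug-drug-similarity",
                  np.array([0, 1]), np.array([1, 2]),
                  np.array([0.123456789012345, 1 / 3])).symmetrized()
    path = tmp_path / "edges_sim.tsv"
    dg.write_view_tsv(v, es, path)
    back = dg.read_view_tsv(path, es)
    assert np.array_equal(back.src, v.src)
    assert np.array_equal(back.dst, v.dst)
    assert np.array_equal(back.weight, v.weight)  # full float precision


def test_minimal_assembly(tmp_path):
    (tmp_path / "entities.tsv").write_text("id\ttype\nD1\tdrug\nP1\tprotein\n")
    (tmp_path / "edges_x.tsv").write_text(
        "source_id\ttarget_id\tweight\trelation\nD1\tP1\t1.0\tdrug-protein-interaction\n")
    g = dg.assemble_multiview_graph(tmp_path / "entities.tsv", [tmp_path / "edges_x.tsv"])
    assert len(g.entities) == 2
    assert g.n_views == 1
    assert g.views[0].n_edges == 2  # symmetrized pair


def test_unknown_edge_id_names_the_row(tmp_path):
    (tmp_path / "entities.tsv").write_text("id\ttype\nD1\tdrug\n")
    (tmp_path / "edges_x.tsv").write_text(
        "source_id\ttarget_id\tweight\trelation\nD1\tNOPE\t1.0\tr\n")
    with pytest.raises(ReferentialIntegrityError, match="line 2"):
        dg.assemble_multiview_graph(tmp_path / "entities.tsv", [tmp_path / "edges_x.tsv"])


def test_duplicate_entity_id_rejected():
    with pytest.raises(InputError, match="duplicate"):
        EntitySet(ids=["a", "a"], kinds=["drug", "drug"])


def test_synthetic_fixture_roundtrip_fifteen_views(tmp_path):
    cfg = dg.SyntheticConfig(n_drugs=20, n_proteins=20, n_diseases=5,
                             sequence_length=25, fingerprint_bits=16,
                             knn_k=3, seed=2)
    world = dg.generate_world(cfg)
    dg.write_fixtures(world, dg.generate_views(world, cfg), tmp_path)
    edge_files = sorted(tmp_path.glob("edges_*.tsv"))
    g = dg.assemble_multiview_graph(tmp_path / "entities.tsv", edge_files,
                                    fasta=tmp_path / "proteins.fasta",
                                    fingerprints_tsv=tmp_path / "fingerprints.tsv",
                                    kmer_k=1)
    assert g.n_views == 15
    assert g.features is not None
    assert g.features.chem.shape == (20, 16)
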