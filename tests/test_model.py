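"""Attention, message passing, fusion and the pair scorer."""

import numpy as np
import pytest

import dtigat as dg
from dtigat import autodiff as ad
from dtigat.graphs import ConfigurationError

from helpers import permuted_scores_match


# ---------------------------------------------------------------------------
# Attention scores
# ---------------------------------------------------------------------------


def test_attention_singleton_neighborhood():
    w = dg.attention_scores(np.array([1.0]), np.array([[2.0]]),
                            Wq=np.array([[1.0]]), Wk=np.array([[1.0]]))
    assert np.array_equal(w, [1.0])


def test_attention_equal_dot_products_uniform():
    node = np.array([1.0, 0.0])
    nbrs = np.array([[1.0, 1.0]] * 4)
    w = dg.attention_scores(node, nbrs, Wq=np.eye(2), Wk=np.eye(2))
    assert np.allclose(w, 0.25)


def test_attention_closed_form_quarter_three_quarters():
    # logits (0, ln 3) -> softmax (0.25, 0.75)
    node = np.array([1.0])
    nbrs = np.array([[0.0], [np.log(3.0)]])
    w = dg.attention_scores(node, nbrs, Wq=np.array([[1.0]]), Wk=np.array([[1.0]]))
    assert np.allclose(w, [0.25, 0.75])


def test_attention_rows_sum_to_one_in_model(tiny_trained):
    # normalization inside the trained model: softmax over each mask row
    model = tiny_trained.model
    h = model.initial_features()
    vp = model.pack.views[0]
    ha = ad.gather_rows(h, vp.active)
    q = ad.matmul(ha, model.params["Wq_0_0_0"])
    k = ad.matmul(ha, model.params["Wk_0_0_0"])
    attn = ad.masked_softmax(ad.matmul_t(q, k), vp.mask)
    assert np.allclose(attn.data.sum(axis=1), 1.0)
    assert np.all(attn.data >= 0)


# ---------------------------------------------------------------------------
# Message passing
# ---------------------------------------------------------------------------


def _mask(n, edges, self_loops=True):
    m = np.zeros((n, n), dtype=bool)
    for i, j in edges:
        m[i, j] = m[j, i] = True
    if self_loops:
        np.fill_diagonal(m, True)
    return m


def test_zero_features_give_zero_output():
    h = np.zeros((4, 3))
    out = dg.message_pass(h, _mask(4, [(0, 1), (2, 3)]), W=np.eye(3),
                          Wq=np.eye(3), Wk=np.eye(3))
    assert np.all(out == 0)


def test_single_neighbor_identity_passthrough():
    h = np.array([[0.0, 0.0], [2.0, 5.0]])
    mask = np.array([[False, True], [False, True]])  # node 0 sees only node 1
    out = dg.message_pass(h, mask, W=np.eye(2), Wq=np.eye(2), Wk=np.eye(2))
    assert np.allclose(out[0], [2.0, 5.0])


def test_weighted_sum_hand_example():
    # weights (0.25, 0.75) over h1=(4,0), h2=(0,4) -> ReLU(1,3)
    h = np.array([[1.0, 0.0, 1.0],
                  [4.0, 0.0, 0.0],
                  [0.0, 4.0, 0.0]])
    mask = np.array([[False, True, True],
                     [False, True, False],
                     [False, False, True]])
    Wq = np.array([[0.0], [0.0], [1.0]])          # q_0 = 1
    Wk = np.array([[0.0], [np.log(3) / 4], [0.0]])  # K_1 = 0, K_2 = ln3
    W = np.eye(3)
    out = dg.message_pass(h, mask, W=W, Wq=Wq, Wk=Wk)
    assert np.allclose(out[0], [1.0, 3.0, 0.0])


def test_gcn_singleton_equivalence():
    h = np.array([[1.5, 2.0], [3.0, 1.0]])
    mask = np.array([[False, True], [True, False]])
    att = dg.message_pass(h, mask, W=np.eye(2), Wq=np.eye(2), Wk=np.eye(2))
    gcn = dg.gcn_message_pass(h, mask, W=np.eye(2))
    assert np.array_equal(att, gcn)


def test_gcn_four_neighbor_mean():
    h = np.vstack([np.zeros(2), np.array([[4, 0], [0, 4], [2, 2], [6, 2]])])
    mask = np.zeros((5, 5), dtype=bool)
    mask[0, 1:] = True
    for i in range(1, 5):
        mask[i, i] = True
    out = dg.gcn_message_pass(h, mask, W=np.eye(2))
    assert np.allclose(out[0], [3.0, 2.0])  # mean of the four neighbors


@pytest.mark.parametrize("seed", range(5))
def test_uniform_logit_attention_equals_gcn_bitwise(seed):
    """Forcing all attention logits equal (zero Q/K maps) reproduces the
    uniform-aggregation variant exactly, bit for bit."""
    rng = np.random.default_rng(seed)
    n, d = 20, 6
    h = rng.normal(size=(n, d))
    edges = {(int(a), int(b)) for a, b in rng.integers(0, n, (40, 2)) if a != b}
    mask = _mask(n, edges)
    W = rng.normal(size=(d, d))
    att = dg.message_pass(h, mask, W=W, Wq=np.zeros((d, d)), Wk=np.zeros((d, d)))
    gcn = dg.gcn_message_pass(h, mask, W=W)
    assert np.array_equal(att, gcn)


def test_hidden_embeddings_nonnegative(tiny_trained):
    for h in tiny_trained.model.encode_views():
        assert np.all(h.data >= 0)


# ---------------------------------------------------------------------------
# Fusion
# ---------------------------------------------------------------------------


def test_fusion_single_view_is_identity():
    h = np.array([[1.0, 2.0], [3.0, 4.0]])
    assert np.allclose(dg.fuse_views([h], np.array([-7.3])), h)


def test_fusion_identical_views_any_logits():
    h = np.array([[1.0, 2.0]])
    z = dg.fuse_views([h, h, h], np.array([5.0, -2.0, 0.1]))
    assert np.allclose(z, h)


def test_fusion_half_half_hand_example():
    z = dg.fuse_views([np.array([[2.0, 0.0]]), np.array([[0.0, 2.0]])],
                      np.array([0.0, 0.0]))
    assert np.allclose(z, [[1.0, 1.0]])


def test_fusion_weights_positive_and_sum_to_one(tiny_trained):
    alpha = tiny_trained.model.fusion_alpha()
    assert np.all(alpha > 0)
    assert alpha.sum() == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# Pair scoring and serialization
# ---------------------------------------------------------------------------


def test_scores_strictly_inside_unit_interval(tiny_trained, tiny_folds):
    s = tiny_trained.model.forward_scores(tiny_folds[0].test_pairs)
    assert np.all(s > 0) and np.all(s < 1)


def test_zero_mlp_weights_score_half(tiny_graph, micro_model_config):
    pack = dg.prepare_graph(tiny_graph)
    model = dg.DTGModel(pack, micro_model_config, seed=0)
    state = model.state_dict()
    for k in state:
        if k.startswith("mlp_"):
            state[k] = np.zeros_like(state[k])
    model.load_state_dict(state)
    assert model.predict_pair(0, 0) == 0.5


def test_repeat_and_serialization_roundtrip_scores(tiny_trained, tiny_graph,
                                                   tiny_folds, tmp_path):
    model = tiny_trained.model
    probe = tiny_folds[0].test_pairs[:10]
    s1 = model.forward_scores(probe)
    s2 = model.forward_scores(probe)
    assert np.array_equal(s1, s2)
    path = tmp_path / "model.npz"
    model.save(path)
    back = dg.DTGModel.load(path, dg.prepare_graph(tiny_graph))
    assert np.array_equal(back.forward_scores(probe), s1)


def test_permutation_equivariance_of_pair_scores(tiny_world, tiny_config, tiny_folds):
    ok, before, after = permuted_scores_match(tiny_world, tiny_config, tiny_folds[0])
    assert ok, np.abs(before - after).max()


def test_model_config_validation():
    with pytest.raises(ConfigurationError):
        dg.ModelConfig(mlp_layers=5)
    with pytest.raises(ConfigurationError):
        dg.ModelConfig(embed_dim=10, n_heads=3)
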