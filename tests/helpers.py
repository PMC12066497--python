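"""Shared test utilities: brute-force oracles and the permutation probe."""

import numpy as np

import dtigat as dg


def brute_force_auc(labels, scores):
    """All-pairs Mann-Whitney comparison (ties count one half)."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


def brute_force_aupr(labels, scores):
    """Exhaustive threshold sweep with step-wise precision."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    n_pos = labels.sum()
    area = 0.0
    prev_recall = 0.0
    for t in sorted(set(scores), reverse=True):
        pred = scores >= t
        tp = int(np.sum(pred & (labels == 1)))
        fp = int(np.sum(pred & (labels == 0)))
        recall = tp / n_pos
        precision = tp / (tp + fp)
        area += (recall - prev_recall) * precision
        prev_recall = recall
    return area


def permuted_scores_match(world, cfg, fold, seed=0, atol=1e-9):
    """Score a probe set of pairs, consistently permute every node-indexed
    object (entities, edges, free embeddings), rescore, and compare."""
    graph = dg.build_fold_graph(world, cfg, fold, kmer_k=1)
    mc = dg.ModelConfig(embed_dim=8, mlp_hidden=8, dtype="float64")
    pack = dg.prepare_graph(graph)
    model = dg.DTGModel(pack, mc, seed=seed)
    probe = fold.test_pairs[: min(20, len(fold.test_pairs))]
    before = model.forward_scores(probe)

    n = len(graph.entities)
    rng = np.random.default_rng(seed + 1)
    perm = rng.permutation(n)  # new index i holds old node perm[i]
    inv = np.empty(n, dtype=int)
    inv[perm] = np.arange(n)

    ids2 = [graph.entities.ids[perm[i]] for i in range(n)]
    kinds2 = [graph.entities.kinds[perm[i]] for i in range(n)]
    es2 = dg.EntitySet(ids=ids2, kinds=kinds2)
    es2.fingerprints.update(graph.entities.fingerprints)
    es2.sequences.update(graph.entities.sequences)
    views2 = [
        dg.ViewGraph(v.name, v.relation, inv[v.src], inv[v.dst], v.weight.copy())
        for v in graph.views
    ]
    from dtigat.features import build_prior_features

    g2 = dg.MultiViewGraph(entities=es2, views=views2,
                           features=build_prior_features(es2, k=1))
    pack2 = dg.prepare_graph(g2)
    model2 = dg.DTGModel(pack2, mc, seed=seed)
    state = model.state_dict()
    state["node_emb"] = state["node_emb"][perm]
    model2.load_state_dict(state)

    # map old (drug, protein) kind-local indices to the permuted ordering
    old_d, old_p = graph.entities.indices_of_kind("drug"), graph.entities.indices_of_kind("protein")
    new_d, new_p = es2.indices_of_kind("drug"), es2.indices_of_kind("protein")
    d_map = {g: i for i, g in enumerate(new_d)}
    p_map = {g: i for i, g in enumerate(new_p)}
    probe2 = np.array([
        [d_map[inv[old_d[d]]], p_map[inv[old_p[p]]]] for d, p in probe
    ])
    after = model2.forward_scores(probe2)
    return np.allclose(before, after, atol=atol), before, after
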