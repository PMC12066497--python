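"""Shared fixtures: small synthetic worlds and trained micro-models."""

import numpy as np
import pytest

import dtigat as dg


@pytest.fixture(scope="session")
def tiny_config():
    return dg.SyntheticConfig(
        n_drugs=30, n_proteins=25, n_diseases=8, n_views=5,
        fingerprint_bits=32, sequence_length=40, knn_k=4, seed=11,
    )


@pytest.fixture(scope="session")
def tiny_world(tiny_config):
    return dg.generate_world(tiny_config)


@pytest.fixture(scope="session")
def tiny_folds(tiny_world, tiny_config):
    return dg.build_fold_data(
        tiny_world.positives,
        (tiny_config.n_drugs, tiny_config.n_proteins),
        k=2, seed=5,
    )


@pytest.fixture(scope="session")
def tiny_graph(tiny_world, tiny_config, tiny_folds):
    return dg.build_fold_graph(tiny_world, tiny_config, tiny_folds[0], kmer_k=1)


@pytest.fixture(scope="session")
def micro_model_config():
    return dg.ModelConfig(embed_dim=8, mlp_hidden=8, dtype="float64")


@pytest.fixture(scope="session")
def tiny_trained(tiny_graph, tiny_folds, micro_model_config):
    tc = dg.TrainConfig(seed=3, max_epochs=8, patience=8, lr=5e-3)
    return dg.train_model(tiny_graph, tiny_folds[0], micro_model_config, tc)
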