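import warnings

import numpy as np
import pytest

import funcmap as fm


@pytest.fixture(scope="session")
def small_dataset():
    """Default-condition synthetic bundle at desk scale (n=300, tiny graph)."""
    cfg = fm.SyntheticConfig(
        n_subjects=300, seed=7, n_regions=8, planted_edges_per_factor=2
    )
    return fm.generate_dataset(cfg)


@pytest.fixture(scope="session")
def planted_edge_dataset():
    """Connectivity bundle with 50 planted edges per factor among 2016."""
    cfg = fm.SyntheticConfig(
        n_subjects=200,
        n_regions=64,
        planted_edges_per_factor=50,
        edge_effect_size=0.6,
        edge_noise_sd=1.0,
        seed=11,
    )
    return fm.generate_dataset(cfg)


@pytest.fixture(scope="session")
def planted_edge_matrix(planted_edge_dataset):
    from funcmap.connectivity import edge_index_map, vectorize_edges

    ds = planted_edge_dataset
    E = np.stack([vectorize_edges(M) for M in ds.connectivity])
    emap = edge_index_map(ds.connectivity[0].shape[0])
    pos = {(r.i, r.j): r.edge for r in emap.itertuples()}
    planted = {f: {pos[e] for e in edges} for f, edges in ds.planted_edge_index.items()}
    return E, emap, planted


@pytest.fixture(scope="session")
def fitted_model(small_dataset):
    X = small_dataset.responses.T.astype(float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        model = fm.fit_opnmf(X, 2, seed=0)
    return X, model


@pytest.fixture
def cheap_rcc_config():
    return fm.RccConfig(
        outer_folds=5,
        outer_repeats=2,
        inner_folds=3,
        inner_search_iters=3,
        bootstrap_reps=20,
        n_features_min=50,
        n_features_max=300,
        perm_outer_repeats=1,
        seed=0,
    )
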