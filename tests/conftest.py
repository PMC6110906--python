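import dataclasses

import numpy as np
import pytest

from foldnet import pipeline as pl
from foldnet import synthetic_cortex as syn


@pytest.fixture(scope="session")
def paradigm():
    return syn.make_paradigm()


@pytest.fixture(scope="session")
def mesh():
    return syn.make_surface(32, 8, fold_period=8.0)


@pytest.fixture(scope="session")
def desk_config():
    return pl.PipelineConfig(seed=1)


@pytest.fixture(scope="session")
def desk_report(desk_config):
    """One full desk-scale pipeline run, shared across test modules."""
    return pl.run_pipeline(desk_config)


@pytest.fixture(scope="session")
def tiny_config():
    """Fast configuration for CLI / cohort / null-calibration tests."""
    return pl.PipelineConfig(seed=0, nx=32, ny=16, k_networks=2,
                             rois_per_network=2, m_atoms=20, n_perm=400)


def run_with_seed(cfg, seed):
    return pl.run_pipeline(dataclasses.replace(cfg, seed=seed))


@pytest.fixture(scope="session")
def null_runs(tiny_config):
    """200 seeded delta=0 pipeline runs: list of (observed_diff, p_perm)."""
    cfg0 = dataclasses.replace(tiny_config, delta=0.0)
    out = []
    for s in range(200):
        rep = run_with_seed(cfg0, 5000 + s)
        net = rep.network_tests.iloc[0]
        out.append((float(net["observed_diff"]), float(net["p_permutation"])))
    return out


def greedy_match_count(D_true, D_learned, threshold=0.9):
    """Greedy one-to-one atom matching by maximal |cosine|; low index wins ties."""
    Dt = D_true / np.maximum(np.linalg.norm(D_true, axis=0), 1e-12)
    Dl = D_learned / np.maximum(np.linalg.norm(D_learned, axis=0), 1e-12)
    C = np.abs(Dt.T @ Dl)
    hits = 0
    for _ in range(C.shape[0]):
        i, j = np.unravel_index(np.argmax(C), C.shape)
        if C[i, j] > threshold:
            hits += 1
        C[i, :] = -1.0
        C[:, j] = -1.0
    return hits


@pytest.fixture(scope="session")
def planted_dictionary_problem():
    """t=50, 20 unit atoms, 2000 signals, 3-sparse + sd 0.01 noise."""
    rng = np.random.default_rng(1)
    t, m, n = 50, 20, 2000
    D_true = rng.normal(size=(t, m))
    D_true /= np.linalg.norm(D_true, axis=0)
    X = np.zeros((t, n))
    for j in range(n):
        idx = rng.choice(m, 3, replace=False)
        coef = rng.uniform(0.5, 1.5, 3) * rng.choice([-1.0, 1.0], 3)
        X[:, j] = D_true[:, idx] @ coef + rng.normal(scale=0.01, size=t)
    return D_true, X
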