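import numpy as np
import pytest

import tetragp as tg


@pytest.fixture(scope="session")
def small_pop():
    """100 individuals x 400 markers, weak 2-subpop structure."""
    cfg = tg.SimulationConfig(
        n_individuals=100, n_markers=400, n_subpops=2, structure_strength=0.02, seed=42
    )
    dm, labels = tg.simulate_dosages(cfg)
    return dm, labels


@pytest.fixture(scope="session")
def hwe_pop():
    """Unstructured population for HWE-based expectations."""
    cfg = tg.SimulationConfig(
        n_individuals=200, n_markers=1000, n_subpops=1, structure_strength=0.0, seed=7
    )
    dm, _ = tg.simulate_dosages(cfg)
    return dm


def additive_trait(dm, h2, seed, n_qtl=None):
    """Additive polygenic phenotype with heritability h2 on the BLUE scale."""
    rng = np.random.default_rng(seed)
    X = dm.dosages
    m = X.shape[1]
    q = m if n_qtl is None else n_qtl
    qtl = rng.choice(m, q, replace=False)
    g = (X[:, qtl] - X[:, qtl].mean(axis=0)) @ rng.standard_normal(q)
    g = (g - g.mean()) / g.std()
    if h2 <= 0:
        return np.zeros(len(g)), rng.standard_normal(len(g))
    e = rng.normal(0, np.sqrt((1 - h2) / h2), len(g))
    return g, g + e
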