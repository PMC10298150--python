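import numpy as np
import pytest

from kgxpress.synthetic_data import SyntheticConfig, generate


@pytest.fixture(scope="session")
def default_bundle():
    """One generated bundle + truth shared by read-only tests."""
    return generate(SyntheticConfig(seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def two_cluster_matrix(rng, n_per_cluster=10, n_families=40, flip=0.05):
    """Binary gene x family matrix with two planted profile clusters."""
    template_a = (rng.random(n_families) < 0.5).astype(np.int8)
    template_b = 1 - template_a
    rows, genes, labels = [], [], []
    for c, template in enumerate((template_a, template_b)):
        for i in range(n_per_cluster):
            noise = rng.random(n_families) < flip
            rows.append(np.where(noise, 1 - template, template).astype(np.int8))
            genes.append(f"g{c}{i:02d}")
            labels.append(c)
    return genes, np.array(rows), np.array(labels)
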