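"""Shared fixtures: one small synthetic bundle and its pipeline products."""
import numpy as np
import pytest

import scburden as sb


SMALL_SIZES = {"neurons": 60, "astrocytes": 40, "oligodendrocytes": 40}


def small_config(seed=7, **kwargs):
    defaults = dict(seed=seed, n_genes=400, cell_type_sizes=dict(SMALL_SIZES),
                    n_markers_per_type=20)
    defaults.update(kwargs)
    return sb.SynthConfig(**defaults)


@pytest.fixture(scope="session")
def bundle():
    return sb.generate_all(small_config())


@pytest.fixture(scope="session")
def clustering(bundle):
    labeling, norm, pcs = sb.scpipe.run_clustering(bundle.counts, n_hvg=300,
                                                   seed=1)
    return labeling, norm, pcs


@pytest.fixture(scope="session")
def consensus_degs(clustering):
    labeling, norm, _ = clustering
    return sb.de.run_consensus_de(norm, labeling)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
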