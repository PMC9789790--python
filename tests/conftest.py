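import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")

import graphdeconv as gd
from graphdeconv import synthetic_data as sd


@pytest.fixture(scope="session")
def easy_dataset():
    """Blocks-layout tissue with 3 well-separated types plus its reference."""
    cfg = gd.SyntheticConfig(seed=11)  # marker_fold=8, blocks layout by default
    ref, ann = sd.simulate_reference(cfg)
    tissue = sd.simulate_spatial_tissue(cfg, (ref, ann))
    st, coords, truth = sd.make_visium_like(cfg, tissue)
    return {
        "cfg": cfg,
        "ref": ref,
        "ann": ann,
        "tissue": tissue,
        "st": st,
        "coords": coords,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def pipeline_config():
    """Operating point scaled to the synthetic fixture's 200-gene regime."""
    return gd.PipelineConfig(
        top_k_genes=100, n_pseudo=4000, ae_hidden=64, knn_k=100, seed=3
    )


@pytest.fixture(scope="session")
def easy_result(easy_dataset, pipeline_config):
    """One full pipeline run on the easy fixture, shared across tests."""
    d = easy_dataset
    return gd.deconvolve(
        d["st"], d["coords"], d["ref"], d["ann"], pipeline_config, truth=d["truth"]
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
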