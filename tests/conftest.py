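import numpy as np
import pytest

from linkseg import simulate
from linkseg.embeddings import reference_embedding
from linkseg.graph import GraphConfig, build_dataset
from linkseg.model import ModelConfig, train


@pytest.fixture(scope="session")
def tissue_small():
    """A tiny tissue patch for fast unit-level tests."""
    return simulate(n_cells=30, extent=(80.0, 80.0), seed=3)


@pytest.fixture(scope="session")
def tissue_default():
    """The standard study conditions (default parameters, seed 0)."""
    return simulate(seed=0)


@pytest.fixture(scope="session")
def tissue_noiseless():
    """No diffusion, every cell nucleated: the sanity-oracle regime."""
    return simulate(seed=0, diffusion_fraction=0.0, nucleus_free_fraction=0.0)


def _train_on(tissue, **model_overrides):
    emb = reference_embedding(tissue.reference, d=len(tissue.reference.cell_types))
    cfg = GraphConfig()
    plan, graphs, stats = build_dataset(tissue.transcripts, tissue.nuclei, emb, cfg)
    mcfg = ModelConfig(seed=0, **model_overrides)
    model = train(graphs, mcfg, emb, cfg, stats)
    return model


@pytest.fixture(scope="session")
def model_default(tissue_default):
    return _train_on(tissue_default)


@pytest.fixture(scope="session")
def model_noiseless(tissue_noiseless):
    return _train_on(tissue_noiseless)


@pytest.fixture(scope="session")
def graphs_small(tissue_small):
    emb = reference_embedding(tissue_small.reference, d=len(tissue_small.reference.cell_types))
    cfg = GraphConfig()
    plan, graphs, stats = build_dataset(tissue_small.transcripts, tissue_small.nuclei, emb, cfg)
    return {"plan": plan, "graphs": graphs, "stats": stats, "embedding": emb, "cfg": cfg}
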