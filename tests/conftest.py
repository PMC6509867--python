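import numpy as np
import pytest

from stagewise import ingest, synthio


@pytest.fixture(scope="session")
def small_cfg() -> synthio.SynthConfig:
    """A scaled-down study: quick to generate, still has recoverable signal."""
    return synthio.SynthConfig(
        n_samples=120,
        n_genes=200,
        signal_genes_per_stage=8,
        effect_size=2.0,
        noise_sd=1.0,
        ppi_mean_degree=6.0,
        n_pathways=30,
        pathway_size_range=(8, 20),
        seed=11,
    )


@pytest.fixture(scope="session")
def small_world(small_cfg):
    """Generated omics + clinical + truth for the small study."""
    expr, meth, clinical, truth = synthio.gen_omics(small_cfg)
    edges = synthio.gen_ppi(small_cfg, truth)
    pathways = synthio.gen_pathways(small_cfg, truth)
    return {
        "cfg": small_cfg,
        "expr": expr,
        "meth": meth,
        "clinical": clinical,
        "truth": truth,
        "ppi_edges": edges,
        "pathways": pathways,
    }


@pytest.fixture(scope="session")
def small_features(small_world):
    """FeatureMatrix + stage labels assembled from the small study."""
    expr, meth = small_world["expr"], small_world["meth"]
    el = ingest.OmicsLayer(
        values=expr.T, gene_of_feature={g: g for g in expr.index}, layer="expression"
    )
    ml = ingest.OmicsLayer(
        values=meth.T, gene_of_feature={g: g for g in meth.index}, layer="methylation"
    )
    labels = ingest.binarize_stages(small_world["clinical"])
    X = ingest.assemble_features(el, ml, labels[0].sample_ids)
    return X, labels


def random_regression(rng: np.random.Generator, m: int, n: int):
    """A small standardized regression instance with a few true effects."""
    X = rng.normal(size=(m, n))
    X = (X - X.mean(axis=0)) / X.std(axis=0)
    beta = np.zeros(n)
    k = max(1, n // 4)
    beta[rng.choice(n, size=k, replace=False)] = rng.normal(scale=2.0, size=k)
    y = X @ beta + rng.normal(scale=0.5, size=m)
    return X, y
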