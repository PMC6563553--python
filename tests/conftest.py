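import numpy as np
import pandas as pd
import pytest

from coexdiv.io_pipeline import CountMatrix, ExpressionMatrix, SampleMetadata


def make_metadata(n, stage="1dph", morphs=None, prefix="s"):
    morphs = morphs if morphs is not None else ["benthic"] * n
    return SampleMetadata(
        pd.DataFrame(
            {
                "sample_id": [f"{prefix}{i}" for i in range(n)],
                "stage": stage,
                "morph": morphs,
                "species": "sp",
                "lake": "lake",
            }
        )
    )


def make_expression(values, metadata=None, genes=None):
    """samples x genes array -> ExpressionMatrix with generated ids."""
    values = np.asarray(values, float)
    n, p = values.shape
    metadata = metadata or make_metadata(n)
    genes = genes or [f"g{j}" for j in range(p)]
    return ExpressionMatrix(
        pd.DataFrame(values, index=metadata.sample_ids, columns=genes), metadata
    )


def planted_expression(rng, n_samples, module_sizes, n_noise, loading=(0.6, 0.9)):
    """Gaussian module data: blocks driven by independent latent scores."""
    blocks, labels = [], []
    for mi, size in enumerate(module_sizes):
        s = rng.standard_normal(n_samples)
        a = rng.uniform(*loading, size)
        blocks.append(a * s[:, None] + np.sqrt(1 - a**2) * rng.standard_normal((n_samples, size)))
        labels += [f"M{mi + 1}"] * size
    blocks.append(rng.standard_normal((n_samples, n_noise)))
    labels += ["none"] * n_noise
    return np.hstack(blocks), labels


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_counts():
    meta = make_metadata(4, morphs=["benthic", "benthic", "limnetic", "limnetic"])
    frame = pd.DataFrame(
        np.array([[10, 20, 30, 40], [5, 5, 5, 5], [100, 200, 150, 120]]),
        index=["gA", "gB", "gC"],
        columns=meta.sample_ids,
    )
    return CountMatrix(frame, meta)
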