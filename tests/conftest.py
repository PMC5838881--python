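import numpy as np
import pytest

from pairlim import MultiOmicsDataset, OmicsMatrix, SampleMetadata
from pairlim.simulate import SyntheticSpec, generate

import pandas as pd


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_dataset():
    """Seeded 12-sample, 3-gene x 2-metabolite dataset with planted signal."""
    rng = np.random.default_rng(77)
    samples = [f"S{i}" for i in range(12)]
    pheno = np.array([0] * 6 + [1] * 6)
    G = rng.normal(8, 1, size=(3, 12))
    M = np.empty((2, 12))
    M[0] = 10 + 0.8 * G[0] + 1.5 * G[0] * pheno + rng.normal(0, 0.5, 12)
    M[1] = 12 - 0.3 * G[1] + rng.normal(0, 0.5, 12)
    meta = SampleMetadata(
        pd.DataFrame(
            {"phenotype": np.where(pheno == 0, "ctrl", "case")},
            index=pd.Index(samples, name="sample_id"),
        ),
        "phenotype",
    )
    return MultiOmicsDataset(
        genes=OmicsMatrix([f"G{i}" for i in range(3)], samples, G, "gene"),
        metabolites=OmicsMatrix(["M0", "M1"], samples, M, "metabolite"),
        metadata=meta,
        phenotype_encoding={"ctrl": 0, "case": 1},
    )


@pytest.fixture
def signal_data():
    """Synthetic dataset with 5% interacting pairs and strong signal."""
    return generate(
        SyntheticSpec(
            seed=123,
            n_genes=40,
            n_metabolites=20,
            fraction_interacting=0.025,
            beta4_magnitude=2.0,
            baseline_slope=-1.0,
            noise_sd=0.3,
        )
    )


def random_matrix(rng, n_features=8, n_samples=6, layer="metabolite", missing=0.0, prefix="F"):
    vals = rng.uniform(1, 100, size=(n_features, n_samples))
    if missing:
        mask = rng.random(vals.shape) < missing
        vals[mask] = np.nan
    return OmicsMatrix(
        [f"{prefix}{i:03d}" for i in range(n_features)],
        [f"S{j:02d}" for j in range(n_samples)],
        vals,
        layer,
    )
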