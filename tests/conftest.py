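import numpy as np
import pandas as pd
import pytest

import grexcontact as gc


@pytest.fixture(scope="session")
def small_config():
    return gc.SimConfig(
        n_samples=200,
        n_ernas=40,
        n_genes=25,
        genome_length=1_000_000,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return gc.simulate_study(small_config)


@pytest.fixture(scope="session")
def planted_pairs():
    """A mid-size pair-level benchmark with a known noiseless signal."""
    ds, noiseless = gc.planted_link_dataset(6000, seed=11)
    return ds, noiseless


def make_genotypes(n_samples, n_variants, maf=0.3, seed=0, spacing=1000, chrom="chrS"):
    rng = np.random.default_rng(seed)
    dosage = rng.binomial(2, maf, size=(n_samples, n_variants)).astype(float)
    variants = pd.DataFrame(
        {
            "variant_id": [f"v{i:04d}" for i in range(n_variants)],
            "chrom": chrom,
            "pos": np.arange(n_variants) * spacing + spacing // 2,
            "maf": maf,
        }
    )
    return gc.GenotypeMatrix(dosage, variants, [f"s{i}" for i in range(n_samples)])
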