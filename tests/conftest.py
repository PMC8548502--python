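import numpy as np
import pandas as pd
import pytest

from plastisel.simulate import (GeneratorConfig, generate_expression_dataset,
                                generate_variant_dataset)


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale generator configuration reused across tests."""
    return GeneratorConfig(n_genes=400, n_candidates=60, n_snps=1200, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    meta, counts, truth = generate_expression_dataset(small_config)
    return meta, counts, truth


@pytest.fixture(scope="session")
def small_variants(small_config, small_dataset):
    meta, _, truth = small_dataset
    return generate_variant_dataset(small_config, truth, meta)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def toy_metadata(groups):
    """Build a metadata frame from (n, municipality, habitat, rearing,
    treatment) tuples; ctmax is filled with a simple ramp."""
    rows = []
    for n, muni, habitat, rearing, treatment in groups:
        for _ in range(n):
            rows.append({"municipality": muni, "habitat": habitat,
                         "rearing": rearing, "treatment": treatment})
    meta = pd.DataFrame(rows)
    meta.index = [f"T{i:03d}" for i in range(len(meta))]
    meta.index.name = "sample_id"
    meta["ctmax_C"] = 36.0 + np.arange(len(meta)) * 0.05
    return meta
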