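import numpy as np
import pandas as pd
import pytest

from mqtl import synthetic as syn


@pytest.fixture(scope="session")
def demo_panel():
    """Small multi-block panel shared by read-only tests."""
    return syn.simulate_genotypes(
        400,
        [(8, 0.8, (0.2, 0.5)), (8, 0.8, (0.2, 0.5)), (8, 0.3, (0.1, 0.4))],
        seed=7,
    )


@pytest.fixture(scope="session")
def demo_covariates():
    return syn.simulate_covariates(400, seed=8)


def make_assoc_table(rows):
    """Association-table helper for locus/coloc tests."""
    df = pd.DataFrame(rows)
    defaults = {"ref": "A", "alt": "G", "eaf": 0.3, "beta": 0.5, "se": 0.05, "n": 1000}
    for k, v in defaults.items():
        if k not in df.columns:
            df[k] = v
    if "snp" not in df.columns:
        df["snp"] = [f"snp{i}" for i in range(len(df))]
    df["chrom"] = df["chrom"].astype(str)
    return df


@pytest.fixture
def assoc_builder():
    return make_assoc_table
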