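"""Shared fixtures: one small synthetic population reused across test modules."""

import numpy as np
import pandas as pd
import pytest

from mqtlkit import features, gwas, simulate


@pytest.fixture(scope="session")
def geno_small():
    geno, _ = simulate.generate_genotypes(
        n_lines=120, n_snps=600, n_subpops=2, seed=11)
    return geno


@pytest.fixture(scope="session")
def kinship_small(geno_small):
    return gwas.kinship(geno_small)


@pytest.fixture(scope="session")
def metabolome_small(geno_small):
    """Feature tables with strong drought shifts, redundancy and missingness."""
    ww, ds, truth = simulate.generate_metabolome(
        geno_small, n_metabolites=150, n_causal=15, pve=0.2,
        drought_frac=0.25, fc_log2_mean=2.0, missing_rate=0.08,
        redundancy=0.4, seed=12)
    return ww, ds, truth


@pytest.fixture(scope="session")
def processed_small(metabolome_small):
    ww, ds, _ = metabolome_small
    return features.process_feature_tables(ww, ds)


@pytest.fixture()
def rng():
    return np.random.default_rng(2026)


def toy_matrix(values, condition="WW", log_transformed=True):
    """Helper: MetaboliteMatrix from a plain array (lines x metabolites)."""
    from mqtlkit.containers import MetaboliteMatrix

    arr = np.asarray(values, dtype=float)
    df = pd.DataFrame(arr, index=[f"L{i}" for i in range(arr.shape[0])],
                      columns=[f"M{j}" for j in range(arr.shape[1])])
    return MetaboliteMatrix(values=df, condition=condition,
                            log_transformed=log_transformed)
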