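import dataclasses

import numpy as np
import pandas as pd
import pytest

from dcgwas.containers import GenotypeMatrix
from dcgwas.pipeline import default_study_config, run_pipeline
from dcgwas.simulate import EffectSpec, SimulationConfig, simulate_cohorts


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A down-scaled study: same structure, a few hundred samples."""
    return dataclasses.replace(
        default_study_config(seed=3),
        n_case=400, n_ctrl_a=150, n_ctrl_b=300,
        m_common=300, m_rare_per_gene=4, n_genes=60, batch_size=8000,
        effect_table=[
            EffectSpec("v00010", "case_disease", 1.5),
            EffectSpec("v00020", "ctrl_a_disease", 2.0),
            EffectSpec("G0005", "case_disease", 1.6),
        ],
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return simulate_cohorts(small_config)


@pytest.fixture(scope="session")
def small_pipeline(small_config):
    return run_pipeline(small_config, n_perm=500)


def toy_matrix(dosages, gq=None, ad_ref=None, ad_alt=None, chrom="1"):
    """Build a GenotypeMatrix from a plain nested list of dosages."""
    d = np.asarray(dosages, dtype=np.int8)
    n, m = d.shape
    variants = pd.DataFrame(
        {
            "chrom": [chrom] * m,
            "pos": np.arange(1, m + 1) * 1000,
            "ref": ["A"] * m,
            "alt": ["G"] * m,
        },
        index=pd.Index([f"var{j}" for j in range(m)], name="variant_id"),
    )
    def arr(x, dtype):
        return None if x is None else np.asarray(x, dtype=dtype)
    return GenotypeMatrix(
        dosages=d,
        samples=pd.Index([f"s{i}" for i in range(n)]),
        variants=variants,
        gq=arr(gq, np.int16),
        ad_ref=arr(ad_ref, np.int32),
        ad_alt=arr(ad_alt, np.int32),
    )
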