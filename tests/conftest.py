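import numpy as np
import pandas as pd
import pytest

from gliohub.simulate import SynthConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort (discovery-shaped, n=200)."""
    return generate_cohort(SynthConfig(), seed=11)


@pytest.fixture(scope="session")
def small_cohort():
    """A light cohort for quick structural checks."""
    cfg = SynthConfig(n_normal=10, n_grade2=30, n_grade3=30, n_grade4=30,
                      n_rep_grade2=30, n_rep_grade3=30, n_rep_grade4=30,
                      n_modules=3, genes_per_module=40, n_background_genes=40,
                      module_grade_cor=(0.75, -0.7, 0.0))
    return generate_cohort(cfg, seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def toy_expression(values, genes=None, samples=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i+1}" for i in range(values.shape[0])]
    samples = samples or [f"s{j+1}" for j in range(values.shape[1])]
    return pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=samples)
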