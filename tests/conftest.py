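import numpy as np
import pandas as pd
import pytest

from metadrug import synth


@pytest.fixture(scope="session")
def small_config() -> synth.SynthConfig:
    return synth.SynthConfig(
        n_genes=300,
        n_ccl=80,
        n_patients_per_cohort=50,
        n_drugs=12,
        n_planted_hg=3,
        n_planted_de=2,
        geneset_sizes={"glycolysis": 20, "oxphos": 40, "ar": 10},
        seed=7,
    )


@pytest.fixture(scope="session")
def small_panel(small_config):
    return synth.generate_ccl_panel(small_config)


@pytest.fixture(scope="session")
def small_cohort(small_config, small_panel):
    _, _, _, truth = small_panel
    return synth.generate_patient_cohort(small_config, truth, "EC-like")


def random_expression(n_genes=50, n_samples=20, seed=0, prefix="g"):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        rng.normal(5.0, 1.0, size=(n_genes, n_samples)),
        index=[f"{prefix}{i:03d}" for i in range(n_genes)],
        columns=[f"s{j:03d}" for j in range(n_samples)],
    )
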