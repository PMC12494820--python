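import numpy as np
import pandas as pd
import pytest

from tfsignals import GeneratorConfig, generate_dataset, run_pipeline
from tfsignals.synthetic import generate_truth


@pytest.fixture(scope="session")
def default_bundle():
    """The default synthetic study bundle (seed 7)."""
    return generate_dataset(GeneratorConfig())


@pytest.fixture(scope="session")
def noiseless_bundle():
    """Same design at zero expression noise, for exact-recovery checks."""
    return generate_dataset(GeneratorConfig(noise_sd_expression=0.0))


@pytest.fixture(scope="session")
def pipeline_result(default_bundle):
    """Full pipeline run on the default bundle, shared across tests."""
    b = default_bundle
    return run_pipeline(
        b.expression,
        b.network,
        b.metabolome,
        b.model,
        b.known,
        n_samples=300,
        seed=1,
    )


@pytest.fixture()
def tiny_truth():
    cfg = GeneratorConfig(
        n_tfs=5, n_genes=30, n_conditions=12, n_metabolites=8,
        targets_per_tf=4, n_planted=3, n_ko_conditions=2, seed=3,
    )
    truth, net = generate_truth(cfg)
    return cfg, truth, net
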