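import numpy as np
import pandas as pd
import pytest

from platesig import CohortDesign, SimulationSpec, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """19 matched pairs, 100 genes, two genes shifted up by 2 sigma."""
    spec = SimulationSpec(
        n_pairs=19, n_genes=100, signal=((3, 1.0), (47, 1.0)),
        gene_sd_range=(0.5, 0.5), seed=101,
    )
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def null_cohort():
    """19 matched pairs, 300 genes, no signal anywhere."""
    spec = SimulationSpec(n_pairs=19, n_genes=300, seed=202)
    return generate_cohort(spec)


@pytest.fixture
def tiny_design():
    return CohortDesign.from_records(
        [
            ("s1", "case", "P1"), ("s2", "control", "P1"),
            ("s3", "case", "P2"), ("s4", "control", "P2"),
            ("s5", "case", "P3"), ("s6", "control", "P3"),
        ]
    )


@pytest.fixture
def tiny_matrix(tiny_design):
    rng = np.random.default_rng(7)
    return pd.DataFrame(
        rng.normal(8.0, 1.0, size=(6, 4)),
        index=tiny_design.sample_ids,
        columns=["gA", "gB", "gC", "gD"],
    )
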