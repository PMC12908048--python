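import numpy as np
import pandas as pd
import pytest

from dysbiom import AbundanceTable, CohortSpec, DysbiosisPanel, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort shared across tests (fixed seed)."""
    return generate_cohort(CohortSpec(seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_panel():
    return DysbiosisPanel(enriched={"A": 1.0, "B": 1.0}, depleted={"C": 1.0, "D": 1.0})


def random_relative_table(rng, n_samples=6, n_taxa=8):
    vals = rng.dirichlet(np.ones(n_taxa), size=n_samples)
    return AbundanceTable(
        pd.DataFrame(
            vals,
            index=[f"s{i}" for i in range(n_samples)],
            columns=[f"t{j}" for j in range(n_taxa)],
        ),
        "relative",
    )
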