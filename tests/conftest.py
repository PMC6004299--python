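import numpy as np
import pandas as pd
import pytest

from prognosig.synthetic import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A modest cohort with planted signal, shared across read-only tests."""
    return simulate_cohort(
        SimulationConfig(n_samples=120, n_genes=150, n_prognostic=12, seed=11)
    )


@pytest.fixture(scope="session")
def labels(small_cohort):
    from prognosig.prep import assign_prognosis_labels

    return assign_prognosis_labels(small_cohort.clinical)


@pytest.fixture()
def toy_expr():
    """4 genes x 6 samples with known structure for hand-checkable cases."""
    rng = np.random.default_rng(42)
    data = rng.uniform(1, 10, size=(4, 6))
    return pd.DataFrame(
        data, index=[f"g{i}" for i in range(4)], columns=[f"s{i}" for i in range(6)]
    )
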