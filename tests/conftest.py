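import numpy as np
import pytest

import qscan


@pytest.fixture(scope="session")
def table1():
    return qscan.fixture_table1()


@pytest.fixture(scope="session")
def table2():
    return qscan.fixture_table2()


@pytest.fixture(scope="session")
def fitted_variables(table1):
    """Derived variables fitted from the reference cohort (all 12 subjects),
    plus the calibrated shared demand constant."""
    model = qscan.CohortPhenotyping(table1)
    return model.derive_variables()


@pytest.fixture(scope="session")
def table2_pca(table2):
    return qscan.run_pca(table2)


@pytest.fixture(scope="session")
def reference_clusters(table2_pca):
    """Two-cluster solution on the published derived-variable table."""
    return qscan.gmm_cluster(table2_pca, seed=1)


def gaussian_curve(doses, log_amp, log_mean, width):
    """Noiseless inverted-U responses on a dose grid (helper for tests)."""
    x = np.log10(np.asarray(doses, dtype=float))
    return 10.0 ** (log_amp * np.exp(-0.5 * ((x - log_mean) / width) ** 2))
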