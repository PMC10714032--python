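import warnings

import numpy as np
import pandas as pd
import pytest

from evintegra import syndata
from evintegra.containers import CASE, CONTROL, IntensityMatrix


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


@pytest.fixture(scope="session")
def planted():
    """Reference signature with planted disjoint markers (5 types, 500 genes)."""
    sig, markers = syndata.gen_cell_signatures(500, 5, 60, 3.0, seed=11)
    return sig, markers


@pytest.fixture(scope="session")
def cohort(planted):
    """Two-group EV proteome cohort with noise and MNAR dropout plus truth."""
    sig, _ = planted
    truth = syndata.make_truth(
        sig.columns, (0.40, 0.30, 0.15, 0.10, 0.05), (0.25, 0.25, 0.15, 0.10, 0.25),
        n_samples_per_group=5, dropout_rate=0.1, noise_sd=0.1, seed=21)
    return syndata.gen_ev_proteome(sig, truth), truth


@pytest.fixture(scope="session")
def cells(planted):
    sig, _ = planted
    return syndata.gen_single_cell_counts(sig, cells_per_type=40,
                                          library_size=20000.0, dispersion=0.3,
                                          seed=31)


@pytest.fixture()
def small_matrix():
    """Tiny complete two-group matrix for hand-checked statistics."""
    samples = ["c1", "c2", "c3", "t1", "t2", "t3"]
    groups = pd.Series([CONTROL] * 3 + [CASE] * 3, index=samples)
    rng = np.random.default_rng(5)
    vals = pd.DataFrame(rng.normal(10, 1, size=(40, 6)),
                        index=[f"P{i:02d}" for i in range(40)], columns=samples)
    return IntensityMatrix(values=vals, groups=groups)
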