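import numpy as np
import pytest

from modae.data import DrugResponseMatrix, OmicsMatrix, SurvivalRecordSet
from modae.synthetic import SyntheticConfig, generate_cohorts


@pytest.fixture(scope="session")
def small_cohorts():
    """A small paired cohort shared by read-only tests."""
    cfg = SyntheticConfig(
        n_patients=60, n_celllines=50, n_genes=20, n_drugs=6, seed=11
    )
    return generate_cohorts(cfg)


@pytest.fixture()
def toy_omics():
    rng = np.random.default_rng(5)
    return OmicsMatrix(
        rng.normal(size=(8, 4)),
        [f"s{i}" for i in range(8)],
        [f"g{j}" for j in range(4)],
        np.zeros(8, dtype=int),
    )


@pytest.fixture()
def toy_survival():
    return SurvivalRecordSet(
        [f"s{i}" for i in range(8)],
        [5.0, 3.0, 8.0, 2.0, 9.0, 4.0, 7.0, 6.0],
        [1, 0, 1, 1, 0, 1, 0, 1],
    )


@pytest.fixture()
def toy_drugs():
    rng = np.random.default_rng(7)
    values = rng.uniform(size=(6, 3))
    mask = np.ones((6, 3), dtype=bool)
    mask[0, 1] = False
    return DrugResponseMatrix(values, mask, [f"c{i}" for i in range(6)], ["d0", "d1", "d2"])
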