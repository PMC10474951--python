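import numpy as np
import pytest

from mirimpact.de_engine import DEEngine
from mirimpact.perm_null import simulate_null
from mirimpact.synthetic_data import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def null_cohort_engine():
    """A small synthetic cohort with no mutation effects and its DE engine."""
    cfg = SimulationConfig(seed=11, n_patients=100, n_features=200, effects=[])
    cohort, mutmatrix, truth = simulate_cohort(cfg)
    return cohort, DEEngine(cohort.counts)


@pytest.fixture(scope="session")
def null_b1000(null_cohort_engine):
    """B=1000 permutation null at category 0.2 on the null cohort."""
    cohort, engine = null_cohort_engine
    return simulate_null(cohort, 0.2, engine, B=1000, seed=202)


@pytest.fixture(scope="session")
def structured_nulls():
    """A heterogeneous null cohort (subpopulation-expressed features, no
    mutation effects) whose permutation nulls are non-degenerate: B=200
    nulls for the low-frequency categories plus a B=1000 null at 0.05."""
    cfg = SimulationConfig(
        seed=42, n_patients=100, n_features=300, effects=[],
        subpop_feature_frac=0.5, subpop_expressed_range=(0.05, 0.5),
    )
    cohort, _, _ = simulate_cohort(cfg)
    engine = DEEngine(cohort.counts)
    cats = [0.05, 0.10, 0.15, 0.20, 0.25]
    nulls = {
        c: simulate_null(cohort, c, engine, B=200, seed=100 + i)
        for i, c in enumerate(cats)
    }
    return cohort, engine, nulls


@pytest.fixture(scope="session")
def structured_null_b1000(structured_nulls):
    cohort, engine, _ = structured_nulls
    return simulate_null(cohort, 0.05, engine, B=1000, seed=505)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
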