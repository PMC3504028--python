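import numpy as np
import pandas as pd
import pytest

from grsjoint.grs import exclude_high_missing
from grsjoint.panel import load_panel
from grsjoint.simulate import CANONICAL_SEED, SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def panel():
    return load_panel()


@pytest.fixture(scope="session")
def small_cohort(panel):
    """A quick cohort at the default margins/ORs for structural tests."""
    config = SimulationConfig(n_cases=900, n_controls=1100, seed=CANONICAL_SEED)
    matrix, phenos = simulate_cohort(config, panel)
    return config, matrix, phenos


@pytest.fixture(scope="session")
def canonical_cohort(panel):
    """The rigged reference cohort: 6,075 participants, 74 heavy-missing."""
    config = SimulationConfig(n_cases=2679, n_controls=3396, seed=CANONICAL_SEED)
    matrix, phenos = simulate_cohort(config, panel, n_heavy=74, heavy_min=4)
    return config, matrix, phenos


@pytest.fixture(scope="session")
def analytic_sample(canonical_cohort, panel):
    """Canonical cohort after the >=4-missing exclusion."""
    _, matrix, phenos = canonical_cohort
    matrix_f, phenos_f, n_excluded = exclude_high_missing(matrix, phenos, threshold=4)
    return matrix_f, phenos_f, n_excluded
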