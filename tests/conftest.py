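import numpy as np
import pytest

from moralcni import (
    CniCounts,
    CniParams,
    GeneratorConfig,
    category_probabilities,
    default_battery,
    generate_study,
)


@pytest.fixture(scope="session")
def battery():
    return default_battery()


@pytest.fixture(scope="session")
def small_study():
    """One modest simulated study reused across read-only tests."""
    return generate_study(GeneratorConfig(n_participants=60, seed=20240501))


def exact_counts(params: CniParams, per_cell: float = 1000.0, group="all") -> CniCounts:
    """Counts exactly proportional to the analytic category probabilities."""
    p = category_probabilities(params)
    return CniCounts(p * per_cell, (1 - p) * per_cell, group=group)


def random_counts(rng: np.random.Generator, group="g") -> CniCounts:
    """A random interior-parameter count table of moderate size."""
    params = CniParams(*rng.uniform(0.1, 0.8, size=3))
    totals = rng.integers(120, 320, size=4)
    p = category_probabilities(params)
    actions = rng.binomial(totals, p)
    return CniCounts(actions.astype(float), (totals - actions).astype(float), group=group)
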