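"""Shared fixtures: atlas, small graphs, and synthetic cohorts."""

import numpy as np
import pandas as pd
import pytest

from cfosnet import CohortTable, WeightedGraph, default_atlas


@pytest.fixture(scope="session")
def atlas():
    return default_atlas()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture()
def cohort_factory(atlas):
    """Build a cohort from an animals x regions matrix (NaN = missing)."""

    def build(X, condition="cond"):
        X = np.asarray(X, dtype=float)
        data = pd.DataFrame(
            X, index=[f"m{i+1:02d}" for i in range(X.shape[0])], columns=atlas.codes
        )
        return CohortTable(condition=condition, data=data, atlas=atlas)

    return build


@pytest.fixture()
def random_cohort(cohort_factory, rng):
    """An 8-animal cohort of independent log-normal densities."""
    return cohort_factory(rng.lognormal(5.0, 0.4, size=(8, 30)))


@pytest.fixture()
def triangle_graph():
    W = np.array([[0, 0.5, 0.5], [0.5, 0, 0.5], [0.5, 0.5, 0]], dtype=float)
    return WeightedGraph(nodes=["a", "b", "c"], W=W)


@pytest.fixture()
def star_graph():
    """4-node star, unit weights, center first."""
    W = np.zeros((4, 4))
    W[0, 1:] = W[1:, 0] = 1.0
    return WeightedGraph(nodes=["c", "l1", "l2", "l3"], W=W)
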