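"""Shared fixtures. The heavy edge-recovery cohort/ensemble run is
session-scoped so module tests and acceptance tests reuse one computation."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

from nasonet import (
    AbundanceTable,
    EnsembleConfig,
    SimulationConfig,
    infer_network,
    simulate_cohort,
)


def make_table(values, taxa=None, samples=None, domains=None, mode="relative"):
    values = np.asarray(values, dtype=float)
    p, n = values.shape
    taxa = taxa or [f"T{i}" for i in range(p)]
    samples = samples or [f"S{j}" for j in range(n)]
    domains = domains or ["bacteria"] * p
    df = pd.DataFrame(values, index=taxa, columns=samples)
    return AbundanceTable(df, pd.Series(domains, index=taxa), mode)


@pytest.fixture
def simple_relative_table():
    return make_table([[0.5, 0.25], [0.25, 0.25], [0.25, 0.5]])


@pytest.fixture(scope="session")
def recovery_cohort():
    """Two-group cohort with planted density-0.1 networks (p=30, n=500/group)."""
    cfg = SimulationConfig(
        n_samples=(500, 500),
        n_bacteria=15,
        n_fungi=15,
        edge_density=0.1,
        zero_inflation_prob=0.0,
        sequencing_depth=100_000,
        seed=11,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def recovery_ensemble(recovery_cohort):
    """Full ensemble run (100 bootstraps / 100 permutations) on group 1."""
    table = recovery_cohort.relative["group1"]
    result = infer_network(table, EnsembleConfig(seed=3, edge_p_threshold=0.01))
    return recovery_cohort, result


def edge_labels_and_scores(cohort, result, group="group1"):
    """Pairwise planted-edge indicators and aggregate scores, aligned."""
    taxa = result.taxon_ids
    planted = cohort.planted[group].edge_set
    y, s = [], []
    for i, j in itertools.combinations(range(len(taxa)), 2):
        key = tuple(sorted((taxa[i], taxa[j])))
        y.append(1 if key in planted else 0)
        s.append(result.aggregate_score[i, j])
    return np.array(y), np.array(s)
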