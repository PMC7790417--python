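"""Shared fixtures: one benchmark cohort, reused residuals, toy graphs."""

from __future__ import annotations

import warnings

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from irnet import normalize, synth


def bench_params(seed: int = 1, **overrides) -> synth.SimulationParams:
    """The benchmark study conditions: 60 donors x 3 clones, 800 genes,
    5 modules each organised around one planted key driver."""
    kw = dict(n_donors=60, clones_per_donor=3, n_genes=800, n_modules=5,
              n_kd=5, seed=seed)
    kw.update(overrides)
    return synth.SimulationParams(**kw)


@pytest.fixture(scope="session")
def cohort():
    params = bench_params(seed=1)
    counts, metadata, truth = synth.simulate_cohort(params)
    return params, counts, metadata, truth


@pytest.fixture(scope="session")
def residuals(cohort):
    _params, counts, metadata, _truth = cohort
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        filtered = normalize.filter_low_expression(counts)
        factors = normalize.tmm_factors(filtered)
        logcpm = normalize.log_cpm(filtered, factors)
        res = normalize.adjust_covariates(logcpm, metadata)
    return res


@pytest.fixture()
def chain_graph():
    g = nx.DiGraph()
    nx.add_path(g, ["a", "b", "c", "d"])
    return g


def random_dag(rng: np.random.Generator, n_nodes: int, p_edge: float = 0.08):
    """Random DAG: edges only from lower to higher node index."""
    g = nx.DiGraph()
    nodes = [f"n{i}" for i in range(n_nodes)]
    g.add_nodes_from(nodes)
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < p_edge:
                g.add_edge(nodes[i], nodes[j])
    return g
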