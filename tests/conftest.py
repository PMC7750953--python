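"""Shared fixtures: seeded random instances and one end-to-end refinement run.

The end-to-end fixtures are session-scoped because the multi-tissue
refinement (4 tissues x 200 iterations) is the most expensive thing the
suite does and several tests read from it without mutating it.
"""
from __future__ import annotations

import warnings

import numpy as np
import pytest

import pumanet as pn


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture()
def small_prior() -> pn.RegulatoryNetwork:
    rng = np.random.default_rng(7)
    W = (rng.random((4, 6)) < 0.4).astype(float)
    W[0, 0] = 1.0  # guarantee a nonzero row
    return pn.RegulatoryNetwork(
        [f"miR{i}" for i in range(4)],
        [f"g{j}" for j in range(6)],
        W,
        np.array([True, True, False, False]),
    )


@pytest.fixture()
def small_expression(small_prior) -> pn.ExpressionMatrix:
    rng = np.random.default_rng(8)
    return pn.ExpressionMatrix(
        list(small_prior.genes),
        [f"s{k}" for k in range(10)],
        rng.normal(size=(6, 10)),
        tissue_label="toy",
    )


@pytest.fixture(scope="session")
def study_config() -> pn.SimulationConfig:
    """The benchmark study conditions used throughout the suite."""
    return pn.SimulationConfig(
        m=20, n=60, tissues=4, samples=100, density=0.05,
        beta=2.0, sigma=1.0, prior_dropout=0.3, seed=1,
    )


def _refine_all_tissues(cfg: pn.SimulationConfig):
    data = pn.simulate(cfg)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # 200-iteration cap
        nets = [
            pn.run_puma(data["priorA"], expr, mirna_ids=data["mirna_ids"])
            for expr in data["expression"]
        ]
    coll = pn.NetworkCollection([e.tissue_label for e in data["expression"]], nets)
    return data, coll


@pytest.fixture(scope="session")
def refined_study(study_config):
    """(simulated data, refined per-tissue collection) under planted signal."""
    return _refine_all_tissues(study_config)


@pytest.fixture(scope="session")
def refined_null_study(study_config):
    """Same study with beta=0: no co-expression signal (negative control)."""
    cfg = pn.SimulationConfig(
        m=study_config.m, n=study_config.n, tissues=study_config.tissues,
        samples=study_config.samples, density=study_config.density,
        beta=0.0, sigma=study_config.sigma,
        prior_dropout=study_config.prior_dropout, seed=study_config.seed,
    )
    return _refine_all_tissues(cfg)
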