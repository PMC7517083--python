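"""Shared fixtures: the expensive solver runs are computed once per session.

The standard parameter point throughout is a0 = 0.5, eps = 0.01, x0 = 0.5
(carrying capacity 50) on the grid dt = 0.05, t_end = 40."""

import numpy as np
import pytest

from stochpop import (
    MCConfig,
    ModelParams,
    TimeGrid,
    decompose_variance,
    em_paths,
    exact_path_samples,
    gpc_whe_solve,
    nested_mc,
    whe_solve,
)

LAMBDAS = (0.01, 0.015, 0.0175, 0.02)
A1_SWEEP = (0.0, 0.005, 0.010, 0.015, 0.020, 0.025, 0.030, 0.035)


def std_params(lam=0.0, a1=0.0, a0=0.5):
    return ModelParams(a0=a0, a1=a1, eps=0.01, x0=0.5, lam=lam)


@pytest.fixture(scope="session")
def grid40():
    return TimeGrid.from_horizon(0.05, 40.0)


@pytest.fixture(scope="session")
def whe_runs(grid40):
    """lam -> (kernels, moments) for the noise-amplitude sweep."""
    return {lam: whe_solve(std_params(lam=lam), grid40) for lam in LAMBDAS}


@pytest.fixture(scope="session")
def gpc_sweep(grid40):
    """a1 -> (VarianceReport, moment table), chaos-coefficient convention."""
    out = {}
    for a1 in A1_SWEEP:
        kernels, table = gpc_whe_solve(
            std_params(lam=0.02, a1=a1), grid40, convention="coefficient"
        )
        out[a1] = (decompose_variance(kernels, grid40), table)
    return out


@pytest.fixture(scope="session")
def gpc_halfwidth(grid40):
    """Random growth rate a ~ U[0.49, 0.51] in the half-width convention."""
    kernels, table = gpc_whe_solve(
        std_params(lam=0.02, a1=0.01), grid40, convention="half_width"
    )
    return decompose_variance(kernels, grid40), table


@pytest.fixture(scope="session")
def extinction_report(grid40):
    """Noise-dominated decay regime a0 < lam^2/2."""
    params = ModelParams(a0=0.0001, a1=0.00004, eps=0.01, x0=0.5, lam=0.02)
    kernels, table = gpc_whe_solve(params, grid40, convention="coefficient")
    return decompose_variance(kernels, grid40), table


@pytest.fixture(scope="session")
def em_runs(grid40):
    """Euler-Maruyama reference moments, 10,000 paths, for lam in {0.01, 0.02}."""
    cfg = MCConfig(n_paths=10_000, seed=7, dt_mc=0.01)
    return {lam: em_paths(std_params(lam=lam), grid40, cfg) for lam in (0.01, 0.02)}


@pytest.fixture(scope="session")
def exact_path_run(grid40):
    cfg = MCConfig(n_paths=4000, seed=8, dt_mc=0.01, scheme="exact_path")
    return exact_path_samples(std_params(lam=0.01), grid40, cfg)


@pytest.fixture(scope="session")
def nested_run(grid40):
    cfg = MCConfig(n_paths=500, seed=9, dt_mc=0.01, n_param_draws=200)
    return nested_mc(std_params(lam=0.02, a1=0.01), grid40, cfg)
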