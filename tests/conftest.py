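"""Shared fixtures.

The expensive simulated experiments are session-scoped so the recovery,
noise-characterisation and comparison tests share one run each.
"""

from __future__ import annotations

import numpy as np
import pytest

from bequant.assign import assign_and_genotype
from bequant.quantify import quantify
from bequant.simulate import (
    SimConfig,
    benchmark_preset,
    build_library,
    dual_preset,
    null_preset,
    simulate_experiment,
    truth_statistics,
)


def run_pipeline(exp):
    """Assign + quantify a simulated experiment."""
    assignment = assign_and_genotype(
        {rep: exp.read_pairs(rep) for rep in exp.reads}, exp.library
    )
    return assignment, quantify(assignment)


@pytest.fixture(scope="session")
def small_experiment():
    """Tiny error-free experiment for exact-count unit tests."""
    from dataclasses import replace

    cfg = SimConfig(n_members=12, mean_depth=40, rng_seed=7)
    model = replace(benchmark_preset(), seq_error_rate=0.0)
    return simulate_experiment(cfg, model)


@pytest.fixture(scope="session")
def benchmark_run():
    """Recovery benchmark: 200 members, 2 replicates, Poisson(300) depth,
    truth window 3..8 and truth selectivity exactly 25."""
    cfg = SimConfig(n_members=200, mean_depth=300, rng_seed=11)
    model = benchmark_preset()
    exp = simulate_experiment(cfg, model)
    assignment, results = run_pipeline(exp)
    truth = truth_statistics(model, exp.library)
    return {
        "config": cfg,
        "model": model,
        "exp": exp,
        "truth": truth,
        "assignment": assignment,
        "results": results,
    }


@pytest.fixture(scope="session")
def attenuated_run(benchmark_run):
    """The same library edited by a 1.25-fold attenuated editor."""
    model = benchmark_run["model"].attenuated(1.25)
    cfg = SimConfig(n_members=200, mean_depth=300, rng_seed=13)
    exp = simulate_experiment(cfg, model, library=benchmark_run["exp"].library)
    assignment, results = run_pipeline(exp)
    return {"model": model, "exp": exp, "assignment": assignment, "results": results}


@pytest.fixture(scope="session")
def noise_run():
    """Pure sequencing-noise condition: no editing, 200 members, depth 300."""
    cfg = SimConfig(n_members=200, mean_depth=300, rng_seed=17)
    model = null_preset()
    exp = simulate_experiment(cfg, model)
    assignment = assign_and_genotype(
        {rep: exp.read_pairs(rep) for rep in exp.reads}, exp.library
    )
    return {"config": cfg, "model": model, "exp": exp, "assignment": assignment}


@pytest.fixture(scope="session")
def dual_run():
    """Dual-editor condition with latent engagement coupling (co-editing)."""
    cfg = SimConfig(n_members=80, mean_depth=300, rng_seed=19)
    model = dual_preset()
    exp = simulate_experiment(cfg, model)
    assignment, results = run_pipeline(exp)
    truth = truth_statistics(model, exp.library)
    return {
        "model": model,
        "exp": exp,
        "truth": truth,
        "assignment": assignment,
        "results": results,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(123)
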