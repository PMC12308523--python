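"""Shared fixtures: a small synthetic winter and a null permutation sample."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from pairwinter.inference import ModelSpec, fit_binomial, permutation_pvalues
from pairwinter.synthetic_data import SimConfig, simulate_daily_table, simulate_dataset

SMALL_PAIRS = {"faithful": 10, "divorcing": 4, "new": 10, "juvenile": 10}


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """A reduced study design for unit tests: fewer feeders and pairs."""
    return SimConfig(
        n_feeders=10,
        n_pairs_per_status=dict(SMALL_PAIRS),
        n_floaters=8,
        n_unclear_decoys=3,
        n_absent_decoys=3,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    """(population, visits) for the reduced design, one fixed seed."""
    return simulate_dataset(small_config, seed=7)


@pytest.fixture(scope="session")
def null_pperm_sample() -> np.ndarray:
    """p_perm for the divorcing contrast under 200 no-effect replicates.

    Data are drawn with identical association probability in every status and
    no trend; each replicate fits the aggregate WA model and computes the
    status-label permutation p-value at B=99. Shared by the type-I-error and
    uniformity checks.
    """
    spec = ModelSpec(response="wa", degree=0)
    pvals = []
    for rep in range(200):
        table = simulate_daily_table(
            seed=50_000 + rep,
            n_pairs_per_status={"faithful": 10, "divorcing": 4, "new": 10, "juvenile": 10},
            mean_events_per_day=8.0,
        )
        p = permutation_pvalues(table, spec, B=99, seed=rep)
        pvals.append(p["status[divorcing]"])
    return np.asarray(pvals)


@pytest.fixture(scope="session")
def null_asymptotic_decisions() -> np.ndarray:
    """Paired (asymptotic p, p_perm) for the same 60 null replicates."""
    spec = ModelSpec(response="wa", degree=0)
    out = []
    for rep in range(60):
        table = simulate_daily_table(
            seed=90_000 + rep,
            n_pairs_per_status={"faithful": 10, "divorcing": 4, "new": 10, "juvenile": 10},
            mean_events_per_day=8.0,
        )
        fit = fit_binomial(table, spec)
        p_perm = permutation_pvalues(table, spec, B=99, seed=rep)
        j = fit.terms.index("status[divorcing]")
        out.append((fit.pvalues[j], p_perm["status[divorcing]"]))
    return np.asarray(out)
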