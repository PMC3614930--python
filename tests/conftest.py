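"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from mamprog.data_model import GeneSet, TimeCourseMatrix
from mamprog.synthetic import SimulationConfig, simulate_development


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(seed=11, n_genes=400, n_tumors=60)


@pytest.fixture(scope="session")
def small_development(small_config):
    """One small simulated time course shared across read-only tests."""
    return simulate_development(small_config)


@pytest.fixture
def tiny_matrix() -> TimeCourseMatrix:
    """3 genes x 6 arrays over 3 time points, hand-readable values."""
    values = pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
         [5.0, 5.0, 5.0, 5.0, 5.0, 5.0],
         [2.0, 2.0, 6.0, 6.0, 4.0, 4.0]],
        index=["gA", "gB", "gC"],
        columns=["a1", "a2", "b1", "b2", "c1", "c2"],
    )
    design = pd.Series(["T1", "T1", "T2", "T2", "T3", "T3"],
                       index=values.columns)
    return TimeCourseMatrix(values=values, design=design,
                            timepoint_order=["T1", "T2", "T3"])


def fisher_two_sided_oracle(a: int, b: int, c: int, d: int) -> float:
    """Exhaustive hypergeometric enumeration of the two-sided Fisher p.

    Sums the probabilities of every table with the observed margins whose
    point probability is at most the observed table's (point-probability
    convention). Independent of scipy's implementation.
    """
    from math import comb

    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = comb(n, c1)
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    probs = {x: comb(r1, x) * comb(r2, c1 - x) / denom for x in range(lo, hi + 1)}
    p_obs = probs[a]
    return sum(p for p in probs.values() if p <= p_obs * (1 + 1e-12))


@pytest.fixture(scope="session")
def fisher_oracle():
    return fisher_two_sided_oracle


def make_gene_set(ids, name="s") -> GeneSet:
    return GeneSet(name, frozenset(ids))


@pytest.fixture(scope="session")
def gene_set_factory():
    return make_gene_set
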