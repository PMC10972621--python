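"""Shared fixtures and independent brute-force oracles.

The oracles here are deliberately naive (full enumeration, direct
summation) and never call the implementation paths they check.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

import metaniche as mn


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def exact_ranksum_p(x, y) -> float:
    """Two-sided rank-sum p by full enumeration of group assignments.

    p = P(|U - E[U]| >= |u_obs - E[U]|) over all C(n1+n2, n1) equally likely
    assignments of the pooled ranks to group x. Assumes no ties.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    pooled = np.concatenate([x, y])
    ranks = pooled.argsort().argsort() + 1.0
    n1 = len(x)
    r_obs = ranks[:n1].sum()
    mu = n1 * (len(pooled) + 1) / 2.0
    count = total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        r = ranks[list(combo)].sum()
        count += abs(r - mu) >= abs(r_obs - mu) - 1e-12
        total += 1
    return count / total


def brute_force_bh(p):
    """BH by the definition: p_(i) * n / i, then running minimum from the top."""
    p = np.asarray(p, float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(n)
    running = np.inf
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        adj[i] = min(running, 1.0)
    return adj


def logrank_oracle(times, events, in_a):
    """Log-rank by direct accumulation of hypergeometric moments."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    in_a = np.asarray(in_a, bool)
    o_e = v = 0.0
    for t in sorted(set(times[events == 1])):
        at_risk = times >= t
        n, n1 = at_risk.sum(), (at_risk & in_a).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & in_a).sum()
        o_e += d1 - d * n1 / n
        if n > 1:
            v += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_e ** 2 / v


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def default_cohort():
    """The full-scale default synthetic cohort (seed 0), generated once."""
    counts, cells, genes, truth = mn.generate_sc_cohort(mn.SimConfig(seed=0))
    return counts, cells, genes, truth


@pytest.fixture(scope="session")
def filtered_cohort(default_cohort):
    counts, cells, genes, truth = default_cohort
    fcounts, fcells, _ = mn.filter_cells(counts, cells)
    norm = mn.normalize(fcounts, genes, fcells)
    return fcounts, fcells, genes, truth, norm


@pytest.fixture(scope="session")
def small_cohort():
    """A fast, reduced cohort for structural/unit tests."""
    cfg = mn.SimConfig(
        n_samples_per_condition={"nonmetastatic": 2, "metastatic": 2},
        n_primary_samples=1, cells_per_sample=(60, 80),
        n_genes=400, n_chromosomes=4, cnv_segments=(), seed=5)
    counts, cells, genes, truth = mn.generate_sc_cohort(cfg)
    return counts, cells, genes, truth


@pytest.fixture()
def tiny_norm():
    """A hand-sized normalized matrix: 3 genes x 4 cells, known values."""
    vals = np.array([[1.0, 3.0, 0.0, 2.0],
                     [2.0, 1.0, 4.0, 0.0],
                     [0.0, 0.0, 1.0, 1.0]])
    cells = pd.DataFrame({
        "cell_id": ["c1", "c2", "c3", "c4"],
        "sample_id": ["s1", "s1", "s2", "s2"],
        "condition": ["metastatic"] * 4,
        "cell_type": ["A", "A", "B", "B"],
    })
    norm = mn.NormalizedMatrix(
        vals, pd.Index(["g1", "g2", "g3"]), np.array(["g1", "g2", "g3"]),
        pd.Index(cells["cell_id"]), scale=1e4, log=True)
    return norm, cells
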