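"""Shared fixtures and independent oracles for the test suite.

The oracles deliberately avoid the implementation's code paths: degrees are
counted from edge lists, triangles by explicit triple loops, and hypergeometric
tails by exact rational enumeration of 2x2 tables.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest

from coexpreserve import CountMatrix, SimulationConfig


# ---------------------------------------------------------------------------
# independent oracles


def random_adjacency(rng: np.random.Generator, n: int, p: float = 0.3) -> np.ndarray:
    """Random binary symmetric zero-diagonal matrix."""
    upper = rng.random((n, n)) < p
    a = np.triu(upper, k=1)
    return (a | a.T).astype(np.int8)


def degrees_from_edge_list(a: np.ndarray) -> np.ndarray:
    """Node degrees recounted from an explicit edge list."""
    n = a.shape[0]
    deg = np.zeros(n, dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            if a[i, j]:
                deg[i] += 1
                deg[j] += 1
    return deg


def clustering_by_triangle_enumeration(a: np.ndarray) -> np.ndarray:
    """O(n^3) clustering coefficient: count triangles through each node."""
    n = a.shape[0]
    out = np.full(n, np.nan)
    for i in range(n):
        neighbors = [j for j in range(n) if a[i, j]]
        k = len(neighbors)
        if k <= 1:
            continue
        triangles = 0
        for u_idx in range(k):
            for v_idx in range(u_idx + 1, k):
                if a[neighbors[u_idx], neighbors[v_idx]]:
                    triangles += 1
        out[i] = 2.0 * triangles / (k * (k - 1))
    return out


def hypergeom_upper_tail_exact(N: int, K: int, n: int, x: int) -> float:
    """P(X >= x) for X ~ Hypergeometric(N, K, n) by exact rational summation."""
    lo = max(0, n + K - N)
    hi = min(n, K)
    total = Fraction(0)
    denom = comb(N, n)
    for x_prime in range(max(x, lo), hi + 1):
        total += Fraction(comb(K, x_prime) * comb(N - K, n - x_prime), denom)
    return float(min(total, Fraction(1)))


# ---------------------------------------------------------------------------
# fixtures


@pytest.fixture
def toy_counts() -> CountMatrix:
    df = pd.DataFrame(
        {"s1": [10, 0, 5], "s2": [3, 7, 2], "s3": [1, 1, 1], "s4": [4, 4, 4]},
        index=pd.Index(["G1", "G2", "G3"], name="gene_id"),
    )
    return CountMatrix(df, {"s1": "A", "s2": "A", "s3": "B", "s4": "B"})


@pytest.fixture
def small_sim_config() -> SimulationConfig:
    """A small but structurally complete simulation: one strong planted module."""
    return SimulationConfig(
        n_genes=200,
        gene_set_size=60,
        modules=((20, 0.8), (15, 0.7)),
        disruption=0.85,
        seed=11,
    )
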