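"""Significance-thresholded binary coexpression networks and node statistics.

For each condition a Pearson correlation matrix R = (r_ij) over the condition's
samples is turned into a binary adjacency matrix A = (a_ij) by the hard rule

    a_ij = 1  iff  |r_ij| >= r_min  and  p_ij <= p_max      (both inclusive),

with defaults r_min = 0.5 and p_max = 0.05. The resulting unweighted network is
summarized per gene by its connectivity

    k_i = sum_{j != i} a_ij

and its clustering coefficient

    c_i = (sum_{j != i} sum_{l != i} a_ij a_jl a_li)
          / ((sum_{j != i} a_ij)^2 - sum_{j != i} a_ij^2),

whose denominator equals k_i (k_i - 1) for binary adjacency (a^2 = a). c_i is
undefined (NaN) when k_i <= 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ConfigurationError, DataError
from .exprio import ExpressionMatrix

__all__ = [
    "CorrelationResult",
    "AdjacencyNetwork",
    "NodeStats",
    "pearson_matrix",
    "correlation_pvalue",
    "threshold_adjacency",
    "connectivity",
    "clustering_coefficient",
    "node_stats",
    "network_summary",
]


@dataclass
class CorrelationResult:
    """Symmetric Pearson r and two-sided p matrices for one condition.

    The p diagonal is NaN: a gene's correlation with itself is not a test.
    """

    gene_ids: list[str]
    r: np.ndarray
    p: np.ndarray
    n_samples: int


@dataclass
class AdjacencyNetwork:
    """Binary symmetric adjacency matrix with zero diagonal."""

    gene_ids: list[str]
    a: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.a)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise DataError("adjacency must be square")
        if not np.array_equal(a, a.T):
            raise DataError("adjacency must be symmetric")
        if not np.isin(a, (0, 1)).all():
            raise DataError("adjacency entries must be 0 or 1")
        if np.diagonal(a).any():
            raise DataError("adjacency diagonal must be zero")
        self.a = a.astype(np.int8)

    @property
    def n_nodes(self) -> int:
        return self.a.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.a.sum()) // 2

    def edge_list(self) -> list[tuple[str, str]]:
        ii, jj = np.nonzero(np.triu(self.a, k=1))
        return [(self.gene_ids[i], self.gene_ids[j]) for i, j in zip(ii, jj)]


@dataclass
class NodeStats:
    """Per-gene connectivity k and clustering coefficient c (NaN = undefined)."""

    gene_ids: list[str]
    k: np.ndarray
    c: np.ndarray


def correlation_pvalue(r, n: int):
    """Two-sided p-value for H0: rho = 0 from a sample Pearson r at n samples.

    Uses t = r * sqrt((n-2) / (1-r^2)) referred to Student's t with n-2 df;
    p = 0 at |r| = 1. Accepts scalars or arrays.
    """
    if n < 3:
        raise ConfigurationError(f"correlation test needs n >= 3 samples, got {n}")
    r_arr = np.asarray(r, dtype=float)
    if np.nanmax(np.abs(r_arr), initial=0.0) > 1.0 + 1e-9:
        raise DataError("|r| > 1")
    r_clip = np.clip(r_arr, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.abs(r_clip) * np.sqrt((n - 2) / (1.0 - r_clip**2))
    p = 2.0 * stats.t.sf(t, df=n - 2)
    p = np.where(np.abs(r_clip) >= 1.0, 0.0, p)
    p = np.minimum(p, 1.0)
    return float(p) if np.isscalar(r) or np.asarray(r).ndim == 0 else p


def pearson_matrix(expr: ExpressionMatrix, strict: bool = False) -> CorrelationResult:
    """All-pairs Pearson correlation across samples with two-sided p-values.

    Genes with zero variance have no defined correlation; they are excluded
    with a warning (default) or rejected outright in strict mode.
    """
    data = expr.data.to_numpy(float)
    n = data.shape[1]
    if n < 3:
        raise DataError(f"need >= 3 samples for correlation analysis, got {n}")
    if not np.isfinite(data).all():
        raise DataError("expression matrix contains non-finite values")
    sd = data.std(axis=1)
    const = sd == 0.0
    gene_ids = list(expr.gene_ids)
    if const.any():
        bad = [g for g, c in zip(gene_ids, const) if c]
        if strict:
            raise DataError(f"constant-expression genes: {bad[:10]}")
        warnings.warn(f"excluding {len(bad)} constant-expression gene(s): {bad[:10]}", stacklevel=2)
        data = data[~const]
        gene_ids = [g for g, c in zip(gene_ids, const) if not c]
        if data.shape[0] == 0:
            raise DataError("all genes constant; nothing to correlate")
    r = np.corrcoef(data)
    r = np.clip(r, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    p = correlation_pvalue(r, n)
    np.fill_diagonal(p, np.nan)
    return CorrelationResult(gene_ids, r, p, n)


def threshold_adjacency(
    corr: CorrelationResult, r_min: float = 0.5, p_max: float = 0.05
) -> AdjacencyNetwork:
    """Hard-threshold a correlation matrix into a binary network.

    An edge requires |r_ij| >= r_min AND p_ij <= p_max, both inclusive; the
    diagonal is forced to zero.
    """
    if not (0.0 <= r_min <= 1.0):
        raise ConfigurationError(f"r_min must lie in [0, 1], got {r_min}")
    if not (0.0 < p_max <= 1.0):
        raise ConfigurationError(f"p_max must lie in (0, 1], got {p_max}")
    with np.errstate(invalid="ignore"):
        a = (np.abs(corr.r) >= r_min) & (corr.p <= p_max)
    a = a.astype(np.int8)
    np.fill_diagonal(a, 0)
    return AdjacencyNetwork(list(corr.gene_ids), a)


def connectivity(net: AdjacencyNetwork) -> np.ndarray:
    """k_i = sum_{j != i} a_ij (integer row sums; diagonal is zero by invariant)."""
    return net.a.astype(np.int64).sum(axis=1)


def clustering_coefficient(net: AdjacencyNetwork) -> np.ndarray:
    """Local clustering coefficient per the closed-path-count formula.

    Numerator: sum_{j,l != i} a_ij a_jl a_li = diag(A^3)_i (twice the triangle
    count through i). Denominator: (sum_j a_ij)^2 - sum_j a_ij^2, which equals
    k_i(k_i - 1) for binary a. NaN where k_i <= 1 (denominator zero).
    """
    a = net.a.astype(np.int64)
    closed = np.einsum("ij,jl,li->i", a, a, a)
    row = a.sum(axis=1)
    denom = row.astype(float) ** 2 - (a**2).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, closed / denom, np.nan)
    return c


def node_stats(net: AdjacencyNetwork) -> NodeStats:
    return NodeStats(list(net.gene_ids), connectivity(net), clustering_coefficient(net))


def network_summary(net: AdjacencyNetwork) -> dict:
    """Edge count, density, mean k, mean c over defined nodes, isolated-node count."""
    k = connectivity(net)
    c = clustering_coefficient(net)
    n = net.n_nodes
    n_pairs = n * (n - 1) / 2
    defined = ~np.isnan(c)
    return {
        "n_nodes": n,
        "n_edges": net.n_edges,
        "density": net.n_edges / n_pairs if n_pairs else 0.0,
        "mean_k": float(k.mean()) if n else 0.0,
        "mean_c": float(c[defined].mean()) if defined.any() else float("nan"),
        "n_c_defined": int(defined.sum()),
        "n_isolated": int((k == 0).sum()),
    }
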