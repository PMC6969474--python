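"""Network preservation between conditions: per-gene deltas and a permutation test.

The comparison mirrors the classic two-condition preservation display: node
connectivity k and clustering coefficient c are computed per condition from the
same gene list, condition means are taken over defined values, and the
difference in means (B minus A) is assessed by pooled sample-label permutation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coexnet import NodeStats, correlation_pvalue
from .errors import ConfigurationError, DataError
from .exprio import ExpressionMatrix

__all__ = [
    "PreservationReport",
    "compare_node_stats",
    "permutation_preservation_test",
    "preservation_analysis",
]


@dataclass
class PreservationReport:
    """Per-gene node-statistic comparison between two condition networks.

    ``table`` columns: gene, k_A, k_B, c_A, c_B, delta_k, delta_c.
    ``means`` holds mean_k_A/B and mean_c_A/B (c means over defined values).
    ``p_values`` (when a permutation test ran) holds p_delta_k / p_delta_c.
    """

    table: pd.DataFrame
    means: dict[str, float]
    p_values: dict[str, float] | None = None
    n_permutations: int | None = None
    seed: int | None = None


def _nanmean_or_nan(x: np.ndarray) -> float:
    x = x[~np.isnan(x)]
    return float(x.mean()) if x.size else float("nan")


def compare_node_stats(stats_A: NodeStats, stats_B: NodeStats) -> PreservationReport:
    """Align two per-condition NodeStats on their (identical) gene lists."""
    if list(stats_A.gene_ids) != list(stats_B.gene_ids):
        raise DataError("node statistics have mismatched gene ID lists")
    table = pd.DataFrame(
        {
            "gene": stats_A.gene_ids,
            "k_A": stats_A.k.astype(int),
            "k_B": stats_B.k.astype(int),
            "c_A": stats_A.c,
            "c_B": stats_B.c,
        }
    )
    table["delta_k"] = table["k_B"] - table["k_A"]
    table["delta_c"] = table["c_B"] - table["c_A"]
    means = {
        "mean_k_A": float(np.mean(stats_A.k)),
        "mean_k_B": float(np.mean(stats_B.k)),
        "mean_c_A": _nanmean_or_nan(stats_A.c),
        "mean_c_B": _nanmean_or_nan(stats_B.c),
    }
    return PreservationReport(table, means)


def _mean_stats(data: np.ndarray, r_min: float, p_max: float) -> tuple[float, float]:
    """Mean connectivity and mean clustering of the thresholded network on raw arrays.

    Fast path used inside the permutation loop; mean c over defined nodes, 0.0
    when no node has k >= 2 (an empty clustering landscape contributes no
    disruption signal either way).
    """
    n = data.shape[1]
    sd = data.std(axis=1)
    keep = sd > 0
    n_genes = data.shape[0]
    if not keep.all():
        data = data[keep]
        if data.shape[0] < 2:
            return 0.0, 0.0
    r = np.clip(np.corrcoef(data), -1.0, 1.0)
    p = correlation_pvalue(r, n)
    a = ((np.abs(r) >= r_min) & (p <= p_max)).astype(np.int64)
    np.fill_diagonal(a, 0)
    k = a.sum(axis=1)
    closed = np.einsum("ij,jl,li->i", a, a, a)
    denom = k.astype(float) * (k - 1)
    defined = denom > 0
    mean_k = float(k.sum()) / n_genes  # constant genes count as isolated
    mean_c = float((closed[defined] / denom[defined]).mean()) if defined.any() else 0.0
    return mean_k, mean_c


def permutation_preservation_test(
    expr_A: ExpressionMatrix,
    expr_B: ExpressionMatrix,
    n_perm: int = 999,
    seed: int = 0,
    r_min: float = 0.5,
    p_max: float = 0.05,
) -> dict:
    """Two-sided permutation test for a condition effect on mean k and mean c.

    The observed statistic is T = mean(B) - mean(A) for each of mean
    connectivity and mean clustering. The null pools the samples of both
    conditions and reassigns them at random to two groups of the original
    sizes, rebuilding both networks per permutation. P-values use the add-one
    estimator (1 + #{|T_perm| >= |T_obs|}) / (n_perm + 1), so they are never 0.
    """
    if list(expr_A.gene_ids) != list(expr_B.gene_ids):
        raise DataError("expression matrices have mismatched gene ID lists")
    if n_perm < 99:
        raise ConfigurationError(f"n_perm must be >= 99, got {n_perm}")
    a = expr_A.data.to_numpy(float)
    b = expr_B.data.to_numpy(float)
    n_A, n_B = a.shape[1], b.shape[1]
    if n_A < 3 or n_B < 3:
        raise DataError("each condition needs >= 3 samples")
    mk_A, mc_A = _mean_stats(a, r_min, p_max)
    mk_B, mc_B = _mean_stats(b, r_min, p_max)
    t_obs_k = mk_B - mk_A
    t_obs_c = mc_B - mc_A

    pooled = np.hstack([a, b])
    rng = np.random.default_rng(seed)
    count_k = count_c = 0
    for _ in range(n_perm):
        order = rng.permutation(n_A + n_B)
        pa = pooled[:, order[:n_A]]
        pb = pooled[:, order[n_A:]]
        pk_A, pc_A = _mean_stats(pa, r_min, p_max)
        pk_B, pc_B = _mean_stats(pb, r_min, p_max)
        if abs(pk_B - pk_A) >= abs(t_obs_k):
            count_k += 1
        if abs(pc_B - pc_A) >= abs(t_obs_c):
            count_c += 1
    return {
        "t_obs_k": t_obs_k,
        "t_obs_c": t_obs_c,
        "p_delta_k": (1 + count_k) / (n_perm + 1),
        "p_delta_c": (1 + count_c) / (n_perm + 1),
        "n_permutations": n_perm,
        "seed": seed,
    }


def preservation_analysis(
    expr_A: ExpressionMatrix,
    expr_B: ExpressionMatrix,
    n_perm: int = 999,
    seed: int = 0,
    r_min: float = 0.5,
    p_max: float = 0.05,
) -> PreservationReport:
    """Full preservation comparison: networks, per-gene deltas, permutation p-values."""
    from .coexnet import node_stats, pearson_matrix, threshold_adjacency

    stats = []
    for expr in (expr_A, expr_B):
        corr = pearson_matrix(expr)
        net = threshold_adjacency(corr, r_min=r_min, p_max=p_max)
        stats.append(node_stats(net))
    # constant-gene exclusion may desynchronize lists; insist on shared genes
    if stats[0].gene_ids != stats[1].gene_ids:
        raise DataError(
            "conditions yielded different gene lists after constant-gene exclusion; "
            "filter constant genes upstream"
        )
    report = compare_node_stats(stats[0], stats[1])
    perm = permutation_preservation_test(
        expr_A, expr_B, n_perm=n_perm, seed=seed, r_min=r_min, p_max=p_max
    )
    report.p_values = {"p_delta_k": perm["p_delta_k"], "p_delta_c": perm["p_delta_c"]}
    report.n_permutations = n_perm
    report.seed = seed
    return report
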