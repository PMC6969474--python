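"""Differential-expression selection by FDR and gene-set overrepresentation.

The FDR step is Benjamini-Hochberg step-up; it also reports the implied
p-value cutoff (k/m)*q, the largest raw p-value among the rejections' critical
values, which is how a printed "P-value <= x" threshold relates to an FDR
level. Overrepresentation of a gene set among the selected genes is tested
one-sided with the cumulative hypergeometric distribution (Fisher's exact test
upper tail) against a background of all tested genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, DataError
from .exprio import GeneSetCollection

__all__ = [
    "EnrichmentResult",
    "bh_adjust",
    "select_de_genes",
    "fisher_enrichment",
]


@dataclass
class EnrichmentResult:
    """One gene set's 2x2 overlap counts and upper-tail Fisher p-value.

    N: background size; K: set members in background; n: selected (DE) genes;
    x: overlap between set and selection.
    """

    set_name: str
    N: int
    K: int
    n: int
    x: int
    p_fisher: float


def bh_adjust(p_values, q: float = 0.05) -> tuple[np.ndarray, np.ndarray, float]:
    """Benjamini-Hochberg step-up procedure.

    Returns (q_values, rejected, implied_cutoff):

    * q_values: monotone cumulative-minimum adjusted p-values, clipped to 1;
    * rejected: boolean flags for the step-up rejection set at level ``q``
      (reject the k smallest p-values where k is the largest rank with
      p_(k) <= (k/m) * q);
    * implied_cutoff: (k/m) * q, i.e. the raw-p threshold the rejection set
      corresponds to; 0.0 when nothing is rejected.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise DataError("empty p-value list")
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise DataError("p-values must lie in [0, 1]")
    if not (0.0 < q < 1.0):
        raise ConfigurationError(f"q must lie in (0, 1), got {q}")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ps = p[order]
    ranks = np.arange(1, m + 1)
    passed = ps <= q * ranks / m
    k = int(np.max(np.nonzero(passed)[0])) + 1 if passed.any() else 0
    rejected = np.zeros(m, dtype=bool)
    rejected[order[:k]] = True
    q_sorted = np.minimum.accumulate((ps * m / ranks)[::-1])[::-1]
    q_values = np.empty(m, dtype=float)
    q_values[order] = np.minimum(q_sorted, 1.0)
    implied_cutoff = q * k / m if k else 0.0
    return q_values, rejected, implied_cutoff


def select_de_genes(
    de_table: pd.DataFrame, q: float = 0.05, require_annotation: bool = True
) -> list[str]:
    """Genes rejected by BH at level ``q``, optionally restricted to annotated ones.

    ``de_table`` needs columns gene_id and p_value; an optional boolean
    ``annotated`` column marks genes with usable set-membership annotation
    (absent column = all annotated). BH runs over all tested genes; the
    annotation restriction applies to the selection only.
    """
    if de_table["gene_id"].duplicated().any():
        raise DataError("duplicated gene IDs in DE table")
    _, rejected, _ = bh_adjust(de_table["p_value"].to_numpy(float), q=q)
    selected = pd.Series(rejected, index=de_table.index)
    if require_annotation and "annotated" in de_table.columns:
        selected &= de_table["annotated"].astype(bool)
    return de_table.loc[selected, "gene_id"].tolist()


def fisher_enrichment(
    de_genes: list[str],
    background: list[str],
    sets: GeneSetCollection,
) -> list[EnrichmentResult]:
    """One-sided overrepresentation test per gene set, sorted by p-value.

    With N background genes, K of them in the set, and n selected genes of
    which x fall in the set, p = P(X >= x) for X ~ Hypergeometric(N, K, n).
    Set members are intersected with the background before counting; sets
    disjoint from the background are skipped with a warning.
    """
    bg = list(dict.fromkeys(background))
    if not bg:
        raise DataError("empty background gene list")
    bg_set = set(bg)
    de = list(dict.fromkeys(de_genes))
    outside = [g for g in de if g not in bg_set]
    if outside:
        raise DataError(f"DE genes absent from background: {outside[:10]}")
    de_set = set(de)
    N, n = len(bg), len(de)
    results = []
    for gs in sets:
        members = set(gs.members) & bg_set
        K = len(members)
        if K == 0:
            warnings.warn(f"gene set {gs.name!r} is disjoint from the background; skipped", stacklevel=2)
            continue
        x = len(members & de_set)
        p = float(min(stats.hypergeom.sf(x - 1, N, K, n), 1.0))
        results.append(EnrichmentResult(gs.name, N, K, n, x, p))
    results.sort(key=lambda r: (r.p_fisher, r.set_name))
    return results
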