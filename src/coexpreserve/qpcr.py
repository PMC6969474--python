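"""qPCR validation statistics: delta-Ct, 2^-ddCt fold change, likelihood-ratio test.

A Ct table holds, per sample, the threshold cycle of the target gene and of a
stably expressed reference gene (internal control). Normalized expression is
dCt = Ct_target - Ct_reference (lower dCt = higher expression). Relative
expression follows the 2^-ddCt convention with ddCt referenced to the mean dCt
of the control group, assuming a doubling of product per cycle.

The treatment effect on dCt is tested with a Gaussian-linear-model likelihood
ratio: null = one common mean, full = one mean per group; the statistic
n*ln(RSS0/RSS1) (equal to twice the log-likelihood difference at the Gaussian
MLE) is referred to chi-square with 1 df.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError

__all__ = [
    "REQUIRED_CT_COLUMNS",
    "validate_ct_table",
    "delta_ct",
    "relative_expression",
    "lrt_group_effect",
    "analyze_qpcr",
]

REQUIRED_CT_COLUMNS = ("sample_id", "group", "ct_target", "ct_reference")


def validate_ct_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_CT_COLUMNS if c not in table.columns]
    if missing:
        raise DataError(f"Ct table missing columns: {missing}")
    for col in ("ct_target", "ct_reference"):
        vals = table[col].to_numpy(float)
        if not np.isfinite(vals).all():
            raise DataError(f"non-finite or missing Ct values in column {col!r}")
    counts = table.groupby("group").size()
    if (counts < 2).any():
        small = counts[counts < 2].index.tolist()
        raise DataError(f"groups with fewer than 2 samples: {small}")
    return table


def delta_ct(table: pd.DataFrame) -> pd.Series:
    """Per-sample dCt = ct_target - ct_reference, indexed by sample_id."""
    validate_ct_table(table)
    dct = table["ct_target"].to_numpy(float) - table["ct_reference"].to_numpy(float)
    return pd.Series(dct, index=pd.Index(table["sample_id"], name="sample_id"), name="delta_ct")


def relative_expression(
    delta_ct_values: pd.Series, groups: pd.Series, control_group: str
) -> tuple[pd.Series, dict[str, float]]:
    """2^-ddCt relative expression per sample and geometric group means.

    ddCt = dCt - mean(dCt of the control group); fold = 2^-ddCt. Group means
    are geometric (2^-mean(ddCt)), so the control group's mean fold is exactly
    1 and a +1 cycle shift maps to a mean fold of 0.5.
    """
    groups = pd.Series(np.asarray(groups), index=delta_ct_values.index)
    control_mask = groups == control_group
    if not control_mask.any():
        raise DataError(f"control group {control_group!r} is empty")
    ddct = delta_ct_values - delta_ct_values[control_mask].mean()
    fold = (2.0 ** (-ddct)).rename("fold_change")
    group_means = {g: float(2.0 ** (-ddct[groups == g].mean())) for g in groups.unique()}
    return fold, group_means


def lrt_group_effect(values, groups) -> tuple[float, float]:
    """Likelihood-ratio test for a two-group mean difference on dCt values.

    Returns (statistic, p) with statistic = n*ln(RSS0/RSS1) and p from
    chi-square with 1 df. Degenerate fits (zero residual variance under the
    full model) are rejected.
    """
    y = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    levels = pd.unique(g)
    if len(levels) != 2:
        raise DataError(f"need exactly 2 groups, got {len(levels)}")
    n = y.size
    masks = [g == lev for lev in levels]
    if any(m.sum() < 2 for m in masks):
        raise DataError("each group needs >= 2 samples")
    rss0 = float(((y - y.mean()) ** 2).sum())
    rss1 = sum(float(((y[m] - y[m].mean()) ** 2).sum()) for m in masks)
    if rss1 <= 0.0:
        raise DataError("zero residual variance under the full model; LRT undefined")
    statistic = n * np.log(rss0 / rss1)
    p = float(stats.chi2.sf(statistic, df=1))
    return float(statistic), p


def analyze_qpcr(table: pd.DataFrame, control_group: str) -> dict:
    """One gene's full validation record: dCt, fold changes, LRT."""
    table = validate_ct_table(table)
    dct = delta_ct(table)
    groups = pd.Series(np.asarray(table["group"]), index=dct.index)
    if control_group not in set(groups):
        raise DataError(f"control group {control_group!r} not present in Ct table")
    fold, group_means = relative_expression(dct, groups, control_group)
    statistic, p = lrt_group_effect(dct.to_numpy(), groups.to_numpy())
    treatment = [g for g in group_means if g != control_group]
    return {
        "delta_ct": dct,
        "fold_change": fold,
        "group_mean_fold": group_means,
        "fold_treatment_vs_control": group_means[treatment[0]] if len(treatment) == 1 else None,
        "lrt_statistic": statistic,
        "lrt_p": p,
    }
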