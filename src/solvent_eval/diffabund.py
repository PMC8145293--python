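"""Per-feature differential abundance between physiological stages.

Classical one-way ANOVA on natural-log abundances, feature by feature, with
Benjamini-Hochberg false-discovery-rate adjustment across features.  The
EBPR cycle's anaerobic/aerobic stages are the factor of interest; for the
two-compartment reactor the stage x compartment combination can be used as a
single composite factor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class DiffTestResult:
    """Per-feature F, raw p, BH-adjusted q and group means (log scale)."""

    table: pd.DataFrame  # index feature_id: f_stat, p_value, q_value, significant
    factor: str
    q_threshold: float
    group_means: pd.DataFrame

    @property
    def n_significant(self) -> int:
        return int(self.table["significant"].sum())


def per_feature_anova(
    log_table: pd.DataFrame, groups: pd.Series
) -> pd.DataFrame:
    """One-way ANOVA for every feature (row) of a log-abundance frame.

    ``groups`` maps sample id -> factor level.  Degenerate features (zero
    within-group and zero between-group variance) get p = 1 by convention;
    zero within-group with non-zero between-group variance gives the p -> 0
    limit and is flagged.
    """
    groups = groups.loc[log_table.columns].astype(str)
    levels = list(pd.unique(groups))
    if len(levels) < 2:
        raise ValueError("factor needs >= 2 levels")
    arrays = [log_table.loc[:, groups[groups == lev].index].to_numpy(float) for lev in levels]
    if min(a.shape[1] for a in arrays) < 2:
        raise ValueError("every level needs >= 2 observations")
    n_total = sum(a.shape[1] for a in arrays)
    k = len(levels)

    grand = np.concatenate(arrays, axis=1).mean(axis=1)
    ss_between = sum(
        a.shape[1] * (a.mean(axis=1) - grand) ** 2 for a in arrays
    )
    ss_within = sum(((a - a.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) for a in arrays)
    df_b, df_w = k - 1, n_total - k
    ms_b = ss_between / df_b
    ms_w = ss_within / df_w

    with np.errstate(divide="ignore", invalid="ignore"):
        f = ms_b / ms_w
    p = stats.f.sf(f, df_b, df_w)
    both_zero = (ss_within <= 1e-300) & (ss_between <= 1e-12 * np.maximum(1.0, grand**2))
    zero_within = (ss_within <= 1e-300) & ~both_zero
    f = np.where(both_zero, 0.0, f)
    p = np.where(both_zero, 1.0, p)
    p = np.where(zero_within, 0.0, p)
    return pd.DataFrame(
        {
            "f_stat": f,
            "p_value": p,
            "df_between": df_b,
            "df_within": df_w,
            "degenerate": both_zero,
            "zero_within_var": zero_within,
        },
        index=log_table.index,
    )


def fdr_adjust(pvalues, method: str = "fdr_bh") -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, clipped at 1, original order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method=method)
    return q


def differential_features(
    log_table: pd.DataFrame,
    metadata,
    factor: str | list[str],
    q_threshold: float = 0.05,
) -> DiffTestResult:
    """ANOVA + BH over all features for one factor (or a composite of
    several factors, combined into a single one-way grouping)."""
    meta = metadata.table if hasattr(metadata, "table") else metadata
    meta = meta.loc[[s for s in log_table.columns]]
    if isinstance(factor, str):
        groups = meta[factor].astype(str)
        name = factor
    else:
        groups = meta[list(factor)].astype(str).agg("|".join, axis=1)
        name = "+".join(factor)
    anova = per_feature_anova(log_table, groups)
    q = fdr_adjust(anova["p_value"].to_numpy())
    anova["q_value"] = q
    anova["significant"] = q < q_threshold
    means = log_table.T.groupby(groups).mean().T
    return DiffTestResult(table=anova, factor=name, q_threshold=q_threshold,
                          group_means=means)


def count_significant(result: DiffTestResult, annotations=None) -> tuple[int, int]:
    """(significant features, significant features with >= 1 compound match)."""
    sig = result.table.index[result.table["significant"]]
    n = len(sig)
    if annotations is None:
        return n, 0
    annotated = {r.feature_id for r in annotations if r.is_annotated}
    return n, sum(1 for f in sig if f in annotated)


def count_significant_compounds(result: DiffTestResult, annotations) -> int:
    """Unique compounds matched by significant features."""
    sig = set(result.table.index[result.table["significant"]])
    out = set()
    for r in annotations:
        if r.feature_id in sig:
            out.update(m.compound_id for m in r.matches)
    return len(out)
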