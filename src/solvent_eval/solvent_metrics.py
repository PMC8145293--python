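"""Per-solvent evaluation metrics: extraction capacity, annotation
proportions, analytical-repeatability (RSD) distributions, and
retention-time / m/z occupancy uniformity.

Annotation proportion is 100 * detected compounds / detected features per
group; the benchmark-style summary reports mean / min / max across groups,
rounded half-up to one decimal (full precision kept internally).
Axis-occupancy uniformity is quantified as Shannon evenness over equal-width
bins: 1 when every bin is equally filled, 0 when a single bin holds
everything.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .preprocess import QCReport

RSD_THRESHOLDS = (5.0, 10.0, 20.0, 30.0, 50.0)


def round_half_up(x: float, decimals: int = 1) -> float:
    """Decimal half-up rounding (matches conventional reporting, unlike
    IEEE round-half-even)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class CapacitySummary:
    per_group: pd.DataFrame  # n_features, n_compounds, annotation_pct
    mean_pct: float  # rounded half-up, 1 decimal
    min_pct: float
    max_pct: float
    mean_pct_raw: float

    def as_dict(self) -> dict:
        return {
            "mean_pct": self.mean_pct,
            "min_pct": self.min_pct,
            "max_pct": self.max_pct,
        }


def capacity_summary(counts: dict) -> CapacitySummary:
    """Annotation-proportion summary from per-group (n_features, n_compounds).

    ``counts`` maps group label -> (total detected features, annotated
    compounds).  Groups with zero features are contract violations.
    """
    rows = []
    for group, (n_feat, n_comp) in counts.items():
        if n_feat <= 0:
            raise ValueError(f"group {group!r} has zero detected features")
        rows.append((group, int(n_feat), int(n_comp), 100.0 * n_comp / n_feat))
    per_group = pd.DataFrame(
        rows, columns=["group", "n_features", "n_compounds", "annotation_pct"]
    ).set_index("group")
    pct = per_group["annotation_pct"].to_numpy()
    return CapacitySummary(
        per_group=per_group,
        mean_pct=round_half_up(pct.mean()),
        min_pct=round_half_up(pct.min()),
        max_pct=round_half_up(pct.max()),
        mean_pct_raw=float(pct.mean()),
    )


@dataclass
class RsdDistribution:
    per_group: dict  # group -> np.ndarray of RSD values
    fractions: pd.DataFrame  # groups x thresholds: fraction of RSDs below
    empty_groups: list

    def median(self, group: str) -> float:
        vals = self.per_group[group]
        return float(np.median(vals)) if len(vals) else float("nan")


def rsd_distribution(
    qc_report: QCReport, group_features: dict, thresholds=RSD_THRESHOLDS
) -> RsdDistribution:
    """Empirical RSD% distributions per group.

    ``group_features`` maps group label -> feature ids belonging to that
    group (e.g. features detected in that solvent's samples).  Only features
    retained by the QC filters contribute.  Fractions below each threshold
    are non-decreasing in the threshold by construction.
    """
    pf = qc_report.per_feature
    retained = set(pf.index[pf["retained"]])
    per_group, empty, rows = {}, [], []
    for group, feats in group_features.items():
        ids = [f for f in feats if f in retained]
        vals = pf.loc[ids, "qc_rsd"].to_numpy(float)
        per_group[group] = vals
        if len(vals) == 0:
            empty.append(group)
            rows.append([group] + [np.nan] * len(thresholds))
        else:
            rows.append([group] + [float(np.mean(vals < t)) for t in thresholds])
    fractions = pd.DataFrame(
        rows, columns=["group"] + [f"lt_{int(t)}" for t in thresholds]
    ).set_index("group")
    return RsdDistribution(per_group=per_group, fractions=fractions, empty_groups=empty)


@dataclass
class UniformityScore:
    evenness: float  # in [0, 1]; NaN when undefined
    n_bins: int
    bin_edges: np.ndarray
    bin_counts: np.ndarray


def axis_uniformity(values, n_bins: int = 20) -> UniformityScore:
    """Shannon evenness of occupancy over equal-width bins of the observed
    range: H / ln(n_bins) with H = -sum p_i ln p_i (0 ln 0 := 0).

    Invariant to affine rescaling of the axis.  All-identical values leave
    the range degenerate and the score undefined (NaN).
    """
    x = np.asarray(values, dtype=float)
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if x.size < 2 or np.ptp(x) == 0:
        return UniformityScore(float("nan"), n_bins, np.array([]), np.array([]))
    counts, edges = np.histogram(x, bins=n_bins, range=(x.min(), x.max()))
    p = counts / counts.sum()
    nz = p[p > 0]
    h = float(-(nz * np.log(nz)).sum())
    return UniformityScore(h / np.log(n_bins), n_bins, edges, counts)
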