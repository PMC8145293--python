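"""QC-based feature filtration, internal-standard normalisation and the log
transform used for per-feature inference.

Two filters, applied jointly to every feature:

* pooled-QC repeatability: RSD% = 100 * sd / mean over pooled-QC injections;
  features with RSD > ``rsd_max`` (default 30%) are removed;
* dilution linearity: Pearson correlation between intensity and dilution
  fraction over the dilution-QC series; features with r < ``r_min`` (default
  0.8) are removed.  Genuine compounds dilute linearly; carry-over and
  background contaminants do not.

Undefined statistics (zero QC mean, zero variance) fail the corresponding
filter: such features carry no usable signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import FeatureTable, SampleMetadata


@dataclass
class QCReport:
    """Per-feature QC statistics and filter outcomes."""

    per_feature: pd.DataFrame  # qc_rsd, dilution_r, pass_rsd, pass_dilution, retained
    rsd_max: float
    r_min: float

    @property
    def n_input(self) -> int:
        return len(self.per_feature)

    @property
    def n_retained(self) -> int:
        return int(self.per_feature["retained"].sum())

    @property
    def n_failed_rsd(self) -> int:
        return int((~self.per_feature["pass_rsd"]).sum())

    @property
    def n_failed_dilution(self) -> int:
        return int((~self.per_feature["pass_dilution"]).sum())

    def summary(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_retained": self.n_retained,
            "n_failed_rsd": self.n_failed_rsd,
            "n_failed_dilution": self.n_failed_dilution,
            "rsd_max": self.rsd_max,
            "r_min": self.r_min,
        }


def compute_qc_rsd(table: FeatureTable, metadata: SampleMetadata) -> pd.Series:
    """Per-feature RSD% over pooled-QC injections.

    RSD = 100 * s / m with m the arithmetic mean and s the n-1 sample
    standard deviation.  A zero mean yields +inf (fails the filter).
    """
    qc_ids = [s for s in metadata.pooled_qc["sample_id"] if s in table.intensities.columns]
    if len(qc_ids) < 2:
        raise ValueError(f"need >= 2 pooled-QC samples, found {len(qc_ids)}")
    x = table.intensities[qc_ids].to_numpy(float)
    mean = x.mean(axis=1)
    sd = x.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        rsd = np.where(mean > 0, 100.0 * sd / np.where(mean > 0, mean, 1.0), np.inf)
    return pd.Series(rsd, index=table.intensities.index, name="qc_rsd")


def compute_dilution_r(table: FeatureTable, metadata: SampleMetadata) -> pd.Series:
    """Per-feature Pearson correlation of intensity against dilution fraction
    over the dilution-QC injections (each injection one point).

    Zero variance in either variable leaves r undefined (NaN), which fails
    the linearity filter downstream.
    """
    dil = metadata.dilution_qc
    dil_ids = [s for s in dil["sample_id"] if s in table.intensities.columns]
    if len(dil_ids) < 3:
        raise ValueError(f"need >= 3 dilution-QC injections, found {len(dil_ids)}")
    frac = dil.loc[dil_ids, "dilution_fraction"].to_numpy(float)
    if len(np.unique(frac)) < 2:
        raise ValueError("dilution-QC series spans fewer than 2 distinct fractions")
    y = table.intensities[dil_ids].to_numpy(float)
    xc = frac - frac.mean()
    yc = y - y.mean(axis=1, keepdims=True)
    denom = np.sqrt((xc**2).sum()) * np.sqrt((yc**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(denom > 0, (yc @ xc) / np.where(denom > 0, denom, 1.0), np.nan)
    return pd.Series(r, index=table.intensities.index, name="dilution_r")


def apply_qc_filters(
    table: FeatureTable,
    metadata: SampleMetadata,
    rsd_max: float = 30.0,
    r_min: float = 0.8,
) -> tuple[FeatureTable, QCReport]:
    """Retain features with qc_rsd <= rsd_max AND dilution_r >= r_min.

    Returns the filtered table restricted to biological samples (QC, dilution
    and blank columns dropped) plus a report covering all input features.
    """
    if not np.isfinite(rsd_max) and rsd_max != np.inf:
        raise ValueError("rsd_max must be finite or +inf")
    rsd = compute_qc_rsd(table, metadata)
    r = compute_dilution_r(table, metadata)
    pass_rsd = rsd.to_numpy() <= rsd_max
    rvals = r.to_numpy()
    pass_dil = np.where(np.isnan(rvals), False, rvals >= r_min)
    retained = pass_rsd & pass_dil
    report = QCReport(
        per_feature=pd.DataFrame(
            {
                "qc_rsd": rsd,
                "dilution_r": r,
                "pass_rsd": pass_rsd,
                "pass_dilution": pass_dil,
                "retained": retained,
            },
            index=table.intensities.index,
        ),
        rsd_max=rsd_max,
        r_min=r_min,
    )
    bio_ids = [s for s in metadata.biological["sample_id"] if s in table.intensities.columns]
    kept = table.intensities.index[retained]
    filtered = FeatureTable(
        table.mode,
        table.features.loc[kept].copy(),
        table.intensities.loc[kept, bio_ids].copy(),
    )
    return filtered, report


def normalize_to_internal_standards(
    table: FeatureTable, metadata: SampleMetadata, is_feature_ids
) -> FeatureTable:
    """Remove per-sample multiplicative scale using spiked internal standards.

    For each biological sample j the scale is the geometric mean over IS
    features i of x_ij / med_i, where med_i is the median of IS feature i
    over biological samples; all intensities in sample j are divided by it.
    Exactly removes any per-sample multiplicative factor.
    """
    is_ids = list(is_feature_ids)
    missing = [f for f in is_ids if f not in table.intensities.index]
    if missing:
        raise ValueError(f"internal-standard features absent from table: {missing}")
    bio_ids = [s for s in metadata.biological["sample_id"] if s in table.intensities.columns]
    x = table.intensities.loc[is_ids, bio_ids].to_numpy(float)
    zero_samples = [bio_ids[j] for j in np.argwhere((x <= 0).any(axis=0)).ravel()]
    if zero_samples:
        raise ValueError(
            f"internal standard missing/zero in biological sample(s): {zero_samples}"
        )
    med = np.median(x, axis=1, keepdims=True)
    scale = np.exp(np.log(x / med).mean(axis=0))  # geometric mean of ratios
    out = table.intensities.copy()
    out.loc[:, bio_ids] = out[bio_ids].to_numpy(float) / scale
    return FeatureTable(table.mode, table.features.copy(), out)


def log_transform(table: FeatureTable, zero_policy: str = "half_min") -> tuple[pd.DataFrame, int]:
    """Natural-log transform with per-feature zero replacement.

    Zeros are replaced by half the smallest positive intensity of that
    feature (``half_min``, default) or by 1 (``one``).  Features that are
    zero everywhere cannot be transformed and are dropped; the count of
    dropped features is returned alongside the (features x samples) frame of
    log abundances.
    """
    x = table.intensities.to_numpy(float).copy()
    all_zero = (x <= 0).all(axis=1)
    n_dropped = int(all_zero.sum())
    keep = ~all_zero
    x = x[keep]
    if zero_policy == "half_min":
        repl = np.array([0.5 * row[row > 0].min() for row in x])
    elif zero_policy == "one":
        repl = np.ones(x.shape[0])
    else:
        raise ValueError(f"unknown zero_policy {zero_policy!r}")
    x = np.where(x > 0, x, repl[:, None])
    logged = pd.DataFrame(
        np.log(x), index=table.intensities.index[keep], columns=table.intensities.columns
    )
    return logged, n_dropped
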