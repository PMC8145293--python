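"""End-to-end orchestration: simulate or load -> QC filter -> internal-
standard normalisation -> accurate-mass annotation -> pathway coverage ->
per-solvent metrics -> ordination + PERMANOVA -> differential abundance,
with a machine-readable run report and a per-solvent ranked comparison.

No composite "best solvent" score is produced: suitability is biomass
specific, so the three criterion families (repeatability, capacity,
differentiation) are surfaced side by side with per-criterion ranks.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotation as ann
from . import diffabund as da
from . import multivariate as mv
from . import pathways as pw
from . import preprocess as pp
from . import solvent_metrics as sm
from .core_io import FeatureTable, SampleMetadata, write_feature_table, write_sample_metadata
from .synthetic import SimulationConfig, generate_compound_db, generate_experiment

log = logging.getLogger("solvent_eval")


@dataclass
class PipelineConfig:
    """One configuration for a full run (simulation-backed by default)."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    n_db_compounds: int | None = None  # defaults to simulation.n_true_compounds
    n_db_pathways: int = 12
    rsd_max: float = 30.0
    r_min: float = 0.8
    ppm_tol: float = 10.0
    q_threshold: float = 0.05
    design: str = "reactor_a"  # or "reactor_b"
    n_perm: int = 9999
    detection_min_fraction: float = 0.5
    seed: int = 0
    outdir: str | None = None

    def __post_init__(self) -> None:
        if not 0 < self.rsd_max:
            raise ValueError("rsd_max must be positive")
        if not -1.0 <= self.r_min <= 1.0:
            raise ValueError(f"r_min must lie in [-1, 1], got {self.r_min}")
        if self.ppm_tol <= 0 or not 0 < self.q_threshold < 1:
            raise ValueError("ppm_tol must be > 0 and q_threshold in (0, 1)")
        if self.design not in ("reactor_a", "reactor_b"):
            raise ValueError(f"unknown design {self.design!r}")


def detected_features(
    table: FeatureTable, sample_ids, min_fraction: float = 0.5
) -> list[str]:
    """Features with non-zero intensity in >= min_fraction of the samples."""
    ids = [s for s in sample_ids if s in table.intensities.columns]
    x = table.intensities[ids].to_numpy(float)
    frac = (x > 0).mean(axis=1)
    return list(table.intensities.index[frac >= min_fraction])


def replicate_rsd(table: FeatureTable, metadata: SampleMetadata, solvent: str) -> float:
    """Median within-cell replicate RSD% for one solvent (repeatability as
    seen in biological replicates, where solvent-specific noise lives)."""
    bio = metadata.biological
    bio = bio[bio["solvent"] == solvent]
    rsds = []
    for (_, _), cell in bio.groupby(["stage", "compartment"], observed=True):
        ids = [s for s in cell["sample_id"] if s in table.intensities.columns]
        if len(ids) < 2:
            continue
        x = table.intensities[ids].to_numpy(float)
        mean = x.mean(axis=1)
        sd = x.std(axis=1, ddof=1)
        ok = mean > 0
        rsds.append(100.0 * sd[ok] / mean[ok])
    if not rsds:
        return float("nan")
    return float(np.median(np.concatenate(rsds)))


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage on a simulated dataset; returns the run report.

    The report nests per-mode sections: QC filtering counts, per-solvent
    capacity/annotation/uniformity, pathway recovery, the PERMANOVA table,
    and differential-abundance counts per solvent.  When ``config.outdir``
    is set, tables and the JSON report are also written there.
    """
    rng = np.random.default_rng(config.seed)
    sim = config.simulation
    n_db = config.n_db_compounds or sim.n_true_compounds
    log.info("generating compound/pathway databases (n=%d)", n_db)
    compound_db, pathway_db = generate_compound_db(n_db, config.n_db_pathways, seed=config.seed)
    log.info("simulating experiment: %d biological samples", sim.n_biological)
    tables, metadata, truth = generate_experiment(sim, compound_db)

    design = mv.reactor_a_design() if config.design == "reactor_a" else mv.reactor_b_design()
    solvents = list(sim.solvents)
    report: dict = {
        "config": {
            "design": config.design,
            "rsd_max": config.rsd_max,
            "r_min": config.r_min,
            "ppm_tol": config.ppm_tol,
            "q_threshold": config.q_threshold,
            "n_perm": config.n_perm,
            "seed": config.seed,
            "n_biological_samples": sim.n_biological,
        },
        "modes": {},
    }
    artifacts: dict = {"metadata": metadata, "truth": truth, "compound_db": compound_db,
                       "pathway_db": pathway_db, "tables": tables}

    for mode, table in tables.items():
        sec: dict = {"n_features_input": table.n_features}
        log.info("[%s] QC filtering %d features", mode, table.n_features)
        filtered, qc_report = pp.apply_qc_filters(
            table, metadata, rsd_max=config.rsd_max, r_min=config.r_min
        )
        sec["qc_filter"] = qc_report.summary()

        is_ids = [f for f in sim.internal_standards if f in filtered.intensities.index]
        if is_ids:
            normalized = pp.normalize_to_internal_standards(filtered, metadata, is_ids)
        else:
            log.warning("[%s] no internal standards survived filtering", mode)
            normalized = filtered
        sec["n_internal_standards_used"] = len(is_ids)

        results = ann.annotate_table(table, compound_db, ppm_tol=config.ppm_tol)
        retained_ids = set(normalized.intensities.index)
        filt_results = [r for r in results if r.feature_id in retained_ids]
        n_feat_ann, n_cmpd = ann.count_annotated(filt_results)
        sec["annotation"] = {"n_annotated_features": n_feat_ann, "n_unique_compounds": n_cmpd}
        ann_by_feature = {r.feature_id: r for r in results}

        # per-solvent groups: features the solvent yields in its biological
        # samples.  Capacity is counted before QC filtration: the shared
        # pooled-QC series censors near the mean extraction level, which
        # would mask per-solvent detection differences among efficient
        # solvents; what a solvent extracts is a property of its own samples.
        group_features: dict[str, list[str]] = {}
        detected_cmpds: dict[str, set] = {}
        counts: dict[str, tuple[int, int]] = {}
        bio = metadata.biological
        for s in solvents:
            ids = list(bio.loc[bio["solvent"] == s, "sample_id"])
            feats = detected_features(table, ids, config.detection_min_fraction)
            feats = [f for f in feats if f not in sim.internal_standards]
            group_features[s] = feats
            cmpds = set()
            for f in feats:
                cmpds.update(m.compound_id for m in ann_by_feature[f].matches)
            detected_cmpds[s] = cmpds
            counts[s] = (len(feats), len(cmpds))
        capacity = sm.capacity_summary(counts) if all(c[0] > 0 for c in counts.values()) else None
        sec["capacity"] = {
            "per_group": {s: counts[s] for s in solvents},
            "summary": capacity.as_dict() if capacity else None,
        }

        coverage = pw.pathway_coverage(detected_cmpds, pathway_db)
        sec["pathways"] = {
            "recovered_per_group": {
                s: pw.recovered_pathway_count(coverage, s) for s in solvents
            },
            "shared_all_groups": pw.shared_pathways(coverage, solvents),
            "mean_coverage_per_group": {
                s: pw.mean_coverage(coverage, s, over="all") for s in solvents
            },
        }

        rsd_dist = sm.rsd_distribution(qc_report, group_features)
        sec["rsd"] = {
            "fractions": rsd_dist.fractions.to_dict("index"),
            "median_per_group": {s: rsd_dist.median(s) for s in solvents},
        }
        sec["uniformity"] = {}
        for s in solvents:
            feats = table.features.loc[group_features[s]]
            sec["uniformity"][s] = {
                "rt": sm.axis_uniformity(feats["rt"]).evenness if len(feats) > 1 else None,
                "mz": sm.axis_uniformity(feats["mz"]).evenness if len(feats) > 1 else None,
            }

        log.info("[%s] ordination + PERMANOVA (%s perms)", mode, config.n_perm)
        dist = mv.bray_curtis(normalized)
        ordination = mv.pcoa(dist)
        perma = mv.permanova(
            dist, metadata, design, n_perm=config.n_perm,
            seed=int(rng.integers(2**31 - 1)),
        )
        sec["permanova"] = perma.table.to_dict("records")
        sec["pcoa_proportion_explained"] = [float(v) for v in ordination.proportion_explained[:4]]

        log_table, n_dropped = pp.log_transform(normalized)
        sec["n_allzero_dropped_at_log"] = n_dropped
        diff_factor = ["stage"] if config.design == "reactor_a" else ["stage", "compartment"]
        diff_counts = {}
        per_solvent_results = {}
        for s in solvents:
            ids = [c for c in log_table.columns
                   if c in bio.index and bio.loc[c, "solvent"] == s]
            sub = log_table[ids]
            res = da.differential_features(sub, metadata, diff_factor if len(diff_factor) > 1 else diff_factor[0],
                                           q_threshold=config.q_threshold)
            n_sig, n_sig_ann = da.count_significant(res, results)
            diff_counts[s] = {
                "n_significant": n_sig,
                "n_significant_annotated": n_sig_ann,
                "n_significant_compounds": da.count_significant_compounds(res, results),
            }
            per_solvent_results[s] = res
        sec["differential_abundance"] = diff_counts

        sec["_replicate_rsd"] = {s: replicate_rsd(normalized, metadata, s) for s in solvents}
        report["modes"][mode] = sec
        artifacts.setdefault("per_mode", {})[mode] = {
            "filtered": filtered,
            "normalized": normalized,
            "qc_report": qc_report,
            "annotations": results,
            "coverage": coverage,
            "distance": dist,
            "pcoa": ordination,
            "permanova": perma,
            "diff": per_solvent_results,
        }

    report["solvent_comparison"] = compare_solvents(report)
    if config.outdir:
        _write_artifacts(config, report, artifacts)
    report["_artifacts"] = artifacts
    return report


def compare_solvents(report: dict) -> dict:
    """Per-solvent summary of the three criterion families with ranks.

    Repeatability: median replicate RSD (lower better) and pooled-QC RSD
    fraction below 5%.  Capacity: detected features, annotated compounds and
    mean axis evenness (higher better).  Differentiation: significant
    differentially-abundant features (higher better).  Ranks are per
    criterion; no composite score is formed.
    """
    modes = report["modes"]
    solvents: list[str] = []
    for sec in modes.values():
        for s in sec["capacity"]["per_group"]:
            if s not in solvents:
                solvents.append(s)
    if len(solvents) < 2:
        raise ValueError("solvent comparison needs >= 2 solvent groups")

    rows = {}
    for s in solvents:
        n_feat = sum(sec["capacity"]["per_group"][s][0] for sec in modes.values())
        n_cmpd = sum(sec["capacity"]["per_group"][s][1] for sec in modes.values())
        med_rsd = float(np.nanmean([sec["_replicate_rsd"][s] for sec in modes.values()]))
        frac5 = float(np.nanmean([
            sec["rsd"]["fractions"][s]["lt_5"] for sec in modes.values()
        ]))
        even_vals = [
            v
            for sec in modes.values()
            for v in (sec["uniformity"][s]["rt"], sec["uniformity"][s]["mz"])
            if v is not None
        ]
        even = float(np.nanmean(even_vals)) if even_vals else float("nan")
        n_sig = sum(sec["differential_abundance"][s]["n_significant"] for sec in modes.values())
        rows[s] = {
            "n_features": n_feat,
            "n_compounds": n_cmpd,
            "median_replicate_rsd": med_rsd,
            "qc_rsd_frac_lt_5": frac5,
            "mean_evenness": even,
            "n_significant": n_sig,
        }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df["rank_capacity"] = df["n_features"].rank(ascending=False, method="min").astype(int)
    df["rank_repeatability"] = df["median_replicate_rsd"].rank(ascending=True, method="min").astype(int)
    df["rank_differentiation"] = df["n_significant"].rank(ascending=False, method="min").astype(int)
    return df.to_dict("index")


def _write_artifacts(config: PipelineConfig, report: dict, artifacts: dict) -> None:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_sample_metadata(artifacts["metadata"], outdir / "sample_metadata.tsv")
    for mode, table in artifacts["tables"].items():
        write_feature_table(table, outdir / f"features_{mode}.tsv")
    for mode, sub in artifacts.get("per_mode", {}).items():
        sub["qc_report"].per_feature.to_csv(outdir / f"qc_report_{mode}.tsv", sep="\t")
        sub["permanova"].table.to_csv(outdir / f"permanova_{mode}.tsv", sep="\t", index=False)
        sub["coverage"].class_sorted().to_csv(outdir / f"pathway_coverage_{mode}.tsv", sep="\t")
    for mode, truth_frame in artifacts["truth"].features.items():
        truth_frame.to_csv(outdir / f"ground_truth_{mode}.tsv", sep="\t")
    clean = {k: v for k, v in report.items() if not k.startswith("_")}
    with open(outdir / "report.json", "w") as fh:
        json.dump(clean, fh, indent=2, default=_json_default)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        v = float(obj)
        return None if np.isnan(v) else v
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, float) and np.isnan(obj):
        return None
    raise TypeError(f"not JSON serialisable: {type(obj)}")
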