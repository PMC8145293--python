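"""Synthetic LC-MS feature tables with known ground truth.

The generator emulates the structure of a two-reactor solvent-comparison
study of EBPR bioreactor communities:

* Reactor A: 5 extraction solvents x 4 EBPR-cycle stages x 3 technical
  replicates, intracellular metabolites only (60 biological samples);
* Reactor B: 3 solvents x 2 stages x 2 compartments (intracellular /
  extracellular) x 3 replicates (36 biological samples);

plus pooled-QC injections interleaved every ``qc_every`` biological runs, an
8-level dilution-QC series and blank injections.

Intensity model (natural-log scale) for a biological sample with solvent s,
stage t, compartment c:

    log x = mu_f + log e(s) + gamma_f(c) + beta_f * [t in affected] + eps,
    eps ~ Normal(0, sigma_bio^2 + sigma_ana(s)^2)

with multiplicative lognormal noise throughout (RSD ~ 100 * sigma for small
sigma, which makes the QC filters analytically checkable).  Pooled-QC
intensity is the per-feature exponential of the mean biological log level
times lognormal analytical noise; dilution-QC intensity is proportional to
the dilution fraction for genuine features and independent of it for
planted contaminants.  Unstable features carry ``sigma_unstable`` instead of
the analytical sigma.  Internal standards are spiked at a constant level in
every non-blank sample.  Intensities below the detection limit are stored as
zero ("not detected").

Compound m/z values follow the single-adduct rule ([M+H]+ / [M-H]-); noise
features receive masses at least 25 ppm away from every database compound,
so accurate-mass annotation is unambiguous by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import PROTON_MASS
from .core_io import (
    NEGATIVE,
    PATHWAY_CLASSES,
    POSITIVE,
    CompoundDB,
    FeatureTable,
    PathwayDB,
    SampleMetadata,
)

MASS_RANGE = (80.0, 900.0)
MIN_SPACING_PPM = 25.0

DEFAULT_DILUTION_LEVELS = (1.0, 0.8, 0.6, 0.4, 0.2, 0.1, 0.01, 0.0)
#: Injections per level; the 0% level gets none (blank-equivalent), keeping
#: the series total at 46 injections.
DEFAULT_DILUTION_INJECTIONS = (10, 5, 3, 3, 5, 10, 10, 0)

DEFAULT_SOLVENTS_A = {"M": 0.75, "MW1": 1.5, "MW2": 1.2, "MW3": 0.95, "MCW": 0.45}
DEFAULT_SOLVENTS_B = {"M": 0.9, "MW1": 1.4, "MCW": 1.1}

DEFAULT_INTERNAL_STANDARDS = {
    "IS_hippuric_acid_d5": 5.0e5,
    "IS_phenylalanine_13C9_15N": 5.0e5,
}


@dataclass
class SimulationConfig:
    """Study-design and noise parameters for one simulated experiment.

    ``solvents`` maps solvent label -> extraction-efficiency multiplier (a
    multiplicative factor on every genuine feature's abundance).
    ``sigma_analytical`` may be overridden per solvent via
    ``sigma_analytical_by_solvent`` (the pooled-QC series, shared across
    solvents, always uses the mean analytical sigma).
    """

    solvents: dict = field(default_factory=lambda: dict(DEFAULT_SOLVENTS_A))
    stages: tuple = ("S1", "S2", "S3", "S4")
    compartments: tuple = ("intracellular",)
    n_replicates: int = 3
    n_true_compounds: int = 120
    n_noise_features: int = 240  # per ionisation mode
    frac_contaminant: float = 0.05
    frac_unstable: float = 0.10
    frac_differential: float = 0.10
    log_fold_change: float = 2.0
    sigma_biological: float = 0.30
    sigma_analytical: float = 0.05
    sigma_analytical_by_solvent: dict | None = None
    sigma_unstable: float = 0.50
    sigma_compartment: float = 1.0
    qc_every: int = 5
    dilution_levels: tuple = DEFAULT_DILUTION_LEVELS
    dilution_injections: tuple = DEFAULT_DILUTION_INJECTIONS
    internal_standards: dict = field(default_factory=lambda: dict(DEFAULT_INTERNAL_STANDARDS))
    n_blanks: int = 2
    # median feature abundance ~4x the detection limit: the lower tail of the
    # abundance distribution is censored, so extraction efficiency shows up in
    # detected-feature counts (as in real feature tables) and not only in scale
    baseline_log_mean: float = math.log(2200.0)
    baseline_log_sd: float = 1.5
    detection_limit: float = 500.0
    modes: tuple = (POSITIVE, NEGATIVE)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_contaminant", "frac_unstable", "frac_differential"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in (
            "sigma_biological",
            "sigma_analytical",
            "sigma_unstable",
            "sigma_compartment",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if len(self.dilution_levels) != len(self.dilution_injections):
            raise ValueError("dilution_levels and dilution_injections length mismatch")
        if self.n_replicates < 1 or self.n_true_compounds < 0 or self.n_noise_features < 0:
            raise ValueError("counts must be non-negative (replicates >= 1)")

    @property
    def n_biological(self) -> int:
        return (
            len(self.solvents)
            * len(self.stages)
            * len(self.compartments)
            * self.n_replicates
        )

    def analytical_sigma(self, solvent: str) -> float:
        if self.sigma_analytical_by_solvent:
            return float(self.sigma_analytical_by_solvent.get(solvent, self.sigma_analytical))
        return self.sigma_analytical

    @property
    def mean_analytical_sigma(self) -> float:
        return float(np.mean([self.analytical_sigma(s) for s in self.solvents]))


def reactor_a_config(**overrides) -> SimulationConfig:
    """The 5-solvent x 4-stage x 3-replicate intracellular design."""
    return SimulationConfig(**{"solvents": dict(DEFAULT_SOLVENTS_A), **overrides})


def reactor_b_config(**overrides) -> SimulationConfig:
    """The 3-solvent x 2-stage x 2-compartment x 3-replicate design."""
    defaults = dict(
        solvents=dict(DEFAULT_SOLVENTS_B),
        stages=("S1", "S3"),
        compartments=("intracellular", "extracellular"),
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@dataclass
class GroundTruth:
    """Per-feature truth flags plus the planted design effects."""

    features: dict  # mode -> DataFrame indexed by feature_id
    solvent_efficiency: dict
    affected_stages: tuple

    def frame(self, mode: str) -> pd.DataFrame:
        return self.features[mode]


# ---------------------------------------------------------------------------
# compound / pathway database generation
# ---------------------------------------------------------------------------

def max_compounds_at_spacing(
    mass_range=MASS_RANGE, spacing_ppm: float = MIN_SPACING_PPM
) -> int:
    """Largest number of masses that fit in the range with the given minimum
    pairwise relative spacing (geometric-progression pigeonhole bound)."""
    lo, hi = mass_range
    return int(math.floor(math.log(hi / lo) / math.log1p(spacing_ppm * 1e-6))) + 1


def _spaced_masses(n: int, rng: np.random.Generator, mass_range=MASS_RANGE,
                   spacing_ppm: float = MIN_SPACING_PPM,
                   avoid: np.ndarray | None = None) -> np.ndarray:
    """Draw n uniform masses whose pairwise relative spacing exceeds
    ``spacing_ppm`` (also relative to any masses in ``avoid``)."""
    cap = max_compounds_at_spacing(mass_range, spacing_ppm)
    n_avoid = 0 if avoid is None else len(avoid)
    if n + n_avoid > cap // 2:
        raise ValueError(
            f"cannot place {n} masses with >{spacing_ppm} ppm spacing in "
            f"{mass_range}; widen the mass range or reduce the count"
        )
    kept: list[float] = []
    existing = np.sort(avoid) if avoid is not None else np.array([])
    tol = spacing_ppm * 1e-6
    attempts = 0
    while len(kept) < n:
        attempts += 1
        if attempts > 1000 * n + 1000:
            raise ValueError("mass sampling failed to converge; range too crowded")
        m = float(rng.uniform(*mass_range))
        pool = np.concatenate([existing, np.array(kept)]) if kept or len(existing) else np.array([])
        if pool.size:
            rel = np.abs(pool - m) / np.minimum(pool, m)
            if rel.min() <= tol:
                continue
        kept.append(m)
    return np.array(kept)


def generate_compound_db(
    n_compounds: int, n_pathways: int, seed: int
) -> tuple[CompoundDB, PathwayDB]:
    """Random compound database with unambiguous accurate-mass spacing plus
    a pathway database whose members cover all compounds."""
    if not n_compounds >= n_pathways >= 1:
        raise ValueError("need n_compounds >= n_pathways >= 1")
    rng = np.random.default_rng([int(seed), 101])
    masses = np.sort(_spaced_masses(n_compounds, rng))
    ids = [f"C{i + 1:05d}" for i in range(n_compounds)]
    compounds = CompoundDB(
        pd.DataFrame(
            {
                "compound_id": ids,
                "name": [f"compound_{i + 1}" for i in range(n_compounds)],
                "monoisotopic_mass": masses,
            }
        )
    )
    # round-robin base assignment covers every compound; random extras overlap
    members: list[set] = [set() for _ in range(n_pathways)]
    for i, cid in enumerate(ids):
        members[i % n_pathways].add(cid)
    for p in range(n_pathways):
        extra = rng.integers(0, max(1, n_compounds // max(2, n_pathways)) + 1)
        if extra:
            members[p].update(rng.choice(ids, size=int(extra), replace=False))
    pathways = PathwayDB(
        pd.DataFrame(
            {
                "pathway_id": [f"PW{p + 1:03d}" for p in range(n_pathways)],
                "class_label": [
                    PATHWAY_CLASSES[p % len(PATHWAY_CLASSES)] for p in range(n_pathways)
                ],
                "members": [frozenset(m) for m in members],
            }
        )
    )
    return compounds, pathways


# ---------------------------------------------------------------------------
# experiment generation
# ---------------------------------------------------------------------------

def _lognormal_noise(rng, sigma, size):
    if np.all(np.asarray(sigma) == 0):
        return np.ones(size)
    return np.exp(rng.normal(0.0, 1.0, size=size) * sigma)


def generate_experiment(
    config: SimulationConfig, compound_db: CompoundDB
) -> tuple[dict, SampleMetadata, GroundTruth]:
    """Simulate feature tables (one per mode), sample metadata and truth.

    Returns ``(tables, metadata, truth)`` where ``tables`` maps ionisation
    mode to a FeatureTable covering biological, pooled-QC, dilution-QC and
    blank samples; deterministic in ``config.seed``.
    """
    if config.n_true_compounds > len(compound_db):
        raise ValueError(
            f"config requests {config.n_true_compounds} compounds but the "
            f"database holds {len(compound_db)}"
        )
    rng_design = np.random.default_rng([config.seed, 1])
    rng_feat = np.random.default_rng([config.seed, 2])
    rng_noise = np.random.default_rng([config.seed, 3])

    # --- sample layout -----------------------------------------------------
    bio_rows = []
    for s in config.solvents:
        for t in config.stages:
            for c in config.compartments:
                for r in range(1, config.n_replicates + 1):
                    comp_tag = "" if len(config.compartments) == 1 else f"_{c[:5]}"
                    bio_rows.append(
                        {
                            "sample_id": f"{s}_{t}{comp_tag}_r{r}",
                            "role": "biological",
                            "solvent": s,
                            "stage": t,
                            "compartment": c,
                            "replicate": r,
                            "dilution_fraction": np.nan,
                        }
                    )
    bio = pd.DataFrame(bio_rows)
    bio = bio.iloc[rng_design.permutation(len(bio))].reset_index(drop=True)

    dil_rows = []
    for level, count in zip(config.dilution_levels, config.dilution_injections):
        for i in range(count):
            dil_rows.append(
                {
                    "sample_id": f"DQC_{level * 100:g}pct_{i + 1:02d}",
                    "role": "dilution_qc",
                    "solvent": "n/a",
                    "stage": "n/a",
                    "compartment": "n/a",
                    "replicate": 0,
                    "dilution_fraction": float(level),
                }
            )

    n_qc = 1 + len(bio) // config.qc_every
    qc_ids = [f"QC_{i + 1:02d}" for i in range(n_qc)]
    blank_ids = [f"BLANK_{i + 1}" for i in range(config.n_blanks)]

    # run order: blanks, dilution series, then pooled QC before run 1 and
    # after every qc_every biological runs
    ordered: list[tuple[str, str]] = [(b, "blank") for b in blank_ids]
    ordered += [(r["sample_id"], "dilution_qc") for r in dil_rows]
    qc_iter = iter(qc_ids)
    ordered.append((next(qc_iter), "pooled_qc"))
    for i, sid in enumerate(bio["sample_id"], start=1):
        ordered.append((sid, "biological"))
        if i % config.qc_every == 0:
            nxt = next(qc_iter, None)
            if nxt is not None:
                ordered.append((nxt, "pooled_qc"))

    meta_rows = []
    run_order = {sid: i + 1 for i, (sid, _) in enumerate(ordered)}
    for b in blank_ids:
        meta_rows.append(
            dict(sample_id=b, role="blank", solvent="n/a", stage="n/a",
                 compartment="n/a", replicate=0, dilution_fraction=np.nan)
        )
    meta_rows += dil_rows
    for q in qc_ids:
        meta_rows.append(
            dict(sample_id=q, role="pooled_qc", solvent="n/a", stage="n/a",
                 compartment="n/a", replicate=0, dilution_fraction=np.nan)
        )
    meta_rows += bio.to_dict("records")
    meta = pd.DataFrame(meta_rows)
    meta["run_order"] = meta["sample_id"].map(run_order)
    meta = meta.sort_values("run_order").reset_index(drop=True)
    metadata = SampleMetadata(meta[[
        "sample_id", "role", "solvent", "stage", "compartment", "replicate",
        "run_order", "dilution_fraction",
    ]])

    # --- per-mode feature models ------------------------------------------
    affected = tuple(config.stages[len(config.stages) // 2:])  # later (aerobic) stages
    chosen = list(compound_db.compound_ids[: config.n_true_compounds])
    db_masses = compound_db.masses.to_numpy(float)

    tables: dict[str, FeatureTable] = {}
    truth_frames: dict[str, pd.DataFrame] = {}
    for mode in config.modes:
        n_cmpd = len(chosen)
        n_noise = config.n_noise_features
        n_is = len(config.internal_standards)
        n_feat = n_cmpd + n_noise + n_is

        fids = (
            [f"{mode[:3]}_F{i + 1:04d}" for i in range(n_cmpd + n_noise)]
            + list(config.internal_standards)
        )
        cmpd_of = {fids[i]: chosen[i] for i in range(n_cmpd)}

        sign = 1.0 if mode == POSITIVE else -1.0
        cmpd_masses = compound_db.masses.loc[chosen].to_numpy(float)
        noise_masses = _spaced_masses(
            n_noise + n_is, rng_feat, avoid=db_masses
        )
        neutral = np.concatenate([cmpd_masses, noise_masses])
        mz = neutral + sign * PROTON_MASS
        rt = rng_feat.uniform(0.5, 12.0, size=n_feat)

        baseline = rng_feat.normal(config.baseline_log_mean, config.baseline_log_sd, n_feat)
        is_is = np.zeros(n_feat, bool)
        is_is[n_cmpd + n_noise:] = True
        flags_rand = rng_feat.uniform(size=n_feat)
        is_contaminant = (flags_rand < config.frac_contaminant) & ~is_is
        flags_rand2 = rng_feat.uniform(size=n_feat)
        is_unstable = (flags_rand2 < config.frac_unstable) & ~is_is & ~is_contaminant
        is_diff = (rng_feat.uniform(size=n_feat) < config.frac_differential) & ~is_is & ~is_contaminant
        beta = np.where(
            is_diff,
            config.log_fold_change * rng_feat.choice([-1.0, 1.0], size=n_feat),
            0.0,
        )
        gamma = {
            c: (rng_feat.normal(0.0, config.sigma_compartment, n_feat) if i > 0 else np.zeros(n_feat))
            for i, c in enumerate(config.compartments)
        }

        sigma_feat_ana = np.where(is_unstable, config.sigma_unstable, config.mean_analytical_sigma)

        # biological samples (latent log levels; contaminants ignore design)
        bio_meta = metadata.biological
        latent = np.empty((n_feat, len(bio_meta)))
        for j, (_, row) in enumerate(bio_meta.iterrows()):
            s = row["solvent"]
            sig_ana = np.where(
                is_unstable, config.sigma_unstable, config.analytical_sigma(s)
            )
            sig = np.sqrt(config.sigma_biological**2 + sig_ana**2)
            eps = rng_noise.normal(0.0, 1.0, n_feat) * sig
            log_x = (
                baseline
                + math.log(config.solvents[s])
                + gamma[row["compartment"]]
                + beta * (row["stage"] in affected)
                + eps
            )
            log_x = np.where(is_contaminant, baseline + eps, log_x)
            latent[:, j] = log_x
        # internal standards: constant spike, analytical noise only
        spikes = np.array([config.internal_standards[f] for f in fids[n_cmpd + n_noise:]])
        for k, spike in enumerate(spikes):
            idx = n_cmpd + n_noise + k
            latent[idx, :] = math.log(spike) + rng_noise.normal(
                0.0, config.mean_analytical_sigma, len(bio_meta)
            )

        qc_level = np.exp(latent.mean(axis=1))

        cols = {}
        for j, sid in enumerate(bio_meta["sample_id"]):
            cols[sid] = np.exp(latent[:, j])
        for sid in qc_ids:
            cols[sid] = qc_level * _lognormal_noise(rng_noise, sigma_feat_ana, n_feat)
        for row in dil_rows:
            d = row["dilution_fraction"]
            # dilutions are made from the IS-spiked QC pool, so internal
            # standards dilute proportionally like genuine compounds
            base = np.where(is_contaminant, qc_level, d * qc_level)
            vals = base * _lognormal_noise(rng_noise, sigma_feat_ana, n_feat)
            cols[row["sample_id"]] = vals
        for bid in blank_ids:
            cols[bid] = np.zeros(n_feat)

        inten = pd.DataFrame(cols, index=pd.Index(fids, name="feature_id"))
        inten[inten < config.detection_limit] = 0.0
        feats = pd.DataFrame({"mz": mz, "rt": rt}, index=inten.index)
        order = [sid for sid, _ in ordered]
        tables[mode] = FeatureTable(mode, feats, inten[order])

        truth_frames[mode] = pd.DataFrame(
            {
                "compound_id": [cmpd_of.get(f, "") for f in fids],
                "is_internal_standard": is_is,
                "is_contaminant": is_contaminant,
                "is_unstable": is_unstable,
                "is_differential": is_diff,
                "beta": beta,
                "baseline_log": baseline,
            },
            index=pd.Index(fids, name="feature_id"),
        )

    truth = GroundTruth(
        features=truth_frames,
        solvent_efficiency=dict(config.solvents),
        affected_stages=affected,
    )
    return tables, metadata, truth


# ---------------------------------------------------------------------------
# truth-based evaluation of the downstream pipeline
# ---------------------------------------------------------------------------

def truth_report(
    truth: GroundTruth,
    mode: str,
    qc_report=None,
    annotations=None,
    diff_result=None,
) -> dict:
    """Confusion summaries of filtering / annotation / differential testing
    against the planted ground truth for one ionisation mode."""
    tf = truth.frame(mode)
    out: dict = {}

    if qc_report is not None:
        pf = qc_report.per_feature
        if not set(pf.index) == set(tf.index):
            raise ValueError("QC report and ground truth cover different features")
        pf = pf.loc[tf.index]
        cont = tf["is_contaminant"].to_numpy()
        unst = tf["is_unstable"].to_numpy()
        clean = ~cont & ~unst
        fail_dil = ~pf["pass_dilution"].to_numpy()
        fail_rsd = ~pf["pass_rsd"].to_numpy()
        out["dilution_filter"] = {
            "sensitivity": float(fail_dil[cont].mean()) if cont.any() else float("nan"),
            "specificity": float(pf["pass_dilution"].to_numpy()[clean].mean())
            if clean.any()
            else float("nan"),
        }
        out["rsd_filter"] = {
            "sensitivity": float(fail_rsd[unst].mean()) if unst.any() else float("nan"),
            "specificity": float(pf["pass_rsd"].to_numpy()[clean].mean())
            if clean.any()
            else float("nan"),
        }
        retained = pf["retained"].to_numpy()
        out["overall_filter"] = {
            "retained_clean_fraction": float(retained[clean].mean()) if clean.any() else float("nan"),
            "retained_flagged_fraction": float(retained[cont | unst].mean())
            if (cont | unst).any()
            else float("nan"),
        }

    if annotations is not None:
        true_cmpd = tf["compound_id"]
        n_correct = n_cmpd_feat = n_false = n_noise_feat = 0
        for res in annotations:
            truth_id = true_cmpd.get(res.feature_id, "")
            if truth_id:
                n_cmpd_feat += 1
                if res.matches and res.matches[0].compound_id == truth_id:
                    n_correct += 1
            elif not tf.loc[res.feature_id, "is_internal_standard"]:
                n_noise_feat += 1
                if res.matches:
                    n_false += 1
        out["annotation"] = {
            "accuracy": n_correct / n_cmpd_feat if n_cmpd_feat else float("nan"),
            "false_annotation_rate": n_false / n_noise_feat if n_noise_feat else float("nan"),
        }

    if diff_result is not None:
        dt = diff_result.table
        truth_flags = tf.loc[dt.index, "is_differential"].to_numpy()
        called = dt["significant"].to_numpy()
        n_true = int(truth_flags.sum())
        n_called = int(called.sum())
        out["differential"] = {
            "recall": float(called[truth_flags].mean()) if n_true else None,
            "precision": float(truth_flags[called].mean()) if n_called else None,
        }
    return out
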