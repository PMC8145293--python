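"""Putative compound identification by accurate mass.

Features are assigned [M+H]+ / [M-H]- adducts (positive / negative ionisation
mode), so the neutral monoisotopic mass is recovered as m/z -+ the proton
mass.  A feature is putatively annotated with every database compound whose
monoisotopic mass lies within a relative tolerance (default 10 ppm, boundary
inclusive) of the observed neutral mass; the ppm error is expressed relative
to the theoretical (database) mass.

The matcher is an interval search on a sorted mass array and is
contract-equivalent to an exhaustive all-pairs scan.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import POSITIVE, NEGATIVE, CompoundDB, FeatureTable

#: Proton mass in Da; the electron mass (~0.5 mDa) is neglected, a sub-0.01
#: ppm approximation over the 80-900 Da range covered here.
PROTON_MASS = 1.007276


@dataclass(frozen=True)
class CompoundMatch:
    compound_id: str
    theoretical_mass: float
    ppm_error: float


@dataclass
class AnnotationResult:
    """All database matches for one feature, sorted by |ppm error|."""

    feature_id: str
    mode: str
    observed_mz: float
    neutral_mass: float
    matches: list[CompoundMatch]

    @property
    def is_annotated(self) -> bool:
        return len(self.matches) > 0


def neutral_mass(mz: float, mode: str) -> float:
    """Neutral monoisotopic mass from an observed m/z under the single-adduct
    rule: M = mz - proton (positive mode), M = mz + proton (negative mode)."""
    if mode == POSITIVE:
        m = mz - PROTON_MASS
    elif mode == NEGATIVE:
        m = mz + PROTON_MASS
    else:
        raise ValueError(f"unknown ionisation mode {mode!r}")
    if m <= 0:
        raise ValueError(f"m/z {mz} below proton mass in {mode} mode")
    return m


def ppm_difference(observed: float, theoretical: float) -> float:
    """Signed relative mass error in parts per million (denominator:
    theoretical mass)."""
    return 1e6 * (observed - theoretical) / theoretical


def match_compounds(
    neutral_masses,
    compound_db: CompoundDB,
    ppm_tol: float = 10.0,
    feature_ids=None,
    mode: str = POSITIVE,
    observed_mz=None,
) -> list[AnnotationResult]:
    """Match observed neutral masses against the compound database.

    Every compound within ``ppm_tol`` (inclusive) is returned, sorted by
    absolute ppm error.  No match yields an empty list, never an error.
    """
    if ppm_tol <= 0:
        raise ValueError("ppm_tol must be positive")
    if len(compound_db) == 0:
        raise ValueError("compound database is empty")
    masses = np.asarray(neutral_masses, dtype=float)
    if feature_ids is None:
        feature_ids = [f"query_{i}" for i in range(len(masses))]
    if observed_mz is None:
        observed_mz = [np.nan] * len(masses)

    db = compound_db.table.sort_values("monoisotopic_mass")
    db_mass = db["monoisotopic_mass"].to_numpy(float)
    db_ids = db["compound_id"].to_numpy(object)

    results = []
    for fid, m_obs, mz in zip(feature_ids, masses, observed_mz):
        # |M_obs - M_c| <= tol * M_c / 1e6  <=>  M_c in [M_obs/(1+t), M_obs/(1-t)];
        # interval widened by machine epsilon, exact check per candidate
        t = ppm_tol * 1e-6
        lo = np.searchsorted(db_mass, m_obs / (1.0 + t) * (1.0 - 1e-12), side="left")
        hi = np.searchsorted(db_mass, m_obs / (1.0 - t) * (1.0 + 1e-12), side="right")
        matches = []
        for k in range(lo, hi):
            err = ppm_difference(m_obs, db_mass[k])
            if abs(err) <= ppm_tol + 1e-6:  # boundary inclusive at fp precision
                matches.append(CompoundMatch(str(db_ids[k]), float(db_mass[k]), float(err)))
        matches.sort(key=lambda c: abs(c.ppm_error))
        results.append(AnnotationResult(str(fid), mode, float(mz), float(m_obs), matches))
    return results


def annotate_table(
    table: FeatureTable, compound_db: CompoundDB, ppm_tol: float = 10.0
) -> list[AnnotationResult]:
    """Annotate every feature of a table via the mode's adduct rule."""
    mz = table.features["mz"].to_numpy(float)
    masses = [neutral_mass(v, table.mode) for v in mz]
    return match_compounds(
        masses,
        compound_db,
        ppm_tol=ppm_tol,
        feature_ids=table.feature_ids,
        mode=table.mode,
        observed_mz=mz,
    )


def count_annotated(results) -> tuple[int, int]:
    """(number of features with >= 1 match, number of unique matched compounds)."""
    n_feat = sum(1 for r in results if r.is_annotated)
    compounds = set()
    for r in results:
        compounds.update(m.compound_id for m in r.matches)
    return n_feat, len(compounds)


def annotated_compounds(results) -> set:
    """Union of compound ids matched by any feature."""
    out = set()
    for r in results:
        out.update(m.compound_id for m in r.matches)
    return out
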