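"""Typed data model and delimited-text I/O for the solvent-evaluation pipeline.

The pipeline starts from aligned LC-MS feature tables (one per ionisation
mode) of per-sample ion intensities, a sample-metadata table describing the
experimental design and QC structure, and small compound/pathway databases
used for accurate-mass annotation and pathway-recovery scoring.

All files are plain delimited text: comma-separated for ``.csv``,
tab-separated otherwise.  Intensities are floating point; a stored zero means
"not detected in this sample".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

POSITIVE = "positive"
NEGATIVE = "negative"
MODES = (POSITIVE, NEGATIVE)

ROLES = ("biological", "pooled_qc", "dilution_qc", "blank")

#: KEGG-style pathway class abbreviations used in coverage matrices.
PATHWAY_CLASSES = ("AA", "C", "E", "L", "N", "O", "OAA", "SM", "T", "TP", "V", "X")

_FEATURE_COLS = ("feature_id", "mz", "rt")
_METADATA_COLS = (
    "sample_id",
    "role",
    "solvent",
    "stage",
    "compartment",
    "replicate",
    "run_order",
    "dilution_fraction",
)


class ParseError(ValueError):
    """Raised when an input file violates the documented format."""


def _sep(path: Path | str) -> str:
    return "," if str(path).endswith(".csv") else "\t"


@dataclass
class FeatureTable:
    """Aligned LC-MS features with per-sample intensities for one ion mode.

    ``features`` is indexed by feature_id with columns ``mz`` (Th) and ``rt``
    (minutes); ``intensities`` is a (features x samples) frame of non-negative
    abundances sharing the feature index.
    """

    mode: str
    features: pd.DataFrame
    intensities: pd.DataFrame

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ParseError(f"unknown ionisation mode {self.mode!r}")
        if not self.features.index.is_unique:
            dup = self.features.index[self.features.index.duplicated()][0]
            raise ParseError(f"duplicate feature id {dup!r}")
        if not self.intensities.columns.is_unique:
            dup = self.intensities.columns[self.intensities.columns.duplicated()][0]
            raise ParseError(f"duplicate sample id {dup!r}")
        if not self.features.index.equals(self.intensities.index):
            raise ParseError("feature metadata and intensity matrix indices differ")
        mz = self.features["mz"].to_numpy(float)
        rt = self.features["rt"].to_numpy(float)
        if not np.all(np.isfinite(mz)) or np.any(mz <= 0):
            bad = self.features.index[~(np.isfinite(mz) & (mz > 0))][0]
            raise ParseError(f"non-positive or non-numeric m/z for feature {bad!r}")
        if not np.all(np.isfinite(rt)) or np.any(rt < 0):
            bad = self.features.index[~(np.isfinite(rt) & (rt >= 0))][0]
            raise ParseError(f"negative or non-numeric retention time for feature {bad!r}")
        vals = self.intensities.to_numpy(float)
        if not np.all(np.isfinite(vals)):
            i, j = np.argwhere(~np.isfinite(vals))[0]
            raise ParseError(
                f"non-finite intensity at feature {self.intensities.index[i]!r}, "
                f"sample {self.intensities.columns[j]!r}"
            )
        if np.any(vals < 0):
            i, j = np.argwhere(vals < 0)[0]
            raise ParseError(
                f"negative intensity at feature {self.intensities.index[i]!r}, "
                f"sample {self.intensities.columns[j]!r}"
            )

    @property
    def feature_ids(self) -> list[str]:
        return list(self.features.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.intensities.columns)

    @property
    def n_features(self) -> int:
        return len(self.features)

    def subset_features(self, feature_ids) -> "FeatureTable":
        ids = list(feature_ids)
        return FeatureTable(self.mode, self.features.loc[ids].copy(), self.intensities.loc[ids].copy())

    def subset_samples(self, sample_ids) -> "FeatureTable":
        ids = list(sample_ids)
        return FeatureTable(self.mode, self.features.copy(), self.intensities[ids].copy())

    def copy(self) -> "FeatureTable":
        return FeatureTable(self.mode, self.features.copy(), self.intensities.copy())


@dataclass
class SampleMetadata:
    """Per-sample design metadata: QC role, solvent, stage, compartment,
    replicate, acquisition run order and (dilution QCs only) dilution fraction.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in _METADATA_COLS if c not in t.columns]
        if missing:
            raise ParseError(f"metadata missing columns {missing}")
        if not t["sample_id"].is_unique:
            dup = t["sample_id"][t["sample_id"].duplicated()].iloc[0]
            raise ParseError(f"duplicate sample id {dup!r}")
        bad_role = set(t["role"]) - set(ROLES)
        if bad_role:
            raise ParseError(f"unknown sample role(s) {sorted(bad_role)}")
        if not t["run_order"].is_unique:
            dup = t["run_order"][t["run_order"].duplicated()].iloc[0]
            raise ParseError(f"duplicate run_order {dup!r}")
        dil = t["role"] == "dilution_qc"
        frac = pd.to_numeric(t["dilution_fraction"], errors="coerce")
        if dil.any() and frac[dil].isna().any():
            bad = t.loc[dil & frac.isna(), "sample_id"].iloc[0]
            raise ParseError(f"dilution_qc sample {bad!r} lacks dilution_fraction")
        if (~dil & frac.notna()).any():
            bad = t.loc[~dil & frac.notna(), "sample_id"].iloc[0]
            raise ParseError(f"non-dilution sample {bad!r} carries a dilution_fraction")
        if dil.any() and ((frac[dil] < 0) | (frac[dil] > 1)).any():
            raise ParseError("dilution_fraction outside [0, 1]")
        bio = t["role"] == "biological"
        for col in ("solvent", "stage", "replicate"):
            if bio.any() and t.loc[bio, col].isna().any():
                bad = t.loc[bio & t[col].isna(), "sample_id"].iloc[0]
                raise ParseError(f"biological sample {bad!r} lacks {col}")
        self.table = t.set_index("sample_id", drop=False)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def with_role(self, role: str) -> pd.DataFrame:
        return self.table[self.table["role"] == role]

    @property
    def biological(self) -> pd.DataFrame:
        return self.with_role("biological")

    @property
    def pooled_qc(self) -> pd.DataFrame:
        return self.with_role("pooled_qc")

    @property
    def dilution_qc(self) -> pd.DataFrame:
        return self.with_role("dilution_qc")


@dataclass
class CompoundDB:
    """Compound id -> name and monoisotopic neutral mass (Da)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        for col in ("compound_id", "name", "monoisotopic_mass"):
            if col not in t.columns:
                raise ParseError(f"compound DB missing column {col!r}")
        if not t["compound_id"].is_unique:
            dup = t["compound_id"][t["compound_id"].duplicated()].iloc[0]
            raise ParseError(f"duplicate compound id {dup!r}")
        mass = pd.to_numeric(t["monoisotopic_mass"], errors="coerce")
        if mass.isna().any() or (mass <= 0).any() or not np.isfinite(mass).all():
            bad = t.loc[~(mass > 0) | ~np.isfinite(mass), "compound_id"].iloc[0]
            raise ParseError(f"non-positive/non-finite mass for compound {bad!r}")
        t = t.copy()
        t["monoisotopic_mass"] = mass
        self.table = t.set_index("compound_id", drop=False)

    @property
    def compound_ids(self) -> list[str]:
        return list(self.table["compound_id"])

    @property
    def masses(self) -> pd.Series:
        return self.table["monoisotopic_mass"]

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class PathwayDB:
    """Pathway id -> class label and member compound ids."""

    table: pd.DataFrame  # columns pathway_id, class_label, members (frozenset)

    def __post_init__(self) -> None:
        t = self.table
        for col in ("pathway_id", "class_label", "members"):
            if col not in t.columns:
                raise ParseError(f"pathway DB missing column {col!r}")
        if not t["pathway_id"].is_unique:
            dup = t["pathway_id"][t["pathway_id"].duplicated()].iloc[0]
            raise ParseError(f"duplicate pathway id {dup!r}")
        t = t.copy()
        t["members"] = t["members"].map(frozenset)
        for pid, members in zip(t["pathway_id"], t["members"]):
            if not members:
                raise ParseError(f"pathway {pid!r} has no members")
            if any(not m for m in members):
                raise ParseError(f"pathway {pid!r} has an empty member id")
        self.table = t.set_index("pathway_id", drop=False)

    @property
    def pathway_ids(self) -> list[str]:
        return list(self.table["pathway_id"])

    def members(self, pathway_id: str) -> frozenset:
        return self.table.loc[pathway_id, "members"]

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class Dataset:
    """A full study: one feature table per ionisation mode plus metadata and
    the optional annotation databases."""

    tables: dict[str, FeatureTable]
    metadata: SampleMetadata
    compound_db: CompoundDB | None = None
    pathway_db: PathwayDB | None = None
    extras: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_feature_table(path: Path | str, mode: str) -> FeatureTable:
    """Read a feature table: columns feature_id, mz, rt, then one per sample."""
    df = pd.read_csv(path, sep=_sep(path), dtype={"feature_id": str})
    missing = [c for c in _FEATURE_COLS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    sample_cols = [c for c in df.columns if c not in _FEATURE_COLS]
    feats = df[["mz", "rt"]].apply(pd.to_numeric, errors="coerce").astype(float)
    feats.index = pd.Index(df["feature_id"], name="feature_id")
    inten = df[sample_cols].apply(pd.to_numeric, errors="coerce")
    inten.index = feats.index
    return FeatureTable(mode, feats, inten)


def write_feature_table(table: FeatureTable, path: Path | str) -> None:
    out = pd.concat([table.features[["mz", "rt"]], table.intensities], axis=1)
    out.insert(0, "feature_id", table.features.index)
    out.to_csv(path, sep=_sep(path), index=False, float_format="%.10g")


def read_sample_metadata(path: Path | str) -> SampleMetadata:
    df = pd.read_csv(path, sep=_sep(path), dtype={"sample_id": str, "solvent": str})
    return SampleMetadata(df)


def write_sample_metadata(meta: SampleMetadata, path: Path | str) -> None:
    meta.table.to_csv(path, sep=_sep(path), index=False)


def read_compound_db(path: Path | str) -> CompoundDB:
    df = pd.read_csv(path, sep=_sep(path), dtype={"compound_id": str, "name": str})
    return CompoundDB(df)


def write_compound_db(db: CompoundDB, path: Path | str) -> None:
    db.table.to_csv(path, sep=_sep(path), index=False, float_format="%.10g")


def read_pathway_db(path: Path | str) -> PathwayDB:
    df = pd.read_csv(path, sep=_sep(path), dtype=str)
    if "members" not in df.columns:
        raise ParseError(f"{path}: missing column 'members'")
    df = df.copy()
    df["members"] = [
        frozenset(s for s in str(m).split(";") if s) for m in df["members"]
    ]
    return PathwayDB(df)


def write_pathway_db(db: PathwayDB, path: Path | str) -> None:
    out = db.table.copy()
    out["members"] = [";".join(sorted(m)) for m in out["members"]]
    out.to_csv(path, sep=_sep(path), index=False)


def validate_dataset(dataset: Dataset) -> list[str]:
    """Cross-reference checks; returns human-readable violations (empty = ok)."""
    violations: list[str] = []
    meta_ids = set(dataset.metadata.sample_ids)
    for mode, table in dataset.tables.items():
        tab_ids = set(table.sample_ids)
        for sid in sorted(tab_ids - meta_ids):
            violations.append(f"sample {sid!r} in {mode} table but absent from metadata")
        for sid in sorted(meta_ids - tab_ids):
            violations.append(f"sample {sid!r} in metadata but absent from {mode} table")
        if table.mode != mode:
            violations.append(f"table stored under mode {mode!r} declares {table.mode!r}")
    if dataset.pathway_db is not None and dataset.compound_db is not None:
        known = set(dataset.compound_db.compound_ids)
        for pid in dataset.pathway_db.pathway_ids:
            unknown = dataset.pathway_db.members(pid) - known
            for cid in sorted(unknown):
                violations.append(f"pathway {pid!r} references unknown compound {cid!r}")
    annotations = dataset.extras.get("annotations")
    if annotations is not None and dataset.compound_db is not None:
        known = set(dataset.compound_db.compound_ids)
        for res in annotations:
            for m in res.matches:
                if m.compound_id not in known:
                    violations.append(
                        f"annotation of feature {res.feature_id!r} references "
                        f"unknown compound {m.compound_id!r}"
                    )
    return violations
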