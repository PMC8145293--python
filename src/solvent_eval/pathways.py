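"""Pathway-recovery scoring.

A pathway is "recovered" by an extraction method when at least one of its
member compounds is putatively detected; its coverage is the proportion of
member compounds detected.  Scores are presence-only (independent of
intensities) and are tabulated per analysis group (e.g. solvent x ionisation
mode), mirroring a coverage heatmap with classes as row blocks.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .core_io import PathwayDB


@dataclass
class CoverageMatrix:
    """Pathways x groups matrix of member-compound coverage in [0, 1]."""

    coverage: pd.DataFrame  # index pathway_id, columns group labels
    class_labels: pd.Series  # pathway_id -> class label
    n_members: pd.Series  # pathway_id -> member count

    @property
    def recovered(self) -> pd.DataFrame:
        """Boolean mask: >= 1 member compound detected."""
        return self.coverage > 0

    def tidy(self) -> pd.DataFrame:
        out = self.coverage.reset_index().melt(
            id_vars="pathway_id", var_name="group", value_name="coverage"
        )
        out["class_label"] = out["pathway_id"].map(self.class_labels)
        out["recovered"] = out["coverage"] > 0
        return out

    def class_sorted(self) -> pd.DataFrame:
        """Coverage matrix sorted by pathway class then id, for heatmaps."""
        order = (
            pd.DataFrame({"class_label": self.class_labels})
            .sort_values(["class_label"], kind="stable")
            .index
        )
        out = self.coverage.loc[order].copy()
        out.insert(0, "class_label", self.class_labels.loc[order])
        return out


def pathway_coverage(detected_compounds: dict, pathway_db: PathwayDB) -> CoverageMatrix:
    """Coverage cell(g, p) = |members(p) & detected(g)| / |members(p)|.

    ``detected_compounds`` maps group label -> set of detected compound ids.
    """
    rows = {}
    for pid in pathway_db.pathway_ids:
        members = pathway_db.members(pid)
        rows[pid] = {
            g: len(members & set(det)) / len(members)
            for g, det in detected_compounds.items()
        }
    cov = pd.DataFrame.from_dict(rows, orient="index")
    cov = cov.reindex(index=pathway_db.pathway_ids, columns=list(detected_compounds))
    cov.index.name = "pathway_id"
    return CoverageMatrix(
        coverage=cov,
        class_labels=pathway_db.table["class_label"],
        n_members=pathway_db.table["members"].map(len),
    )


def recovered_pathway_count(matrix: CoverageMatrix, group: str) -> int:
    """Pathways with >= 1 detected member compound in the group."""
    if group not in matrix.coverage.columns:
        raise KeyError(f"unknown group label {group!r}")
    return int((matrix.coverage[group] > 0).sum())


def shared_pathways(matrix: CoverageMatrix, groups) -> int:
    """Pathways recovered by every one of the listed groups."""
    groups = list(groups)
    for g in groups:
        if g not in matrix.coverage.columns:
            raise KeyError(f"unknown group label {g!r}")
    return int((matrix.coverage[groups] > 0).all(axis=1).sum())


def mean_coverage(matrix: CoverageMatrix, group: str, over: str = "all") -> float:
    """Mean coverage across pathways: over all pathways or only recovered
    ones.  Returns NaN when ``over='recovered'`` and nothing was recovered."""
    if group not in matrix.coverage.columns:
        raise KeyError(f"unknown group label {group!r}")
    col = matrix.coverage[group]
    if over == "all":
        return float(col.mean())
    if over == "recovered":
        rec = col[col > 0]
        return float(rec.mean()) if len(rec) else float("nan")
    raise ValueError(f"over must be 'all' or 'recovered', got {over!r}")
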