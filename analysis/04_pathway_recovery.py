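"""Pathway recovery per solvent.

For each solvent's detected-and-annotated compounds, computes the proportion
of each pathway's member compounds recovered, the number of pathways with at
least one detected member, the pathway set shared by all solvents, and the
mean coverage — the biological-interpretation view of solvent choice.
Outputs a class-sorted coverage matrix per reactor/mode to results/pathways/.
"""

import sys
from pathlib import Path

from solvent_eval.annotation import annotate_table
from solvent_eval.core_io import (
    read_compound_db,
    read_feature_table,
    read_pathway_db,
    read_sample_metadata,
)
from solvent_eval.pathways import (
    mean_coverage,
    pathway_coverage,
    recovered_pathway_count,
    shared_pathways,
)
from solvent_eval.pipeline import detected_features

ROOT = Path(__file__).resolve().parents[1] / "results"


def main():
    outdir = ROOT / "pathways"
    outdir.mkdir(parents=True, exist_ok=True)
    for reactor in ("reactor_a", "reactor_b"):
        datadir = ROOT / "data" / reactor
        metadata = read_sample_metadata(datadir / "sample_metadata.tsv")
        compound_db = read_compound_db(datadir / "compounds.tsv")
        pathway_db = read_pathway_db(datadir / "pathways.tsv")
        bio = metadata.biological
        for mode in ("positive", "negative"):
            table = read_feature_table(datadir / f"features_{mode}.tsv", mode)
            ann = {r.feature_id: r for r in annotate_table(table, compound_db)}
            detected = {}
            for solvent in bio["solvent"].unique():
                ids = list(bio.loc[bio["solvent"] == solvent, "sample_id"])
                cmpds = set()
                for f in detected_features(table, ids):
                    cmpds.update(m.compound_id for m in ann[f].matches)
                detected[solvent] = cmpds
            matrix = pathway_coverage(detected, pathway_db)
            matrix.class_sorted().to_csv(
                outdir / f"{reactor}_{mode}_coverage.tsv", sep="\t")
            solvents = list(detected)
            recovered = {s: recovered_pathway_count(matrix, s) for s in solvents}
            print(f"{reactor}/{mode}: pathways recovered per solvent {recovered}; "
                  f"shared by all: {shared_pathways(matrix, solvents)}; "
                  f"mean coverage "
                  + ", ".join(f"{s}={mean_coverage(matrix, s, 'all'):.2f}"
                              for s in solvents))


if __name__ == "__main__":
    sys.exit(main())
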