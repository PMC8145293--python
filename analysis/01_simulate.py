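"""Simulate the two-reactor solvent-comparison study.

Generates synthetic LC-MS feature tables with known ground truth for both
bioreactor designs — Reactor A (5 solvents x 4 EBPR-cycle stages x 3
replicates, intracellular) and Reactor B (3 solvents x 2 stages x 2
compartments x 3 replicates) — together with the pooled-QC series, the
46-injection dilution-QC series, blanks, and the compound/pathway databases
used for annotation.  Everything is written as delimited text under
results/data/.
"""

import sys
from pathlib import Path

from solvent_eval.core_io import (
    write_compound_db,
    write_feature_table,
    write_pathway_db,
    write_sample_metadata,
)
from solvent_eval.synthetic import (
    generate_compound_db,
    generate_experiment,
    reactor_a_config,
    reactor_b_config,
)

SEED = 2026
OUT = Path(__file__).resolve().parents[1] / "results" / "data"


def write_dataset(name, cfg):
    compound_db, pathway_db = generate_compound_db(
        cfg.n_true_compounds, 12, seed=cfg.seed)
    tables, metadata, truth = generate_experiment(cfg, compound_db)
    outdir = OUT / name
    outdir.mkdir(parents=True, exist_ok=True)
    for mode, table in tables.items():
        write_feature_table(table, outdir / f"features_{mode}.tsv")
    write_sample_metadata(metadata, outdir / "sample_metadata.tsv")
    write_compound_db(compound_db, outdir / "compounds.tsv")
    write_pathway_db(pathway_db, outdir / "pathways.tsv")
    for mode, frame in truth.features.items():
        frame.to_csv(outdir / f"ground_truth_{mode}.tsv", sep="\t")
    n_bio = len(metadata.biological)
    print(f"{name}: {n_bio} biological samples, {len(metadata.pooled_qc)} pooled QCs, "
          f"{len(metadata.dilution_qc)} dilution-QC injections, "
          f"{tables['positive'].n_features} features/mode -> {outdir}")


def main():
    write_dataset("reactor_a", reactor_a_config(seed=SEED))
    write_dataset("reactor_b", reactor_b_config(seed=SEED + 1))


if __name__ == "__main__":
    sys.exit(main())
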