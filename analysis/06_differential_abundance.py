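"""Differential abundance between EBPR-cycle stages, per solvent.

Within each solvent, one-way ANOVA of log-transformed abundances across
stages (stage x compartment combinations for Reactor B) with
Benjamini-Hochberg FDR at q < 0.05, counting significant features and the
annotated subset — the extent to which each solvent captures the
physiological contrast, checked against the planted stage effects.
Outputs: results/differential/.
"""

import sys
from pathlib import Path

import pandas as pd

from solvent_eval.annotation import annotate_table
from solvent_eval.core_io import (
    read_compound_db,
    read_feature_table,
    read_sample_metadata,
)
from solvent_eval.diffabund import count_significant, differential_features
from solvent_eval.preprocess import log_transform

ROOT = Path(__file__).resolve().parents[1] / "results"


def main():
    outdir = ROOT / "differential"
    outdir.mkdir(parents=True, exist_ok=True)
    factors = {"reactor_a": "stage", "reactor_b": ["stage", "compartment"]}
    rows = []
    for reactor, factor in factors.items():
        datadir = ROOT / "data" / reactor
        metadata = read_sample_metadata(datadir / "sample_metadata.tsv")
        compound_db = read_compound_db(datadir / "compounds.tsv")
        truth = pd.read_csv(datadir / "ground_truth_positive.tsv", sep="\t",
                            index_col="feature_id")
        bio = metadata.biological
        for mode in ("positive", "negative"):
            table = read_feature_table(datadir / f"features_{mode}.tsv", mode)
            annotations = annotate_table(table, compound_db)
            counts = {}
            for solvent in bio["solvent"].unique():
                ids = list(bio.loc[bio["solvent"] == solvent, "sample_id"])
                logged, _ = log_transform(table.subset_samples(ids))
                res = differential_features(logged, metadata, factor)
                n_sig, n_ann = count_significant(res, annotations)
                counts[solvent] = n_sig
                rows.append(dict(reactor=reactor, mode=mode, solvent=solvent,
                                 n_significant=n_sig, n_significant_annotated=n_ann))
            print(f"{reactor}/{mode}: significant features per solvent {counts}")
    pd.DataFrame(rows).to_csv(outdir / "significant_counts.tsv", sep="\t", index=False)


if __name__ == "__main__":
    sys.exit(main())
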