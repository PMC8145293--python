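import numpy as np
import pandas as pd
import pytest

from solvent_eval.core_io import FeatureTable, SampleMetadata
from solvent_eval.synthetic import (
    generate_compound_db,
    generate_experiment,
    reactor_a_config,
)


def make_metadata(rows):
    return SampleMetadata(pd.DataFrame(rows))


@pytest.fixture
def qc_metadata():
    """3 pooled QCs, a 3-point dilution series and 4 biological samples."""
    rows = []
    order = 1
    for i in range(3):
        rows.append(dict(sample_id=f"q{i}", role="pooled_qc", solvent="n/a",
                         stage="n/a", compartment="n/a", replicate=0,
                         run_order=order, dilution_fraction=np.nan))
        order += 1
    for frac in (1.0, 0.5, 0.0):
        rows.append(dict(sample_id=f"d{frac}", role="dilution_qc", solvent="n/a",
                         stage="n/a", compartment="n/a", replicate=0,
                         run_order=order, dilution_fraction=frac))
        order += 1
    for i, (sol, stage) in enumerate([("M", "S1"), ("M", "S2"), ("W", "S1"), ("W", "S2")]):
        rows.append(dict(sample_id=f"b{i}", role="biological", solvent=sol,
                         stage=stage, compartment="intracellular", replicate=1,
                         run_order=order, dilution_fraction=np.nan))
        order += 1
    return make_metadata(rows)


def make_table(intensity_rows, sample_ids, mode="positive", mz=None, rt=None):
    fids = list(intensity_rows)
    n = len(fids)
    feats = pd.DataFrame(
        {
            "mz": mz if mz is not None else np.linspace(100.0, 500.0, n),
            "rt": rt if rt is not None else np.linspace(1.0, 10.0, n),
        },
        index=pd.Index(fids, name="feature_id"),
    )
    inten = pd.DataFrame(
        {s: [float(intensity_rows[f][j]) for f in fids] for j, s in enumerate(sample_ids)},
        index=feats.index,
    )
    return FeatureTable(mode, feats, inten)


@pytest.fixture(scope="session")
def small_experiment():
    """A Reactor-A-shaped simulated study at reduced feature count."""
    cfg = reactor_a_config(seed=11, n_true_compounds=25, n_noise_features=35)
    compound_db, pathway_db = generate_compound_db(25, 6, seed=11)
    tables, metadata, truth = generate_experiment(cfg, compound_db)
    return dict(config=cfg, compound_db=compound_db, pathway_db=pathway_db,
                tables=tables, metadata=metadata, truth=truth)
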