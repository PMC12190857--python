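"""Shared fixtures: small layouts, an engineered filter fixture, and one
session-scoped default synthetic cohort run end to end."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from cfmeth.filters import CountMatrix, SampleSheet, run_filter_cascade
from cfmeth.genome import GenomeLayout, build_bin_grid, cpg_per_bin
from cfmeth.simulate import SimulationConfig, simulate_counts, simulate_genome

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=60)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def layout_small() -> GenomeLayout:
    return GenomeLayout.from_dict({"chrA": 3_000, "chrB": 1_000})


@pytest.fixture(scope="session")
def grid_small(layout_small):
    return build_bin_grid(layout_small, 300)


@pytest.fixture(scope="session")
def default_cohort():
    """Default synthetic cohort: genome, tracks, counts, truth, filtered
    matrix, and filter report — computed once per session."""
    cfg = SimulationConfig(seed=1)
    layout, sequences, db = simulate_genome(cfg)
    grid = build_bin_grid(layout, cfg.bin_width)
    counts, sheet, truth = simulate_counts(cfg, grid, sequences, db)
    cpg = cpg_per_bin(grid, sequences)
    filtered, report = run_filter_cascade(counts, sheet, db.blacklist, cpg)
    return {
        "config": cfg,
        "layout": layout,
        "sequences": sequences,
        "db": db,
        "grid": grid,
        "counts": counts,
        "sheet": sheet,
        "truth": truth,
        "cpg": cpg,
        "filtered": filtered,
        "report": report,
    }


def make_cascade_fixture():
    """A 10-bin, hand-engineered fixture where each cascade stage removes
    exactly one designated bin.

    Genome: one chromosome of 3,000 bp -> bins 0..9 of 300 bp.
      bin 0: blacklisted (1-bp overlap)
      bin 1: PBL background (21 reads in one PBL sample; strict > 20)
      bin 2: low total (sum 9 over cfDNA samples; strict < 10)
      bin 3: no CpG
      bin 4: PBL exactly 20 in both samples  -> retained (boundary)
      bin 5: cfDNA total exactly 10          -> retained (boundary)
      bins 6-9: comfortably clean
    """
    layout = GenomeLayout.from_dict({"chrF": 3_000})
    grid = build_bin_grid(layout, 300)
    from cfmeth.genome import GInterval

    blacklist = [GInterval("chrF", 299, 300)]  # 1-bp overlap with bin 0 only

    samples = ["OC1", "OC2", "BEN1", "HLT1", "PBL1", "PBL2"]
    groups = ["OC", "OC", "benign", "healthy", "PBL", "PBL"]
    sheet = SampleSheet(
        pd.DataFrame({"sample_id": samples, "group": groups, "batch": "b1"})
    )
    counts = pd.DataFrame(
        20, index=range(10), columns=samples, dtype=np.int64
    )
    counts.index.name = "bin_id"
    counts.loc[:, ["PBL1", "PBL2"]] = 0
    counts.loc[1, "PBL1"] = 21  # strict > 20 in one PBL sample
    counts.loc[4, ["PBL1", "PBL2"]] = 20  # boundary: retained
    counts.loc[2, ["OC1", "OC2", "BEN1", "HLT1"]] = [3, 3, 2, 1]  # total 9
    counts.loc[5, ["OC1", "OC2", "BEN1", "HLT1"]] = [3, 3, 2, 2]  # total 10
    cm = CountMatrix(grid, counts)

    # per-bin sequence: one CpG everywhere except bin 3
    seq = []
    for b in range(10):
        block = list("ATATAT" * 50)
        if b != 3:
            block[10], block[11] = "C", "G"
        seq.append("".join(block))
    sequences = {"chrF": "".join(seq)}
    cpg = cpg_per_bin(grid, sequences)
    return cm, sheet, blacklist, cpg, sequences


@pytest.fixture()
def cascade_fixture():
    return make_cascade_fixture()
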