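"""Packaged reference tables.

The robust hypermethylated DMR table ships with the package: 15 unique
gene-annotated 300-bp regions (hg38, 1-based inclusive coordinates as
printed in clinical reports) with their log2 fold changes and BH-adjusted
p-values.  These regions were reproducibly hypermethylated in ovarian-cancer
plasma cfDNA relative to non-cancer controls and serve as a fixed worked
example / fixture for the coordinate and annotation machinery.
"""

from __future__ import annotations

from importlib.resources import files

import pandas as pd

from .genome import GInterval, from_one_based

__all__ = ["load_robust_dmr_table", "robust_dmr_intervals"]


def load_robust_dmr_table() -> pd.DataFrame:
    """The packaged robust hypermethylated DMR table.

    Columns: gene, chrom, start_1based, stop_1based (1-based inclusive),
    log2fc, padj.  Every region spans exactly 300 bp.
    """
    path = files("cfmeth.data").joinpath("robust_dmrs.tsv")
    with path.open() as fh:
        return pd.read_csv(fh, sep="\t")


def robust_dmr_intervals() -> list[GInterval]:
    """The robust DMRs as half-open intervals named by their gene."""
    table = load_robust_dmr_table()
    return [
        from_one_based(row.chrom, row.start_1based, row.stop_1based, name=row.gene)
        for row in table.itertuples()
    ]
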