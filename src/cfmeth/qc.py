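"""ddPCR quality control for cfDNA samples.

Two multiplexed droplet-digital-PCR read-outs gate samples before library
preparation:

* **Contamination with high-molecular-weight DNA** — the percentage of
  lymphocyte-derived copies (PBC assay) relative to total cfDNA copies
  (RPP30 assay): ``(PBC / RPP30) x 100``.  Below 0.5% is acceptable; above
  2% flags the sample as contaminated; the band in between (and the exact
  boundary values) is reported as ``warn``.
* **cfDNA integrity** — the ratio of long- to short-amplicon copies.
  Genuine cfDNA is short, so a low ratio (< 0.4) is acceptable and a high
  ratio (> 0.7) indicates genomic contamination; in between is ``warn``.

Wells enter the calculation only when they reach 10,000 accepted droplets
(inclusive).  Technical replicate wells are averaged after that gating; a
sample with no admissible well is ``invalid``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "QCRecord",
    "QCVerdict",
    "contamination_pct",
    "integrity_ratio",
    "well_admissible",
    "merge_replicates",
    "assess_sample",
    "evaluate_wells",
    "MIN_ACCEPTED_DROPLETS",
]

MIN_ACCEPTED_DROPLETS = 10_000
CONTAMINATION_PASS = 0.5  # percent
CONTAMINATION_FAIL = 2.0
INTEGRITY_PASS = 0.4  # long/short ratio
INTEGRITY_FAIL = 0.7


@dataclass(frozen=True)
class QCRecord:
    """One ddPCR well (or a replicate-merged pseudo-well) for one sample."""

    sample_id: str
    pbc_copies: float
    rpp30_copies: float
    long_copies: float
    short_copies: float
    accepted_droplets: int
    replicate: int = 0

    def __post_init__(self) -> None:
        for fname in ("pbc_copies", "rpp30_copies", "long_copies", "short_copies"):
            if getattr(self, fname) < 0:
                raise ValueError(f"{fname} must be >= 0")
        if self.accepted_droplets < 0:
            raise ValueError("accepted_droplets must be >= 0")


@dataclass(frozen=True)
class QCVerdict:
    sample_id: str
    contamination_pct: float
    contamination_flag: str
    integrity_ratio: float
    integrity_flag: str
    droplet_ok: bool
    n_wells: int = 0
    n_admissible: int = 0


def _flag(value: float, pass_below: float, fail_above: float) -> str:
    """pass below the lower bound, fail above the upper, warn in between
    (boundary values inclusive into warn)."""
    if math.isnan(value):
        return "invalid"
    if value < pass_below:
        return "pass"
    if value > fail_above:
        return "fail"
    return "warn"


def contamination_pct(pbc: float, rpp30: float) -> tuple[float, str]:
    """HMW-DNA contamination percentage (PBC/RPP30 x 100) and its flag."""
    if rpp30 <= 0:
        return float("nan"), "invalid"
    value = pbc / rpp30 * 100.0
    return value, _flag(value, CONTAMINATION_PASS, CONTAMINATION_FAIL)


def integrity_ratio(long: float, short: float) -> tuple[float, str]:
    """Long/short amplicon copy ratio and its flag."""
    if short <= 0:
        return float("nan"), "invalid"
    value = long / short
    return value, _flag(value, INTEGRITY_PASS, INTEGRITY_FAIL)


def well_admissible(accepted_droplets: int) -> bool:
    """True iff the well reached the accepted-droplet minimum (inclusive)."""
    return accepted_droplets >= MIN_ACCEPTED_DROPLETS


def merge_replicates(records: Sequence[QCRecord]) -> QCRecord:
    """Average copy numbers over admissible replicate wells of one sample.

    Raises if the records span multiple samples; if no well is admissible
    the merged record keeps the (inadmissible) maximum droplet count so the
    downstream verdict comes out invalid.
    """
    if not records:
        raise ValueError("no records to merge")
    ids = {r.sample_id for r in records}
    if len(ids) > 1:
        raise ValueError(f"records span multiple samples: {sorted(ids)}")
    ok = [r for r in records if well_admissible(r.accepted_droplets)]
    pool = ok if ok else records
    n = len(pool)
    return QCRecord(
        sample_id=records[0].sample_id,
        pbc_copies=sum(r.pbc_copies for r in pool) / n,
        rpp30_copies=sum(r.rpp30_copies for r in pool) / n,
        long_copies=sum(r.long_copies for r in pool) / n,
        short_copies=sum(r.short_copies for r in pool) / n,
        accepted_droplets=max(r.accepted_droplets for r in pool),
        replicate=-1,
    )


def assess_sample(records: Sequence[QCRecord]) -> QCVerdict:
    """Merge replicate wells and classify a sample on both QC metrics."""
    n_adm = sum(well_admissible(r.accepted_droplets) for r in records)
    merged = merge_replicates(records)
    if n_adm == 0:
        return QCVerdict(
            sample_id=merged.sample_id,
            contamination_pct=float("nan"),
            contamination_flag="invalid",
            integrity_ratio=float("nan"),
            integrity_flag="invalid",
            droplet_ok=False,
            n_wells=len(records),
            n_admissible=0,
        )
    c_val, c_flag = contamination_pct(merged.pbc_copies, merged.rpp30_copies)
    i_val, i_flag = integrity_ratio(merged.long_copies, merged.short_copies)
    return QCVerdict(
        sample_id=merged.sample_id,
        contamination_pct=c_val,
        contamination_flag=c_flag,
        integrity_ratio=i_val,
        integrity_flag=i_flag,
        droplet_ok=True,
        n_wells=len(records),
        n_admissible=n_adm,
    )


def _records_from_long(wells: pd.DataFrame) -> dict[str, list[QCRecord]]:
    """Long-format well table -> per-sample QCRecord lists.

    Expected columns: sample_id, replicate, assay (pbc/rpp30/long/short),
    copies_per_ul, accepted_droplets.  Droplet counts are per physical well
    (replicate), shared by the multiplexed assays.
    """
    required = {"sample_id", "replicate", "assay", "copies_per_ul", "accepted_droplets"}
    missing = required - set(wells.columns)
    if missing:
        raise ValueError(f"wells table missing columns: {sorted(missing)}")
    out: dict[str, list[QCRecord]] = {}
    for (sample, rep), sub in wells.groupby(["sample_id", "replicate"], sort=True):
        copies = dict(zip(sub["assay"], sub["copies_per_ul"]))
        unknown = set(copies) - {"pbc", "rpp30", "long", "short"}
        if unknown:
            raise ValueError(f"unknown assay labels: {sorted(unknown)}")
        rec = QCRecord(
            sample_id=str(sample),
            pbc_copies=float(copies.get("pbc", 0.0)),
            rpp30_copies=float(copies.get("rpp30", 0.0)),
            long_copies=float(copies.get("long", 0.0)),
            short_copies=float(copies.get("short", 0.0)),
            accepted_droplets=int(sub["accepted_droplets"].iloc[0]),
            replicate=int(rep),
        )
        out.setdefault(str(sample), []).append(rec)
    return out


def evaluate_wells(wells: pd.DataFrame) -> pd.DataFrame:
    """QC report for a long-format well table, one row per sample."""
    verdicts = [assess_sample(recs) for recs in _records_from_long(wells).values()]
    report = pd.DataFrame([v.__dict__ for v in verdicts])
    return report.sort_values("sample_id").reset_index(drop=True)


def write_report(report: pd.DataFrame, tsv_path: str | Path, json_path: str | Path | None = None) -> None:
    report.to_csv(tsv_path, sep="\t", index=False, float_format="%.6g")
    if json_path is not None:
        flags = {
            row.sample_id: {
                "contamination": row.contamination_flag,
                "integrity": row.integrity_flag,
                "droplet_ok": bool(row.droplet_ok),
            }
            for row in report.itertuples()
        }
        with open(json_path, "w") as fh:
            json.dump(flags, fh, indent=2, sort_keys=True)
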