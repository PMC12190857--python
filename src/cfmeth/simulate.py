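"""Synthetic cfMeDIP-seq cohort generator with ground truth.

The raw patient sequencing data behind this kind of study cannot be
shared, so the package ships a generator that reproduces the *statistical
structure* the analysis assumes, end to end:

* a small multi-chromosome genome with CpG-depleted background sequence and
  CpG-dense islands, plus annotation tracks (blacklist, islands, stranded
  gene models with exon/UTR structure, repeats);
* negative-binomially distributed bin counts whose baseline mean scales
  with bin CpG content, per-sample log-normal depth factors, group-specific
  hypermethylation spikes (log2 fold changes drawn from the 0.9-1.9 range
  observed for robust ovarian-cancer DMRs), a leukocyte high-background bin
  track, and one over-sequenced outlier sample (the "OC40" analogue);
* ddPCR quality-control wells spanning pass / warn / fail regimes;
* a :class:`SyntheticTruth` record (spiked bins, true effects, affected
  genes, background bins, outlier id) for parameter-recovery testing.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .annotate import AnnotationDB, GeneModel, REPEAT_CLASSES
from .filters import CountMatrix, SampleSheet
from .genome import BinGrid, GenomeLayout, GInterval, cpg_per_bin

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "simulate_genome",
    "simulate_counts",
    "simulate_ddpcr_wells",
    "simulate_gene_sets",
]


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Group sizes follow the cohort this analysis targets (40 ovarian-cancer,
    38 benign, 38 healthy plasma samples and 20 external leukocyte
    references); spike effect sizes are uniform on [0.9, 1.9] log2 units,
    the range reported for robust hypermethylated regions; the outlier
    depth multiplier reflects a sample sequenced at roughly an order of
    magnitude greater depth.
    """

    # genome
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 1_500_000, "chr2": 1_500_000}
    )
    bin_width: int = 300
    island_spacing: int = 30_000  # mean distance between island starts
    island_length: tuple[int, int] = (400, 1_200)
    island_cpg_rate: float = 0.10  # CpG starts per bp inside islands
    background_cpg_depletion: float = 0.92  # fraction of chance CpGs removed
    gene_length: tuple[int, int] = (4_000, 15_000)
    gene_gap: tuple[int, int] = (3_000, 20_000)
    n_blacklist_per_chrom: int = 2
    blacklist_length: tuple[int, int] = (1_000, 3_000)
    repeat_density: float = 1 / 4_000  # repeats per bp

    # cohort
    n_oc: int = 40
    n_benign: int = 38
    n_healthy: int = 38
    n_pbl: int = 20

    # count model
    mu_base: float = 5.0  # NB baseline mean at zero CpG slope
    beta_cpg: float = 0.15  # per-CpG multiplicative slope: mu0 = mu_base*(1+beta*c)
    mu_no_cpg: float = 0.05  # residual background mean for CpG-free bins
    dispersion: float = 0.2  # NB alpha; var = mu + alpha*mu^2
    depth_sigma: float = 0.25  # log-normal depth-factor SD (log scale)

    # spikes and nuisance structure
    n_spikes: int = 100
    lfc_range: tuple[float, float] = (0.9, 1.9)
    hypo_fraction: float = 0.0  # fraction of spikes made hypomethylated
    spikes_in_genes: bool = True
    # cancer hypermethylation preferentially hits CpG islands and shores;
    # these fractions mirror the observed CpG-feature mix of
    # hypermethylated regions (islands ~10%, shores ~15%)
    spike_island_frac: float = 0.10
    spike_shore_frac: float = 0.15
    pbl_bin_fraction: float = 0.03
    pbl_inflation: float = 10.0
    pbl_depth: float = 0.5  # leukocyte reference libraries vs plasma depth
    pbl_cpg_cap: float = 5.0  # CpG islands are unmethylated in leukocytes:
    # their MeDIP signal does not scale into island-level CpG densities
    outlier_multiplier: float = 10.0

    n_batches: int = 4
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_oc, self.n_benign, self.n_healthy, self.n_pbl) < 1:
            raise ValueError("all group sizes must be >= 1")
        if self.bin_width < 1:
            raise ValueError("bin width must be >= 1")
        if not 0.0 <= self.hypo_fraction <= 1.0:
            raise ValueError("hypo_fraction must be in [0, 1]")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")


@dataclass
class SyntheticTruth:
    """Ground truth of one simulated cohort."""

    spiked_bins: dict[int, float]  # bin id -> true log2 fold change
    spike_genes: dict[int, tuple[str, ...]]  # bin id -> overlapped gene names
    pbl_background_bins: set[int]
    outlier_sample: str

    @property
    def spiked_gene_set(self) -> set[str]:
        return {g for genes in self.spike_genes.values() for g in genes}

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            {
                "bin_id": b,
                "true_lfc": lfc,
                "genes": ",".join(self.spike_genes.get(b, ())) or ".",
            }
            for b, lfc in sorted(self.spiked_bins.items())
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Genome simulation

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _simulate_sequence(
    length: int,
    islands: list[tuple[int, int]],
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> str:
    """Random sequence, CpG-depleted outside islands, CpG-enriched inside."""
    arr = _BASES[rng.integers(0, 4, size=length)].copy()
    in_island = np.zeros(length, dtype=bool)
    for s, e in islands:
        in_island[s:e] = True
    # deplete chance CpGs in background (mutate the G)
    cg = np.nonzero((arr[:-1] == ord("C")) & (arr[1:] == ord("G")) & ~in_island[:-1])[0]
    kill = cg[rng.random(len(cg)) < cfg.background_cpg_depletion]
    arr[kill + 1] = np.where(rng.random(len(kill)) < 0.5, ord("A"), ord("T"))
    # implant CpGs inside islands
    for s, e in islands:
        n_cpg = rng.binomial(max(e - s - 1, 1), cfg.island_cpg_rate)
        pos = s + rng.choice(max(e - s - 1, 1), size=min(n_cpg, max(e - s - 1, 1)), replace=False)
        arr[pos] = ord("C")
        arr[pos + 1] = ord("G")
    return arr.tobytes().decode("ascii")


def _place_islands(length: int, cfg: SimulationConfig, rng: np.random.Generator) -> list[tuple[int, int]]:
    if cfg.island_spacing <= 0:
        return []
    islands: list[tuple[int, int]] = []
    pos = int(rng.integers(1_000, cfg.island_spacing))
    while pos < length - cfg.island_length[1] - 1:
        ilen = int(rng.integers(cfg.island_length[0], cfg.island_length[1] + 1))
        islands.append((pos, pos + ilen))
        pos += ilen + int(rng.integers(cfg.island_spacing // 2, 3 * cfg.island_spacing // 2))
    return islands


def _make_gene(
    name: str, chrom: str, start: int, end: int, rng: np.random.Generator
) -> GeneModel:
    strand = "+" if rng.random() < 0.5 else "-"
    n_exons = int(rng.integers(2, 7))
    length = end - start
    seg = length // n_exons
    exons = []
    for k in range(n_exons):
        es = start + k * seg + int(rng.integers(0, max(seg // 3, 1)))
        el = int(rng.integers(100, 401))
        ee = min(es + el, start + (k + 1) * seg, end)
        if ee > es:
            exons.append((es, ee))
    if not exons:
        exons = [(start, min(start + 200, end))]
    # anchor terminal exons at the body ends so UTRs sit at the boundaries
    exons[0] = (start, exons[0][1])
    exons[-1] = (exons[-1][0], end) if exons[-1][0] < end else exons[-1]
    exons = sorted(set(exons))
    first, last = exons[0], exons[-1]
    u5_len = int(rng.integers(50, 151))
    u3_len = int(rng.integers(50, 151))
    if strand == "+":
        utr5 = ((first[0], min(first[0] + u5_len, first[1])),)
        utr3 = ((max(last[1] - u3_len, last[0]), last[1]),)
    else:
        utr5 = ((max(last[1] - u5_len, last[0]), last[1]),)
        utr3 = ((first[0], min(first[0] + u3_len, first[1])),)
    return GeneModel(
        name=name, chrom=chrom, strand=strand, start=start, end=end,
        exons=tuple(exons), utr5=utr5, utr3=utr3,
    )


_REPEAT_LEN = {"LINE": (500, 6_000), "SINE": (100, 300), "LTR": (300, 1_000), "other": (200, 2_000)}
_REPEAT_P = np.array([0.30, 0.30, 0.15, 0.25])


def simulate_genome(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[GenomeLayout, dict[str, str], AnnotationDB]:
    """Generate layout, FASTA sequences, and all annotation tracks."""
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    layout = GenomeLayout.from_dict(config.chrom_lengths)
    min_needed = config.gene_length[0] + 2_000
    for name, length in layout.chromosomes:
        if length < min_needed:
            raise ValueError(
                f"chromosome {name!r} ({length} bp) shorter than one gene model "
                f"(needs >= {min_needed} bp)"
            )

    sequences: dict[str, str] = {}
    islands: list[GInterval] = []
    genes: list[GeneModel] = []
    repeats: list[GInterval] = []
    blacklist: list[GInterval] = []
    gene_no = 0

    for chrom, length in layout.chromosomes:
        isl = _place_islands(length, config, rng)
        sequences[chrom] = _simulate_sequence(length, isl, config, rng)
        islands.extend(GInterval(chrom, s, e, name="island") for s, e in isl)

        pos = int(rng.integers(*config.gene_gap))
        while pos + config.gene_length[0] < length - 1_000:
            glen = int(rng.integers(*config.gene_length))
            gend = min(pos + glen, length - 1)
            gene_no += 1
            genes.append(_make_gene(f"G{gene_no:04d}", chrom, pos, gend, rng))
            pos = gend + int(rng.integers(*config.gene_gap))

        n_rep = rng.poisson(config.repeat_density * length)
        classes = rng.choice(len(REPEAT_CLASSES), size=n_rep, p=_REPEAT_P)
        for ci in classes:
            cls = REPEAT_CLASSES[ci]
            rlen = int(rng.integers(*_REPEAT_LEN[cls]))
            rlen = min(rlen, length - 1)
            rs = int(rng.integers(0, length - rlen))
            repeats.append(GInterval(chrom, rs, rs + rlen, name=cls))

        for _ in range(config.n_blacklist_per_chrom):
            blen = int(rng.integers(*config.blacklist_length))
            bs = int(rng.integers(0, length - blen))
            blacklist.append(GInterval(chrom, bs, bs + blen, name="blacklist"))

    db = AnnotationDB(
        layout=layout,
        cpg_islands=islands,
        genes=genes,
        repeats=repeats,
        blacklist=blacklist,
    )
    return layout, sequences, db


# ---------------------------------------------------------------------------
# Count simulation


def _nb_draw(
    mean: np.ndarray, alpha: float, rng: np.random.Generator
) -> np.ndarray:
    """NB(mu, alpha) with var = mu + alpha*mu^2; Poisson when alpha ~ 0."""
    mean = np.asarray(mean, dtype=float)
    if alpha < 1e-12:
        return rng.poisson(mean)
    r = 1.0 / alpha
    p = r / (r + mean)
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    out[pos] = rng.negative_binomial(r, p[pos])
    return out


def _sample_ids(config: SimulationConfig) -> tuple[list[str], list[str]]:
    ids, groups = [], []
    for prefix, group, n in (
        ("OC", "OC", config.n_oc),
        ("BEN", "benign", config.n_benign),
        ("HLT", "healthy", config.n_healthy),
        ("PBL", "PBL", config.n_pbl),
    ):
        for k in range(1, n + 1):
            ids.append(f"{prefix}{k:02d}")
            groups.append(group)
    return ids, groups


def _draw_spike_bins(
    config: SimulationConfig,
    grid: BinGrid,
    db: AnnotationDB,
    eligible: set[int],
    rng: np.random.Generator,
) -> np.ndarray:
    """Spiked-bin placement with a CpG-context mix: a configured fraction
    of spikes lands on island- and shore-overlapping bins (cancer
    hypermethylation concentrates there), the remainder uniformly over the
    eligible set."""
    from .annotate import derive_cpg_context

    ctx = derive_cpg_context(db.cpg_islands, grid.layout)
    island_bins: set[int] = set()
    shore_bins: set[int] = set()
    for chrom in grid.layout.names:
        for s, e in ctx.sets[chrom]["island"]:
            island_bins.update(grid.overlapping_bins(GInterval(chrom, s, e)))
        for s, e in ctx.sets[chrom]["shore"]:
            shore_bins.update(grid.overlapping_bins(GInterval(chrom, s, e)))
    shore_bins -= island_bins

    pools = [
        (sorted(eligible & island_bins), round(config.spike_island_frac * config.n_spikes)),
        (sorted(eligible & shore_bins), round(config.spike_shore_frac * config.n_spikes)),
    ]
    chosen: list[int] = []
    for pool, want in pools:
        pool = [b for b in pool if b not in chosen]
        take = min(want, len(pool))
        if take:
            chosen.extend(rng.choice(pool, size=take, replace=False).tolist())
    rest_pool = sorted(eligible - set(chosen))
    rest = config.n_spikes - len(chosen)
    chosen.extend(rng.choice(rest_pool, size=rest, replace=False).tolist())
    return np.array(sorted(chosen))


def simulate_counts(
    config: SimulationConfig,
    grid: BinGrid,
    sequences: dict[str, str],
    db: AnnotationDB,
    rng: np.random.Generator | None = None,
) -> tuple[CountMatrix, SampleSheet, SyntheticTruth]:
    """NB bin x sample counts with spikes, depth factors and background.

    count[b, s] ~ NB(mean = d_s * mu0(cpg_b) * 2^(lfc_b * [s in OC]), alpha)
    for plasma samples; leukocyte (PBL) samples get `pbl_inflation`-times
    the baseline mean on the designated background bins.  One ovarian-cancer
    sample receives the outlier depth multiplier.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    cpg = cpg_per_bin(grid, sequences)
    B = grid.n_bins

    mu0 = np.where(
        cpg > 0, config.mu_base * (1.0 + config.beta_cpg * cpg), config.mu_no_cpg
    )

    # eligible spike bins: CpG-bearing, outside blacklist, outside PBL track
    from .filters import blacklist_filter

    black_bins = blacklist_filter(grid, db.blacklist)
    n_pbl_bins = int(round(config.pbl_bin_fraction * B))
    pbl_bins = set(rng.choice(B, size=n_pbl_bins, replace=False).tolist()) if n_pbl_bins else set()

    eligible = set(np.nonzero(cpg > 0)[0].tolist()) - black_bins - pbl_bins
    if config.spikes_in_genes:
        gene_bins: set[int] = set()
        for gene in db.genes:
            gene_bins.update(grid.overlapping_bins(gene.body))
        eligible &= gene_bins
    eligible_arr = np.array(sorted(eligible))
    if config.n_spikes > len(eligible_arr):
        raise ValueError(
            f"spike set ({config.n_spikes}) larger than eligible bins ({len(eligible_arr)})"
        )
    spike_ids = _draw_spike_bins(config, grid, db, eligible, rng)
    lfc = rng.uniform(*config.lfc_range, size=config.n_spikes)
    hypo = rng.random(config.n_spikes) < config.hypo_fraction
    lfc = np.where(hypo, -lfc, lfc)
    spiked = dict(zip(spike_ids.tolist(), lfc.tolist()))

    spike_genes: dict[int, tuple[str, ...]] = {}
    for b in spike_ids.tolist():
        iv = grid.bin_interval(b)
        names = tuple(
            g.name for g in db.genes if g.chrom == iv.chrom and iv.start < g.end and g.start < iv.end
        )
        spike_genes[b] = names

    ids, groups = _sample_ids(config)
    depth = np.exp(rng.normal(0.0, config.depth_sigma, size=len(ids)))
    outlier = f"OC{config.n_oc:02d}"
    # multiplier applied to the nominal unit depth so the outlier's library
    # lands at ~multiplier x the cohort median
    depth[ids.index(outlier)] = config.outlier_multiplier

    lfc_vec = np.zeros(B)
    for b, v in spiked.items():
        lfc_vec[b] = v
    pbl_mask = np.zeros(B, dtype=bool)
    pbl_mask[sorted(pbl_bins)] = True

    # leukocyte baseline: CpG-capped (islands unmethylated in leukocytes)
    mu_pbl = np.where(
        cpg > 0,
        config.mu_base * (1.0 + config.beta_cpg * np.minimum(cpg, config.pbl_cpg_cap)),
        config.mu_no_cpg,
    )

    cols = {}
    for s, group, d in zip(ids, groups, depth):
        if group == "OC":
            mean = mu0 * d * np.exp2(lfc_vec)
        elif group == "PBL":
            mean = mu_pbl * d * config.pbl_depth
            mean = np.where(pbl_mask, mean * config.pbl_inflation, mean)
        else:
            mean = mu0 * d
        cols[s] = _nb_draw(mean, config.dispersion, rng)
    counts = pd.DataFrame(cols)
    counts.index.name = "bin_id"

    batches = [f"batch{(k % config.n_batches) + 1}" for k in range(len(ids))]
    sheet = SampleSheet(pd.DataFrame({"sample_id": ids, "group": groups, "batch": batches}))
    truth = SyntheticTruth(
        spiked_bins=spiked,
        spike_genes=spike_genes,
        pbl_background_bins=pbl_bins,
        outlier_sample=outlier,
    )
    return CountMatrix(grid, counts), sheet, truth


# ---------------------------------------------------------------------------
# ddPCR wells


_CONTAM_RANGE = {"pass": (0.05, 0.40), "warn": (0.70, 1.80), "fail": (2.20, 5.00)}
_INTEG_RANGE = {"pass": (0.10, 0.35), "warn": (0.45, 0.65), "fail": (0.75, 1.20)}


def simulate_ddpcr_wells(
    n_samples: int = 12,
    rng: np.random.Generator | None = None,
    seed: int = 0,
    regimes: Sequence[tuple[str, str, str]] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long-format ddPCR well table plus the generating regimes.

    Each sample gets duplicate multiplexed wells; regimes (contamination,
    integrity, droplet) cycle through pass/warn/fail and normal/lowdroplet
    so every classification branch is exercised.  Regime values are drawn
    away from the decision boundaries.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    c_regimes = ("pass", "warn", "fail")
    d_regimes = ("normal", "normal", "lowdroplet")
    rows = []
    truth_rows = []
    for i in range(n_samples):
        sid = f"S{i + 1:03d}"
        if regimes is not None:
            c_reg, i_reg, d_reg = regimes[i]
        else:
            c_reg = c_regimes[i % 3]
            i_reg = c_regimes[(i // 3) % 3]
            d_reg = d_regimes[i % len(d_regimes)] if i % 7 != 6 else "lowdroplet"
        truth_rows.append(
            {"sample_id": sid, "contamination_regime": c_reg, "integrity_regime": i_reg,
             "droplet_regime": d_reg}
        )
        for rep in (1, 2):
            rpp30 = float(rng.uniform(200, 2_000))
            ratio = float(rng.uniform(*_CONTAM_RANGE[c_reg]))
            pbc = ratio * rpp30 / 100.0
            short = float(rng.uniform(50, 500))
            integ = float(rng.uniform(*_INTEG_RANGE[i_reg]))
            long = integ * short
            if d_reg == "lowdroplet":
                droplets = int(rng.integers(3_000, 9_500))
            else:
                droplets = int(rng.integers(12_000, 20_000))
            for assay, copies in (("pbc", pbc), ("rpp30", rpp30), ("long", long), ("short", short)):
                rows.append(
                    {"sample_id": sid, "replicate": rep, "assay": assay,
                     "copies_per_ul": round(copies, 4), "accepted_droplets": droplets}
                )
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# Gene sets (for over-representation analysis)


def simulate_gene_sets(
    universe: Sequence[str],
    enriched_genes: Sequence[str],
    n_terms: int = 10,
    term_size: tuple[int, int] = (10, 40),
    rng: np.random.Generator | None = None,
    seed: int = 0,
) -> dict[str, set[str]]:
    """Random gene sets plus one term deliberately loaded with the
    `enriched_genes` so over-representation is recoverable."""
    if rng is None:
        rng = np.random.default_rng(seed)
    universe = list(dict.fromkeys(universe))
    sets: dict[str, set[str]] = {}
    for t in range(1, n_terms + 1):
        k = int(rng.integers(*term_size))
        k = min(k, len(universe))
        members = rng.choice(len(universe), size=k, replace=False)
        sets[f"TERM{t:03d}"] = {universe[m] for m in members}
    loaded = set(enriched_genes)
    pad = [g for g in universe if g not in loaded]
    n_pad = min(len(pad), max(0, term_size[0] - len(loaded)))
    if n_pad:
        extra = rng.choice(len(pad), size=n_pad, replace=False)
        loaded |= {pad[m] for m in extra}
    sets["TERM_SPIKED"] = loaded
    return sets
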