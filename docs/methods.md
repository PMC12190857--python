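# Methods

## Count model and differential testing

Bin counts are modelled as negative binomial,
`K_bs ~ NB(mean mu_bs, dispersion alpha_b)` with
`Var(K) = mu + alpha * mu^2`, the standard parameterisation for
sequencing counts with biological replicate variability. The mean
factorises as `mu_bs = s_s * q_bg`: a per-sample size factor `s_s`
absorbing sequencing depth, and a per-bin, per-group abundance `q_bg`.

**Size factors** are median-of-ratios: over bins with strictly positive
counts in every sample, each sample's factor is the median ratio of its
count to the bin's geometric mean across samples, rescaled so factors have
geometric mean 1. When no bin is all-positive (tiny or very sparse
matrices) an explicit opt-in fallback uses bins positive in at least half
the samples, with the geometric mean taken over positive entries only.

**Dispersion** is estimated per bin by method of moments on
depth-normalised counts: `alpha_b = max((s2_b − m_b) / m_b^2, 1e-8)` with
`s2_b` the pooled within-group variance and `m_b` the overall mean.
The floor (1e-8) makes the Poisson limit explicit rather than letting the
estimate go negative. No trend fitting and no shrinkage are applied: with
~115 residual degrees of freedom the raw estimator is adequate, and
keeping it transparent makes the calibration properties easy to reason
about. The trade-off is a noisier far tail than a shrinkage estimator
would give.

**Testing.** For the two-group contrast the group abundances are fitted by
Fisher-scoring maximum likelihood in `eta = log q_g` at fixed `alpha_b`,
with `log s_s` offsets (vectorised across all bins; convergence tolerance
1e-12 on the step, step clipped to ±5 log units for safety). The log2
fold change is `log2(q_case / q_ctrl)`; its standard error comes from the
expected Fisher information `I_g = sum_s mu_bs / (1 + alpha_b mu_bs)` via
the delta method, `SE = sqrt(1/I_case + 1/I_ctrl) / ln 2`. The Wald
statistic `z = lfc / SE` gets a two-sided normal p-value; BH step-up
adjustment runs over tested bins only, and bins in which either group is
all zero are reported untested (NA statistics) rather than pseudocounted —
pseudocounts would fabricate effect sizes exactly where the data say
least. Significance is `padj < 0.1`, strict.

Measured behaviour (recomputed by the test suite and
`scripts/acceptance.py`, not quoted from elsewhere): on a pure-null
two-group cohort (2,000 bins, 40 vs 76 samples, dispersion 0.3) the
empirical type-I error at nominal 0.05 lands near 0.05 (0.043–0.062
across seeds), and spikes with log2FC in [0.9, 1.9] are recovered with
near-complete sensitivity at `padj < 0.1`, every recovered spike with a
positive estimated fold change.

**On the composition of calls at FDR 0.1.** When ~100 true
hypermethylated effects are present, BH at 0.1 admits on the order of ten
false discoveries among the calls, and under a two-sided test roughly
half of those land on the hypomethylated side. The expected
hypermethylated fraction of *all* calls is therefore ~90–95% even for a
perfectly calibrated test — strong hyper-dominance, but not arbitrarily
close to 100%. A further small negative bias on null bins arises from
compositional normalization: one-sided spikes pull case-sample size
factors slightly up. Both effects shrink as the genome grows relative to
the number of spiked bins; at the desk-scale genome used here (10,000
bins) they are visible. Assertions about call composition are therefore
made on the recovered spikes (sign of every called spike) and on
hyper-dominance, not on a razor-thin fraction of all calls.

## Filtering cascade

Order: blacklist → PBL background → low total → no CpG. Boundaries are
strict as specified by the thresholds' wording: a bin is removed when it
overlaps a blacklist interval by ≥ 1 bp; when **more than** 20 reads
appear in at least one PBL sample (21 removes, 20 survives); when the
summed count over all plasma samples is **below** 10 (9 removes, 10
survives); when the bin sequence contains no CpG dinucleotide. The
"any PBL sample" reading of the background rule is the strictest
plausible one and is the default; the cascade records per-stage removals
against the bins alive when the stage runs, so swapping stage order
changes the attribution (covered by a test). The cascade is idempotent
and invariant to row/column order.

Fragments are assigned to the single bin containing their midpoint
(`floor((start+end)/2)`), conserving totals; per-overlap incrementing
would double-count boundary-spanning fragments.

## Synthetic cohort generator

The generator reproduces the statistical structure the analysis assumes,
with group sizes 40 cancer / 38 benign / 38 healthy plasma samples and 20
leukocyte references, on a deliberately small genome (2 × 1.5 Mb,
10,000 bins of 300 bp) chosen so a full analysis runs in seconds.

* **Sequence**: uniform background, CpG-depleted by mutating 92% of
  chance CG dinucleotides (real genomes are CpG-poor), with CpG islands
  (~one per 30 kb, 400–1,200 bp, CpG rate 0.10/bp) implanted.
* **Tracks**: stranded gene models (2–6 exons, terminal UTRs), repeats
  (LINE/SINE/LTR/other with class-typical lengths), a small blacklist.
* **Counts**: `NB(d_s * mu0(c_b) * 2^(lfc_b * [s in case]), alpha)` with
  `mu0(c) = mu_base (1 + beta c)` for CpG count `c` (`mu_base` 5,
  `beta` 0.15 — MeDIP enrichment scales with methylatable CpG content),
  residual mean 0.05 for CpG-free bins, shared dispersion `alpha = 0.2`,
  log-normal depth factors (sigma 0.25).
* **Spikes**: 100 hypermethylated bins, lfc ~ U[0.9, 1.9] (the range
  reported for robust ovarian-cancer DMRs); placement is gene-body
  restricted and CpG-context-weighted (10% island, 15% shore bins),
  mirroring the concentration of cancer hypermethylation in islands and
  shores. Hypomethylation spikes are supported but off by default.
* **Leukocyte background**: 3% of bins carry 10× inflated PBL means (the
  hematopoietic track the >20-read filter must remove). PBL baselines are
  CpG-capped at c = 5 — CpG islands are unmethylated in normal
  leukocytes, so leukocyte MeDIP signal must not scale into island-level
  CpG densities — and PBL libraries run at half plasma depth (external
  reference data).
* **Outlier**: the last cancer sample is set to 10× nominal depth
  (flow-cell loading error analogue); it isolates as a k-means singleton
  and anchors the leave-one-out robustness procedure.
* **ddPCR wells**: duplicate multiplexed wells per sample with
  contamination/integrity/droplet regimes drawn away from the decision
  boundaries, so regime recovery can be asserted exactly.

What the generator does **not** emulate: fragment-length and
antibody-efficiency structure, GC bias, copy-number aberrations,
per-bin dispersion heterogeneity (single shared alpha by default), gene
co-location structure of real annotation, and genome scale (10^4 bins vs
10^7). Passing tests therefore demonstrate correctness and calibration of
the machinery under the assumed model, not performance on real plasma
data.

## Annotation and enrichment

CpG context derives from the island track by pure interval arithmetic:
shores are the 0–2 kb island flanks minus islands, shelves the 2–4 kb
flanks minus both, open sea the complement — the four sets partition the
genome exactly (asserted by bp accounting). Widths are the standard
2 kb / 4 kb conventions and configurable. Gene features are strand-aware:
promoter `[TSS−1 kb, TSS)`, upstream `[TSS−5 kb, TSS−1 kb)`, introns =
body minus exons, intergenic only when nothing else is hit. A 300-bp
region can straddle boundaries, so classifiers return every category
overlapped by ≥ 1 bp, and distribution percentages use total
(region, category) assignments as denominator — the only convention
under which multi-category regions still give within-family bars summing
to 100%.

Permutation enrichment redistributes each region uniformly on its own
chromosome (length and chromosome preserved; placements independent, and
overlaps among randomized regions permitted; an optional mask excludes
forbidden territory). Overlaps are counted per region (≥ 1 bp, each
region at most once), `Z = (obs − mean)/SD` with the n−1 sample SD over
n = 1000 permutations by default; SD = 0 yields an explicit "undefined"
verdict. The engine is validated against a closed-form uniform-placement
null and calibrated so that random feature placement flags |Z| > 2 rarely.

ORA uses the hypergeometric upper tail on universe-intersected terms,
BH adjustment, and a Storey q-value with fixed lambda = 0.5 (falling back
to pi0 = 1, i.e. BH weighting, when the estimate degenerates); a term is
significant only when both padj and q fall below 0.1.

## Exploratory components

The variance-stabilizing transform is `log2(count/size_factor + 1)` —
monotone, depth-invariant, and sufficient to flatten the count-mean
relationship for the SVD batch check; it is named exactly this in all
outputs rather than borrowing the name of any package-internal transform.
The batch check row-centres, takes the SVD, and runs one-way ANOVA of the
first two sample score vectors against library batches (degenerate
decompositions return NA). K-means (k = 2, 10 k-means++ restarts, seeded)
runs on raw counts of the top-variance bins, the transpose convention
stated explicitly; PCA signs are fixed by forcing each component's
largest-magnitude loading positive. The heatmap matrix is
`rowscale(log2(count + 1))` over each gene's lowest-padj representative
DMR, columns ordered by diagnostic group and stable by sample id;
constant rows are zeroed with a warning rather than erroring.

## Numerical and design choices

* Coordinates: 0-based half-open internally and in all BED I/O; report
  tables echo 1-based inclusive coordinates. The last bin per chromosome
  is kept truncated (tiling completeness).
* ddPCR thresholds define pass (< 0.5% contamination, < 0.4 integrity)
  and fail (> 2%, > 0.7); the band in between — including the exact
  boundary values — is "warn", a conservative reading that preserves both
  printed inequalities. Replicate wells are averaged only after the
  ≥ 10,000 accepted-droplet gate (inclusive); samples with no admissible
  well are invalid.
* BH is implemented from the step-up definition and cross-checked against
  an independent oracle in tests; ties in gene-representative selection
  break by (chromosome order, start).
* Leave-one-out robustness re-estimates size factors and dispersions from
  scratch on the reduced cohort, as do the subgroup contrasts — reusing
  full-cohort estimates would leak the excluded sample.
* Pipeline determinism: every stochastic stage draws from a generator
  seeded deterministically from the single run seed; tables are written
  with a fixed float format, making reruns byte-identical.

## Known limitations

* No numeric parity with any specific established count-testing package
  is attempted (no fold-change shrinkage, no independent filtering, no
  outlier refitting); acceptance is via calibration and recovery
  properties instead.
* The normal reference for the Wald statistic is slightly anticonservative
  in the extreme tail when dispersion is noisy; with ~115 samples the
  effect on type-I at conventional levels is small (measured above) but
  the far tail should not be over-interpreted.
* Continuous covariates, paired designs, and >2-group contrasts are out
  of scope; the model is strictly two-group with offsets.
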