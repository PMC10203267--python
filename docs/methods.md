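# Methods

`zwscan` implements three analyses for a female-heterogametic (ZW) plant
genome: detection of the sex-determination region (SDR) from pooled
female/male read depth plus SNP evidence, dating of W/Z evolutionary strata
from inversion-aware gene-pair divergence, and detection of domestication
selective sweeps from the intersection of diversity-ratio and LD-ω outlier
scans. A seeded simulator generates inputs with the statistical structure
each detector assumes, together with a machine-readable truth set, so every
stage is validated by parameter recovery.

## Coordinate conventions

All in-memory coordinates are 1-based and inclusive; BED/bedGraph's 0-based
half-open convention is converted at the I/O boundary. Megabase spans are
reported as `(end − start)/1e6` rounded half-up to two decimals — the
convention under which Chr14:39,979,216–52,678,755 prints as 12.70 Mb.
(`GenomicInterval.length_bp` is the covered base count, `end − start + 1`.)

## SDR detection

Pooled female (F) and male (M) depth is averaged into fixed windows
(default 10 kb) and summarized by the female share F/(F+M). A window is
**W-specific** when F/(F+M) > 0.5 + δ (the W has no male counterpart, so
male reads are absent), **male-elevated** when F/(F+M) < 0.5 − δ (males are
ZZ, so Z-specific sequence doubles male depth), else balanced; windows
below a minimum total depth (10 reads) are set aside. δ defaults to 0.05;
δ = 0 reproduces the strict 0.5 cutoff. Divergent runs are maximal runs of
at least `min_run` (5) non-balanced windows; the SDR span on the
best-supported chromosome (most divergent bp) is the envelope of runs whose
gaps are ≤ 1 Mb — merging across internally balanced stretches is required
because a real SDR is a mosaic of W-specific sequence and W homologs of Z
sequence.

Three SNP layers annotate the call: (i) a per-site 2×2 allelic chi-square
of sex × allele; (ii) windowed Weir–Cockerham Fst between the sexes (20-kb
windows, ratio-of-sums aggregation), thresholded at the empirical
genome-wide top-1% quantile; (iii) female-specific SNP blocks — runs of
≥ 10 sites whose allele is carried by ≥ 90% of females and ≤ 0 males, with
gaps ≤ 100 kb. `support_count` (0–3) counts the layers with at least one
element inside the span.

A caveat documented deliberately: the exact allelic chi-square at a fully
penetrant W-linked site in a 22-female / 22-male panel is bounded at
χ² = 29.33, i.e. −log10 P ≈ 7.2. A mixed-model association scan can exceed
10 there (its statistic is unbounded as the fit becomes exact), so the
conventional −log10 P ≥ 10 cutoff — kept as the default — cannot fire for
this test at that panel size. Use `assoc_cut ≈ 7` for panels of that scale,
or rely on the Fst and female-specific-SNP layers, which are unaffected.

The genetic-map diagnostic ranks chromosomes by Spearman ρ between physical
and genetic position (ascending) and reports each chromosome's widest
zero-cM plateau; a recombination-suppressed sex chromosome ranks first.
Marker alignment rates are percentages rounded half-up to one decimal.

## Strata dating

W–Z anchor pairs ordered along the W are chained into blocks by monotone
runs of Z rank: consecutive members must move in one direction with
|Δrank| ≤ `max_rank_gap` (2); runs shorter than `min_block_anchors` (3) are
dropped. Ascending runs are collinear, descending runs are inversions. This
monotone-run chaining replaces a full dynamic-programming collinearity
scorer because the input is an already-paired microsynteny gene set, for
which maximal monotone runs are sufficient.

Per pair, Ka/Ks follows Nei & Gojobori (1986): fractional synonymous site
counts per codon (per position, the synonymous fraction of the non-stop
single changes, so S + N = 3 per codon), pathway averaging over all
orderings of single changes for multi-hit codons with stop-codon paths
excluded and weights renormalized (a `count-nonsyn` toggle keeps them,
scoring stop steps as nonsynonymous), and the Jukes–Cantor correction
d = −(3/4)·ln(1 − 4p/3), undefined (NA) at p ≥ 0.75. Ksil equals Ks for
CDS-only input (no noncoding silent sites are supplied) and is flagged as
such. Divergence time is T = Ksil/(2µ) with µ = 7.5×10⁻¹⁰ substitutions
per site per year. Each inverted block defines one stratum summarized by
the median member time; strata are numbered oldest-first; blocks with < 3
dated pairs are flagged low-confidence.

**Estimator behavior at desk scale.** At young-stratum divergences
(d ≈ 0.005) a ~1000-codon gene carries a small, right-skewed synonymous
difference count, so the *median* over pairs converges slightly below the
true age: Monte Carlo at the packaged conditions (gene lengths uniform in
0.5–1.5× the 1000-codon mean) gives asymptotes of 8.065 Mya for a true
8.18 Mya stratum (−1.4%) and 3.358 Mya for 3.47 Mya (−3.2%), with a
standard error of ≈ 2–4% of the age for a 200-pair median. No bias
correction is applied — the median is the method. Gene-length variation is
deliberate: with one fixed length every pair's Ks lies on the same 1/S
lattice and the block median snaps to lattice points.

## Sweep scan

After the standard site filters (DP within [2, 40], quality ≥ 20, missing
rate ≤ 20%, MAF ≥ 5% — all strict inequalities for removal), nucleotide
diversity π is computed for the wild group and each cultivar subgroup in
50-kb windows with 10-kb steps (π per window = Σ 2p̂q̂·n/(n−1) over sites
divided by window bp). The ratio π_wild/π_cultivar is +∞ where the
cultivar window is invariant but the wild is not; windows with fewer than
10 usable wild sites are dropped.

The LD ω statistic is evaluated on a 20-kb grid within each cultivar
subgroup: at a grid point, for the best split into up to 25 SNPs on each
side, ω = mean r² within the two flanks over mean r² across them (+10⁻⁶ in
the denominator); r² is the squared Pearson correlation of unphased
dosages, a documented divergence from haplotype-based r² that preserves the
outlier ranking the scan consumes.

Candidate regions are the top 5% of each statistic (ties at the quantile
included), expanded by 4-kb flanks, intersected pairwise, and merged where
the intersections overlap; every reported region must be supported by both
statistics, and overlapping genes (any-overlap, ≥ 1 bp) are attached. On
top of the quantile rule the caller requires ratio ≥ 2 and ω ≥ 5 (absolute
floors, configurable; 0 restores the literal top-quantile rule): an
empirical quantile selects 5% of windows unconditionally, so the floors
are what keeps a sweep-free genome sweep-free, while a planted 5-fold
diversity reduction sits far above both.

## The simulator

The default configuration is the study system: a 55-Mb ZW chromosome whose
SDR spans Chr14:39,979,216–52,678,755 with three inversions at the
published coordinates and ages (8.18, 3.80, 3.47 Mya), two flanking
collinear blocks, nine W-specific segments tiling the SDR boundary to
boundary, and two 20-Mb autosomes; pooled depth λ = 30 reads per pool;
22 females and 22 males; a wild (16) + Cultivar_I/II/III (10/20/91) panel
with genome-wide diversities 1.16/0.93/0.94/1.02 ×10⁻³; sweeps of 100 kb
with 5-fold cultivar diversity reduction.

- **Coverage**: per-base Poisson depth averaged over 1-kb bins
  (`Poisson(λ·B)/B`); male mean 0 on W-specific segments, doubled on
  Z-analogue segments.
- **Genotypes**: segregating sites are drawn from the neutral folded
  spectrum P(k) ∝ 1/k + 1/(n−k) with *exactly* k carriers placed uniformly
  (so the folded SFS passes a goodness-of-fit test); per-subgroup
  diversity and sweep reductions are planted by fixing a site within the
  subgroup with the complementary probability.
- **Sex panel**: W-linked sites (heterozygous in all females, absent in
  all males) every 5 kb on W-specific segments; male genotypes at
  background sites inside W-specific sequence are missing (no male reads),
  which reproduces the heavy male missingness of real W-specific regions
  and means those sites drop out at the missing-rate filter.
- **Sweep LD**: within each flank of a sweep center, the affected
  subgroup's carriers are rearranged onto one fixed slot order (nested
  haplotypes, D′ = 1), independently per flank — elevated within-flank r²
  and depressed cross-center r², the ω signature. The planted LD break is
  abrupt at the center, so the default sweep coordinates place centers on
  the 20-kb ω grid; real sweeps produce broader breaks that a coarse grid
  can detect off-center. Singleton sites would make flank haplotypes
  degenerate, but the MAF ≥ 5% filter removes them before scanning.
- **Gene pairs**: codons are drawn from the six fully four-fold-degenerate
  families (GCN, GGN, GTN, CCN, ACN, TCN), so each codon contributes
  exactly one synonymous site and the planted Jukes–Cantor distance
  2µT at third positions is the estimand with no site-counting bias;
  positions 1–2 diverge at 5% of the synonymous rate with stop-creating
  changes rejected; Z anchor order is reversed within inverted blocks.
- **Genetic map**: cM accumulates as positive gamma-noise increments
  (ρ ≈ 1 against bp on autosomes) and is exactly flat across the SDR.

What the simulator does **not** emulate — and what passing tests therefore
do not establish about real data: family structure of pooled F1 samples
(individuals are unrelated), linked neutral variation from a genealogy (no
coalescent; background LD is near zero, making the ω null conservative),
recombination-graded sweep edges, sequencing-error or mapping artifacts in
depth tracks, and codon-usage or transition/transversion structure in CDS
evolution.

## Numerical choices and degenerate inputs

Empirical quantiles use linear interpolation with ties at the threshold
included (≥). All-identical outlier statistics yield an empty region set
with a warning; fewer than 20 values warns that the quantile is unstable.
Windows with no segregating site give Tajima's D = NA (not 0); Fst windows
with no informative site are NA; ω grid points with fewer than 2 SNPs on a
side are NA. Missing genotypes are excluded pairwise per site everywhere
except Tajima's D, which drops incompletely called sites to keep one
sample size per window. Zero-variance sites are skipped in LD. The LD
half-decay distance interpolates linearly between distance-bin centers and
is NA when the binned curve never falls to half its maximum. All
generators are pure functions of (config, seed) via independent
`numpy` Generator streams keyed (seed, stage).

## Problem sizes used by the packaged checks

Recovery and null-control checks run on scaled-down genomes chosen to
preserve the relevant geometry: SDR recovery on a 5.5-Mb ZW chromosome +
2-Mb autosome over 20 seeds; sweep recovery and nulls on a 10-Mb autosome
with three 100-kb sweeps (a ~3% swept fraction, near the study's 1.3–2%,
so the top-5% rule can cover every sweep) over 20 seeds; strata recovery
on 600 pairs × ~1000 codons per block. The acceptance script uses 200
pairs × ~1000 codons per stratum.

## Known limitations

- The strata median is biased low by 1–3% at desk-scale gene counts (see
  above); the published three-strata pattern and ordering are recovered
  robustly, the third decimal of an age is not.
- ω on genotype r² with a 25-SNP budget is a ranking statistic, not a
  calibrated likelihood; absolute ω values are not comparable across
  panel sizes.
- The W-specific gene criteria consume externally produced reciprocal hit
  tables; no alignment is performed.
- Fst's top-1% threshold is computed genome-wide; a per-chromosome
  alternative would shift the threshold on small genomes.
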