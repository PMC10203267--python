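"""Domestication sweep detection: π_wild/π_cultivar ratio × LD ω statistic.

Candidate regions are the top 5% of each statistic with 4-kb flanks,
intersected, and merged where they overlap. On top of the quantile rule the
caller applies absolute floors (ratio >= 2, ω >= 5 by default): an
empirical quantile always selects something, so the floors are what keeps a
sweep-free genome sweep-free; set them to 0 to recover the literal
top-quantile rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix
from .intervals import (
    GenomicInterval,
    intersect_interval_sets,
    merge_intervals,
)


# ---------------------------------------------------------------------------
# π ratio
# ---------------------------------------------------------------------------

def pi_ratio_windows(
    wild: pd.DataFrame, cultivar: pd.DataFrame, min_sites: int = 10
) -> pd.DataFrame:
    """π_W/π_C per window from two WindowStat tables on identical windows.

    Windows where π_C = 0 but π_W > 0 get +inf (they are outliers by
    definition); windows where both are 0, or either side has fewer than
    ``min_sites`` usable sites, are dropped.
    """
    key = ["chrom", "start", "end"]
    if len(wild) != len(cultivar) or not (
        wild[key].reset_index(drop=True) == cultivar[key].reset_index(drop=True)
    ).all().all():
        raise ValueError("wild and cultivar window grids differ")
    pw = wild["value"].to_numpy(dtype=float)
    pc = cultivar["value"].to_numpy(dtype=float)
    n_w = wild["n_sites"].to_numpy()
    n_c = cultivar["n_sites"].to_numpy()

    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(pc > 0, pw / np.maximum(pc, 1e-300), np.inf)
    keep = ~((pw == 0) & (pc == 0)) & (n_w >= min_sites)
    out = wild[key].copy()
    out["stat"] = "pi_ratio"
    out["value"] = ratio
    out["n_sites"] = np.minimum(n_w, n_c)
    return out[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# omega statistic
# ---------------------------------------------------------------------------

def _r2_matrix(d: np.ndarray) -> np.ndarray:
    """Pairwise dosage r² for the columns of d (samples × sites); columns
    with zero variance produce zero r² against everything."""
    x = d.astype(float)
    x -= x.mean(axis=0)
    sd = x.std(axis=0)
    ok = sd > 0
    x[:, ok] /= sd[None, ok]
    r = (x.T @ x) / x.shape[0]
    r[~ok, :] = 0.0
    r[:, ~ok] = 0.0
    return r * r


def _omega_from_blocks(m: np.ndarray, n_left: int, eps: float,
                       min_side: int = 2) -> tuple[float, int, int]:
    """Maximize ω over sub-splits of an r² matrix whose first ``n_left``
    sites are left of the grid point: the left set is the last i of those
    (nearest the point), the right set the first j of the rest."""
    n = m.shape[0]
    n_right = n - n_left
    best = (-np.inf, 0, 0)
    # prefix sums for O(1) block sums
    cs = m.cumsum(axis=0).cumsum(axis=1)

    def block_sum(r0, r1, c0, c1):  # inclusive index ranges
        total = cs[r1, c1]
        if r0 > 0:
            total -= cs[r0 - 1, c1]
        if c0 > 0:
            total -= cs[r1, c0 - 1]
        if r0 > 0 and c0 > 0:
            total += cs[r0 - 1, c0 - 1]
        return total

    for i in range(min_side, n_left + 1):
        l0, l1 = n_left - i, n_left - 1
        within_l = (block_sum(l0, l1, l0, l1) - i) / 2.0
        for j in range(min_side, n_right + 1):
            r0, r1 = n_left, n_left + j - 1
            within_r = (block_sum(r0, r1, r0, r1) - j) / 2.0
            between = block_sum(l0, l1, r0, r1)
            w_pairs = i * (i - 1) // 2 + j * (j - 1) // 2
            omega = ((within_l + within_r) / w_pairs) / (between / (i * j) + eps)
            if omega > best[0]:
                best = (omega, i, j)
    return best


def omega_statistic(
    gm: GenotypeMatrix,
    group: str,
    chrom_lengths: dict[str, int],
    grid_size: int = 20_000,
    max_snps_side: int = 25,
    eps: float = 1e-6,
    min_side: int = 2,
) -> pd.DataFrame:
    """LD ω on a regular grid: at each grid point, the ratio of mean r²
    within the flanking SNP sets to mean r² across them, maximized over the
    split extents (up to ``max_snps_side`` SNPs per side). Grid points with
    fewer than ``min_side`` SNPs on either side are NA.

    r² is the squared Pearson correlation of unphased dosages within the
    named subgroup (OmegaPlus uses binary haplotypes; only the outlier
    ranking is consumed downstream).
    """
    mask = gm.sample_mask(subgroup=group)
    if int(mask.sum()) < 4:
        raise ValueError(f"subgroup {group!r} has fewer than 4 samples")
    d_all = gm.dosage[mask, :]
    chrom_arr, pos_arr = np.asarray(gm.chrom), np.asarray(gm.pos)
    # only sites segregating within the group carry LD information
    called = (d_all != MISSING).astype(float)
    x = np.where(d_all != MISSING, d_all, 0).astype(float)
    n_called = np.maximum(called.sum(axis=0), 1)
    m1 = x.sum(axis=0) / n_called
    m2 = (x * x).sum(axis=0) / n_called
    poly = (m2 - m1 * m1) > 1e-12

    rows = []
    for chrom, length in chrom_lengths.items():
        idx = np.flatnonzero((chrom_arr == chrom) & poly)
        idx = idx[np.argsort(pos_arr[idx], kind="stable")]
        pos = pos_arr[idx]
        for g in range(grid_size, length + 1, grid_size):
            k = np.searchsorted(pos, g, side="right")
            li = idx[max(0, k - max_snps_side): k]
            ri = idx[k: k + max_snps_side]
            if len(li) < min_side or len(ri) < min_side:
                rows.append((chrom, g, np.nan, len(li), len(ri)))
                continue
            cols = np.concatenate([li, ri])
            d = d_all[:, cols].astype(float)
            d[d == MISSING] = np.nan
            col_mean = np.nanmean(d, axis=0)
            inds = np.where(np.isnan(d))
            d[inds] = np.take(col_mean, inds[1])
            m = _r2_matrix(d)
            omega, i, j = _omega_from_blocks(m, len(li), eps, min_side)
            rows.append((chrom, g, omega, i, j))
    return pd.DataFrame(rows, columns=["chrom", "grid_pos", "omega", "n_left", "n_right"])


# ---------------------------------------------------------------------------
# outlier regions, intersection, genes
# ---------------------------------------------------------------------------

def top_percentile_regions(
    stats: pd.DataFrame,
    q: float = 0.05,
    flank: int = 4_000,
    value_col: str | None = None,
    min_value: float = 0.0,
    chrom_lengths: dict[str, int] | None = None,
) -> list[GenomicInterval]:
    """Carrier intervals of values at/above the empirical (1−q) quantile
    (ties inclusive), each expanded by ``flank`` bp and merged where the
    expansions overlap. Accepts WindowStat tables (start/end columns) or ω
    grids (grid_pos column -> point intervals). ``min_value`` is an
    additional absolute floor."""
    df = stats
    if value_col is None:
        value_col = "omega" if "omega" in df.columns else "value"
    vals = df[value_col].to_numpy(dtype=float)
    finite = vals[np.isfinite(vals)]
    n_inf = int(np.isposinf(vals).sum())
    usable = np.concatenate([finite, np.full(n_inf, np.inf)])
    if len(usable) == 0:
        return []
    if len(usable) < 20:
        warnings.warn(f"only {len(usable)} values: the {1-q:.0%} quantile is unstable")
    if np.nanmin(usable) == np.nanmax(usable):
        warnings.warn("all values identical: no outlier regions")
        return []
    thresh = np.quantile(usable, 1.0 - q)
    sel = df[(vals >= thresh) & (vals >= min_value)]

    ivs = []
    for r in sel.itertuples():
        if hasattr(r, "start"):
            iv = GenomicInterval(r.chrom, int(r.start), int(r.end))
        else:
            iv = GenomicInterval(r.chrom, int(r.grid_pos), int(r.grid_pos))
        length = chrom_lengths.get(iv.chrom) if chrom_lengths else None
        ivs.append(iv.expand(flank, length))
    return merge_intervals(ivs)


@dataclass
class SweepRegion:
    """A region supported by both the π-ratio and the ω statistic."""

    interval: GenomicInterval
    pi_support: list[int] = field(default_factory=list)   # indices into π regions
    omega_support: list[int] = field(default_factory=list)
    genes: list[str] = field(default_factory=list)


def intersect_merge(
    a: list[GenomicInterval], b: list[GenomicInterval]
) -> list[SweepRegion]:
    """Pairwise intersections of two outlier region sets, merged where the
    intersections overlap; provenance (supporting members of a and b) kept."""
    pieces = intersect_interval_sets(a, b)
    if not pieces:
        return []
    pieces.sort(key=lambda t: (t[0].chrom, t[0].start, t[0].end))
    regions: list[SweepRegion] = []
    for iv, ai, bi in pieces:
        if (
            regions
            and iv.chrom == regions[-1].interval.chrom
            and iv.start <= regions[-1].interval.end + 1
        ):
            last = regions[-1]
            last.interval = GenomicInterval(
                iv.chrom, last.interval.start, max(last.interval.end, iv.end)
            )
            if ai not in last.pi_support:
                last.pi_support.append(ai)
            if bi not in last.omega_support:
                last.omega_support.append(bi)
        else:
            regions.append(SweepRegion(iv, [ai], [bi]))
    for r in regions:
        assert r.pi_support and r.omega_support, "sweep region lost a support"
    return regions


def annotate_sweep_genes(
    regions: list[SweepRegion], genes: dict[str, GenomicInterval]
) -> list[SweepRegion]:
    """Assign genes to regions by any-overlap (>= 1 bp)."""
    for r in regions:
        r.genes = sorted(
            gid for gid, iv in genes.items() if iv.overlaps(r.interval)
        )
    return regions


# ---------------------------------------------------------------------------
# end-to-end scan
# ---------------------------------------------------------------------------

@dataclass
class SweepScanResult:
    regions: list[SweepRegion]
    pi_ratio: pd.DataFrame
    omega: pd.DataFrame
    pi_regions: list[GenomicInterval]
    omega_regions: list[GenomicInterval]
    thresholds: dict[str, float]


def detect_sweeps(
    pi_wild: pd.DataFrame,
    pi_cultivar: pd.DataFrame,
    omega: pd.DataFrame,
    q: float = 0.05,
    flank: int = 4_000,
    min_ratio: float = 2.0,
    min_omega: float = 5.0,
    min_sites: int = 10,
    genes: dict[str, GenomicInterval] | None = None,
    chrom_lengths: dict[str, int] | None = None,
) -> SweepScanResult:
    """Intersect the top-q π-ratio windows with the top-q ω grid points
    (both flank-expanded, both subject to their absolute floors) and merge."""
    ratio = pi_ratio_windows(pi_wild, pi_cultivar, min_sites=min_sites)
    pi_regions = top_percentile_regions(
        ratio, q=q, flank=flank, min_value=min_ratio, chrom_lengths=chrom_lengths
    )
    omega_regions = top_percentile_regions(
        omega, q=q, flank=flank, min_value=min_omega, chrom_lengths=chrom_lengths
    )
    regions = intersect_merge(pi_regions, omega_regions)
    if genes:
        regions = annotate_sweep_genes(regions, genes)
    finite_ratio = ratio["value"].replace(np.inf, np.nan).dropna()
    thresholds = {
        "pi_ratio_q": float(np.quantile(ratio["value"], 1 - q)) if len(ratio) else np.nan,
        "pi_ratio_q_finite": float(finite_ratio.quantile(1 - q)) if len(finite_ratio) else np.nan,
        "omega_q": float(np.nanquantile(omega["omega"], 1 - q)) if len(omega) else np.nan,
        "min_ratio": min_ratio,
        "min_omega": min_omega,
    }
    return SweepScanResult(regions, ratio, omega, pi_regions, omega_regions, thresholds)
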