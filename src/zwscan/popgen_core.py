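"""Windowed population-genetic statistics and per-site tests.

All windowed functions return a tidy DataFrame with columns
``chrom, start, end, stat, value, n_sites`` (the WindowStat table). Windows
are 1-based inclusive, default 50-kb span with 10-kb steps.

Missing genotypes are excluded pairwise per site: allele counts use
observed alleles only (Tajima's D, which needs one sample size per window,
instead drops sites with any missing call).
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .genotypes import MISSING, GenotypeMatrix
from .intervals import GenomicInterval, sliding_windows

WINDOW_COLUMNS = ["chrom", "start", "end", "stat", "value", "n_sites"]


# ---------------------------------------------------------------------------
# variant filtering
# ---------------------------------------------------------------------------

def filter_variants(
    gm: GenotypeMatrix,
    dp_min: float = 2,
    dp_max: float = 40,
    q_min: float = 20,
    max_missing: float = 0.20,
    maf_min: float = 0.05,
) -> GenotypeMatrix:
    """Site filters of the standard resequencing pipeline.

    A site is removed when DP < dp_min or DP > dp_max, quality < q_min,
    missing-genotype rate > max_missing, or minor allele frequency < maf_min
    (all rules strict, so MAF exactly at the threshold is retained).
    Sites with undefined DP/quality pass those rules. Idempotent.
    """
    if gm.n_sites == 0:
        raise ValueError("empty genotype matrix")
    if dp_min > dp_max:
        raise ValueError("dp_min > dp_max")
    if not (0 <= max_missing <= 1 and 0 <= maf_min <= 0.5):
        raise ValueError("invalid missing/MAF thresholds")

    dp, qual = np.asarray(gm.dp, float), np.asarray(gm.qual, float)
    ok_dp = ~((dp < dp_min) | (dp > dp_max))
    ok_dp |= np.isnan(dp)
    ok_q = ~(qual < q_min) | np.isnan(qual)

    miss = (gm.dosage == MISSING).mean(axis=0)
    ok_miss = ~(miss > max_missing)

    ac, an = gm.allele_counts()
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(an > 0, ac / np.maximum(an, 1), 0.0)
    maf = np.minimum(p, 1.0 - p)
    ok_maf = ~(maf < maf_min)

    keep = np.flatnonzero(ok_dp & ok_q & ok_miss & ok_maf)
    return gm.take_sites(keep)


# ---------------------------------------------------------------------------
# window machinery
# ---------------------------------------------------------------------------

def make_windows(
    chrom_lengths: dict[str, int], window: int = 50_000, step: int = 10_000
) -> list[GenomicInterval]:
    if window < step:
        warnings.warn("window smaller than step: windows will not tile the genome")
    out: list[GenomicInterval] = []
    for chrom, length in chrom_lengths.items():
        out.extend(sliding_windows(chrom, length, window, step))
    return out


def _window_frame(
    windows: Sequence[GenomicInterval], stat: str,
    values: np.ndarray, n_sites: np.ndarray
) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [w.chrom for w in windows],
            "start": [w.start for w in windows],
            "end": [w.end for w in windows],
            "stat": stat,
            "value": values,
            "n_sites": n_sites,
        }
    )


def _per_window_sums(
    gm: GenotypeMatrix,
    windows: Sequence[GenomicInterval],
    per_site: dict[str, np.ndarray],
) -> dict[str, np.ndarray]:
    """Sum per-site arrays over each window (cumsum + searchsorted)."""
    chrom_arr = np.asarray(gm.chrom)
    pos_arr = np.asarray(gm.pos)
    out = {name: np.zeros(len(windows)) for name in per_site}
    by_chrom: dict[str, tuple[np.ndarray, dict[str, np.ndarray]]] = {}
    for chrom in pd.unique(chrom_arr):
        idx = np.flatnonzero(chrom_arr == chrom)
        pos = pos_arr[idx]
        order = np.argsort(pos, kind="stable")
        csums = {
            name: np.concatenate([[0.0], np.cumsum(arr[idx][order])])
            for name, arr in per_site.items()
        }
        by_chrom[chrom] = (pos[order], csums)
    for wi, w in enumerate(windows):
        if w.chrom not in by_chrom:
            continue
        pos, csums = by_chrom[w.chrom]
        lo = np.searchsorted(pos, w.start, side="left")
        hi = np.searchsorted(pos, w.end, side="right")
        for name in per_site:
            out[name][wi] = csums[name][hi] - csums[name][lo]
    return out


def _site_het(gm: GenotypeMatrix, sample_mask: np.ndarray | None) -> tuple[np.ndarray, np.ndarray]:
    """Per-site unbiased expected heterozygosity 2p̂q̂·n/(n−1) over observed
    alleles; second array flags sites usable (≥2 observed alleles)."""
    ac, an = gm.allele_counts(sample_mask)
    usable = an >= 2
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(usable, ac / np.maximum(an, 1), 0.0)
        h = np.where(usable, 2.0 * p * (1.0 - p) * an / np.maximum(an - 1, 1), 0.0)
    return h, usable


def nucleotide_diversity(
    gm: GenotypeMatrix,
    chrom_lengths: dict[str, int],
    window: int = 50_000,
    step: int = 10_000,
    sample_mask: np.ndarray | None = None,
    windows: Sequence[GenomicInterval] | None = None,
) -> pd.DataFrame:
    """Windowed nucleotide diversity π.

    π(window) = Σ_sites 2p̂q̂·n/(n−1) / window_bp: the per-bp convention,
    where monomorphic (and unobserved) positions contribute zero.
    """
    n_samples = gm.n_samples if sample_mask is None else int(np.sum(sample_mask))
    if n_samples < 1:
        # one diploid sample = two sequences, the minimum for diversity
        raise ValueError("need >= 2 sequences (1 diploid sample) for diversity")
    if windows is None:
        windows = make_windows(chrom_lengths, window, step)
    h, usable = _site_het(gm, sample_mask)
    seg = (h > 0).astype(float)
    sums = _per_window_sums(gm, windows, {"h": h, "seg": seg})
    span = np.array([w.length_bp for w in windows], dtype=float)
    return _window_frame(windows, "pi", sums["h"] / span, sums["seg"].astype(int))


# ---------------------------------------------------------------------------
# Tajima's D
# ---------------------------------------------------------------------------

def tajima_constants(n: int) -> dict[str, float]:
    """The 1989 normalization constants for a sample of n sequences."""
    if n < 4:
        raise ValueError("Tajima's D needs >= 4 sequences")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2,
            "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajimas_d(
    gm: GenotypeMatrix,
    chrom_lengths: dict[str, int],
    window: int = 50_000,
    step: int = 10_000,
    sample_mask: np.ndarray | None = None,
    windows: Sequence[GenomicInterval] | None = None,
) -> pd.DataFrame:
    """Windowed Tajima's D. Sites with any missing call are dropped so the
    sample size is constant; windows with no segregating site are NA."""
    mask = (
        np.ones(gm.n_samples, dtype=bool) if sample_mask is None
        else np.asarray(sample_mask)
    )
    n = 2 * int(mask.sum())
    const = tajima_constants(n)
    if windows is None:
        windows = make_windows(chrom_lengths, window, step)

    d = gm.dosage[mask, :]
    complete = ~(d == MISSING).any(axis=0)
    ac = np.where(complete, np.maximum(d, 0).sum(axis=0), 0)
    seg = complete & (ac > 0) & (ac < n)
    p = ac / n
    h = np.where(seg, 2.0 * p * (1.0 - p) * n / (n - 1), 0.0)

    sums = _per_window_sums(gm, windows, {"pi": h, "S": seg.astype(float)})
    S = sums["S"]
    theta_w = S / const["a1"]
    var = const["e1"] * S + const["e2"] * S * (S - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        D = np.where(S > 0, (sums["pi"] - theta_w) / np.sqrt(var), np.nan)
    return _window_frame(windows, "tajimas_d", D, S.astype(int))


# ---------------------------------------------------------------------------
# Weir & Cockerham Fst
# ---------------------------------------------------------------------------

def _wc_site_components(
    d1: np.ndarray, d2: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-site Weir & Cockerham (1984) variance components a, b, c for two
    diploid populations given dosage matrices (samples × sites)."""
    r = 2.0
    n1 = (d1 != MISSING).sum(axis=0).astype(float)
    n2 = (d2 != MISSING).sum(axis=0).astype(float)
    ok = (n1 >= 1) & (n2 >= 1) & (n1 + n2 >= 2)
    n1s, n2s = np.maximum(n1, 1), np.maximum(n2, 1)
    p1 = np.where(d1 != MISSING, d1, 0).sum(axis=0) / (2 * n1s)
    p2 = np.where(d2 != MISSING, d2, 0).sum(axis=0) / (2 * n2s)
    h1 = np.where(d1 == 1, 1, 0).sum(axis=0) / n1s
    h2 = np.where(d2 == 1, 1, 0).sum(axis=0) / n2s

    nbar = (n1 + n2) / r
    nc = (n1 + n2) - (n1**2 + n2**2) / np.maximum(n1 + n2, 1)
    pbar = (n1 * p1 + n2 * p2) / np.maximum(n1 + n2, 1)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * np.maximum(nbar, 1e-12))
    hbar = (n1 * h1 + n2 * h2) / np.maximum(n1 + n2, 1)

    with np.errstate(divide="ignore", invalid="ignore"):
        inner = pbar * (1 - pbar) - s2 * (r - 1) / r
        a = (nbar / np.maximum(nc, 1e-12)) * (
            s2 - (inner - hbar / 4.0) / np.maximum(nbar - 1, 1e-12)
        )
        b = (nbar / np.maximum(nbar - 1, 1e-12)) * (
            inner - hbar * (2 * nbar - 1) / (4 * nbar)
        )
        c = hbar / 2.0
    bad = ~ok | (nbar <= 1) | (nc <= 0)
    a, b, c = (np.where(bad, 0.0, x) for x in (a, b, c))
    return a, b, c


def fst_weir_cockerham(
    gm: GenotypeMatrix,
    group_a_mask: np.ndarray,
    group_b_mask: np.ndarray,
    chrom_lengths: dict[str, int],
    window: int = 50_000,
    step: int = 10_000,
    windows: Sequence[GenomicInterval] | None = None,
) -> pd.DataFrame:
    """Windowed Weir-Cockerham Fst, aggregated as the ratio of sums
    Σa / Σ(a+b+c) over the sites of each window (NA where no data)."""
    if int(np.sum(group_a_mask)) < 2 or int(np.sum(group_b_mask)) < 2:
        raise ValueError("need >= 2 diploid samples per group")
    if windows is None:
        windows = make_windows(chrom_lengths, window, step)
    a, b, c = _wc_site_components(
        gm.dosage[np.asarray(group_a_mask), :], gm.dosage[np.asarray(group_b_mask), :]
    )
    denom_site = a + b + c
    used = (denom_site != 0).astype(float)
    sums = _per_window_sums(gm, windows, {"a": a, "abc": denom_site, "n": used})
    with np.errstate(divide="ignore", invalid="ignore"):
        fst = np.where(sums["n"] > 0, sums["a"] / sums["abc"], np.nan)
    return _window_frame(windows, "fst_wc", fst, sums["n"].astype(int))


def fst_weir_cockerham_sites(
    gm: GenotypeMatrix, group_a_mask: np.ndarray, group_b_mask: np.ndarray
) -> pd.DataFrame:
    """Per-site W&C Fst (a/(a+b+c)); NA where the denominator is zero."""
    a, b, c = _wc_site_components(
        gm.dosage[np.asarray(group_a_mask), :], gm.dosage[np.asarray(group_b_mask), :]
    )
    denom = a + b + c
    with np.errstate(divide="ignore", invalid="ignore"):
        fst = np.where(denom != 0, a / denom, np.nan)
    return pd.DataFrame(
        {"chrom": gm.chrom, "pos": gm.pos, "fst": fst, "a": a, "denom": denom}
    )


# ---------------------------------------------------------------------------
# folded SFS
# ---------------------------------------------------------------------------

def folded_sfs(gm: GenotypeMatrix, group_mask: np.ndarray | None = None) -> np.ndarray:
    """Count-based folded SFS: vector over minor-allele-count classes
    1..n//2. Sites with missing genotypes in the group are skipped."""
    mask = (
        np.ones(gm.n_samples, dtype=bool) if group_mask is None
        else np.asarray(group_mask)
    )
    d = gm.dosage[mask, :]
    n = 2 * d.shape[0]
    complete = ~(d == MISSING).any(axis=0)
    n_skipped = int((~complete).sum())
    if n_skipped:
        warnings.warn(f"folded_sfs: skipped {n_skipped} sites with missing calls")
    ac = np.maximum(d, 0).sum(axis=0)[complete]
    minor = np.minimum(ac, n - ac)
    minor = minor[minor > 0]
    sfs = np.bincount(minor, minlength=n // 2 + 1)[1: n // 2 + 1]
    return sfs.astype(np.int64)


# ---------------------------------------------------------------------------
# linkage disequilibrium
# ---------------------------------------------------------------------------

def ld_r2(
    gm: GenotypeMatrix,
    max_dist: int,
    sample_mask: np.ndarray | None = None,
    max_pairs: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Genotype-correlation r² (squared Pearson correlation of dosages) for
    all site pairs within ``max_dist`` bp. Zero-variance sites are skipped;
    missing calls excluded pairwise. Optionally subsample to max_pairs."""
    mask = (
        np.ones(gm.n_samples, dtype=bool) if sample_mask is None
        else np.asarray(sample_mask)
    )
    if int(mask.sum()) < 4:
        raise ValueError("need >= 4 samples for LD")
    d = gm.dosage[mask, :].astype(float)
    d[d == MISSING] = np.nan
    chrom_arr, pos_arr = np.asarray(gm.chrom), np.asarray(gm.pos)

    rows: list[tuple[str, int, int, int, float]] = []
    for chrom in pd.unique(chrom_arr):
        idx = np.flatnonzero(chrom_arr == chrom)
        idx = idx[np.argsort(pos_arr[idx], kind="stable")]
        pos = pos_arr[idx]
        for ii, site_i in enumerate(idx):
            hi = np.searchsorted(pos, pos[ii] + max_dist, side="right")
            for jj in range(ii + 1, hi):
                site_j = idx[jj]
                x, y = d[:, site_i], d[:, site_j]
                ok = ~(np.isnan(x) | np.isnan(y))
                if ok.sum() < 4:
                    continue
                xv, yv = x[ok], y[ok]
                if xv.std() == 0 or yv.std() == 0:
                    continue
                r = np.corrcoef(xv, yv)[0, 1]
                rows.append((chrom, int(pos[ii]), int(pos[jj]),
                             int(pos[jj] - pos[ii]), float(r * r)))
    df = pd.DataFrame(rows, columns=["chrom", "pos1", "pos2", "dist", "r2"])
    if max_pairs is not None and len(df) > max_pairs:
        df = df.sample(n=max_pairs, random_state=seed).reset_index(drop=True)
    return df


def ld_half_decay(r2: pd.DataFrame, bin_size: int = 1_000) -> float:
    """Distance at which binned mean r² first falls to half of its maximum
    bin value (linear interpolation between bin centers); NaN if the curve
    never decays to half."""
    if len(r2) == 0:
        raise ValueError("no r² records")
    bins = (r2["dist"] // bin_size).astype(int)
    prof = r2.groupby(bins)["r2"].mean()
    if len(prof) < 2:
        raise ValueError("need >= 2 distance bins")
    centers = (prof.index.to_numpy() + 0.5) * bin_size
    vals = prof.to_numpy()
    target = vals.max() / 2.0
    below = np.flatnonzero(vals <= target)
    if below.size == 0:
        warnings.warn("r² does not decay to half its maximum; returning NaN")
        return float("nan")
    j = below[0]
    if j == 0:
        return float(centers[0])
    x0, x1, y0, y1 = centers[j - 1], centers[j], vals[j - 1], vals[j]
    if y0 == y1:
        return float(x1)
    return float(x0 + (y0 - target) / (y0 - y1) * (x1 - x0))


# ---------------------------------------------------------------------------
# sex association and female-specific SNPs
# ---------------------------------------------------------------------------

def sex_association(gm: GenotypeMatrix) -> pd.DataFrame:
    """Per-site 2×2 allelic chi-square of sex × allele.

    chi² = N(ad−bc)² / (row and column products), 1 df, no continuity
    correction; monomorphic sites (or an empty margin) score zero.
    """
    f_mask = gm.sample_mask(sex="F")
    m_mask = gm.sample_mask(sex="M")
    if f_mask.sum() == 0 or m_mask.sum() == 0:
        raise ValueError("both sexes must be present")
    af, anf = gm.allele_counts(f_mask)
    am, anm = gm.allele_counts(m_mask)
    a, b = af.astype(float), (anf - af).astype(float)
    c, d = am.astype(float), (anm - am).astype(float)
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(denom > 0, n * (a * d - b * c) ** 2 / denom, 0.0)
    logp = -sps.chi2.logsf(chi2, df=1) / np.log(10)
    return pd.DataFrame(
        {"chrom": gm.chrom, "pos": gm.pos, "chi2": chi2, "neg_log10_p": logp}
    )


def female_specific_snps(
    gm: GenotypeMatrix,
    min_female_carrier_frac: float = 0.9,
    max_male_carriers: int = 0,
    min_snps: int = 10,
    max_gap: int = 100_000,
) -> tuple[np.ndarray, list[GenomicInterval]]:
    """Female-specific sites and their continuous blocks.

    A site is female-specific iff one of its alleles is carried by at least
    ``min_female_carrier_frac`` of the females and by at most
    ``max_male_carriers`` males. Blocks are runs of >= min_snps flagged
    sites with inter-SNP gaps <= max_gap.
    Returns (site index array, block intervals).
    """
    f_mask = gm.sample_mask(sex="F")
    m_mask = gm.sample_mask(sex="M")
    if f_mask.sum() == 0 or m_mask.sum() == 0:
        raise ValueError("both sexes must be present")
    dF, dM = gm.dosage[f_mask, :], gm.dosage[m_mask, :]
    nF, nM = dF.shape[0], dM.shape[0]

    def carrier_rule(d_f, d_m, carries_f, carries_m):
        f_frac = carries_f.sum(axis=0) / nF
        m_cnt = carries_m.sum(axis=0)
        return (f_frac >= min_female_carrier_frac) & (m_cnt <= max_male_carriers)

    alt_spec = carrier_rule(dF, dM, dF >= 1, dM >= 1)
    ref_spec = carrier_rule(dF, dM, (dF <= 1) & (dF != MISSING), (dM <= 1) & (dM != MISSING))
    flagged = np.flatnonzero(alt_spec | ref_spec)

    blocks: list[GenomicInterval] = []
    chrom_arr, pos_arr = np.asarray(gm.chrom), np.asarray(gm.pos)
    for chrom in pd.unique(chrom_arr[flagged]):
        sel = flagged[chrom_arr[flagged] == chrom]
        pos = np.sort(pos_arr[sel])
        run_start = 0
        for i in range(1, len(pos) + 1):
            if i == len(pos) or pos[i] - pos[i - 1] > max_gap:
                if i - run_start >= min_snps:
                    blocks.append(
                        GenomicInterval(chrom, int(pos[run_start]), int(pos[i - 1]))
                    )
                run_start = i
    return flagged, blocks
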