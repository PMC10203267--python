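"""Sex chromosome and SDR detection from pooled coverage plus SNP evidence.

The coverage rule follows the published F/(F+M) logic: a window is
W-specific when the female share of pooled depth exceeds 0.5 (+ a noise
margin delta), male-elevated when it falls below 0.5 − delta. The SDR call
is the envelope of long divergent runs on the chromosome carrying the most
divergent sequence, merged across internally balanced stretches (the region
is a mosaic of W-specific sequence and W homologs of Z sequence).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats as sps

from .intervals import GenomicInterval, merge_intervals
from .io_formats import CoverageTrack, GeneticMapMarker

COVERAGE_CLASSES = ("W_specific", "male_elevated", "balanced", "low_coverage")


# ---------------------------------------------------------------------------
# coverage windows
# ---------------------------------------------------------------------------

def coverage_windows(
    female: CoverageTrack,
    male: CoverageTrack,
    window: int = 10_000,
    min_total: float = 10.0,
) -> pd.DataFrame:
    """Average both pools into fixed windows and compute the depth shares
    F/(F+M) and M/(F+M); windows below ``min_total`` total depth are marked
    low_coverage and get no ratios."""
    chroms_f, chroms_m = set(female.chromosomes()), set(male.chromosomes())
    if not chroms_f & chroms_m:
        raise ValueError("female and male tracks share no chromosome")

    def _accumulate(track: CoverageTrack) -> dict[str, np.ndarray]:
        # bp-weighted depth sums per window
        sums: dict[str, np.ndarray] = {}
        lengths: dict[str, int] = {}
        for iv in track.intervals:
            lengths[iv.chrom] = max(lengths.get(iv.chrom, 0), iv.end)
        for chrom, length in lengths.items():
            sums[chrom] = np.zeros(int(np.ceil(length / window)))
        for iv, depth in zip(track.intervals, track.depth):
            w0 = (iv.start - 1) // window
            w1 = (iv.end - 1) // window
            for wi in range(w0, w1 + 1):
                lo = max(iv.start, wi * window + 1)
                hi = min(iv.end, (wi + 1) * window)
                sums[iv.chrom][wi] += depth * (hi - lo + 1)
        return sums

    sums_f, sums_m = _accumulate(female), _accumulate(male)
    rows = []
    for chrom in sorted(chroms_f & chroms_m):
        n_win = max(len(sums_f.get(chrom, [])), len(sums_m.get(chrom, [])))
        sf = np.zeros(n_win)
        sm = np.zeros(n_win)
        sf[: len(sums_f.get(chrom, []))] = sums_f.get(chrom, np.zeros(0))
        sm[: len(sums_m.get(chrom, []))] = sums_m.get(chrom, np.zeros(0))
        for wi in range(n_win):
            start, end = wi * window + 1, (wi + 1) * window
            f_depth = sf[wi] / window
            m_depth = sm[wi] / window
            total = f_depth + m_depth
            if total >= min_total:
                ratio_f = f_depth / total
                ratio_m = m_depth / total
            else:
                ratio_f = ratio_m = np.nan
            rows.append((chrom, start, end, f_depth, m_depth, ratio_f, ratio_m))
    df = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "f_depth", "m_depth", "ratio_f", "ratio_m"]
    )
    df["cls"] = "balanced"
    df.loc[df["ratio_f"].isna(), "cls"] = "low_coverage"
    return df


def classify_windows(cw: pd.DataFrame, delta: float = 0.05) -> pd.DataFrame:
    """Partition windows into W_specific / male_elevated / balanced by the
    0.5 ± delta rule (delta = 0 reproduces the strict 0.5 cutoff)."""
    if not 0 <= delta < 0.5:
        raise ValueError("delta must be in [0, 0.5)")
    out = cw.copy()
    low = out["ratio_f"].isna()
    out["cls"] = "balanced"
    out.loc[out["ratio_f"] > 0.5 + delta, "cls"] = "W_specific"
    out.loc[out["ratio_f"] < 0.5 - delta, "cls"] = "male_elevated"
    out.loc[low, "cls"] = "low_coverage"
    return out


# ---------------------------------------------------------------------------
# SDR calling
# ---------------------------------------------------------------------------

@dataclass
class SdrCall:
    """An SDR span with its member divergent runs and evidence supports."""

    chrom: str | None
    interval: GenomicInterval | None
    divergent_runs: list[GenomicInterval] = field(default_factory=list)
    w_specific: list[GenomicInterval] = field(default_factory=list)
    supports: dict[str, float] = field(default_factory=dict)
    support_count: int = 0

    @property
    def is_empty(self) -> bool:
        return self.interval is None

    def span_mb(self) -> float | None:
        if self.interval is None:
            return None
        mb = Decimal(self.interval.end - self.interval.start) / Decimal(10**6)
        return float(mb.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (start_idx, end_idx) inclusive."""
    out = []
    i = 0
    n = len(mask)
    while i < n:
        if mask[i]:
            j = i
            while j + 1 < n and mask[j + 1]:
                j += 1
            out.append((i, j))
            i = j + 1
        else:
            i += 1
    return out


def call_sdr(
    cw: pd.DataFrame, min_run: int = 5, max_gap: int = 1_000_000
) -> SdrCall:
    """Call the SDR from classified coverage windows.

    Divergent runs are maximal runs of >= min_run consecutive non-balanced
    (W_specific or male_elevated) windows. Chromosomes are ranked by total
    divergent bp; on the best one, runs separated by <= max_gap are chained
    and the chain with the most divergent bp becomes the SDR span.
    Returns an empty call when no chromosome has a divergent run.
    """
    best: tuple[float, SdrCall] | None = None
    for chrom, sub in cw.sort_values(["chrom", "start"]).groupby("chrom"):
        sub = sub.reset_index(drop=True)
        divergent = sub["cls"].isin(["W_specific", "male_elevated"]).to_numpy()
        runs_idx = [(i, j) for i, j in _runs(divergent) if j - i + 1 >= min_run]
        if not runs_idx:
            continue
        runs = [
            GenomicInterval(chrom, int(sub.loc[i, "start"]), int(sub.loc[j, "end"]))
            for i, j in runs_idx
        ]
        score = float(sum(r.length_bp for r in runs))

        # chain runs whose gaps are <= max_gap; keep the heaviest chain
        chains: list[list[GenomicInterval]] = [[runs[0]]]
        for r in runs[1:]:
            if r.start - chains[-1][-1].end - 1 <= max_gap:
                chains[-1].append(r)
            else:
                chains.append([r])
        chain = max(chains, key=lambda c: sum(r.length_bp for r in c))
        span = GenomicInterval(chrom, chain[0].start, chain[-1].end)

        w_runs = [
            GenomicInterval(chrom, int(sub.loc[i, "start"]), int(sub.loc[j, "end"]))
            for i, j in _runs((sub["cls"] == "W_specific").to_numpy())
            if j - i + 1 >= min_run
        ]
        w_specific = [w for w in merge_intervals(w_runs) if span.contains(w)]
        call = SdrCall(chrom, span, chain, w_specific)
        if best is None or score > best[0]:
            best = (score, call)
    return best[1] if best is not None else SdrCall(None, None)


def integrate_evidence(
    sdr: SdrCall,
    assoc: pd.DataFrame,
    fst_windows: pd.DataFrame,
    fem_blocks: list[GenomicInterval],
    assoc_cut: float = 10.0,
    fst_top: float = 0.01,
) -> SdrCall:
    """Annotate an SDR call with the three SNP evidence layers.

    Layers: association sites with −log10 P >= assoc_cut; Fst windows at or
    above the empirical top-``fst_top`` quantile; female-specific SNP blocks
    as given. ``support_count`` = number of layers with >= 1 element inside
    the SDR span (0 when the call is empty).
    """
    if sdr.is_empty:
        sdr.supports = {"assoc": 0.0, "fst": 0.0, "fem_blocks": 0.0}
        sdr.support_count = 0
        return sdr
    layer_chroms = set(assoc["chrom"]) | set(fst_windows["chrom"]) | {
        b.chrom for b in fem_blocks
    }
    if layer_chroms and sdr.chrom not in layer_chroms:
        raise ValueError(
            f"SDR chromosome {sdr.chrom!r} absent from evidence layers "
            f"({sorted(layer_chroms)}): chromosome naming mismatch?"
        )
    span = sdr.interval

    assoc_hits = assoc[(assoc["neg_log10_p"] >= assoc_cut)]
    assoc_in = assoc_hits[
        (assoc_hits["chrom"] == span.chrom)
        & (assoc_hits["pos"] >= span.start)
        & (assoc_hits["pos"] <= span.end)
    ]

    vals = fst_windows["value"].to_numpy(dtype=float)
    vals = vals[np.isfinite(vals)]
    fst_thresh = float(np.quantile(vals, 1.0 - fst_top)) if len(vals) else np.inf
    fst_hits = fst_windows[fst_windows["value"] >= fst_thresh]
    fst_in = fst_hits[
        (fst_hits["chrom"] == span.chrom)
        & (fst_hits["end"] >= span.start)
        & (fst_hits["start"] <= span.end)
    ]

    blocks_in = [b for b in fem_blocks if b.overlaps(span)]

    sdr.supports = {
        "assoc": float(len(assoc_in)),
        "fst": float(len(fst_in)),
        "fem_blocks": float(len(blocks_in)),
        "fst_threshold": fst_thresh,
    }
    sdr.support_count = int(
        (len(assoc_in) > 0) + (len(fst_in) > 0) + (len(blocks_in) > 0)
    )
    return sdr


# ---------------------------------------------------------------------------
# genetic-map diagnostics
# ---------------------------------------------------------------------------

def detect_recomb_suppressed_chromosome(
    markers: list[GeneticMapMarker], min_markers: int = 10
) -> pd.DataFrame:
    """Rank chromosomes by Spearman correlation between physical and genetic
    position (ascending: the recombination-suppressed candidate first) and
    report each chromosome's widest zero-recombination plateau."""
    df = pd.DataFrame(
        {
            "chrom": [m.chrom for m in markers],
            "bp": [m.pos_bp for m in markers],
            "cm": [m.pos_cm for m in markers],
        }
    )
    rows = []
    for chrom, sub in df.groupby("chrom"):
        if len(sub) < min_markers:
            import warnings

            warnings.warn(f"{chrom}: fewer than {min_markers} markers; skipped")
            continue
        sub = sub.sort_values("bp")
        rho = float(sps.spearmanr(sub["bp"], sub["cm"]).statistic)
        cm = sub["cm"].to_numpy()
        bp = sub["bp"].to_numpy()
        plateau = 0
        i = 0
        while i < len(cm):
            j = i
            while j + 1 < len(cm) and abs(cm[j + 1] - cm[i]) < 1e-9:
                j += 1
            plateau = max(plateau, int(bp[j] - bp[i]))
            i = j + 1
        rows.append((chrom, rho, plateau, len(sub)))
    out = pd.DataFrame(rows, columns=["chrom", "rho", "plateau_bp", "n_markers"])
    return out.sort_values("rho", kind="stable").reset_index(drop=True)


def marker_alignment_rate(aligned_flags) -> float:
    """Percentage of markers aligned, rounded half-up to one decimal."""
    flags = np.asarray(aligned_flags, dtype=bool)
    if flags.size == 0:
        raise ValueError("no markers")
    pct = Decimal(int(flags.sum())) / Decimal(int(flags.size)) * 100
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))
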