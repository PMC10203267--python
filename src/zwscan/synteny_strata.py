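"""W-Z collinearity, inversion detection, Ka/Ks by Nei-Gojobori, and
evolutionary strata dating.

The divergence estimator is the counting method of Nei & Gojobori (1986):
fractional synonymous site counts per codon, averaging over all orderings
of single-nucleotide changes for multi-hit codons (paths through stop
codons excluded and the weights renormalized), and the Jukes-Cantor
multiple-hit correction d = -(3/4)·ln(1 - (4/3)p). Divergence times follow
the molecular clock T = Ksil / (2·mu).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .intervals import GenomicInterval, merge_intervals, span_mb
from .io_formats import AnchorPair, HitRecord

BASES = "ACGT"
_TABLE = CodonTable.unambiguous_dna_by_id[1]
STOPS = frozenset(_TABLE.stop_codons)
AA = dict(_TABLE.forward_table)


def _is_codon(c: str) -> bool:
    return len(c) == 3 and all(b in BASES for b in c)


def _neighbors(codon: str, pos: int):
    for b in BASES:
        if b != codon[pos]:
            yield codon[:pos] + b + codon[pos + 1:]


@lru_cache(maxsize=None)
def _syn_sites(codon: str) -> float:
    """Fractional synonymous sites of one codon: per position, the fraction
    of non-stop single changes that are synonymous (so s + n = 3)."""
    if codon in STOPS:
        raise ValueError(f"stop codon {codon}")
    s = 0.0
    for pos in range(3):
        alts = [c for c in _neighbors(codon, pos) if c not in STOPS]
        if not alts:
            continue
        syn = sum(AA[c] == AA[codon] for c in alts)
        s += syn / len(alts)
    return s


@lru_cache(maxsize=None)
def _pair_differences(c1: str, c2: str, stop_paths: str = "exclude") -> tuple[float, float]:
    """Synonymous/nonsynonymous difference counts between two codons,
    averaged over all orderings of the single changes.

    stop_paths='exclude' drops orderings that pass through a stop codon and
    renormalizes; 'count-nonsyn' keeps them, counting steps into or out of a
    stop as nonsynonymous. If every path is blocked in exclude mode the
    count-nonsyn fallback is used.
    """
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0

    def walk(order: tuple[int, ...]) -> tuple[float, float] | None:
        cur = c1
        sd = nd = 0.0
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if nxt in STOPS or cur in STOPS:
                if stop_paths == "exclude":
                    return None
                nd += 1.0
            elif AA[cur] == AA[nxt]:
                sd += 1.0
            else:
                nd += 1.0
            cur = nxt
        return sd, nd

    results = [walk(order) for order in itertools.permutations(diff_pos)]
    valid = [r for r in results if r is not None]
    if not valid:  # all orderings blocked by stops: fall back
        return _pair_differences(c1, c2, "count-nonsyn")
    sd = float(np.mean([r[0] for r in valid]))
    nd = float(np.mean([r[1] for r in valid]))
    return sd, nd


def jukes_cantor(p: float) -> float:
    """JC multiple-hit correction; defined for p < 3/4."""
    if p >= 0.75:
        return float("nan")
    return -0.75 * np.log(1.0 - 4.0 * p / 3.0)


@dataclass
class DivergenceEstimate:
    """Nei-Gojobori site and difference counts with JC-corrected rates."""

    s_sites: float
    n_sites: float
    sd: float
    nd: float
    ps: float
    pn: float
    ks: float
    ka: float
    ksil: float
    n_codons: int
    ks_valid: bool = True
    ka_valid: bool = True
    ksil_is_ks: bool = True  # CDS-only input: no noncoding silent sites


def nei_gojobori(
    cds_a: str, cds_b: str, stop_paths: str = "exclude"
) -> DivergenceEstimate:
    """Ka/Ks between two aligned coding sequences (equal length, multiple of
    3, no stop codons). Codons containing non-ACGT characters (gaps,
    ambiguity codes) in either sequence are skipped."""
    if len(cds_a) != len(cds_b):
        raise ValueError("aligned CDS lengths differ")
    if len(cds_a) % 3 != 0:
        raise ValueError("CDS length is not a multiple of 3")
    a, b = cds_a.upper(), cds_b.upper()

    S = N = Sd = Nd = 0.0
    n_codons = 0
    for i in range(0, len(a), 3):
        ca, cb = a[i: i + 3], b[i: i + 3]
        if not (_is_codon(ca) and _is_codon(cb)):
            continue
        if ca in STOPS or cb in STOPS:
            if i == len(a) - 3:
                continue  # aligned terminal stop codon
            raise ValueError(f"internal stop codon at position {i + 1}")
        s = 0.5 * (_syn_sites(ca) + _syn_sites(cb))
        S += s
        N += 3.0 - s
        sd, nd = _pair_differences(ca, cb, stop_paths)
        Sd += sd
        Nd += nd
        n_codons += 1
    if n_codons == 0:
        raise ValueError("no usable codons")

    ps = Sd / S if S > 0 else 0.0
    pn = Nd / N if N > 0 else 0.0
    ks, ka = jukes_cantor(ps), jukes_cantor(pn)
    est = DivergenceEstimate(
        s_sites=S, n_sites=N, sd=Sd, nd=Nd, ps=ps, pn=pn,
        ks=ks, ka=ka, ksil=ks, n_codons=n_codons,
        ks_valid=np.isfinite(ks), ka_valid=np.isfinite(ka),
    )
    return est


@dataclass
class MutationClock:
    """Substitutions per site per year."""

    mu: float = 7.5e-10

    def __post_init__(self) -> None:
        if self.mu <= 0:
            raise ValueError("mu must be > 0")


def date_divergence(est: DivergenceEstimate, clock: MutationClock) -> float:
    """Divergence time in years, T = Ksil / (2·mu); NaN propagates."""
    if not np.isfinite(est.ksil):
        return float("nan")
    return est.ksil / (2.0 * clock.mu)


# ---------------------------------------------------------------------------
# collinear blocks and inversions
# ---------------------------------------------------------------------------

@dataclass
class CollinearBlock:
    anchors: list[AnchorPair]
    orientation: str  # 'collinear' | 'inverted'
    w_span: GenomicInterval
    z_span: GenomicInterval

    @property
    def n_anchors(self) -> int:
        return len(self.anchors)


def _spans(anchors: list[AnchorPair]) -> tuple[GenomicInterval, GenomicInterval]:
    w = GenomicInterval(
        anchors[0].w_interval.chrom,
        min(a.w_interval.start for a in anchors),
        max(a.w_interval.end for a in anchors),
    )
    z = GenomicInterval(
        anchors[0].z_interval.chrom,
        min(a.z_interval.start for a in anchors),
        max(a.z_interval.end for a in anchors),
    )
    return w, z


def build_collinear_blocks(
    anchors: list[AnchorPair],
    min_block_anchors: int = 3,
    max_rank_gap: int = 2,
) -> list[CollinearBlock]:
    """Chain W-ordered anchors into maximal monotone runs of Z rank.

    Consecutive members of a run must move in one direction with
    |Δ z-rank| <= max_rank_gap; ascending runs are collinear, descending
    runs inverted. Runs shorter than min_block_anchors are discarded.
    Duplicated genes keep their first anchor (with a warning).
    """
    seen_w: set[str] = set()
    seen_z: set[str] = set()
    dedup: list[AnchorPair] = []
    for a in sorted(anchors, key=lambda a: (a.w_interval.chrom, a.w_interval.start)):
        if a.w_gene in seen_w or a.z_gene in seen_z:
            warnings.warn(f"duplicate gene in anchors ({a.w_gene}/{a.z_gene}); keeping first")
            continue
        seen_w.add(a.w_gene)
        seen_z.add(a.z_gene)
        dedup.append(a)
    if not dedup:
        return []

    z_order = sorted(
        range(len(dedup)),
        key=lambda i: (dedup[i].z_interval.chrom, dedup[i].z_interval.start),
    )
    rank = np.empty(len(dedup), dtype=int)
    rank[z_order] = np.arange(len(dedup))

    blocks: list[CollinearBlock] = []

    def close(run: list[int], direction: int) -> None:
        if len(run) < min_block_anchors:
            return
        members = [dedup[i] for i in run]
        w_span, z_span = _spans(members)
        blocks.append(
            CollinearBlock(
                members,
                "inverted" if direction < 0 else "collinear",
                w_span,
                z_span,
            )
        )

    run = [0]
    direction = 0
    for t in range(1, len(dedup)):
        delta = int(rank[t] - rank[run[-1]])
        step_ok = 0 < abs(delta) <= max_rank_gap
        if step_ok and (direction == 0 or np.sign(delta) == direction):
            if direction == 0:
                direction = int(np.sign(delta))
            run.append(t)
        else:
            close(run, direction)
            run, direction = [t], 0
    close(run, direction)
    return blocks


@dataclass
class InversionCall:
    w_span: GenomicInterval
    z_span: GenomicInterval
    n_anchors: int
    block: CollinearBlock


def detect_inversions(blocks: list[CollinearBlock]) -> list[InversionCall]:
    """Report every inverted block (W span, Z span, anchor count)."""
    return [
        InversionCall(b.w_span, b.z_span, b.n_anchors, b)
        for b in blocks
        if b.orientation == "inverted"
    ]


def inversion_envelope(calls: list[InversionCall]) -> GenomicInterval | None:
    if not calls:
        return None
    merged = merge_intervals([c.w_span for c in calls], max_gap=10**12)
    return merged[0]


# ---------------------------------------------------------------------------
# W/Z-specific genes
# ---------------------------------------------------------------------------

def call_specific_genes(
    w_genes: set[str],
    z_genes: set[str],
    hits_wz: list[HitRecord],
    hits_zw: list[HitRecord],
    paired_w: set[str] | None = None,
    paired_z: set[str] | None = None,
    id_min: float = 99.0,
    len_min: int = 1000,
) -> tuple[set[str], set[str]]:
    """W- and Z-specific gene sets by the reciprocal-hit criteria.

    A gene is non-specific iff it has at least one hit with identity >=
    id_min AND matching bp >= len_min in the reciprocal table. The result is
    intersected with the genes left unpaired by collinearity (``paired_*``),
    both conditions being required for the final specific set.
    """

    def specific(genes: set[str], hits: list[HitRecord], paired: set[str] | None) -> set[str]:
        matched: set[str] = set()
        for h in hits:
            if h.query not in genes:
                warnings.warn(f"hit query {h.query} not in gene list; ignored")
                continue
            if h.identity >= id_min and h.matching_bp >= len_min:
                matched.add(h.query)
        spec = genes - matched
        if paired is not None:
            spec -= paired
        return spec

    return (
        specific(w_genes, hits_wz, paired_w),
        specific(z_genes, hits_zw, paired_z),
    )


# ---------------------------------------------------------------------------
# strata
# ---------------------------------------------------------------------------

@dataclass
class StratumEstimate:
    stratum_id: int
    block: CollinearBlock
    times: list[float] = field(default_factory=list)
    median_t: float = float("nan")
    low_confidence: bool = False


def assign_strata(
    inversions: list[InversionCall], pair_times: dict[str, float]
) -> list[StratumEstimate]:
    """One stratum per inverted block, summarized by the median member
    divergence time; strata numbered 1.. by descending age (oldest first).
    Blocks with fewer than 3 dated pairs are flagged low-confidence."""
    strata = []
    for call in inversions:
        times = [
            pair_times[a.w_gene]
            for a in call.block.anchors
            if a.w_gene in pair_times and np.isfinite(pair_times[a.w_gene])
        ]
        strata.append(
            StratumEstimate(
                stratum_id=0,
                block=call.block,
                times=times,
                median_t=float(np.median(times)) if times else float("nan"),
                low_confidence=len(times) < 3,
            )
        )
    strata.sort(key=lambda s: -(s.median_t if np.isfinite(s.median_t) else -np.inf))
    for i, s in enumerate(strata, start=1):
        s.stratum_id = i
    return strata


def divergence_table(
    anchors: list[AnchorPair], clock: MutationClock, stop_paths: str = "exclude"
) -> pd.DataFrame:
    """Per-pair Ka/Ks/Ksil and dated divergence time for CDS-bearing anchors."""
    rows = []
    for a in anchors:
        if a.w_cds is None or a.z_cds is None:
            continue
        est = nei_gojobori(a.w_cds, a.z_cds, stop_paths)
        rows.append(
            (
                a.w_gene, a.z_gene,
                a.w_interval.chrom, a.w_interval.start,
                a.z_interval.chrom, a.z_interval.start,
                est.s_sites, est.n_sites, est.sd, est.nd,
                est.ks, est.ka, est.ksil,
                date_divergence(est, clock),
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "w_gene", "z_gene", "w_chrom", "w_start", "z_chrom", "z_start",
            "S", "N", "Sd", "Nd", "Ks", "Ka", "Ksil", "T_years",
        ],
    )


def interval_report(intervals: list[GenomicInterval]) -> pd.DataFrame:
    """Lengths in Mb (2 dp, printed-span convention end − start)."""
    return pd.DataFrame(
        {
            "chrom": [iv.chrom for iv in intervals],
            "start": [iv.start for iv in intervals],
            "end": [iv.end for iv in intervals],
            "length_mb": [span_mb(iv) for iv in intervals],
        }
    )
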