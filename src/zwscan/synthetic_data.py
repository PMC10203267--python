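"""Seeded simulators that emulate the study's inputs.

Every generator is a pure function of ``(config, seed)`` and each dataset
ships a machine-readable :class:`TruthSet`, so the detectors downstream can
be tested by parameter recovery rather than against external data.

The default configuration mirrors the study system: a 55-Mb ZW chromosome
whose sex-determination region (SDR) spans Chr14:39,979,216-52,678,755
(12.70 Mb) and carries three inversions dated 8.18, 3.80 and 3.47 Mya plus
nine W-specific segments, pooled female/male depth of ~30 reads, a 22F/22M
sex panel, and a wild + three-cultivar resequencing panel. Two 20-Mb
autosomes provide the null background.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np

from .genotypes import MISSING, GenotypeMatrix
from .intervals import GenomicInterval
from .io_formats import AnchorPair, CoverageTrack, GeneticMapMarker

# four-fold degenerate codon families: the third position is exactly one
# synonymous site per codon, positions 1-2 carry no synonymous changes
FOURFOLD_PREFIXES = ("GC", "GG", "GT", "CC", "AC", "TC")
BASES = "ACGT"
STOPS = {"TAA", "TAG", "TGA"}


# ---------------------------------------------------------------------------
# truth bookkeeping
# ---------------------------------------------------------------------------

@dataclass
class BlockTruth:
    """A planted W-Z gene-pair block (inversion or collinear)."""

    w_interval: GenomicInterval
    z_interval: GenomicInterval
    age_years: float
    n_anchors: int
    inverted: bool


@dataclass
class SweepTruth:
    interval: GenomicInterval
    reduction_factor: float
    subgroups: tuple[str, ...]


@dataclass
class TruthSet:
    """Planted features of a simulated dataset; round-trips through JSON."""

    sdr: GenomicInterval
    blocks: list[BlockTruth] = field(default_factory=list)
    w_specific: list[GenomicInterval] = field(default_factory=list)
    z_elevated: list[GenomicInterval] = field(default_factory=list)
    sweeps: list[SweepTruth] = field(default_factory=list)
    sex_linked_sites: list[tuple[str, int]] = field(default_factory=list)
    pair_divergence: dict[str, float] = field(default_factory=dict)

    @property
    def inversions(self) -> list[BlockTruth]:
        return [b for b in self.blocks if b.inverted]

    def to_json(self) -> str:
        def enc(obj):
            if isinstance(obj, GenomicInterval):
                return {"chrom": obj.chrom, "start": obj.start, "end": obj.end}
            return obj

        d = asdict(self)
        return json.dumps(d, default=enc, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "TruthSet":
        d = json.loads(text)

        def iv(x) -> GenomicInterval:
            return GenomicInterval(x["chrom"], x["start"], x["end"])

        return cls(
            sdr=iv(d["sdr"]),
            blocks=[
                BlockTruth(iv(b["w_interval"]), iv(b["z_interval"]),
                           b["age_years"], b["n_anchors"], b["inverted"])
                for b in d["blocks"]
            ],
            w_specific=[iv(x) for x in d["w_specific"]],
            z_elevated=[iv(x) for x in d["z_elevated"]],
            sweeps=[
                SweepTruth(iv(s["interval"]), s["reduction_factor"],
                           tuple(s["subgroups"]))
                for s in d["sweeps"]
            ],
            sex_linked_sites=[(c, p) for c, p in d["sex_linked_sites"]],
            pair_divergence=dict(d["pair_divergence"]),
        )


@dataclass
class ReferenceLayout:
    chromosomes: dict[str, int]
    zw_chromosome: str


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

def _default_chromosomes() -> dict[str, int]:
    return {"Chr14": 55_000_000, "Chr01": 20_000_000, "Chr02": 20_000_000}


def _default_inversions() -> list[tuple[int, int, int, int, float, int]]:
    # (w_start, w_end, z_start, z_end, age_years, n_anchors)
    return [
        (49_032_998, 52_416_681, 51_779_783, 52_514_087, 8.18e6, 170),
        (42_858_892, 48_612_698, 50_320_242, 51_728_478, 3.80e6, 173),
        (40_647_874, 42_816_399, 50_002_496, 50_266_641, 3.47e6, 44),
    ]


def _default_collinear() -> list[tuple[int, int, int, int, float, int]]:
    return [
        (39_979_216, 40_460_393, 48_975_748, 49_411_952, 2.0e5, 12),
        (52_417_733, 52_678_755, 52_537_909, 52_967_355, 2.0e5, 12),
    ]


def _default_subgroups() -> dict[str, int]:
    return {"wild": 16, "Cultivar_I": 10, "Cultivar_II": 20, "Cultivar_III": 91}


def _default_theta() -> dict[str, float]:
    # genome-wide nucleotide diversities of the wild and cultivar panels
    return {
        "wild": 1.16e-3,
        "Cultivar_I": 0.93e-3,
        "Cultivar_II": 0.94e-3,
        "Cultivar_III": 1.02e-3,
    }


def _default_sweeps() -> list[tuple[str, int, int, float]]:
    # (chrom, start, end, reduction factor); cultivar subgroups all affected.
    # Centers sit on the default 20-kb omega grid: the planted LD break is
    # abrupt at the sweep center, so a grid point must fall there to see it.
    return [
        ("Chr01", 5_010_001, 5_110_000, 5.0),
        ("Chr01", 12_010_001, 12_110_000, 5.0),
        ("Chr02", 8_010_001, 8_110_000, 5.0),
    ]


@dataclass
class SimulationConfig:
    """Parameters of the simulated study system (all seeded)."""

    seed: int = 0
    chromosomes: dict[str, int] = field(default_factory=_default_chromosomes)
    zw_chromosome: str = "Chr14"
    sdr_start: int = 39_979_216
    sdr_end: int = 52_678_755
    inversions: list[tuple[int, int, int, int, float, int]] = field(
        default_factory=_default_inversions
    )
    collinear_blocks: list[tuple[int, int, int, int, float, int]] = field(
        default_factory=_default_collinear
    )
    n_w_segments: int = 9
    w_segment_bp: int = 600_000
    z_elevated_bp: int = 300_000
    # pooled coverage
    lambda_f: float = 30.0
    lambda_m: float = 30.0
    coverage_bin: int = 1_000
    # sex panel
    n_females: int = 22
    n_males: int = 22
    background_snp_spacing: int = 2_000
    sex_linked_spacing: int = 5_000
    # population panel
    subgroup_sizes: dict[str, int] = field(default_factory=_default_subgroups)
    theta: dict[str, float] = field(default_factory=_default_theta)
    sweeps: list[tuple[str, int, int, float]] = field(default_factory=_default_sweeps)
    sweep_subgroups: tuple[str, ...] = ("Cultivar_I", "Cultivar_II", "Cultivar_III")
    # W-Z gene pairs
    mu: float = 7.5e-10
    codons_per_gene: int = 300
    # genetic map
    marker_spacing: int = 250_000
    cm_per_mb: float = 4.0

    def validate(self) -> None:
        if any(l <= 0 for l in self.chromosomes.values()):
            raise ValueError("chromosome lengths must be positive")
        if self.zw_chromosome not in self.chromosomes:
            raise ValueError(f"{self.zw_chromosome} not in chromosomes")
        zw_len = self.chromosomes[self.zw_chromosome]
        if not (1 <= self.sdr_start <= self.sdr_end <= zw_len):
            raise ValueError("SDR outside ZW chromosome bounds")
        if self.lambda_f <= 0 or self.lambda_m <= 0:
            raise ValueError("pooled depth means must be > 0")
        for name, th in self.theta.items():
            if not 0 < th < 0.1:
                raise ValueError(f"theta[{name}] must be in (0, 0.1)")
        for chrom, s, e, f in self.sweeps:
            if chrom not in self.chromosomes:
                raise ValueError(f"sweep chromosome {chrom} unknown")
            if not (1 <= s <= e <= self.chromosomes[chrom]):
                raise ValueError("sweep interval outside chromosome bounds")
            if f < 1:
                raise ValueError("sweep reduction factor must be >= 1")
        if self.mu <= 0:
            raise ValueError("mu must be > 0")


def _rng(config: SimulationConfig, salt: int) -> np.random.Generator:
    return np.random.default_rng((int(config.seed), int(salt)))


def _check_disjoint(ivs: Sequence[GenomicInterval], what: str) -> None:
    seen = sorted(ivs, key=lambda iv: (iv.chrom, iv.start))
    for a, b in zip(seen, seen[1:]):
        if a.chrom == b.chrom and b.start <= a.end:
            raise ValueError(f"overlapping {what} truth intervals: {a} / {b}")


# ---------------------------------------------------------------------------
# reference layout
# ---------------------------------------------------------------------------

def simulate_zw_reference(config: SimulationConfig) -> tuple[ReferenceLayout, TruthSet]:
    """Lay out the ZW chromosome truth: SDR, inversion blocks, W-specific and
    male-elevated (Z-analogue) segments. Deterministic given the config."""
    config.validate()
    zw = config.zw_chromosome
    sdr = GenomicInterval(zw, config.sdr_start, config.sdr_end)

    blocks = [
        BlockTruth(
            GenomicInterval(zw, ws, we),
            GenomicInterval(f"Z_{zw}", zs, ze),
            age,
            n,
            inverted=True,
        )
        for ws, we, zs, ze, age, n in config.inversions
    ] + [
        BlockTruth(
            GenomicInterval(zw, ws, we),
            GenomicInterval(f"Z_{zw}", zs, ze),
            age,
            n,
            inverted=False,
        )
        for ws, we, zs, ze, age, n in config.collinear_blocks
    ]
    _check_disjoint([b.w_interval for b in blocks], "gene-pair block")
    for b in blocks:
        if not sdr.contains(b.w_interval):
            raise ValueError(f"block {b.w_interval} outside the SDR")

    # W-specific segments tile the SDR from boundary to boundary so that the
    # coverage signal starts/stops exactly at the printed SDR span
    n_seg, seg_bp = config.n_w_segments, config.w_segment_bp
    span = sdr.end - sdr.start + 1
    if n_seg * seg_bp > span:
        raise ValueError("W-specific segments do not fit in the SDR")
    w_specific: list[GenomicInterval] = []
    if n_seg == 0:
        pass  # null layout: no W-specific coverage signal
    elif n_seg == 1:
        w_specific.append(GenomicInterval(zw, sdr.start, sdr.start + seg_bp - 1))
    else:
        stride = (span - seg_bp) / (n_seg - 1)
        for i in range(n_seg):
            s = sdr.start + int(round(i * stride))
            e = min(s + seg_bp - 1, sdr.end)
            w_specific.append(GenomicInterval(zw, s, e))
        # force the last segment to close the SDR exactly
        last = w_specific[-1]
        w_specific[-1] = GenomicInterval(zw, sdr.end - seg_bp + 1, sdr.end)
        if w_specific[-1].start <= w_specific[-2].end:
            raise ValueError("W-specific segments overlap; shrink w_segment_bp")
        del last
    _check_disjoint(w_specific, "W-specific segment")

    # male-elevated (Z-analogue) segments centred in the gaps between
    # W-specific segments
    z_elevated: list[GenomicInterval] = []
    for a, b in zip(w_specific, w_specific[1:]):
        gap_start, gap_end = a.end + 1, b.start - 1
        gap = gap_end - gap_start + 1
        if gap <= config.z_elevated_bp:
            continue
        mid = (gap_start + gap_end) // 2
        half = config.z_elevated_bp // 2
        z_elevated.append(GenomicInterval(zw, mid - half, mid - half + config.z_elevated_bp - 1))
    _check_disjoint(z_elevated + w_specific, "coverage segment")

    sweeps = [
        SweepTruth(GenomicInterval(c, s, e), f, tuple(config.sweep_subgroups))
        for c, s, e, f in config.sweeps
    ]
    _check_disjoint([s.interval for s in sweeps], "sweep")

    truth = TruthSet(
        sdr=sdr,
        blocks=blocks,
        w_specific=w_specific,
        z_elevated=z_elevated,
        sweeps=sweeps,
    )
    return ReferenceLayout(dict(config.chromosomes), zw), truth


# ---------------------------------------------------------------------------
# pooled coverage
# ---------------------------------------------------------------------------

def simulate_pooled_coverage(
    layout: ReferenceLayout, truth: TruthSet, config: SimulationConfig
) -> tuple[CoverageTrack, CoverageTrack]:
    """Female- and male-pool depth tracks in ``coverage_bin``-bp bins.

    Per-base depth is Poisson with mean λ; each bin reports the mean over its
    bases (``Poisson(λ·B)/B``). Male mean is 0 on W-specific segments and
    doubled on the Z-analogue segments; both pools are at base λ elsewhere.
    """
    bin_bp = config.coverage_bin
    if bin_bp > min(layout.chromosomes.values()):
        raise ValueError("coverage bin larger than the smallest chromosome")
    rng = _rng(config, 1)

    intervals: list[GenomicInterval] = []
    lam_f_all: list[np.ndarray] = []
    lam_m_all: list[np.ndarray] = []
    lengths: list[np.ndarray] = []
    for chrom, length in layout.chromosomes.items():
        starts = np.arange(1, length + 1, bin_bp, dtype=np.int64)
        ends = np.minimum(starts + bin_bp - 1, length)
        mids = (starts + ends) // 2
        lam_f = np.full(len(starts), config.lambda_f)
        lam_m = np.full(len(starts), config.lambda_m)
        if chrom == layout.zw_chromosome:
            for seg in truth.w_specific:
                inside = (mids >= seg.start) & (mids <= seg.end)
                lam_m[inside] = 0.0
            for seg in truth.z_elevated:
                inside = (mids >= seg.start) & (mids <= seg.end)
                lam_m[inside] = 2.0 * config.lambda_m
        intervals.extend(
            GenomicInterval(chrom, int(s), int(e)) for s, e in zip(starts, ends)
        )
        lam_f_all.append(lam_f)
        lam_m_all.append(lam_m)
        lengths.append((ends - starts + 1).astype(float))

    lam_f = np.concatenate(lam_f_all)
    lam_m = np.concatenate(lam_m_all)
    nbp = np.concatenate(lengths)
    depth_f = rng.poisson(lam_f * nbp) / nbp
    depth_m = rng.poisson(lam_m * nbp) / nbp
    return (
        CoverageTrack(list(intervals), depth_f),
        CoverageTrack(list(intervals), depth_m),
    )


# ---------------------------------------------------------------------------
# genotype panels
# ---------------------------------------------------------------------------

def _folded_spectrum_counts(rng: np.random.Generator, n_alleles: int,
                            n_sites: int) -> np.ndarray:
    """Sample minor-allele counts from the neutral folded spectrum
    P(k) ∝ (1/k + 1/(n-k)) / (1 + [k == n-k]), k = 1..n//2."""
    ks = np.arange(1, n_alleles // 2 + 1)
    w = 1.0 / ks + 1.0 / (n_alleles - ks)
    w[ks == n_alleles - ks] /= 2.0
    p = w / w.sum()
    return rng.choice(ks, size=n_sites, p=p)


def _assign_exact(rng: np.random.Generator, n_slots: int,
                  k: np.ndarray, chunk: int = 20_000) -> np.ndarray:
    """Boolean (n_sites, n_slots) carrier matrix with exactly k[i] carriers
    per site, uniformly at random (chunked threshold-of-order-statistic)."""
    n_sites = len(k)
    out = np.empty((n_sites, n_slots), dtype=bool)
    for lo in range(0, n_sites, chunk):
        hi = min(lo + chunk, n_sites)
        r = rng.random((hi - lo, n_slots))
        kth = np.sort(r, axis=1)[np.arange(hi - lo), k[lo:hi] - 1]
        out[lo:hi] = r <= kth[:, None]
    return out


def _uniform_positions(rng: np.random.Generator, length: int, n: int) -> np.ndarray:
    pos = np.unique(rng.integers(1, length + 1, size=n))
    return pos


def simulate_sex_panel(
    layout: ReferenceLayout, truth: TruthSet, config: SimulationConfig
) -> GenotypeMatrix:
    """Resequencing panel of females and males.

    W-linked sites planted on the W-specific segments are heterozygous in
    every female and absent from every male; background sites segregate
    independently of sex from the neutral folded spectrum. Background sites
    that fall inside a W-specific segment have no male reads, so male
    genotypes there are missing (as in real pooled ZW data, where W-specific
    regions show heavy male missingness).
    """
    if config.n_females < 2 or config.n_males < 2:
        raise ValueError("need at least 2 samples of each sex")
    rng = _rng(config, 2)
    nF, nM = config.n_females, config.n_males
    n_samples = nF + nM
    n_alleles = 2 * n_samples

    samples = [f"F{i+1}" for i in range(nF)] + [f"M{i+1}" for i in range(nM)]
    sex = np.array(["F"] * nF + ["M"] * nM, dtype=object)
    subgroup = np.array(["other"] * n_samples, dtype=object)

    chroms_l, pos_l, dosage_l = [], [], []
    sex_linked: list[tuple[str, int]] = []
    for chrom, length in layout.chromosomes.items():
        n_bg = length // config.background_snp_spacing
        pos = _uniform_positions(rng, length, n_bg)
        k = _folded_spectrum_counts(rng, n_alleles, len(pos))
        slots = _assign_exact(rng, n_alleles, k)
        dos = (slots[:, 0::2].astype(np.int8) + slots[:, 1::2].astype(np.int8)).T
        planted_pos = np.array([], dtype=np.int64)
        if chrom == layout.zw_chromosome:
            # background sites inside W-specific sequence: no male reads
            in_w = np.zeros(len(pos), dtype=bool)
            for seg in truth.w_specific:
                in_w |= (pos >= seg.start) & (pos <= seg.end)
            dos[nF:, in_w] = MISSING
            planted = []
            for seg in truth.w_specific:
                planted.extend(
                    range(seg.start + config.sex_linked_spacing // 2, seg.end + 1,
                          config.sex_linked_spacing)
                )
            planted_pos = np.asarray(sorted(planted), dtype=np.int64)
            keep = ~np.isin(pos, planted_pos)
            pos, dos = pos[keep], dos[:, keep]
            dos_planted = np.zeros((n_samples, len(planted_pos)), dtype=np.int8)
            dos_planted[:nF, :] = 1  # all females heterozygous, all males ref
            pos = np.concatenate([pos, planted_pos])
            dos = np.concatenate([dos, dos_planted], axis=1)
            order = np.argsort(pos, kind="stable")
            pos, dos = pos[order], dos[:, order]
            sex_linked.extend((chrom, int(p)) for p in planted_pos)
        chroms_l.append(np.full(len(pos), chrom, dtype=object))
        pos_l.append(pos)
        dosage_l.append(dos)

    chrom_arr = np.concatenate(chroms_l)
    pos_arr = np.concatenate(pos_l)
    dosage = np.concatenate(dosage_l, axis=1)
    truth.sex_linked_sites = sex_linked
    n_sites = len(pos_arr)
    return GenotypeMatrix(
        samples=samples,
        sex=sex,
        subgroup=subgroup,
        chrom=chrom_arr,
        pos=pos_arr,
        ref=np.full(n_sites, "A", dtype=object),
        alt=np.full(n_sites, "T", dtype=object),
        dp=np.full(n_sites, 20.0),
        qual=np.full(n_sites, 50.0),
        dosage=dosage,
        meta={"panel": "sex", "seed": config.seed},
    )


def simulate_population_panel(
    layout: ReferenceLayout, truth: TruthSet, config: SimulationConfig
) -> GenotypeMatrix:
    """Wild + cultivar panel with planted domestication sweeps.

    Site frequencies follow the neutral folded spectrum; per-subgroup
    diversity is scaled to its θ by thinning (fixing a site within the
    subgroup); inside a sweep the affected subgroup's diversity is divided
    by the reduction factor and its carriers are rearranged into nested
    haplotype blocks on either flank of the sweep center, which plants the
    elevated flank LD / depressed cross-LD signature the ω statistic keys on.
    """
    for name, size in config.subgroup_sizes.items():
        if size < 4:
            raise ValueError(f"subgroup {name} has fewer than 4 samples")
    for s in truth.sweeps:
        if s.reduction_factor < 1:
            raise ValueError("sweep reduction factor must be >= 1")
    rng = _rng(config, 3)

    groups = list(config.subgroup_sizes)
    sizes = [config.subgroup_sizes[g] for g in groups]
    n_samples = sum(sizes)
    n_alleles = 2 * n_samples
    samples, subgroup = [], []
    for g, size in zip(groups, sizes):
        samples.extend(f"{g}_{i+1}" for i in range(size))
        subgroup.extend([g] * size)
    subgroup = np.array(subgroup, dtype=object)
    sex = np.array(["unknown"] * n_samples, dtype=object)

    theta_max = max(config.theta.get(g, max(config.theta.values())) for g in groups)
    a1 = np.sum(1.0 / np.arange(1, n_alleles))
    # slot ranges per subgroup
    slot_lo = np.cumsum([0] + [2 * s for s in sizes])
    group_slots = {g: (slot_lo[i], slot_lo[i + 1]) for i, g in enumerate(groups)}

    chroms_l, pos_l, dosage_l = [], [], []
    for chrom, length in layout.chromosomes.items():
        n_exp = rng.poisson(theta_max * a1 * length)
        pos = _uniform_positions(rng, length, n_exp)
        n_sites = len(pos)
        k = _folded_spectrum_counts(rng, n_alleles, n_sites)
        slots = _assign_exact(rng, n_alleles, k)  # (n_sites, n_alleles)

        # plant LD blocks: within each sweep flank, a subgroup's carriers are
        # rearranged onto a fixed slot order (nested haplotypes, D' = 1)
        for si, sw in enumerate(truth.sweeps):
            if sw.interval.chrom != chrom:
                continue
            center = (sw.interval.start + sw.interval.end) // 2
            for g in sw.subgroups:
                if g not in group_slots:
                    continue
                lo, hi = group_slots[g]
                for fi, (fs, fe) in enumerate(
                    ((sw.interval.start, center - 1), (center, sw.interval.end))
                ):
                    in_flank = np.flatnonzero((pos >= fs) & (pos <= fe))
                    if in_flank.size == 0:
                        continue
                    order = rng.permutation(hi - lo)
                    m = slots[in_flank, lo:hi].sum(axis=1)
                    blk = np.zeros((in_flank.size, hi - lo), dtype=bool)
                    rows = np.repeat(np.arange(in_flank.size), m)
                    cols = np.concatenate([order[:mm] for mm in m]) if m.sum() else []
                    blk[rows, cols] = True
                    slots[np.ix_(in_flank, np.arange(lo, hi))] = blk

        # per-subgroup thinning: fix a site (all-ref within the subgroup)
        # with prob 1 - (theta_g / theta_max) / factor_g(site)
        for g in groups:
            lo, hi = group_slots[g]
            theta_g = config.theta.get(g, theta_max)
            factor = np.ones(n_sites)
            for sw in truth.sweeps:
                if sw.interval.chrom == chrom and g in sw.subgroups:
                    inside = (pos >= sw.interval.start) & (pos <= sw.interval.end)
                    factor[inside] = sw.reduction_factor
            keep_p = (theta_g / theta_max) / factor
            drop = rng.random(n_sites) > keep_p
            slots[drop, lo:hi] = False

        dos = (slots[:, 0::2].astype(np.int8) + slots[:, 1::2].astype(np.int8)).T
        chroms_l.append(np.full(n_sites, chrom, dtype=object))
        pos_l.append(pos)
        dosage_l.append(dos)

    chrom_arr = np.concatenate(chroms_l)
    pos_arr = np.concatenate(pos_l)
    dosage = np.concatenate(dosage_l, axis=1)
    # drop sites monomorphic across the whole panel after thinning
    poly = dosage.sum(axis=0) > 0
    chrom_arr, pos_arr, dosage = chrom_arr[poly], pos_arr[poly], dosage[:, poly]
    n_sites = len(pos_arr)
    return GenotypeMatrix(
        samples=samples,
        sex=sex,
        subgroup=subgroup,
        chrom=chrom_arr,
        pos=pos_arr,
        ref=np.full(n_sites, "A", dtype=object),
        alt=np.full(n_sites, "T", dtype=object),
        dp=np.full(n_sites, 20.0),
        qual=np.full(n_sites, 50.0),
        dosage=dosage,
        meta={"panel": "population", "seed": config.seed},
    )


# ---------------------------------------------------------------------------
# W-Z gene pairs
# ---------------------------------------------------------------------------

def _jc_p(d: float) -> float:
    """Expected proportion of differing sites after JC divergence d."""
    return 0.75 * (1.0 - np.exp(-4.0 * d / 3.0))


def simulate_wz_gene_pairs(
    layout: ReferenceLayout,
    truth: TruthSet,
    config: SimulationConfig,
    n_pairs_override: int | None = None,
    codons_override: int | None = None,
) -> list[AnchorPair]:
    """CDS-bearing anchor pairs for every planted block.

    Codons come from the six fully four-fold-degenerate families, so the
    third position of each codon is exactly one synonymous site; those
    positions diverge under Jukes-Cantor at the planted distance
    ``2·mu·T``. Positions 1-2 diverge at 5% of that rate (purifying
    selection), with changes creating stop codons rejected. Within inverted
    blocks the Z order of anchors is reversed relative to W.

    Gene lengths vary uniformly between 0.5× and 1.5× the configured codon
    count (as real gene sets do); a fixed length would put every pair's Ks
    on the same 1/S lattice and bias the block median.
    """
    rng = _rng(config, 4)
    mean_codons = codons_override or config.codons_per_gene
    anchors: list[AnchorPair] = []
    truth.pair_divergence = {}
    for bi, block in enumerate(truth.blocks):
        d = 2.0 * config.mu * block.age_years
        if d >= 0.74:
            raise ValueError(f"2*mu*T = {d:.3f} >= 0.74: JC correction undefined")
        n_pairs = n_pairs_override or block.n_anchors
        p_syn = _jc_p(d)
        p_non = _jc_p(0.05 * d)

        w_span, z_span = block.w_interval, block.z_interval
        gene_codons = rng.integers(
            max(10, mean_codons // 2), mean_codons + mean_codons // 2 + 1,
            size=n_pairs,
        )
        max_len = 3 * int(gene_codons.max())
        w_starts = np.linspace(w_span.start, max(w_span.start, w_span.end - max_len),
                               n_pairs).astype(np.int64)
        z_starts = np.linspace(z_span.start, max(z_span.start, z_span.end - max_len),
                               n_pairs).astype(np.int64)
        z_order = z_starts[::-1] if block.inverted else z_starts

        for j in range(n_pairs):
            n_codons = int(gene_codons[j])
            fam = rng.integers(0, len(FOURFOLD_PREFIXES), n_codons)
            third = rng.integers(0, 4, n_codons)
            w_codons = [FOURFOLD_PREFIXES[f] + BASES[t] for f, t in zip(fam, third)]

            # synonymous divergence: JC at the third position
            z_third = third.copy()
            hit = rng.random(n_codons) < p_syn
            shift = rng.integers(1, 4, n_codons)
            z_third[hit] = (third[hit] + shift[hit]) % 4
            z_codons = [FOURFOLD_PREFIXES[f] + BASES[t] for f, t in zip(fam, z_third)]

            # sparse nonsynonymous divergence at positions 1-2 (stop-rejected)
            for p_idx in (0, 1):
                hit_n = np.flatnonzero(rng.random(n_codons) < p_non)
                for ci in hit_n:
                    old = z_codons[ci]
                    new_base = BASES[
                        (BASES.index(old[p_idx]) + rng.integers(1, 4)) % 4
                    ]
                    cand = old[:p_idx] + new_base + old[p_idx + 1:]
                    if cand not in STOPS:
                        z_codons[ci] = cand

            w_gene = f"w_b{bi}_g{j:04d}"
            z_gene = f"z_b{bi}_g{j:04d}"
            anchors.append(
                AnchorPair(
                    w_gene=w_gene,
                    w_interval=GenomicInterval(
                        w_span.chrom, int(w_starts[j]), int(w_starts[j]) + 3 * n_codons - 1
                    ),
                    z_gene=z_gene,
                    z_interval=GenomicInterval(
                        z_span.chrom, int(z_order[j]), int(z_order[j]) + 3 * n_codons - 1
                    ),
                    strand_concordant=not block.inverted,
                    w_cds="".join(w_codons),
                    z_cds="".join(z_codons),
                )
            )
            truth.pair_divergence[w_gene] = d
    return anchors


# ---------------------------------------------------------------------------
# genetic map
# ---------------------------------------------------------------------------

def simulate_genetic_map(
    layout: ReferenceLayout, truth: TruthSet, config: SimulationConfig
) -> list[GeneticMapMarker]:
    """Markers whose cM grows ~linearly with bp on autosomes and plateaus
    (zero recombination) across the SDR on the ZW chromosome."""
    rng = _rng(config, 5)
    markers: list[GeneticMapMarker] = []
    for chrom, length in layout.chromosomes.items():
        pos = np.arange(config.marker_spacing, length + 1, config.marker_spacing)
        base_inc = config.cm_per_mb * config.marker_spacing / 1e6
        inc = base_inc * rng.gamma(20.0, 1.0 / 20.0, size=len(pos))
        if chrom == layout.zw_chromosome:
            in_sdr = (pos > truth.sdr.start) & (pos <= truth.sdr.end)
            inc[in_sdr] = 0.0
        cm = np.cumsum(inc)
        markers.extend(
            GeneticMapMarker("consensus", chrom, int(p), float(c))
            for p, c in zip(pos, cm)
        )
    return markers
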