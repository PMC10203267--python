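"""End-to-end orchestration of the three analyses with one config.

Each ``run_*_pipeline`` function validates its inputs up front, executes the
stage chain, writes its tables next to a JSON run report, and returns the
in-memory results. Everything is deterministic given the config (the only
randomness lives in the simulators, which are seeded).
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .genotypes import GenotypeMatrix
from .intervals import GenomicInterval
from .io_formats import (
    read_anchors,
    read_bedgraph,
    read_gff_genes,
    read_labels,
    read_markers,
    read_vcf,
    write_bed,
)
from .popgen_core import (
    fst_weir_cockerham,
    female_specific_snps,
    filter_variants,
    nucleotide_diversity,
    sex_association,
)
from .sdr_detect import (
    SdrCall,
    call_sdr,
    classify_windows,
    coverage_windows,
    detect_recomb_suppressed_chromosome,
    integrate_evidence,
)
from .sweep_scan import detect_sweeps, omega_statistic
from .synteny_strata import (
    MutationClock,
    assign_strata,
    build_collinear_blocks,
    detect_inversions,
    divergence_table,
    interval_report,
)


class InputError(ValueError):
    """Raised before any computation when a required input is missing/invalid."""


@dataclass
class PipelineConfig:
    """Paths and stage parameters; unspecified parameters keep the published
    defaults (50-kb/10-kb π windows, 20-kb Fst windows and ω grid, top 5% +
    4-kb flanks, −log10 P >= 10, top-1% Fst, mu = 7.5e-10)."""

    outdir: str = "zwscan_out"
    # inputs
    female_cov: str | None = None
    male_cov: str | None = None
    vcf: str | None = None
    labels: str | None = None
    genetic_map: str | None = None
    anchors: str | None = None
    cds: str | None = None
    gff: str | None = None
    # coverage / SDR
    coverage_window: int = 10_000
    min_total_depth: float = 10.0
    delta: float = 0.05
    min_run: int = 5
    max_gap: int = 1_000_000
    assoc_cut: float = 10.0
    fst_top: float = 0.01
    fst_window: int = 20_000
    # variant filters
    dp_min: float = 2
    dp_max: float = 40
    q_min: float = 20
    max_missing: float = 0.20
    maf_min: float = 0.05
    # strata
    mu: float = 7.5e-10
    min_block_anchors: int = 3
    max_rank_gap: int = 2
    # sweeps
    pi_window: int = 50_000
    pi_step: int = 10_000
    grid_size: int = 20_000
    top_q: float = 0.05
    flank: int = 4_000
    min_ratio: float = 2.0
    min_omega: float = 5.0
    max_snps_side: int = 25
    wild_group: str = "wild"
    cultivar_groups: tuple[str, ...] = ("Cultivar_I", "Cultivar_II", "Cultivar_III")
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {k: v for k, v in data.items() if k in cls.__dataclass_fields__}
        unknown = set(data) - set(known)
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**known)
        if isinstance(cfg.cultivar_groups, list):
            cfg.cultivar_groups = tuple(cfg.cultivar_groups)
        return cfg

    def hash(self) -> str:
        text = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(text.encode()).hexdigest()[:16]

    def require(self, *names: str) -> None:
        for name in names:
            value = getattr(self, name)
            if value is None:
                raise InputError(f"required input '{name}' not configured")
            if not Path(value).exists():
                raise InputError(f"input file for '{name}' not found: {value}")


def _report_base(config: PipelineConfig, stage: str) -> dict:
    return {
        "stage": stage,
        "version": __version__,
        "config_hash": config.hash(),
        "config": asdict(config),
    }


def _write_report(report: dict, outdir: Path, name: str) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / name, "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True, default=str)


def _chrom_lengths_from_track(track) -> dict[str, int]:
    lengths: dict[str, int] = {}
    for iv in track.intervals:
        lengths[iv.chrom] = max(lengths.get(iv.chrom, 0), iv.end)
    return lengths


def _sdr_call_dict(call: SdrCall) -> dict:
    return {
        "chrom": call.chrom,
        "interval": None
        if call.is_empty
        else {"start": call.interval.start, "end": call.interval.end},
        "span_mb": call.span_mb(),
        "divergent_runs": [
            {"start": r.start, "end": r.end} for r in call.divergent_runs
        ],
        "w_specific": [{"start": r.start, "end": r.end} for r in call.w_specific],
        "supports": call.supports,
        "support_count": call.support_count,
    }


# ---------------------------------------------------------------------------
# SDR pipeline
# ---------------------------------------------------------------------------

def run_sdr_pipeline(config: PipelineConfig) -> tuple[SdrCall, dict]:
    """coverage → classify → call_sdr → SNP evidence → integrate."""
    config.require("female_cov", "male_cov", "vcf", "labels")
    outdir = Path(config.outdir)

    female = read_bedgraph(config.female_cov)
    male = read_bedgraph(config.male_cov)
    cw = classify_windows(
        coverage_windows(female, male, config.coverage_window, config.min_total_depth),
        config.delta,
    )
    call = call_sdr(cw, min_run=config.min_run, max_gap=config.max_gap)

    gm = read_vcf(config.vcf, read_labels(config.labels))
    gm = filter_variants(
        gm, config.dp_min, config.dp_max, config.q_min, config.max_missing,
        config.maf_min,
    )
    chrom_lengths = _chrom_lengths_from_track(female)
    assoc = sex_association(gm)
    fst = fst_weir_cockerham(
        gm,
        gm.sample_mask(sex="F"),
        gm.sample_mask(sex="M"),
        chrom_lengths,
        window=config.fst_window,
        step=config.fst_window,
    )
    _, fem_blocks = female_specific_snps(gm)
    call = integrate_evidence(
        call, assoc, fst, fem_blocks, config.assoc_cut, config.fst_top
    )

    map_ranking = None
    if config.genetic_map and Path(config.genetic_map).exists():
        map_ranking = detect_recomb_suppressed_chromosome(read_markers(config.genetic_map))

    report = _report_base(config, "sdr")
    report.update(
        {
            "n_windows": int(len(cw)),
            "n_sites_after_filter": int(gm.n_sites),
            "n_female_specific_blocks": len(fem_blocks),
            "sdr_call": _sdr_call_dict(call),
            "map_ranking": None
            if map_ranking is None
            else map_ranking.to_dict(orient="records"),
        }
    )
    _write_report(report, outdir, "sdr_report.json")
    if not call.is_empty:
        write_bed(call.w_specific, outdir / "w_specific.bed")
    cw.to_csv(outdir / "coverage_windows.tsv", sep="\t", index=False)
    return call, report


# ---------------------------------------------------------------------------
# strata pipeline
# ---------------------------------------------------------------------------

def run_strata_pipeline(config: PipelineConfig) -> tuple[list, dict]:
    """anchors → collinear blocks → inversions → Ka/Ks → dating → strata."""
    config.require("anchors")
    outdir = Path(config.outdir)
    anchors = read_anchors(config.anchors, config.cds)
    if not anchors:
        raise InputError("anchor table is empty")

    blocks = build_collinear_blocks(
        anchors, config.min_block_anchors, config.max_rank_gap
    )
    inversions = detect_inversions(blocks)
    clock = MutationClock(config.mu)
    kaks = divergence_table(anchors, clock)
    times = dict(zip(kaks["w_gene"], kaks["T_years"]))
    strata = assign_strata(inversions, times)

    outdir.mkdir(parents=True, exist_ok=True)
    kaks.to_csv(outdir / "kaks.tsv", sep="\t", index=False)
    blocks_df = pd.DataFrame(
        {
            "orientation": [b.orientation for b in blocks],
            "w_chrom": [b.w_span.chrom for b in blocks],
            "w_start": [b.w_span.start for b in blocks],
            "w_end": [b.w_span.end for b in blocks],
            "z_chrom": [b.z_span.chrom for b in blocks],
            "z_start": [b.z_span.start for b in blocks],
            "z_end": [b.z_span.end for b in blocks],
            "n_anchors": [b.n_anchors for b in blocks],
        }
    )
    blocks_df.to_csv(outdir / "blocks.tsv", sep="\t", index=False)
    strata_table = [
        {
            "stratum": s.stratum_id,
            "median_t_mya": None if not np.isfinite(s.median_t) else s.median_t / 1e6,
            "n_pairs": len(s.times),
            "low_confidence": s.low_confidence,
            "w_span": {
                "chrom": s.block.w_span.chrom,
                "start": s.block.w_span.start,
                "end": s.block.w_span.end,
            },
        }
        for s in strata
    ]
    report = _report_base(config, "strata")
    report.update(
        {
            "n_anchors": len(anchors),
            "n_blocks": len(blocks),
            "n_inversions": len(inversions),
            "inversion_spans_mb": interval_report(
                [c.w_span for c in inversions]
            ).to_dict(orient="records"),
            "strata": strata_table,
        }
    )
    _write_report(report, outdir, "strata_report.json")
    with open(outdir / "strata.json", "w") as fh:
        json.dump(strata_table, fh, indent=1)
    return strata, report


# ---------------------------------------------------------------------------
# sweep pipeline
# ---------------------------------------------------------------------------

def run_sweep_pipeline(config: PipelineConfig) -> tuple[dict, dict]:
    """filter → per-group π → ratio → ω → top-5% → intersect/merge → genes.

    Runs once per cultivar subgroup; the report carries per-subgroup sweep
    tables and the cross-subgroup shared-gene counts (Venn table).
    """
    config.require("vcf", "labels")
    outdir = Path(config.outdir)
    gm = read_vcf(config.vcf, read_labels(config.labels))
    present = set(np.asarray(gm.subgroup))
    missing = [
        g for g in (config.wild_group, *config.cultivar_groups) if g not in present
    ]
    if missing:
        raise InputError(f"subgroups named in config absent from labels: {missing}")
    gm = filter_variants(
        gm, config.dp_min, config.dp_max, config.q_min, config.max_missing,
        config.maf_min,
    )
    chrom_lengths = {
        chrom: int(np.max(np.asarray(gm.pos)[np.asarray(gm.chrom) == chrom]))
        for chrom in set(np.asarray(gm.chrom))
    }
    genes = read_gff_genes(config.gff) if config.gff else None

    pi_wild = nucleotide_diversity(
        gm, chrom_lengths, config.pi_window, config.pi_step,
        gm.sample_mask(subgroup=config.wild_group),
    )
    results: dict[str, object] = {}
    gene_sets: dict[str, set[str]] = {}
    for group in config.cultivar_groups:
        pi_c = nucleotide_diversity(
            gm, chrom_lengths, config.pi_window, config.pi_step,
            gm.sample_mask(subgroup=group),
        )
        omega = omega_statistic(
            gm, group, chrom_lengths, config.grid_size, config.max_snps_side
        )
        res = detect_sweeps(
            pi_wild, pi_c, omega,
            q=config.top_q, flank=config.flank,
            min_ratio=config.min_ratio, min_omega=config.min_omega,
            genes=genes, chrom_lengths=chrom_lengths,
        )
        results[group] = res
        gene_sets[group] = set(g for r in res.regions for g in r.genes)

    # Venn-style shared-gene counts
    groups = list(config.cultivar_groups)
    venn: dict[str, int] = {g: len(gene_sets[g]) for g in groups}
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            venn[f"{groups[i]}&{groups[j]}"] = len(
                gene_sets[groups[i]] & gene_sets[groups[j]]
            )
    if len(groups) >= 3:
        shared = set.intersection(*(gene_sets[g] for g in groups))
        venn["&".join(groups)] = len(shared)

    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for group, res in results.items():
        for r in res.regions:
            rows.append(
                (
                    group, r.interval.chrom, r.interval.start, r.interval.end,
                    len(r.pi_support), len(r.omega_support), ";".join(r.genes),
                )
            )
    sweeps_df = pd.DataFrame(
        rows,
        columns=["subgroup", "chrom", "start", "end", "n_pi", "n_omega", "genes"],
    )
    sweeps_df.to_csv(outdir / "sweeps.tsv", sep="\t", index=False)
    all_regions = [r.interval for res in results.values() for r in res.regions]
    if all_regions:
        write_bed(all_regions, outdir / "sweeps.bed")

    report = _report_base(config, "sweeps")
    report.update(
        {
            "n_sites_after_filter": int(gm.n_sites),
            "per_subgroup": {
                g: {
                    "n_regions": len(res.regions),
                    "thresholds": res.thresholds,
                    "n_genes": len(gene_sets[g]),
                }
                for g, res in results.items()
            },
            "venn_gene_counts": venn,
        }
    )
    _write_report(report, outdir, "sweeps_report.json")
    return results, report
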