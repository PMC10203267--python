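"""Readers and writers for the standard formats the pipeline touches.

One convention everywhere: in-memory coordinates are 1-based inclusive
(:class:`~zwscan.intervals.GenomicInterval`); BED/bedGraph's 0-based
half-open coordinates are converted at this boundary.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genotypes import MISSING, GenotypeMatrix
from .intervals import GenomicInterval


# ---------------------------------------------------------------------------
# coverage tracks (bedGraph)
# ---------------------------------------------------------------------------

@dataclass
class CoverageTrack:
    """Ordered, non-overlapping depth intervals (mean read depth each)."""

    intervals: list[GenomicInterval]
    depth: np.ndarray

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=float)
        if len(self.intervals) != len(self.depth):
            raise ValueError("intervals and depth lengths differ")
        if np.any(self.depth < 0):
            raise ValueError("negative depth")
        order = sorted(
            range(len(self.intervals)),
            key=lambda i: (self.intervals[i].chrom, self.intervals[i].start),
        )
        self.intervals = [self.intervals[i] for i in order]
        self.depth = self.depth[order]
        prev: GenomicInterval | None = None
        for iv in self.intervals:
            if prev is not None and prev.chrom == iv.chrom and iv.start <= prev.end:
                raise ValueError(
                    f"overlapping coverage intervals on {iv.chrom}: "
                    f"{prev.start}-{prev.end} and {iv.start}-{iv.end}"
                )
            prev = iv

    def chromosomes(self) -> list[str]:
        seen: dict[str, None] = {}
        for iv in self.intervals:
            seen.setdefault(iv.chrom, None)
        return list(seen)


def read_bedgraph(path: str | os.PathLike) -> CoverageTrack:
    """Read a bedGraph (0-based half-open) into a 1-based CoverageTrack."""
    intervals: list[GenomicInterval] = []
    depths: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 bedGraph columns")
            chrom, start0, end0, depth = parts[0], parts[1], parts[2], parts[3]
            try:
                iv = GenomicInterval(chrom, int(start0) + 1, int(end0))
                depths.append(float(depth))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            intervals.append(iv)
    return CoverageTrack(intervals, np.asarray(depths, dtype=float))


def write_bedgraph(track: CoverageTrack, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for iv, d in zip(track.intervals, track.depth):
            fh.write(f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\t{d:g}\n")


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def write_bed(regions: Sequence[GenomicInterval], path: str | os.PathLike,
              names: Sequence[str] | None = None) -> None:
    """Write intervals as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for i, iv in enumerate(regions):
            start0, end0 = iv.start - 1, iv.end
            if end0 <= start0:  # cannot happen for a valid GenomicInterval
                raise ValueError(f"empty BED span for {iv}")
            if names is not None:
                fh.write(f"{iv.chrom}\t{start0}\t{end0}\t{names[i]}\n")
            else:
                fh.write(f"{iv.chrom}\t{start0}\t{end0}\n")


def read_bed(path: str | os.PathLike) -> list[GenomicInterval]:
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 BED columns")
            out.append(GenomicInterval(parts[0], int(parts[1]) + 1, int(parts[2])))
    return out


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | os.PathLike) -> list[tuple[str, str]]:
    """Read FASTA records as (id, sequence) preserving case."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append((rec.id, str(rec.seq)))
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | os.PathLike) -> None:
    seqs = [SeqRecord(Seq(s), id=name, description="") for name, s in records]
    SeqIO.write(seqs, str(path), "fasta")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: str | os.PathLike, sample_labels: pd.DataFrame) -> GenotypeMatrix:
    """Read a VCF 4.x into a GenotypeMatrix.

    ``sample_labels`` needs columns sample/sex/subgroup; every labelled sample
    must be present in the VCF. Multi-allelic ALTs are split into bi-allelic
    records; dosage is the count of that alt allele, ``./.`` -> missing.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=False)
    vcf_samples = list(vcf.samples)
    labels = sample_labels.set_index("sample")
    missing_samples = [s for s in labels.index if s not in vcf_samples]
    if missing_samples:
        raise ValueError(f"samples in labels absent from VCF: {missing_samples}")

    sample_idx = {s: i for i, s in enumerate(vcf_samples)}
    keep = [s for s in vcf_samples if s in labels.index]
    keep_idx = np.array([sample_idx[s] for s in keep], dtype=int)

    chroms, poss, refs, alts, dps, quals, rows = [], [], [], [], [], [], []
    for var in vcf:
        gt = np.asarray(var.genotype.array())  # (n_samples, ploidy+1)
        a1, a2 = gt[:, 0], gt[:, 1]
        for alt_i, alt in enumerate(var.ALT, start=1):
            dos = np.where(
                (a1 < 0) | (a2 < 0),
                MISSING,
                (a1 == alt_i).astype(np.int8) + (a2 == alt_i).astype(np.int8),
            ).astype(np.int8)
            chroms.append(var.CHROM)
            poss.append(var.POS)
            refs.append(var.REF)
            alts.append(alt)
            dp = var.INFO.get("DP")
            dps.append(float(dp) if dp is not None else np.nan)
            quals.append(var.QUAL if var.QUAL is not None else np.nan)
            rows.append(dos[keep_idx])

    dosage = (
        np.asarray(rows, dtype=np.int8).T
        if rows
        else np.zeros((len(keep), 0), dtype=np.int8)
    )
    return GenotypeMatrix(
        samples=keep,
        sex=labels.loc[keep, "sex"].to_numpy(),
        subgroup=labels.loc[keep, "subgroup"].to_numpy(),
        chrom=np.asarray(chroms, dtype=object),
        pos=np.asarray(poss, dtype=np.int64),
        ref=np.asarray(refs, dtype=object),
        alt=np.asarray(alts, dtype=object),
        dp=np.asarray(dps, dtype=float),
        qual=np.asarray(quals, dtype=float),
        dosage=dosage,
    )


def write_vcf(gm: GenotypeMatrix, path: str | os.PathLike,
              contig_lengths: dict[str, int] | None = None) -> None:
    """Serialize a GenotypeMatrix as a minimal diploid VCF 4.2 file."""
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Total depth">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if contig_lengths:
            for chrom, length in contig_lengths.items():
                fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.samples)
            + "\n"
        )
        for j in range(gm.n_sites):
            qual = gm.qual[j]
            qual_s = f"{qual:g}" if np.isfinite(qual) else "."
            dp = gm.dp[j]
            info = f"DP={int(dp)}" if np.isfinite(dp) else "."
            gts = "\t".join(gt_map[int(d)] for d in gm.dosage[:, j])
            fh.write(
                f"{gm.chrom[j]}\t{gm.pos[j]}\t.\t{gm.ref[j]}\t{gm.alt[j]}\t"
                f"{qual_s}\tPASS\t{info}\tGT\t{gts}\n"
            )


def read_labels(path: str | os.PathLike) -> pd.DataFrame:
    """Read a sample-label TSV with columns sample, sex, subgroup."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample", "sex", "subgroup"}
    if not required <= set(df.columns):
        raise ValueError(f"label table must have columns {sorted(required)}")
    return df


# ---------------------------------------------------------------------------
# pairwise hit tables (12-column blast-style tabular)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HitRecord:
    query: str
    subject: str
    identity: float           # percent, 0-100
    matching_bp: int          # aligned length in bp
    query_interval: GenomicInterval | None = None
    subject_interval: GenomicInterval | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity <= 100.0:
            raise ValueError(f"identity {self.identity} outside [0, 100]")
        if self.matching_bp < 1:
            raise ValueError("matching_bp must be >= 1")


def read_hits(path: str | os.PathLike) -> list[HitRecord]:
    """Read a 12-column tabular hit file (qseqid sseqid pident length ...)."""
    out: list[HitRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 12:
                raise ValueError(f"{path}:{lineno}: expected 12 columns, got {len(parts)}")
            try:
                pident = float(parts[2])
                length = int(float(parts[3]))
                qs, qe = int(parts[6]), int(parts[7])
                ss, se = int(parts[8]), int(parts[9])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric field: {exc}") from exc
            out.append(
                HitRecord(
                    parts[0],
                    parts[1],
                    pident,
                    length,
                    GenomicInterval(parts[0], min(qs, qe), max(qs, qe)),
                    GenomicInterval(parts[1], min(ss, se), max(ss, se)),
                )
            )
    return out


# ---------------------------------------------------------------------------
# genetic map markers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneticMapMarker:
    map_id: str
    chrom: str
    pos_bp: int
    pos_cm: float

    def __post_init__(self) -> None:
        if self.pos_cm < 0:
            raise ValueError("cM must be >= 0")


def read_markers(path: str | os.PathLike) -> list[GeneticMapMarker]:
    df = pd.read_csv(path, sep="\t")
    required = {"map_id", "chrom", "pos_bp", "pos_cm"}
    if not required <= set(df.columns):
        raise ValueError(f"marker table must have columns {sorted(required)}")
    return [
        GeneticMapMarker(str(r.map_id), str(r.chrom), int(r.pos_bp), float(r.pos_cm))
        for r in df.itertuples()
    ]


def write_markers(markers: Sequence[GeneticMapMarker], path: str | os.PathLike) -> None:
    pd.DataFrame(
        {
            "map_id": [m.map_id for m in markers],
            "chrom": [m.chrom for m in markers],
            "pos_bp": [m.pos_bp for m in markers],
            "pos_cm": [m.pos_cm for m in markers],
        }
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# anchors (W-Z gene pairs) and GFF3 genes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnchorPair:
    """A W-Z homologous gene pair, optionally with aligned CDS sequences."""

    w_gene: str
    w_interval: GenomicInterval
    z_gene: str
    z_interval: GenomicInterval
    strand_concordant: bool = True
    w_cds: str | None = None
    z_cds: str | None = None

    def __post_init__(self) -> None:
        if self.w_cds is not None and self.z_cds is not None:
            if len(self.w_cds) != len(self.z_cds):
                raise ValueError("paired CDS lengths differ")
            if len(self.w_cds) % 3 != 0:
                raise ValueError("CDS length not a multiple of 3")


def read_anchors(path: str | os.PathLike,
                 cds_fasta: str | os.PathLike | None = None) -> list[AnchorPair]:
    """Read anchors.tsv (w_gene, w_chrom, w_start, w_end, z_gene, z_chrom,
    z_start, z_end[, strand]) plus optional paired CDS FASTA keyed by gene id."""
    df = pd.read_csv(path, sep="\t")
    cds: dict[str, str] = {}
    if cds_fasta is not None:
        cds = dict(read_fasta(cds_fasta))
    out = []
    for r in df.itertuples():
        out.append(
            AnchorPair(
                w_gene=str(r.w_gene),
                w_interval=GenomicInterval(str(r.w_chrom), int(r.w_start), int(r.w_end)),
                z_gene=str(r.z_gene),
                z_interval=GenomicInterval(str(r.z_chrom), int(r.z_start), int(r.z_end)),
                strand_concordant=bool(getattr(r, "strand", 1)),
                w_cds=cds.get(str(r.w_gene)),
                z_cds=cds.get(str(r.z_gene)),
            )
        )
    return out


def write_anchors(anchors: Sequence[AnchorPair], path: str | os.PathLike,
                  cds_fasta: str | os.PathLike | None = None) -> None:
    pd.DataFrame(
        {
            "w_gene": [a.w_gene for a in anchors],
            "w_chrom": [a.w_interval.chrom for a in anchors],
            "w_start": [a.w_interval.start for a in anchors],
            "w_end": [a.w_interval.end for a in anchors],
            "z_gene": [a.z_gene for a in anchors],
            "z_chrom": [a.z_interval.chrom for a in anchors],
            "z_start": [a.z_interval.start for a in anchors],
            "z_end": [a.z_interval.end for a in anchors],
            "strand": [int(a.strand_concordant) for a in anchors],
        }
    ).to_csv(path, sep="\t", index=False)
    if cds_fasta is not None:
        recs = []
        for a in anchors:
            if a.w_cds is not None and a.z_cds is not None:
                recs.append((a.w_gene, a.w_cds))
                recs.append((a.z_gene, a.z_cds))
        write_fasta(recs, cds_fasta)


def read_gff_genes(path: str | os.PathLike) -> dict[str, GenomicInterval]:
    """Gene features from a GFF3 file, as {gene_id: interval}."""
    genes: dict[str, GenomicInterval] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9 or parts[2] != "gene":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
            )
            gid = attrs.get("ID", f"{parts[0]}:{parts[3]}-{parts[4]}")
            genes[gid] = GenomicInterval(parts[0], int(parts[3]), int(parts[4]))
    return genes


def write_gff_genes(genes: dict[str, GenomicInterval], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gid, iv in sorted(genes.items(), key=lambda kv: (kv[1].chrom, kv[1].start)):
            fh.write(
                f"{iv.chrom}\tzwscan\tgene\t{iv.start}\t{iv.end}\t.\t+\t.\tID={gid}\n"
            )
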