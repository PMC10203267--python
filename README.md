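# zwscan

Tools for three linked questions about a female-heterogametic (ZW) plant
genome, of the kind raised by a dioecious tree crop with a young sex
chromosome and a recent domestication history:

1. **Where is the sex-determination region (SDR)?** From pooled female and
   male resequencing depth over a female (ZW) reference, windows are
   classified by the female share of depth F/(F+M): W-specific sequence has
   no male reads (F/(F+M) → 1), Z-specific sequence doubles male depth
   (F/(F+M) → 1/3), and the SDR is the envelope of the divergent runs. The
   call is cross-checked against per-site sex association (allelic
   chi-square), windowed Weir–Cockerham Fst between the sexes (top-1%
   cutoff), and blocks of female-specific SNPs, plus a genetic-map
   diagnostic for recombination suppression.
2. **When did the W stop recombining?** W–Z gene pairs are chained into
   collinear and inverted blocks by monotone runs of Z rank; per pair,
   synonymous divergence Ks (and Ka) is estimated by the Nei–Gojobori
   counting method with Jukes–Cantor correction, and dated by the molecular
   clock T = Ksil/(2µ), µ = 7.5×10⁻¹⁰ per site per year. Each inversion is
   an evolutionary stratum summarized by the median pair age.
3. **What was swept during domestication?** Diversity loss
   (π_wild/π_cultivar in 50-kb/10-kb sliding windows) and the LD ω
   statistic on a 20-kb grid are scanned per cultivar subgroup; sweep
   regions are the merged intersections of the top-5% outliers of both
   statistics (4-kb flanks), annotated with overlapping genes.

Every analysis is exercisable without external data: `zwscan simulate`
generates pooled coverage tracks, sex and population VCF panels, W–Z CDS
anchor pairs, and genetic maps with planted SDR/inversion/sweep structure
plus a JSON truth set, so each detector is tested by parameter recovery.
See `docs/methods.md` for models, assumptions, and limitations.

## Worked example

Simulate a scaled-down ZW genome (5.5-Mb sex chromosome with a 3-Mb SDR,
three inversions aged 8.18/3.80/3.47 Mya, four W-specific segments; one
2-Mb autosome), then run the SDR and strata pipelines:

```bash
zwscan simulate --config sim.yaml --outdir fixtures/
zwscan sdr --female-cov fixtures/pool_female.bedGraph \
           --male-cov fixtures/pool_male.bedGraph \
           --vcf fixtures/sex_panel.vcf --labels fixtures/sex_labels.tsv \
           --map fixtures/map.tsv --assoc-cut 7 --outdir out/
# {"chrom": "Chr14", "span_mb": 3.0, "support": 3}
zwscan strata --anchors fixtures/anchors.tsv \
              --cds fixtures/cds_pairs.fasta --outdir out/
# [{"stratum": 1, "median_t_mya": 8.25, "n_pairs": 30, ...},
#  {"stratum": 2, "median_t_mya": 4.25, "n_pairs": 30, ...},
#  {"stratum": 3, "median_t_mya": 3.75, "n_pairs": 20, ...}]
```

The SDR line says the sex chromosome is Chr14, the called span is 3.0 Mb
(the planted truth), and all three SNP evidence layers overlap the call
(`support: 3`; the association layer is thresholded at −log10 P ≥ 7 here
because the exact allelic test caps near 7.2 for a fully penetrant
W-linked site in a 22♀/22♂ panel — see the methods note). The strata table
recovers the planted age ordering — oldest stratum ≈ 8.25 Mya against a
planted 8.18 — with the younger strata within the sampling error of a
median over 20–30 gene pairs; `out/kaks.tsv` holds the per-pair Ks/Ka and
dated ages behind the medians. `zwscan sweeps` runs the third analysis the
same way and writes `sweeps.tsv`/`sweeps.bed` plus a JSON report with the
realized outlier thresholds.

The library API mirrors the CLI (`zwscan.sdr_detect`,
`zwscan.synteny_strata`, `zwscan.sweep_scan`, `zwscan.popgen_core`,
`zwscan.synthetic_data`); the pipelines in `zwscan.pipeline` are thin
orchestration over it.

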