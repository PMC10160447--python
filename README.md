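# bsamap

Bulked-segregant mapping of a single dominant locus, end to end and fully
synthetic.  `bsamap` is built for the classic crop-genetics workflow in
which a qualitative trait — here the running example is yellow versus
green fruit peel in zucchini (*Cucurbita pepo*) — is mapped by (i) a
Mendelian segregation test in F2/BC1 populations, (ii) pooled
re-sequencing of phenotypically extreme bulks (BSA-seq / QTL-seq), and
(iii) fine mapping with co-dominant markers genotyped on recombinants.
Because such studies rarely deposit raw reads, the package ships a
cross-and-pooled-sequencing simulator with the statistical structure the
analysis assumes, so every stage is testable without downloads.

## What it computes

**SNP-index and ΔSNP-index.** At a biallelic site where the two inbred
parents are fixed for opposite alleles, the SNP-index of a bulk is the
fraction of its reads carrying a chosen allele,

    SNP-index = alt reads / total reads,     Δ = index(G_pool) − index(Y_pool).

With the yellow parent as the reference, the green (recessive) bulk is
fixed for the alternate allele near the causal locus (index → 1), the
yellow bulk sits near 1/3 (its plants are 1/3 homozygous : 2/3
heterozygous), so Δ → 2/3 there and ≈ 0 at unlinked sites.  Sliding
1 Mb / 100 kb window means are thresholded (index > 0.875 and Δ > 0.5,
strict) to call candidate regions.

**Segregation tests.** Pearson χ² (df = 1, no continuity correction)
against 3:1 (F2) or 1:1 (BC1) yellow:green expectations, with the
upper-tail P from the χ²(1) distribution.

**Fine mapping.** Given ordered co-dominant marker calls
(A/H/B/missing) and phenotypes for recombinant plants, the causal
interval is the intersection of phenotype-compatible positions across
plants (green ⇒ A; yellow F2 ⇒ H or B; yellow BC1 ⇒ H), reported with
its innermost flanking markers.  Helpers select gel-resolvable InDel
markers inside a region and score marker–phenotype concordance in a
germplasm panel.

**Pigments and colour.** Chlorophyll a/b and carotenoid content from
extract absorbances (C_a = 13.96·D665 − 6.88·D649, C_b = 24.96·D649 −
7.32·D665, C_x.c = (1000·D470 − 2.05·C_a − 114.8·C_b)/245) and the
colour index CCI = 1000·a\*/(L\*·b\*) from CIELAB readings.

## Worked example

Test the published-style phenotype counts against Mendelian ratios:

```text
$ bsamap segtest --yellow 443 --green 180
chi2=5.0342 df=1 p=0.0249 -> rejected (3:1)
$ bsamap segtest --yellow 35 --green 36 --ratio 1:1
chi2=0.0141 df=1 p=0.9055 -> fits (1:1)
```

Run the whole synthetic study (simulate an F2 of 623 plants and a BC1 of
71, build 33-plant bulks, sequence them at 30×, call the region,
fine-map it):

```text
$ bsamap run-all --seed 7 --out demo/
...
"candidate_regions": [{"chrom": "LG10", "start": 1, "end": 5000000,
                       "mean_index_G": 0.963254, "mean_delta": 0.58932}],
"mapped_interval": {"chrom": "LG10", "start": 2272728, "end": 2727273,
                    "left_marker": "M06", "right_marker": "M07",
                    "length_kb": 454.545}
```

The candidate region (windowed index of the green bulk > 0.875 and
Δ > 0.5) covers the simulated causal chromosome, and recombinant-based
narrowing boxes the simulated locus (truth: LG10:2,500,000) between
markers M06 and M07.  `demo/` also receives the simulated VCF, per-site
and windowed index tracks (TSV), the candidate regions as BED
(0-based half-open) and the recombinant marker table.

The library mirrors the CLI: `bsamap.simcross` (crosses, bulks, pooled
reads), `bsamap.variantio` (VCF ingestion and informative-site
filtering), `bsamap.bsaindex` (index tracks, windows, region calls),
`bsamap.segregation`, `bsamap.finemap`, `bsamap.pigment`, and
`bsamap.pipeline` (the orchestrated run).

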