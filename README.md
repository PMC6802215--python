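# relocus

Prioritization of target genes and functional non-coding variants at GWAS
risk loci, with atrial fibrillation-style atrial data as the model system.

Most disease-associated variants found by genome-wide association studies
fall in non-coding DNA, where they are thought to perturb regulatory
elements (REs) — enhancers and promoters — and thereby the expression of
nearby genes. Which gene, and which of the hundreds of associated variants,
is rarely obvious. `relocus` implements a complete, testable pipeline that
answers both questions from standard genomic evidence:

1. **Variant regions.** From summary statistics, each locus is built as a
   genome-wide-significant core (p < 1e-8), extended outward to the last
   flanking variant with p < 1e-6, and populated with all subthreshold
   member variants (p < 1e-4) inside the extended span.
2. **Gene scoring.** Every gene with a TSS within 1.9 Mb of the lead SNP
   receives a weighted evidence score

   `S = 2·TAD + 3·PCHiC + Σ_{d=1..5} expr_d + 4·eQTL`

   where TAD ∈ {0,1} is shared-TAD membership, PCHiC ∈ [0,1] is
   promoter-capture contact with the variant region, expr_d ∈ {0,1,2} is
   the expression category in each of five atrial RNA-seq datasets
   (adult LA, adult RA, adult LA cardiomyocytes, fetal LA, fetal RA;
   0 = below the dataset median, 1 = expressed, 2 = at/above the third
   quartile), and eQTL ∈ {0,1,2} counts supporting eQTL studies. The
   maximum is 23; genes scoring ≥ 11 — the smallest integer that cannot be
   reached by expression alone (max 10) — are candidate target genes.
3. **Enhancer prediction.** An EMERGE-style model: epigenomic signal
   tracks (ATAC-seq, histone ChIP-seq, ...) are integrated by L2-penalized
   logistic regression trained on a curated catalogue of validated heart
   enhancers, and peaks are called wherever the prediction read-out
   strictly exceeds 0.05, at single-bp resolution.
4. **Variant shortlists.** Each member variant is annotated with ATAC and
   enhancer-prediction tag-counts, promoter membership (−1500/+500 bp of a
   TSS, strand-oriented), allele-specific PWM motif-disruption scores, and
   contact-linked candidate genes, then rolled up into nested tiers down to
   the strongest class: motif-disrupting variants in open chromatin that
   contact a candidate gene's promoter.

A first-class synthetic-data module generates a miniature genome (2 × 10 Mb
by default) with planted leads, enhancers, target genes and motif-altering
alleles, plus a ground-truth manifest, so the whole pipeline runs and is
validated without any external download.

## Worked example

```sh
cat > example.cfg <<'EOF'
seed = 7
out_dir = example_out
sim.n_chromosomes = 1
sim.n_loci = 4
sim.n_genes = 100
EOF
relocus run-all --config example.cfg
```

which logs each stage and its record counts:

```
INFO relocus: [simulate] files=20
INFO relocus: [regions] variants=3492, regions=4, members=164
INFO relocus: [categorize-expression] genes=100
INFO relocus: [score-genes] scored=133, candidates=12
INFO relocus: [train-emerge] positives=12, negatives=120, auroc_milli=1000
INFO relocus: [predict] chroms=1
INFO relocus: [call-peaks] emerge=12, atac=12
INFO relocus: [annotate-variants] variants=164
INFO relocus: [shortlist] T_RE_both=14, T_RE_any=14, T_promoter=0, T_linked=14, T_motif_open=8, T_motif_linked=8
```

All 4 simulated loci are recovered as variant regions with 164 subthreshold
member variants; 12 of 133 scored locus-gene pairs pass the candidate
threshold of 11 (the 4 planted target genes among them); the enhancer model
reaches training AUROC 1.000 and its peaks recover the 12 planted
enhancers. The tier summary (`example_out/tier_summary.tsv`):

```
tier	count	percent
T_RE_both	14	8.5366
T_RE_any	14	8.5366
T_promoter	0	0.0000
T_linked	14	8.5366
T_motif_open	8	4.8780
T_motif_linked	8	4.8780
```

14 of the 164 member variants (8.5%) fall in a predicted RE by both
evidence streams, and the 8 variants in the strictest tier — inside an
ATAC peak, disrupting a TF binding motif, and contacted to a candidate
gene — are exactly the 8 planted functional variants (2 per locus).

The first rows of `example_out/gene_scores.tsv` (selected columns):

```
locus_id  gene_id  tad  contact  eqtl  total  candidate
L001      RPL32    0    0        0     10     False
L001      G0002    0    0        0     2      False
L001      G0003    0    0        0     9      False
```

Note the reference gene RPL32: highly expressed everywhere (score 10), yet
correctly rejected as a candidate because it has no conformation or eQTL
evidence — this is precisely what the ≥ 11 threshold is for.

Each stage is also exposed individually (`relocus simulate`, `regions`,
`categorize-expression`, `score-genes`, `train-emerge`, `predict`,
`call-peaks`, `annotate-variants`, `shortlist`), reading and writing plain
BED / bedGraph / BEDPE / JASPAR-PFM / FASTA / TSV files, so any stage can be
re-run from on-disk artifacts or fed external data.

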