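# Methods

This note records the models, conventions and numerical choices behind
`relocus`, and what the synthetic-data tests do and do not demonstrate.

## Coordinates and formats

All internal coordinates are 0-based half-open; the only 1-based surface is
the `pos` field of variants (summary-statistics convention) and report
output, converted exactly once at the parser boundary. Chromosome names
pass through verbatim — there is no `chr` normalization; inputs whose
chromosome name sets share nothing raise an explicit error instead of
silently producing empty intersections. bedGraph values are written with 6
significant digits, and contiguous equal-value runs are merged on write;
per-base signal is preserved exactly at that precision.

## Variant regions

A region is a maximal cluster of genome-wide-significant variants
(p < 1e-8) in which consecutive significant variants are ≤ 1 Mb apart. The
1 Mb gap is this package's rule: published locus lists are usually taken as
given, so a generic clustering rule is needed for arbitrary input, and 1 Mb
matches the typical TAD scale at which regulation is confined. Boundary
extension is chained: any variant with p < 1e-6 within the gap distance of
the current boundary moves the boundary to itself, which may pull further
variants into reach; a side with no qualifying variant keeps its core
boundary. All three thresholds are strict `<`, and membership (p < 1e-4)
is inclusive at both extended boundary positions. Construction is verified
against an O(n²) transitive-closure clustering oracle and a full-rescan
extension oracle on random instances.

## Expression normalization and categorization

Each dataset's samples are scaled by a reference-gene size factor: the
geometric mean of the reference-gene counts in that sample (geometric so a
single outlying reference cannot dominate), rescaled so factors average 1.
Note a consequence: multiplying one sample's column by a constant is
absorbed into its factor, but the mean-1 rescaling spreads a global
constant over all samples — normalized values are invariant only up to
that constant. This is harmless because categorization is quantile-based
and therefore invariant under any positive affine rescaling.

Per-gene summaries (mean of normalized values across samples) are binned
per dataset at the median and third quartile computed over **all** genes in
the annotation, including silent ones — restricting to expressed genes
would make category 0 vacuous. Quantiles use linear interpolation between
order statistics (the numpy default); this is fixed and documented because
category flips at the boundaries depend on it. Values exactly at a
threshold take the higher category ("reaching the boundary counts as
expression"). An optional expression floor (`min_value`) zeroes summaries
below a cutoff before binning; it is off by default because the scoring
procedure defines categories directly from the quantiles.

## Gene scoring

The candidate window is ±1.9 Mb around the lead SNP (the documented reach
of long-range RE-promoter contacts), inclusive at both edges; 1 Mb appears
in some descriptions of the same procedure and is available via
`window_bp`. Genes are assigned to windows and TADs by their TSS, not the
gene body, because regulatory input arrives at the promoter; any-overlap
assignment would let long genes straddle loci they are not regulated from.
TAD intervals are half-open, which resolves boundary bases deterministically.

Contact evidence defaults to binary (a qualifying promoter contact was
observed or not); continuous mode instead takes the maximum contact score
in [0,1] for the literal signal-strength reading. A contact qualifies if
one anchor overlaps the region's extended interval and the record either
carries the gene's id or its other anchor overlaps the gene's promoter
window. eQTL evidence counts distinct studies (capped at 2) whose variant
lies inside the extended region; requiring lead status or LD with the lead
is not possible from the record format consumed here, so containment in
the region is the operative definition.

The candidate rule is `total ≥ 11`. The stated rationale — exclude genes
whose only evidence is expression, which tops out at 10 — is satisfied by
`≥`, and expressed genes contacted from outside their TAD (2 + 3 + ... can
total exactly 11) are deliberately included. A strict-`>` flag exists for
the alternative reading. Genes reached by several loci are reported once,
at their maximum score.

## Enhancer model

Training positives are the curated catalogue (flagged misannotated and
outflow-tract entries removed). Negatives are not part of the published
recipe; here they are random genome-wide intervals of the median positive
width, excluding positives, at a 10:1 ratio, drawn from a seeded generator
and documented prominently — AUROC values depend on this choice.
Features are coverage-weighted mean track signals per interval
(uncovered bases count 0), z-scored over the training rows so coefficients
are comparable across tracks of different dynamic range (raw mode
available). The fit is an L2-penalized logistic regression
(regularization strength 0.01, i.e. C = 100) — small enough not to distort
weights, large enough to keep near-separable desk-scale fits deterministic.
Continuous track means are used as features; binarized variants of the
same idea exist, but continuous means preserve amplitude information.

Prediction is emitted as a run-length track binned at `bin_bp` (default 10
for tractability; `bin_bp = 1` gives the exact single-bp read-out and is
used in conformance tests). Peaks are maximal runs with prediction
strictly above the absolute cutoff 0.05 — "absolute" meaning a fixed
probability cutoff, not a rank cutoff — so a base exactly at 0.05 breaks a
run. Held-out AUROC is the rank-based Mann–Whitney statistic with ties
averaged; an independent pair-counting oracle and scikit-learn's
implementation cross-check it in tests.

## Variant annotation and tiers

Tag-counts are point queries at the variant's single base (default: max
value of containing peaks; a signal mode reads the track directly), since
per-variant read-out is defined at SNP positions, not windows. Promoter
windows are −1500/+500 bp of the TSS, strand-oriented and inclusive at
both ends; a variant may lie in several genes' promoters and all are
reported. Motif disruption substitutes each allele at the variant base and
scores every PWM placement covering it on both strands with log2 odds
against the background (pseudocount 0.5 per cell before normalization); a
hit requires either allele's maximum to reach 80% of the PWM's maximum
score — a fraction-of-maximum rule because no universal motif-calling
cutoff exists; `delta = best_alt − best_ref` measures creation (+) or
disruption (−) of the site. The scanner equals an exhaustive
offset × strand × allele enumeration oracle on short PWMs.

Tier definitions: `T_RE_both` = ATAC ∧ prediction signal; `T_RE_any` =
either; `T_promoter` = `T_RE_any` ∩ promoter; `T_linked` = `T_RE_any` with
≥1 contacted candidate gene ("lies in a potential RE" uses the
either-stream parent set); `T_motif_open` = motif hit ∧ ATAC;
`T_motif_linked` = `T_motif_open` with a linked candidate. The subset
chain among these is asserted on every run.

## Synthetic data

The generator emulates the statistical structure the pipeline assumes, at
desk scale: 2 chromosomes × 10 Mb, TADs partitioning each chromosome
(mean 1 Mb), 400 genes with uniform TSS placement, 8 loci with leads
spread ≥ ~2 Mb apart. Association p-values follow
−log10 p ≈ peak · exp(−d/20 kb) + noise around each lead, with lead
exponents drawn from U(15, 30) — strong leads are typical of large
arrhythmia GWAS — plus a uniform non-associated background; no explicit LD
matrix is simulated because the pipeline consumes only p-values, so any
monotone decay exercises it. Three planted enhancers per locus
(300–800 bp, within 15 kb of the lead, clear of promoters) add amplitude
plateaus to the three informative tracks; two tracks are pure noise to
exercise logistic down-weighting. Two functional variants per locus sit at
enhancer midpoints: the planted TF motif consensus is written into the
genome with the variant's reference allele breaking one position and the
alternate allele restoring it, mirroring the minor-allele-creates-a-site
mechanism. Expression counts are negative binomial (dispersion 0.3) with
per-gene strata (25% silent, 50% medium, 25% high) shared across the five
datasets up to fold jitter, so categories correlate across datasets;
reference genes get high stable means with dispersion 0.01 — stability is
the property housekeeping references are selected for. Each enhancer
contacts its target's promoter; decoys gain contacts at a 10%
false-positive rate; 35% of loci (the observed fraction of eQTL-supported
loci in atrial studies of this kind) carry 1–2 eQTL study records.

What passing recovery tests show: the pipeline's logic correctly
propagates each kind of planted evidence to the right gene and variant
under realistic noise. What they do not show: performance under real LD
structure, overlapping loci, cell-type-mixed expression, assay-specific
track artifacts, or enhancer catalogues with label noise — the synthetic
world's evidence channels are conditionally independent given the truth,
which real data are not.

## Determinism and problem sizes

Every stochastic step flows from one `numpy` Generator seeded from the
config, and all writers use fixed float formats, so a fixed seed gives a
byte-identical bundle and byte-identical end-to-end outputs (asserted in
tests). The test suite runs the full default bundle once (a few seconds)
and uses reduced instances (1 chromosome × 2 Mb) for per-stage checks;
problem sizes were chosen so the entire suite completes in well under a
minute on one CPU while keeping every planted-structure recovery
statistically unambiguous.

## Known limitations

- Contact records are consumed as given; no raw Hi-C/PCHi-C processing,
  and no distance-dependent background model for contacts.
- eQTL evidence cannot distinguish lead/LD relationships from mere
  positional containment in the region.
- The enhancer model is linear in track means; it cannot represent
  combinatorial track logic.
- Differential expression, motif enrichment, footprinting and GO analysis
  are out of scope by design.
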