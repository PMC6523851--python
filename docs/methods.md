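# Methods

## Problem setting

The package analyses paired observations of a gut microbial community
(16S rRNA OTU counts) and the host transcriptome (log2 expression) across
treatment arms, asking which metabolic functions change, in which
direction, and which taxa and transcripts drive each change. KEGG
orthologies are the common coordinate system: microbial KO abundance is
inferred from the OTU table, host genes are mapped to KOs through a static
mapping file, and pathway enrichment is scored on each omic and on their
union. Default group labels (NOCIA, CIA, MS, MTXMS) and the four default
contrasts mirror a four-arm arthritis-therapy design — a healthy control,
an induced-arthritis arm, and two therapy arms — but are purely labels:
any ≥2-group design with ≥2 samples per contrasted group works.

## KO inference

Copy-number normalisation divides OTU counts by the per-genome 16S rRNA
gene copy number, correcting the systematic over-counting of taxa with
multiple ribosomal operons. KO abundance is the bilinear projection
`KO(k, s) = Σ_o norm(o, s) · content(o, k)`; each summand is retained as a
contribution record `(o, k, s)`, which is what later allows an enriched
pathway to be attributed to taxa. The invariant `Σ_o contribution = KO
abundance` holds to 1e−9 relative and is enforced by tests.

Predicted abundances are kept as reals. Some legacy inference tools round
to integers; `round_predictions=True` reproduces that, at the cost of the
conservation invariant (contribution records always keep the raw
summands). Rounding discards information before the differential stage,
so it is off by default. No prediction-confidence score (such as NSTI) is
computed: the pipeline consumes whatever gene-content table it is given.

Pathway collapse sums member-KO abundances; a KO annotated to several
pathways contributes its full abundance to each (the standard behaviour
of gene-content categorisation tools — pathway abundances are therefore
not additive across pathways). Genus aggregation parses Greengenes-style
7-rank strings; an empty `g__` field yields `unclassified_<lowest named
rank>` so that no counts are silently dropped (column sums are preserved).

## Differential analysis

One engine serves all four feature spaces. For count-scale tables:

* log2-cpm: `y = log2((c + 0.5)/(L + 1) · 10⁶)`, `L` = library size.
* A group-means model is fit per feature; LOWESS (span 0.5, 3 robustness
  iterations) of `sqrt(residual SD)` on average log2 count gives the
  mean–variance trend. The trend is clamped to its boundary values
  outside the fitted range and floored at 1e−3 on the quarter-root scale
  so degenerate (zero-variance) inputs still yield finite, equal weights.
* Per-observation weight: `trend(fitted log2 count)⁻⁴`.

Log2-scale expression tables skip the transform and use unit weights.

The moderated fit is weighted least squares on group means over the full
design (residual df `d_g = n − #groups`, pooled across all groups), with
a scaled inverse chi-square prior on the residual variances. The prior
parameters are estimated by moment-matching on `z = log s²`: with
`e_g = z_g − ψ(d_g/2) + log(d_g/2)`, the excess variance
`var(e) − ψ′(d_g/2)` determines `d₀ = 2·ψ′⁻¹(·)` (Newton inversion of the
trigamma function, tolerance 1e−10) and the mean determines `s₀²`. When
the observed spread of `z` does not exceed what equal true variances
would produce, `d₀ = ∞` and all variances collapse to `s₀²`. The
moderated statistic is `t = β/(u·s̃)` on `d₀ + d_g` df, with
`β = mean(A) − mean(B)` on the log2 scale, `u` the unscaled SE from the
weights, and `s̃² = (d₀s₀² + d_g s²)/(d₀ + d_g)`. `prior_df=0` recovers
the ordinary t exactly. This implementation matches the R reference
implementation (limma eBayes / voom) to ~1e−14 on the statistics and to
<1% on voom weights (the residual difference comes from the `delta`
speed-up in R's lowess); the test suite carries that cross-check.

Degenerate features with `s² < 1e−12` are floored to the 1st percentile
of the positive variances (1e−8 if none), so constructed zero-noise
fixtures do not produce infinite statistics.

Selection uses the combined gate |log2FC| ≥ 1 and raw p ≤ 0.05, both
inclusive. The gate is deliberately on *uncorrected* p — the design
targets small studies (n = 5/group) where an FDR gate would be nearly
empty and the FC requirement does the heavy lifting; a BH-FDR column is
emitted for information only. A strict `<` variant of the p comparison is
available (`strict_p`). The CI level defaults to 95%.

The log2FC for count data is the model coefficient on the log2-cpm scale,
not a ratio of raw means; for genus-level analysis the counts are
aggregated first and voom is applied to the genus table.

## KO sets and enrichment

Host differential genes are mapped to KOs per direction; a KO reached
from both an up- and a down-gene is a direction conflict — kept in ALL,
excluded from UP and DOWN, and flagged. The same policy is applied
across omics when the joint union is formed. KO sets carry provenance
(which gene, or "microbiome") for later deconvolution.

The EASE score penalises the one-sided Fisher exact test by removing one
hit from the overlap cell: the 2×2 table becomes
`(k−1, n−k, K−k, N−K−n+k)` — every margin shrinks by one — and the
p-value is that table's hypergeometric upper tail; `k ≤ 1` gives exactly
p = 1. The penalisation variant (shrunken margins vs fixed margins) is
isolated in `ease_score(penalized=...)`; the EASE literature is ambiguous
on this point and the shrunken-margin reading is the package's choice.

The background universe is the single most consequential convention in
enrichment: here N = the KOs *measured* in the relevant dataset that are
annotated to ≥ 1 pathway (the DAVID "population" convention). Microbiome
runs use the predicted-KO universe, host runs the mapped-KO universe,
joint runs their union. Pathways with fewer than 3 measured members
(configurable) are skipped. Enrichment p-values are reported raw, with
stars at ≤ 0.05 / ≤ 0.01 / ≤ 0.001; no multiple-testing correction is
applied at the pathway level.

Deconvolution of an enriched pathway reports (a) the provenance genes of
its hit KOs, annotated with their own differential direction, and (b) the
genera of the OTUs with nonzero contribution to the microbially-measured
hit KOs, annotated with the genus-level differential direction and
ordered by contribution share (shares sum to 1 per pathway).

## Synthetic studies

The generator emulates the data shapes of the target study class:

* **OTU counts**: log-normal baseline relative abundances (σ = 1.5),
  negative-binomial sampling with variance `μ + αμ²` (α = 0.1 default),
  sequencing depth 15,000 reads/sample, 5 samples per group. Planted OTUs
  have their mean multiplied by `2^effect` (default effect 2) in one arm
  of their contrast; group compositions are renormalised so depths stay
  at target. Planted OTUs are seeded at or above the median baseline
  abundance so the planted effect is identifiable at the configured
  depth. Taxonomy strings follow the Greengenes 7-rank convention with
  several OTUs per genus and ~5% missing genus labels.
* **Gene content**: sparse (90% zeros) integer OTU × KO matrix, 16S copy
  numbers uniform on {1..7}.
* **Host expression**: gaussian log2 values (baseline N(7, 2), noise SD
  0.5), planted genes shifted by the effect in one arm. The gene→KO map
  is many-to-many with half the targets drawn from the microbial KO space
  so the joint analysis is non-trivial.
* **Planted pathways** are *cassettes*: a pathway whose 12 member KOs are
  carried exclusively by 4 dedicated OTUs (one reserved genus each) and
  targeted by 4 dedicated host genes, all shifted in the same contrast
  and direction. By construction the cassette OTUs are the sole
  contributors of those KOs, so the deconvolution of a recovered cassette
  must name exactly its genera and genes.

One integer seed determines every table byte-for-byte (per-stage
substreams via SeedSequence spawning).

What the generator does **not** emulate: phylogenetic correlation between
OTUs, compositional coupling beyond simple renormalisation, library-size
heterogeneity, batch effects, zero-inflation beyond the NB, or realistic
KEGG pathway overlap structure. Passing tests therefore demonstrate the
*algebra and statistics* of the pipeline under a clean generative model,
not robustness to real-data artefacts.

Default problem sizes (200 OTUs, 400 KOs, 800 genes, 30 pathways; 2,000
features for null-calibration studies; 25–100 seeds for Monte-Carlo
checks) are chosen to make the full validation suite runnable on a laptop
in minutes while keeping the binomial/NB approximations in their
realistic regime.

## Numerical and design notes

* Voom p-values on null NB counts are calibrated in rate (pooled type-I
  ≈ 0.049–0.057 at the 0.05 gate in the validation runs) but not exactly
  uniform per-seed at n = 5/group — a known property of precision-
  weighted count models at low counts. The distributional-uniformity
  check in the test suite is asserted on the gaussian expression route,
  where the model is exact; count tables are held to the pooled-rate
  criterion.
* Enrichment rows are sorted by (p, pathway id); all set iterations are
  over sorted ids, and run logs carry no timestamps, so identical config
  + seed reproduces output trees byte-for-byte.
* `d₀ = ∞` is represented exactly (normal-distribution tails), not by a
  large-df approximation.
* p-values are clipped below at the smallest positive float, never at 0.
* Errors are raised early with offending ids (duplicate features,
  missing copy numbers, singleton groups, zero library sizes); the
  pipeline wrapper prefixes the failing stage name.

## Known limitations

* The gene-content matrix is user-supplied (or synthetic); no
  ancestral-state reconstruction or reference database is shipped, and
  no prediction-confidence weighting is applied.
* Enrichment p-values depend strongly on the background-universe
  convention; results are comparable only across runs using the same
  convention.
* The differential model covers two-group mean contrasts only — no
  time-course terms, random effects or covariates.
* BIOM-format ingestion is not provided; tables are exchanged as TSV.
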