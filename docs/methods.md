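# Methods

This note documents the statistical procedures implemented in `cropscreen`,
the choices made where the design was genuinely open, and what the
synthetic-data generator does and does not emulate.

## Screen model

A pooled sgRNA library (default: 150 target genes × 3 guides + 50
non-targeting controls = 500 guides) is delivered once to a self-renewing
epithelium. The pre-injection plasmid pool (T0) is sequenced per cloning
batch and serves as the normalization baseline; each profiled sample is
paired with the T0 batch it received. Cells carrying a guide are assumed to
propagate clonally, so the number of guide-positive cells per guide at a
later time point, relative to the guide's T0 proportion, measures clonal
expansion or depletion.

## Guide capture (dial-out)

Read 1 carries three 9-nt cell-barcode sections at fixed offsets plus an
8-nt UMI; Read 2 carries the guide's 20-nt protospacer. Decoding rules:

- Each section decodes to the unique whitelist entry within Hamming
  distance ≤ 1; if no entry or two or more entries are within distance 1
  the read is rejected (`bad_barcode_k`). `N` bases count as mismatches, so
  a section with ≥ 2 Ns can never decode. Whitelists are required to have
  minimum pairwise distance 3, which makes one-mismatch decoding
  unambiguous; the generator builds such whitelists by rejection sampling.
- The cell id is the concatenation of the three *decoded whitelist*
  sequences, not the observed ones.
- The protospacer must match a library entry exactly; one substitution
  rejects the read (`bad_guide`).
- Molecules are counted as distinct (cell, guide, UMI) triples; UMIs are
  compared exactly (no error-collapse networks — plain deduplication).
- Assignment: a cell with one detected guide is assigned to it. A cell with
  several guides is assigned to its top guide only if that guide's UMI
  count strictly exceeds the `q = 0.99` quantile of a reference
  distribution; ties for the top are never assigned. The reference
  population is not uniquely determined by the assignment rule as stated,
  so two strategies are implemented: the empirical distribution of all
  per-(cell, guide) UMI counts (`"global"`, the default and the most
  literal reading) and the pooled losing-guide counts of multi-guide cells
  (`"competing"`). The number of assigned cells is monotonically
  non-increasing in `q` under either strategy.
- The Read 1 offsets of the three sections are instrument-specific
  configuration; the default layout (sections at 0/21/43, UMI at 52)
  mimics a bead design with two linkers and is fully configurable.

## Enrichment statistics

Per guide g in sample s: `FC_g = (c_g/Σc) / (t_g/Σt)` with c the cell
counts and t the T0 batch counts. Guides absent from a sample get FC 0.
Gene-level values are arithmetic means over the gene's guides; control
guides are grouped by ascending index into consecutive pseudo-triplets
(ctrl_1 = controls 1–3, …, ctrl_17 = controls 49–50), giving 167
perturbation values per sample for the default library. Ranks are
assigned in decreasing FC order with min-rank tie handling; zeros
therefore share the lowest occupied rank. Replicates are combined by a
weighted mean on the ratio scale (weights = guide-positive cell counts
per sample) and reported in log2 afterwards. Zero fold changes propagate
as flagged missing log2 values; no pseudocount is added by default
because the zeros carry information (they produce the tied bottom ranks).

Median-of-ratios size factors are estimated **on the control guides
only**: controls with a zero in any sample are dropped, per-control
geometric means are taken across samples, and the size factor of a sample
is the median ratio to those geometric means. This is deliberately not
delegated to a DESeq2-style implementation, which estimates factors from
all features and fits a negative-binomial GLM; here the controls-only
estimator feeds simple normalized-count comparisons. The
knockout/wild-type dependency ratio divides control-normalized,
perturbation-collapsed representations (each scaled so the control median
is 1); values below 1 indicate receptor-dependent expansion. Significance
testing of dependency is out of scope — the ratio is the deliverable.

## Phenotype indices

The index formulas are declared interpretations (control-relative
fractions), configurable rather than canonical:

- proliferation index = (fraction of perturbation cells in S or G2M) /
  (same fraction in control cells);
- anti-differentiation index = basal/(basal+differentiated) in the
  perturbation over the same share in controls.

Both equal 1 in expectation when perturbation cells are a uniform
subsample of the control population. Cycle phases are called
Tirosh-style: mean expression of the S (or G2M) marker list minus the
mean of a size-matched random background set, with phase = argmax of the
positive scores, else G1. Genes are standardized before scoring so that
the random background is centred regardless of baseline expression — the
binned-background refinement used by scanpy/Seurat is unnecessary at that
point. Threshold-positive fractions (e.g. cells with TNF above 0.5) apply
on the counts-per-10k normalized scale before log transform by default;
the log1p scale is an option.

## Module scoring

The module eigengene is the first principal component of the per-gene
standardized, log-normalized module submatrix, computed by SVD. The sign
is fixed to correlate positively with mean module expression ("module up"
is positive) and the component is standardized (unit variance, ddof 1,
mirroring R's `scale`). The perturbation score fits
`eigengene ~ indicator(perturbation)` against pooled control cells by
OLS; the coefficient p-value is mathematically identical to a
pooled-variance two-sample t-test, which the tests assert. Per-gene DE
uses the two-sided Wilcoxon rank-sum on log-normalized expression and a
log2 fold change of mean per-10k expression with pseudocount 1. Fisher's
method combines the module-gene p-values (X² = −2Σln p, df 2k; zeros are
clipped to the smallest positive float with a warning) and the average
log2FC summarizes direction; BH adjustment runs across perturbations.
Downsampling cells per perturbation before scoring is available as an
option (default off).

Perturbation module profiles are row-scaled and Ward-clustered on
Euclidean distance; between-cluster expansion differences use the
two-sided rank-sum test. The expansion model regresses perturbation-level
expansion log2FC on per-perturbation module-gene means by OLS and reports
the fitted-vs-observed Pearson r; exact collinearity or n ≤ p triggers a
flagged ridge fallback. Overrepresentation uses the one-sided Fisher's
exact test with BH across gene sets.

## Tumour selection

Reads are counted by exact 20-mer substring lookup over each read's
windows (mirroring MAGeCK-count's default exact matching); reads hitting
two or more distinct protospacers are excluded as ambiguous. For pooled
representation, guide counts are **summed** within a perturbation group
before converting to fractions — unlike the fold-change collapse, which
averages, because representation is a share of reads and averaging would
bias the final 2-member control group. The selection score is
log2(tumour fraction / P60 fraction). "Robust coverage" is implemented as
fraction ≥ 1/(2 · n perturbations) in at least one representation
(configurable); both representations are renormalized over the covered
set (each sums to 1) before scoring, and covered entries with a zero on
either side are flagged undefined rather than scored.

## Synthetic data: what it emulates, and what it does not

The generator plants known effects so every downstream stage has a
testable ground truth:

- T0 abundances are log-normal (σ = 0.5 by default; the real abundance
  distribution of a cloned library is not knowable a priori, so σ is
  exposed as configuration, with σ = 0 as the uniform limit).
- Cell-to-guide draws are multinomial with probabilities ∝ T0 proportion ×
  2^planted-log2FC; a configurable multiplet fraction carries two distinct
  guides.
- Dial-out reads embed the true barcodes/UMI/protospacer with i.i.d.
  per-base substitution errors; the planted (cell, guide, UMI) table is
  returned for round-trip comparisons.
- Expression counts are negative binomial (gamma–Poisson, per-gene
  dispersion 0.3 by default, Poisson in the zero-dispersion limit) with
  log-normal baseline means; module effects scale module-gene means by
  2^δ; 40 S and 40 G2M marker genes are elevated 4-fold in cycling cells
  (list sizes chosen to match the scale of real cell-cycle signatures).
- Tumour counts are multinomial from P60 proportions × 2^selection effect,
  with an optional dominant-clone mode (≥ 80% of a tumour's reads on one
  guide) emulating clonal tumours.

Not emulated: transcriptome-wide co-expression structure, ambient RNA,
doublet transcriptome mixtures, batch effects, PCR amplification bias
within the dial-out reaction, and indels or barcode-position shifts
(errors are substitutions only). Passing recovery tests therefore
demonstrates correctness of the statistical chain under its stated model,
not robustness to every artefact of real data.

## Problem sizes and numerical choices

The test suite and the acceptance script run synthetic screens at reduced
but statistically meaningful sizes — typically 2,000–4,000 cells per
sample, 2–3 replicate samples, 100 null or recovery repetitions, 30–100
simulated tumour cohorts — chosen so recovery and calibration claims are
testable with comfortable margins. Seeds are explicit everywhere; no
global random state is used. Degenerate inputs (all-zero controls,
constant module genes, empty subsets, out-of-range quantiles) raise
informative errors rather than propagating NaNs silently, except where a
missing value is the documented result (zero fold changes, undefined
ratios, empty clusters).

## Known limitations

- UMI errors are not collapsed; two UMIs within distance 1 count as two
  molecules. At 8-nt UMIs and typical depths this inflates counts by well
  under 1% per sequencing error rate, and the assignment rule depends only
  on count ratios.
- The quantile-assignment reference population is a declared
  interpretation (see above); both implemented strategies agree on
  unambiguous cells.
- The expansion-model Pearson r is an in-sample quantity; with 25
  predictors over 150 observations it contains a p/(n−1) ≈ 0.17 null
  contribution to R², which the calibration in the acceptance script
  accounts for explicitly.
- Selection scores compare pooled representations; per-tumour variance
  (e.g. dominant clones) is visible in the per-tumour count table but not
  propagated into a score uncertainty.
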