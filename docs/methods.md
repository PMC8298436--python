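# Methods

## Activity quantification

Barcode activity is the depth-normalized RNA/DNA log-ratio

    value(s, k) = log2[(rna(s,k) + pc) / L_rna(s)] − log2[(dna(k) + pc) / L_dna]

with library sizes `L` taken as raw totals and a pseudocount `pc = 1` applied
to raw counts before normalization (it keeps dropout barcodes finite without
perturbing well-covered ones; `pc = 0` is allowed for exact ratios on
all-positive counts).  A single shared input-plasmid DNA library is assumed.
Log base 2 is used throughout, so effects read as log2 fold changes.

Filtering proceeds in a fixed order — DNA depth (default `min_dna_count =
10`), RNA dropout cells (zero raw RNA masked per sample), barcode sample
support (default ≥ 1 sample), allele representation (default ≥ 3 surviving
barcodes per allele) — and is idempotent; every threshold is config-exposed
because the exact values used in any particular laboratory pipeline vary.
An *element's* per-sample expression is the mean over its unmasked barcodes.

## Allelic tests and the basal empirical null

The composite log2 fold change of a SNP is the mean over samples of
(alt − ref) element expression, paired within sample so well-level shifts
cancel.  The primary test is a two-sided two-sample t test (Welch by default;
pooled available) on the per-sample element values of the two alleles.

Parametric p-values understate barcode-sequence-driven variability: a set of
barcodes carries persistent offsets, so even a null SNP's alleles differ by a
random amount that does not shrink with replicates.  The empirical null
therefore draws two disjoint random subsets of basal barcodes (subset size =
barcodes per allele, 10), averages them to pseudo-element means, and computes
the identical statistic; with the add-one convention

    Pemp = (1 + #{|t_null| ≥ |t_obs|}) / (1 + n_sims),   n_sims = 20,000.

The same construction yields per-coefficient F nulls for the mixed model
(one-sided).  Normality is checked per SNP by Shapiro–Wilk on pooled
per-allele-centered element values; SNPs failing the gate (p ≤ 0.05) with a
significant primary test get a two-sided Mann–Whitney U verification that is
recorded but never used to exclude a SNP.  Single-condition analyses of the
drug arm use BH FDR on the parametric p-values instead of Pemp.

## The allele × drug mixed model

Per SNP, unmasked barcode-level measurements are modelled as

    expression ~ 1 + allele + drug + allele:drug + (1 | replicate)

with allele ref = 0 / alt = 1, drug vehicle = 0 / ATRA = 1, and a random
intercept for the replicate *pair* (wells transfected and processed together
share an index across the two conditions; per-well coding is available via
`replicate_coding="well"`).  A SNP is fitted only when ≥ 40% of its possible
(barcode, sample) cells survive filtering — 96 of 240 under the default
2 alleles × 10 barcodes × 12 samples design; the boundary is inclusive (96
fits, 95 does not).

Because the model has a single variance ratio λ = σ²_rep/σ²_resid, the
(RE)ML criterion is profiled to a one-dimensional function of λ evaluated in
O(groups · p²) from sufficient statistics (per-group Woodbury identities).
Optimization evaluates a six-point log-λ grid plus the λ = 0 boundary and
refines with a bounded scalar search; the boundary is returned whenever it is
not beaten, which also makes the balanced σ_rep = 0 case collapse exactly to
OLS.  This fitter (validated against statsmodels MixedLM in the test suite)
is what makes 20,000-fit F-statistic nulls affordable.  Coefficients and Wald
F = (β/se)² are reported from REML fits; the likelihood-ratio test of the
interaction refits both the full and additive models by ML and refers
2·Δℓ to χ²(1).  Degrees-of-freedom choices are deliberately immaterial:
significance comes from the empirical F null, not a parametric reference.

Classification: an interaction is present iff its empirical p < 0.05.  A SNP
with both a significant interaction and a significant allele coefficient
(empirical p < 0.05) is labelled `both` only when the single-condition
analyses agree — same allelic direction, vehicle Pemp < 0.1 and ATRA FDR
< 0.1 — otherwise it remains `interaction_only`.  Without an interaction, a
significant allele coefficient gives `allele_only`.  The drug coefficient is
computed but drives no category.

A variance-homogeneity diagnostic reports per-condition quartiles of the
across-replicate barcode SD; pooling the two conditions into one model
presumes these are close (in the synthetic defaults the medians agree to
< 0.005 log2 units).

## Motif perturbation scoring

PWMs are position-probability matrices (rows sum to 1; count matrices are
converted with pseudocount 0.8 split by a uniform background).  A window's
log-odds is Σ log2(p_base/0.25), scanned on both strands; `N` bases
contribute 0.  The *relative score* rescales log-odds to [0, 1] between the
matrix's attainable extremes, making thresholds comparable across motifs.
Ties break toward the leftmost window start, then the forward strand.

Allelic perturbation considers only windows overlapping the variant, so any
allelic score difference is attributable to the variant base.  With
`delta = alt_rel − ref_rel`, a perturbation is **strong** when
max(ref_rel, alt_rel) ≥ 0.85 and |delta| ≥ 0.30, **weak** when
|delta| ≥ 0.10.  These are declared surrogates for motif-analysis tools that
label perturbations by internal p-values: downstream enrichment consumes only
the binary strong/weak/none label, so any monotone thresholding preserves the
pipeline's semantics, and all three constants are config-exposed.

## Resampling enrichment and concordance

For each TF, the observed count of functional SNPs carrying a (by default
strong) perturbation record is compared with counts in 10,000 random draws of
|functional| SNPs from the full analyzed set (a label permutation; drawing
from non-functional SNPs only is available via configuration).  P-values use
the add-one convention and are BH-corrected across TFs; a SNP counts once per
TF however many of that TF's matrices it hits.  On small fixtures this
permutation p agrees with the exact hypergeometric tail within Monte-Carlo
error, which the test suite asserts.

The concordance variant counts (SNP, TF) pairs where the better-matching
allele is also the allele with higher reporter expression (sign of the
composite log2FC); ties on either side are excluded and reported.  Set
construction for the two drug-assay comparisons follows fixed thresholds:
allele-main-effect SNPs (allele Pemp < 0.1) vs SNPs null for all three
coefficients (all Pemp > 0.1), and interaction SNPs (Pemp < 0.05) vs
allele-only SNPs (allele Pemp < 0.1, interaction Pemp > 0.1).

ChIP overlap uses 0-based half-open BED intervals: a SNP at 1-based position
`pos` overlaps iff `start ≤ pos−1 < end`.

## The synthetic-data generator

The generator emulates the assay's skeleton — up to ~1454 SNPs × 2 alleles ×
10 barcodes, 110 basal barcodes, 2 conditions × 6 replicates — with latent
barcode activity

    mu0 + b_k + allele·β_allele + drug·β_drug + allele·drug·β_inter + u + ε

where `b_k ~ N(0, σ_bc = 0.05)` are persistent barcode offsets,
`ε ~ N(0, σ_e = 0.125)` is per-cell noise, and planted effects default to the
magnitudes such screens target (|log2FC| 0.1–1.1).  RNA counts are Poisson
around `dna_k · 2^latent` rescaled to the sample depth (2,000 reads/barcode
by default) — a Poisson-lognormal mixture — and DNA counts are lognormal
around the mean depth.  With these defaults the *realized* median
across-replicate barcode SD (what a 6-sample experiment reports, including
count noise and the finite-sample bias of the SD estimator) lands at ≈ 0.122,
matching the ~0.12 scale typical of such assays, with vehicle/drug medians
agreeing well within 0.005.

Two modelling points deserve emphasis:

- **Well effects.**  A well offset shared by every barcode in a sample
  cancels exactly under total-count normalization, so it is unidentifiable
  and not simulated.  What a per-SNP random replicate intercept actually
  absorbs is the element-by-well interaction; `σ_rep` is therefore drawn per
  (SNP, replicate pair).  Because basal barcodes have no element, any nonzero
  σ_rep breaks the element/basal exchangeability that the basal empirical
  null presupposes — the single-condition t-Pemp becomes conservative while
  the mixed-model allele/interaction F statistics stay calibrated (the
  random intercept and the pairing cancel the term in those contrasts).  The
  default is σ_rep = 0 (the exchangeability premise under which the basal
  null is exact); nonzero values are used explicitly in mixed-model recovery
  and LRT-consistency tests as a robustness condition.
- **What is not emulated:** sequencing-read simulation, PCR duplicates,
  barcode sequencing errors, GC/sequence-dependent barcode effects (barcode
  variability is purely the empirical `b_k`), batch structure beyond the
  replicate pairing, and real LD/genomic context.  Passing tests therefore
  demonstrate the statistical machinery's correctness and calibration under
  the stated generative model, not robustness to artefacts absent from it.

Planted motif fixtures rewrite a SNP's element so one allele carries a PWM
consensus across the variant and the other carries a disfavoured base.  The
generated matrices place a near-deterministic "core" position (calibrated to
40% of the total score range) over the SNP, with flank consensus drawn from
the base pair complementary-disjoint from the core base and guard bases just
outside the window — this guarantees no shifted or reverse-complement window
can rescue the broken allele, so planted perturbations are deterministically
*strong* and fully recoverable, which the suite asserts at 100% recall.

## Problem sizes and numerical choices

Default null sizes are 20,000 simulations (t and F) and 10,000 enrichment
draws.  The test suite runs its calibration checks at 500 null SNPs with the
full 20,000-simulation nulls, parameter recovery at 50 seeds, and LRT
consistency at 150 SNPs — sizes chosen so the whole suite completes in about
a minute while keeping Monte-Carlo bands (3 binomial SEs) meaningfully tight.
Empirical p-values can never be 0 by the add-one convention.  Degenerate
inputs are handled explicitly: identical constant groups give t = 0, p = 1
(flagged); constant input to the normality gate is flagged with no test; a
constant interaction column gives an LR statistic of 0 and p = 1; and the
permutation nulls condition on the realized basal set, so their quantiles
wobble around parametric references dataset-to-dataset (tests compare
averages over several datasets).
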