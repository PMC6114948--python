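# Methods

This note documents the models, estimators and numerical choices behind
`luscage`, and what the synthetic test bed does and does not establish.

## Mutation filtering

Three exclusion criteria are applied in a fixed order, then listed patients
are removed; a `FilterReport` records the count after every step.

*Deduplication.* Mutation identity is (patient, chromosome, position, ref
allele, alt allele). The first occurrence wins after a stable sort by sample
barcode, so the surviving record is independent of input row order. Applied
to its own output the filter chain is a no-op (tested).

*Gene ambiguity.* Records whose gene field parses to more than one symbol
(separator `;` or `,`) are removed — a mutation on sequence shared by
paralogs cannot be assigned to one locus.

*Repeat context.* A context fails if, for any unit length u ∈ {1…5} and any
alignment, the number of consecutive tandem copies of a u-mer reaches the
threshold (6, 4, 3, 3, 3). Thresholds count tandem *unit copies* — "4
continuous duplets" means 8 bases of a repeated 2-mer — so the monotone
threshold sequence corresponds to 6/8/9/12/15 bases. A run of k identical
bases counts at every unit length as ⌊k/u⌋ copies; with the default
thresholds, unit length 1 binds first on homopolymers. `N` never extends a
run. The full `ref_context` string is examined as provided (11- or 21-mers
depending on MAF dialect); no window trimming, since the upstream convention
fixes the window. The implementation is checked against an independent
regex-backreference oracle on random contexts.

Patient IDs derive from sample barcodes by a 12-character prefix
(TCGA convention), configurable per dialect. Indels pass through filtering
and count toward loads but are excluded from 96-channel profiling — the
signature formalism is defined for single-base substitutions only.

## Trinucleotide channels

Channels are ordered substitution-major (C>A, C>G, C>T, T>A, T>C, T>G), then
5' flank, then 3' flank, each A/C/G/T — the ordering of the shipped catalog,
so no re-indexing occurs. A purine-reference event is mapped through the
reverse complement (ref/alt complemented, flanks complemented and swapped);
the involution is verified exhaustively over all 12×16 descriptions. Flanks
are read from the record's own context string, never from a reference
genome. Profiles are per patient (post-deduplication), not per sample.
Records whose context cannot supply both flanks, or with non-ACGT alleles,
are tallied as unassigned, preserving the identity
`sum(counts) + n_unassigned = #SNV records`.

## Signature refitting

Model: profile p ≈ S·a with S the 96×30 column-stochastic catalog and a ≥ 0,
estimated by minimizing the residual sum of squares on raw counts. Least
squares is chosen because the bound-constrained quasi-Newton solver
minimizes it naturally and it makes the non-negative-least-squares oracle
exact; counts (not frequencies) are used, which only rescales exposures —
scale equivariance is tested, and rank-based downstream statistics are
unaffected.

Numerics: L-BFGS-B with analytic gradient 2(SᵀS·a − Sᵀp), lower bounds
exactly 0, no upper bounds, start aᵢ = n/30 (feasible, scale-aware,
deterministic; convexity makes the optimum initialization-independent —
verified with random restarts), relative objective tolerance 1e-10, 10,000
iteration cap, both configurable. Tiny negative roundoff at active bounds is
clamped to zero. An all-zero profile short-circuits to zero exposures. No
sparsity penalty and no signature pre-selection: all 30 signatures compete
simultaneously.

Diagnostics per patient: final objective, cosine between observed and
reconstructed profile, exposure total. On catalog mixtures with n ≥ 5,000
mutations the reconstruction cosine stays ≥ 0.95.

## Alteration loads

* SNP load: retained record count per patient.
* Disrupted genes: distinct genes with ≥1 moderate/severe mutation. The
  severity map is configuration (default: nonsense/frameshift/splice/
  nonstop/start-site = severe; missense/in-frame = moderate; everything
  else low); unknown classifications raise by default or can be treated as
  low.
* CNV load: Σ|g| over thresholded calls; values outside {−2…2} raise, since
  they indicate non-thresholded input. All genes count, not only ±2 events.
* Methylation rate: per gene, z = (β − mean)/sd across patients (sample sd,
  ddof 1); per patient, Σ|z|. The absolute value is deliberate: the signed
  sum is ≈0 for every patient by construction (each gene is centered), so
  only the absolute form yields the inter-patient variation the analysis
  correlates with age. A `mode="signed"` flag preserves the literal signed
  reading. Zero-variance genes are dropped with a warning; missing values
  are skipped, not imputed.

## Association statistics

*Spearman.* rho is the Pearson correlation of mid-ranks. p-values are
tiered like the classical R implementation: exact permutation enumeration
for n ≤ 9 without ties (cached S-distributions); for 9 < n ≤ 1290 without
ties an Edgeworth-corrected normal approximation,

    P(|ρ| ≥ r) ≈ 2·[Φ̄(x) + γ₂/24·(x³−3x)·φ(x)],
    x = (r − 6/(n³−n))·√(n−1),

where γ₂ is the exact null excess kurtosis of ρ, obtained from
E[ρ⁴] = 3(25n³−38n²−35n+72) / (25n(n+1)(n−1)³) — a closed form that
reproduces full permutation enumeration exactly for n = 5–9. The half-step
term is the continuity correction (S moves in steps of 2). In the extreme
tail the platykurtic correction can drive the approximated tail mass to ≤0;
the t-approximation t = ρ√((n−2)/(1−ρ²)) is used there instead of reporting
zero, and it is also the fallback under ties (the Edgeworth domain is
tie-free) and for n > 1290. Against R's AS 89 values the approximation
agrees to ~2e-3 at n = 12 and ~1e-4 at n = 50. Pairwise-complete
observations; constant vectors yield a flagged NaN rather than an error.

*Bootstrap CI.* Percentile (not BCa) 95% interval of rho over B = 1000
paired resamples, vectorized, deterministic under seed; degenerate
replicates (constant resample) are skipped. Coverage at n = 200 and
population rho 0.5 measures ≥ 90%, the expected mild undercoverage of the
percentile method.

*Wilcoxon rank-sum.* Exact enumeration when both arms ≤ 25 without ties,
otherwise normal approximation with tie and continuity corrections (the
default behaviour of the classical R test). Fully tied data reports p = 1.

*Fisher exact.* Conditional two-sided test, fixed margins; a zero margin
gives p = 1.

*FDR.* Benjamini–Hochberg step-up within each analysis family (one table =
one family), NaN passthrough for flagged rows; q-values verified against a
literal step-up oracle. The screening threshold used in reports is q ≤ 0.2.

*Local medians.* Integer-age grid spanning the data; at each grid age the
median of values within ±10 years (configurable), 95% CI by percentile
bootstrap of the window sample; windows with <3 observations are undefined.
Plotting is left to the caller — the curve is returned as a tidy frame.

*Age groups.* Left-open right-closed bins (≤50, 50–60, 60–70, 70–80, >80)
plus the ≤60/>60 dichotomy, both configurable.

## Subgroups and ssGSEA

Subgrouping thresholds each signature at its cohort arithmetic mean on the
raw exposure scale (any log display transform is presentation only);
`high` requires strictly greater-than, so exact ties — including an
all-identical cohort — classify low. Labels are invariant to any common
positive rescaling of exposures.

ssGSEA score for one patient and one set: rank genes by value descending
(mid-ranks on ties, ties broken deterministically by gene name), then

    ES = Σᵢ [ P_in(i) − P_out(i) ],

with P_in the cumulative |rank|^α over in-set genes normalized by the
in-set total and P_out the unweighted cumulative out-of-set proportion;
α = 0.25 by default, matching the published projection tool's default.
α = 0 reduces to the unweighted Kolmogorov-style statistic. A set disjoint
from the profile, or covering it entirely (no out-of-set mass), is
degenerate: the scalar scorer raises, the matrix scorer records NaN.
Cross-sample normalization by the overall score range is available behind a
flag, off by default. The SNP layer counts non-silent (moderate/severe)
mutations per gene; silent and other low-severity classes are excluded.
CNV and methylation layers are rank-oriented by absolute value, consistent
with the load definitions. Gene universes stay layer-specific.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes:

* ages uniform on 40–85 via the probability transform of a latent normal
  score;
* per-patient signature mixtures: base fractions (SI4/SI1/SI6/SI5/SI26 =
  0.40/0.20/0.15/0.15/0.10) jittered log-normally (sd 0.5 on the log scale);
  a signature with an age-coupling target ρ obtains it through a Gaussian
  copula with latent correlation 2·sin(πρ/6); defaults couple SI6 at −0.3
  and SI26 at +0.3;
* mutation counts log-normal (median 300/patient — matching the per-patient
  scale of filtered LUSC exomes); channels multinomial from the patient's
  mixture; strand randomized 50/50 so pyrimidine normalization is always
  exercised; contexts are 11-mers, rejection-sampled to be repeat-clean;
* injected fractions: 25% duplicate-sample rows, 0.1% two-gene annotations,
  9% repeat-failing contexts (a ≥6-base run of the ref base crossing the
  center) — the removal rates observed on real LUSC mutation tables;
* CNV matrices with Bernoulli events (rate 0.05, optional age coupling) and
  methylation betas via a logistic transform of Gaussian scores whose
  per-patient dispersion is age-coupled (default target −0.3);
* toy GMT collections with one designated spike set for enrichment tests.

Ground truth (true exposure fractions, counts, targets) is archived with
every dataset so recovery tests never re-simulate. All sampling goes through
one seeded NumPy generator; runs are bit-reproducible.

The shipped signature catalog is synthetic: same shape, labels and
column-stochastic contract as the COSMIC v2 table, with structured spectra
for SI1 (C>T at NpCpG), SI4 (broad C>A), SI5 (flat), SI6 (C>T at NpCpG with
distinct flank weights plus a C>A component) and SI26 (broad T>C), and
sparse Dirichlet columns elsewhere. Peak concentration was set to
COSMIC-like sparsity (90% structured mass with log-normal flank tilts over
a Dirichlet(0.08) background) so that columns are as discriminable as real
signatures; a more diffuse catalog lets multinomial noise masquerade as
spurious exposures, which is a property of the reference object, not of the
refitter. **What passing tests show:** the pipeline recovers mixtures,
couplings and enrichments it was pointed at, under a catalog whose
signatures are distinguishable and with i.i.d. noise. **What they do not
show:** performance under the real catalog's near-collinear signature
pairs, sequencing-depth artefacts, subclonal structure, or gene-length and
replication-timing confounders present in real tumors.

## End-to-end estimand

The generator couples the exposure *share* of a signature to age; the
end-to-end recovery tests therefore correlate the fitted exposure share
(aᵢ/Σa) with age. Count-scale exposures multiply that share by the
age-independent total mutation count, which attenuates the rank correlation
without changing its sign; the pipeline's association tables report the raw
coefficients for fidelity to the original workflow, and the share is the
quantity with a ground-truth target.

## Problem sizes in the test suite

Suite-wide sizes were chosen to make every stochastic check
well-powered yet quick: 10,000 random contexts for the repeat-filter oracle,
100 profiles of 20,000 mutations for exposure recovery, 200 outer
replications (B = 1000) for bootstrap coverage, two 300-patient cohorts for
end-to-end coupling recovery, and 50 spike-in replicates for enrichment
ranking. The full suite runs in about a minute on one CPU.

## Known limitations

* The Edgeworth p-value is an approximation; beyond its deep-tail fallback
  it is not the literal AS 89 polynomial, though it agrees with it to a few
  parts in a thousand across the tested range.
* The ssGSEA tie-break (gene name within tied values) is deterministic but
  arbitrary; scores for heavily tied, short profiles depend on it at the
  margin.
* No covariate adjustment beyond stratification; no survival modelling.
* The synthetic catalog is not the COSMIC v2 catalog; analyses of real data
  should supply the published TSV.
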