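# Methods

This note records the statistical model behind each pipeline stage, the
design choices that were genuinely open, and what the synthetic cohorts do
and do not establish about behaviour on real data.

## Methylation traits

Input is a per-accession table of cytosine sites with methylated and total
read counts in the CG, CHG and CHH contexts. Sites with total coverage of
4 reads or fewer are discarded (`min_total = 5`, i.e. "coverage greater
than 4"). A trait is the methylation percentage of one gene body in one
context; two aggregations are offered:

* `site_mean` (default): mean over in-gene sites of `mc/total × 100` —
  what a BEDtools `map -o mean` workflow produces;
* `weighted`: `Σmc / Σtotal × 100`, the coverage-weighted level.

An accession with no qualifying site in a gene/context is *missing*, never
0%. Traits are retained when `missing_count ≤ floor(rate × n_accessions)`
with `rate = 0.10`. With 811 accessions this floor is 81, so a trait
missing in exactly 81 accessions is retained and one missing in 82 is
dropped; the boundary case is ambiguous in prose descriptions of a "≤10%"
rule and the floor convention used here is configurable. Strand is ignored
for level computation because the context labels already encode the
strand-resolved cytosine classes. The coefficient of variation is
`sd/mean × 100` with the n−1 denominator, computed on non-missing values;
a zero mean flags the CV as undefined (NaN) rather than raising.

## Mixed-model association (EMMAX approximation)

The association model for a trait vector y over n accessions is

    y = Xb + u + e,   u ~ N(0, σ²g K),   e ~ N(0, σ²e I)

with X an intercept and K an accession-relatedness matrix. Variance
components are estimated once on the null model by REML and reused for
every SNP (the EMMAX approximation). The restricted likelihood is profiled
on δ = σ²e/σ²g using the eigenspectrum of the covariate-projected kinship
B'KB (B an orthonormal basis of the complement of span(X)): a 100-point
grid on log δ ∈ [−10, 10] followed by bounded scalar refinement to 1e-6.
The grid-first strategy is robust to the multimodality the restricted
likelihood can show on structured kinships, and deterministic.

Each SNP is then tested by GLS after whitening with Σ^(−1/2), Σ = σ²g K +
σ²e I, computed from one eigendecomposition of K; the statistic is a t
with n − q − 1 degrees of freedom (not a normal approximation — at the
cohort sizes used in validation the difference is visible). Missing
dosages are mean-imputed per SNP, as a complete-matrix method requires;
the ≤25% missing-rate QC bounds the distortion. With K = I the whitening
is a scalar and the scan reduces exactly to OLS t-tests, which is tested.

Kinship default is the centered GRM, K = ZZ'/m with Z the column-centered
dosages scaled by √(2p(1−p)), symmetrized and PSD-repaired by clipping
negative eigenvalues; an IBS (proportion of shared alleles) matrix is
available since the EMMAX tool family offers both and published
descriptions often leave the flavour unstated. Kinship is computed on an
LD-pruned panel: sliding windows of 50 SNPs advancing by 10, removing the
lower-MAF member (ties: larger position) of any pair with r² > 0.1 until
no window pair exceeds the bound — the `--indep-pairwise 50 10 0.1`
procedure. The exact variant-ordering rule of the PLINK binary is not
reproduced bit-for-bit; the pruner is instead verified against a naive
transcription of the stated rule.

LD r² is the squared Pearson correlation of dosages over pairwise-complete
accessions; fewer than 3 complete pairs or zero variance yields an
undefined (NaN) signal. The genome-wide significance threshold is
Bonferroni α/n_tests with α = 0.01; over 1,110,440 tests this is
9.01 × 10⁻⁹.

Accessions with a missing trait value are dropped per trait (with the
kinship sub-matrix subset accordingly) rather than imputed.

## methylQTL calling cascade

Per trait, in order: (1) Bonferroni threshold; (2) density filter — a
significant SNP survives only when strictly more than 20 *other*
significant SNPs lie within a 16 kb window centred on it (±8 kb; the
window is configurable because "within nearby 16 kb" could also be read
as ±16 kb); (3) gap clustering — consecutive SNPs join a cluster while
the gap is ≤8 kb and the chromosome is unchanged; (4) trait cap — traits
with more than 20 clusters are dropped entirely, counting clusters across
all chromosomes jointly, and before LD deduplication (the printed order);
(5) the representative SNP is each cluster's most significant member,
ties broken by smaller position then SNP id; (6) LD deduplication —
processing representatives from most to least significant, a cluster is
discarded if its representative has r² ≥ 0.1 with any already-accepted
representative of the same trait (the greedy implied by "in LD with a
more significant representative"); (7) classification — distance 0 inside
the gene body, otherwise base pairs to the nearer gene edge, infinite
across chromosomes; proximal requires the same chromosome and distance
strictly below 100 kb, so a SNP at exactly 100 kb is distal (the
published wording "<100 kb" / ">100 kb" leaves the point mass
unassigned); (8) PVE.

PVE of a representative SNP is t²/(t² + df) from the whitened single-SNP
regression — the squared partial correlation between SNP and whitened
trait. No formula is published for this quantity; this is the standard
single-SNP variance-explained estimator consistent with an EMMAX scan.
Note that whitening makes it an estimate of variance explained *after*
relatedness adjustment: on cohorts with strong structure it sits below
the raw R² of trait on dosage (we observe ≈0.21 for a planted raw PVE of
0.25), which is inherent to the estimator, not a defect of the cascade.

Every stage's output is a subset of its input; the full cascade is tested
for exact set equality against an unoptimized transcription of the rules.

## Downstream statistics

Trait-variable correlation is Pearson r on pairwise-complete pairs with
the two-sided p from t = r√((n−2)/(1−r²)) (the `corr.test` convention);
edges require p below a user-supplied cutoff (default 6.08 × 10⁻⁵, treated
as a constant of the published analysis whose derivation is not restated)
and n above a per-family floor (720 for geography, 100 for phenotypes).
The network export is a Cytoscape-importable node/edge table.

Enrichment of representative SNPs in an interval track uses a 2×2 table
per feature against the full GWAS SNP background. By default the
representative set is removed from the background so the cells are
disjoint; the alternative reading (background includes the
representatives) is available via `disjoint_background=False`. p is the
exact two-sided hypergeometric probability (point-probability rule); the
odds ratio is the sample (ad)/(bc) with a Haldane–Anscombe +0.5 on every
cell when any cell is zero. Gene features are extended by 2 kb flanks
before membership testing, with overlapping intervals merged per feature.
Multiple-testing adjustment defaults to Benjamini–Hochberg (the published
adjustment method is unstated), with Bonferroni selectable. Note that BH
step-up is not idempotent as a map on p-vectors; the tested invariants are
agreement with a longhand step-up computation, rank monotonicity and the
≤1 bound.

The 2^−ΔΔCt utility implements relative qPCR quantification:
ΔCt = Ct_target − Ct_reference per sample, ΔΔCt subtracts the calibrator's
ΔCt, and the reported level is 2^−ΔΔCt.

## Synthetic cohorts

The generator produces the statistical structure the analysis assumes;
all randomness flows from one master seed through named substreams
(genotypes / methylome / phenotypes / annotations), so components are
individually reproducible and identical seeds give byte-identical output.

**Genotypes.** Each accession carries two haplotypes built by a
founder-mosaic (haplotype-copying) process: per chromosome, a haplotype
copies one of 24 founder haplotypes and switches founders with probability
`recomb_rate_per_bp` per base (6 × 10⁻⁵ by default). Founder haplotypes
are not independent across sites: a latent Gaussian AR(1) copula with
decay 3 × 10⁻⁵/bp correlates both the founder alleles and the common
allele-frequency series, because a mosaic over site-independent founders
produces kinship but essentially no site-to-site LD. With these two rates
the mean r² falls below 0.1 near 8 kb, matching the decay regime of the
target population, and short-range mean r² is ≈0.7. Two subpopulations
with Balding–Nichols-diverged founder frequencies (Fst 0.1) and 10%
per-segment admixture induce kinship structure. SNPs below the MAF floor
(5%) after simulation are removed. The default density is ~9.4 SNPs/kb —
about 150 SNPs per 16 kb, the density regime the cascade's density filter
presumes.

**Methylome.** For each gene, context, and accession a latent logit-scale
propensity is the context baseline (CG 0.2, CHG 0.0, CHH −0.4 —
mid-range percentages where the logit map is nearly linear), plus the
gene's class shift, planted SNP effects, a per-subpopulation random effect
(sd 0.15), and accession noise (sd 0.3). Each cytosine site (spacing
100/100/40 bp for CG/CHG/CHH) adds a fixed site offset (sd 0.3) and emits
total reads ~ Poisson(20) and methylated reads ~ Binomial(total, p);
5% of site observations are dropped. The per-subpopulation effect makes
methylation share structure with kinship, stressing the mixed model's
confounding control.

**Planted effect sizes.** A QTL request specifies a target PVE; the
per-dosage effect is solved as β = √(PVE/(1−PVE) × V_env / Var(dosage)),
where Var(dosage) is the *empirical* variance of the causal dosage vector
(under population structure this differs from the Hardy–Weinberg
2p(1−p), and it is the realized variance that determines realized PVE)
and V_env is the latent-scale environmental variance: subpopulation
variance σ²_s(k−1)/k for k balanced subpopulations, accession variance,
and a delta-method equivalent of the binomial read noise,
E[1/T]/(K_sites × p̄(1−p̄)). Realized PVE — the R² of the emitted trait on
the causal dosage — is recovered to within ±0.05 of targets 0.1/0.25/0.5
in the test suite.

**Phenotypes** are r·z(trait) + √(1−r²)·noise for planted links, pure
noise otherwise. **Chromatin states** tile each chromosome in 2 kb tiles
with Dirichlet-drawn weights; when truth rows carry an enriched-state
label, each tile holding a causal SNP is assigned that state with
probability f × its weight (one decision per tile), planting an
enrichment of factor f that the Fisher stage must recover.

**Named cohort layouts.** Two layouts are frozen as constructors because
the genome geometry matters for what is being measured:

* `null_cohort_config` — 3,000 SNPs over 10 × 3 Mb chromosomes (~1 SNP
  per 10 kb, above the LD decay length). Null calibration needs many
  quasi-independent tests; at the default density 3,000 SNPs collapse to
  ~36 linkage blocks and the genomic-inflation factor of a single scan is
  far too unstable to interpret.
* `qtl_cohort_config` — 42,000 SNPs over 2 × 2.25 Mb at the default
  density. Recovery studies need the pruned kinship panel to be large
  (~500 markers here) so the causal linkage block is a negligible share
  of K; on a small genome the EMMAX whitening absorbs much of the planted
  signal (proximal contamination), exactly as mixed-model theory
  predicts. The real analysis' ~46k-SNP kinship panel has the same
  dilution property.

**What the synthetic cohorts do not show.** Read counts are
binomial–Poisson with a logit-additive propensity; real bisulfite data
add conversion errors, mapping bias, context misassignment and
batch structure, none of which are modelled. Methylation distributions in
real populations are strongly bimodal for CG gene-body methylation,
whereas the generator produces unimodal mid-range levels; the trait
filters are exercised, but their selectivity on real distributions will
differ. LD is stationary along the chromosome — no recombination
hotspots, inversions, or centromeric structure. Passing recovery tests
therefore demonstrates correctness of the statistical machinery under the
assumed model, not robustness to every failure mode of real methylomes.

## Numerical choices and degenerate inputs

* REML: eigenvalues of the projected kinship clipped at 0; non-positive
  whitening weights raise rather than silently regularize.
* SNPs with zero post-whitening variance receive missing p-values with a
  warning (they cannot be tested, and 0 would be a lie).
* λ_gc uses the median of χ²₁ quantile-transformed p-values divided by
  0.4549.
* Ties: the representative SNP and the dedup processing order both break
  p ties by smaller position then lexicographic SNP id, making the
  cascade fully deterministic.
* Coordinates are 0-based half-open internally everywhere; GFF3 and VCF
  positions are converted only at I/O boundaries. SNP positions stay
  1-based on the SNP table (as in VCF) and are converted when intersected
  with intervals.
* All TSV artifacts carry a provenance header (package version, seed,
  config hash); readers skip `#` lines.

## Problem sizes used in validation

The acceptance computations run at desk scale: null calibration pools
3–5 scans of 300 accessions × 3,000 near-independent SNPs; recovery uses
10–20 cohorts of 500 accessions × 42,000 SNPs with one planted cis QTL
(PVE 0.25) or a cis/trans pair (0.20/0.08); enrichment uses 60 planted
causal SNPs against 5 chromatin states at factor 3; correlation power
uses the published n = 768 and p < 6.08 × 10⁻⁵. Fisher p-values are
checked against exhaustive hypergeometric enumeration for every 2×2 table
with total ≤ 40. These sizes were chosen so each quantity is measured
with useful precision by a single-CPU run.
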