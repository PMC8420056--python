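# Methods

This note documents the models, the synthetic-data generators, the
numerical choices and the known limitations of `mqtlkit`. It describes
what the code computes; every empirical statement here is produced by the
test suite or by `scripts/acceptance.py`.

## Feature processing

Features missing in more than `max_missing` (default 0.2) of lines under
*either* growth condition are removed; removal is always by feature,
never by line, and the boundary is inclusive (exactly 20% missing is
retained).

Redundant features are collapsed in two passes over a pairwise
compatibility graph whose connected components become the metabolites:

1. **Within each ionization mode** — an edge requires retention-time
   distance ≤ `rt_tol` (0.2 min) *and* cross-line intensity correlation
   > `corr_min` (0.95). The MS/MS co-occurrence criterion used with raw
   spectra needs data this package does not model; it is accepted as an
   optional externally supplied boolean compatibility matrix that gates
   edges when present.
2. **Across modes** — representatives of the within-mode groups are
   linked by the same retention-time and correlation criteria, but only
   between *opposite* modes: a same-mode pair that the first pass kept
   apart (e.g. because the compatibility matrix vetoed it) must not be
   re-joined through the merge pass.

Correlation is computed across all lines of both conditions, on log
intensities by default (configurable; the choice of scale is a judgment
call — log is standard because LC-MS intensity noise is multiplicative).
The representative intensity of a group is the member with fewest missing
values over both conditions, ties broken by larger median intensity and
then lexicographically — a deterministic rule chosen for data
completeness.

Normalization equalizes per-sample medians (optionally per-batch first:
each batch is scaled so its pooled median matches the global median —
"day" normalization — then every sample individually). Residual missing
cells are imputed with half the per-metabolite minimum on the normalized
raw scale (the conventional below-detection-limit treatment), then the
natural log is taken. The median step is idempotent to 1e-9. Fold
changes downstream are computed on the raw (exponentiated) scale, so the
log base is irrelevant to the responsive calls.

## Drought-responsive calling

A metabolite is responsive iff all three hold: OPLS-DA VIP ≥ 1, BH-FDR of
the two-sided paired t-test ≤ 0.05, and fold change DS/WW ≥ 2 or ≤ 0.5
(a ratio cannot be negative, so "|FC| ≥ 2" is read as two-sided on the
log scale). The rule is monotone: raising VIP or |log2 FC|, or lowering
FDR, never turns a responsive call off (property-tested).

OPLS-DA is a from-scratch Trygg–Wold O-PLS with one predictive component:
metabolites are centered and unit-variance scaled (standard for VIP
comparability), the class vector is the centered condition indicator,
`n_ortho` (default 1) orthogonal components are removed by deflating the
y-orthogonal part of each loading, and the predictive weight is the
normalized X′y of the filtered matrix. With a single predictive
component the VIP reduces to √p·|w_j|, which makes the mean squared VIP
exactly 1. Note that a one-component PLS fit on pure noise still captures
about m/n of the class variance, so R²Y under a permuted-label null sits
near 0.25 at n = 200, m = 50 — "no separation" should be judged against
that null level, not against zero.

The paired t-test uses pairwise-complete lines; metabolites with fewer
than 3 complete pairs are excluded from the BH family; zero-variance
differences give p = 1. BH adjustment is applied jointly across all
tested metabolites.

## Mixed-model association (mQTL and eQTL)

Kinship is VanRaden's centered matrix K = WW′ / 2Σp(1−p) with per-SNP
mean imputation of missing dosages. Structure covariates are the top
`n_pc` (default 5) principal components of the centered dosage matrix.

The scan is P3D/EMMAX: per trait, REML estimates the variance ratio
δ = σ²e/σ²g once under the null model y = Xβ + u + e through the
restricted spectrum. The implementation decomposes S(K+I)S rather than
SKS, where S projects off the fixed effects: for rank-deficient kernels
(always the case for the ridge predictor's MM′ kernel, often nearly so
for kinship) the zero eigenspace of SKS mixes the fixed-effect directions
with the kernel's null space, and selecting "the top n−q eigenvectors"
can leak the trait mean into the restricted likelihood; adding I keeps
the complement-of-X eigenspace strictly positive and cleanly separated.
The 1-D REML objective is maximized by a coarse grid over log δ ∈
[−10, 10] followed by bounded Brent refinement (xatol 1e-6).

Each SNP is then tested by GLS at the fixed ratio, implemented as OLS on
whitened data with Frisch–Waugh projection off the whitened covariates;
the Wald t has df = n − q − 1, which makes the scan *exactly* equal to
the OLS t-test when K = I (verified to |Δlog₁₀p| < 1e-6). PVE is defined
as β̂²·var(g*)/var(y*) on the whitened scale — an internal, comparable
quantity, not an estimate of narrow-sense heritability. Monomorphic SNPs
are skipped and recorded.

The suggestive threshold is 1/M_eff. M_eff uses the simpleM approach:
per chromosome, in windows of 200 markers, the smallest k whose top-k
correlation eigenvalues reach 99.5% of the trace; windows sum. An
externally computed M_eff can be injected instead (`--meff`).

Significant SNPs merge into mQTLs by single linkage with a strict
< 10 kb gap between consecutive position-sorted SNPs; clusters never
span chromosomes; the peak SNP has minimal p (ties → smaller position).
Candidate genes are genes whose 1-based-inclusive span contains at least
one member significant SNP; known-QTL co-localization requires ≥ 1 bp
overlap (BED input converted from 0-based half-open internally).

eQTL scanning reuses the engine on log2(x+1) expression (the transform
is a package choice; expression inputs are raw-scale). A locus is *cis*
when the lead SNP lies within gene span ± 20 kb (positional, strand
ignored), *trans* otherwise and always when on another chromosome.
"Shared" means the same gene has an overlapping (≥ 1 bp) merged locus in
the other condition — locus identity across conditions is not otherwise
well defined, so the overlap rule is explicit and configurable.

## Networks and hubs

Gene–metabolite edges come from simple linear regression of metabolite
on expression; the slope t-test is computed through the algebraically
identical correlation t-transform, vectorized over all pairs, with edges
at p ≤ 1e-5. Gene–gene co-expression edges use the Pearson t-transform
at p ≤ 4.67e-9.

The hub null reassigns each edge's gene endpoint uniformly at random over
the gene universe (metabolite endpoints and edge count preserved),
`n_perm` (1000) times; the per-gene degrees of all permutations are
pooled and the threshold is the smallest k with empirical
P(degree ≥ k) < α (0.01). This per-edge reassignment reproduces the
balls-in-bins structure that makes a per-gene degree threshold
meaningful; an alternative mode reassigns each metabolite's whole edge
bundle to one random gene (`mode="metabolite"`). At E = 100 edges over
G = 100 genes the pooled null is Binomial(100, 0.01) and the threshold
converges to the exact tail value 5 (P(X≥5) = 0.0034 < 0.01 ≤ P(X≥4)).
In the fully degenerate case (a single gene) no tail drops below α and
the threshold collapses to the maximum attainable degree. Enrichment is
the one-sided hypergeometric test per GMT pathway with BH adjustment;
pathways with no universe member are skipped.

Ratio summaries are computed with exact decimal arithmetic and
round-half-even at the requested precision (1 decimal by default, 0 for
integer-percent labels), so printed percentages are reproducible bit for
bit.

## Prediction

The predictor is ridge-regression BLUP: y = 1μ + Mα + e with α ~
N(0, σ²α I), solved in kernel form α̂ = M′(MM′ + λI)⁻¹(y − 1μ̂) with λ
from the same REML machinery (K = MM′, X = 1) and μ̂ the GLS intercept.
At fixed λ this equals the explicit normal-equations ridge solve to
1e-9 (property-tested).

Cross-validation uses unstratified random folds, fresh per repeat
(default 10-fold × 100 repeats). The accuracy of a repeat is the **mean
of within-fold Pearson correlations** between held-out predictions and
observations. The assembled-predictions correlation (also available,
`accuracy="assembled"`) carries a systematic negative bias of order
√(k/n) when predictors are uninformative, because each fold's
predictions track the leave-fold-out training mean, which anti-correlates
with the held-out fold mean; the fold-mean form is the common practice in
genomic-prediction benchmarking and is calibrated at zero under the null.

The accuracy-ratio test bootstraps paired resamples of the per-repeat
accuracies (ordinary bootstrap, default 100 replicates), statistic
θ̂ = mean(a)/mean(b), and inverts the basic (reverse-percentile)
interval: p = 2·min(F*(2θ̂−1), 1−F*(2θ̂−1)), clipped to
[1/(n_boot+1), 1]. Degenerate inputs (all replicate ratios equal) give
p = 1 when θ̂ = 1 and the smallest attainable level otherwise. Under an
exchangeable null the p-value is approximately uniform (KS-tested).

Phenotype BLUPs fit value = μ + Environment (fixed) +
Replicate-within-Environment (random) + Genotype (random) + e by REML
through statsmodels MixedLM variance components; environment can be
moved into the variance components (`env_fixed=False`) since its
fixed/random status is a modeling choice. Genotype BLUPs shrink toward
zero and sum to ≈ 0.

Stepwise selection is bidirectional over OLS fits minimizing
AIC = n·ln(RSS/n) + 2k (k = intercept + selected predictors), hard-capped
at ⌊n/10⌋ moves, followed by repeated k-fold CV (default 5-fold × 10)
reporting the mean squared correlation of held-out predictions. The
survival-rate > 0 row filter used before prediction is applied by the
pipeline and CLI.

## Synthetic data: what it emulates, what it does not

**Genotypes.** Balding–Nichols divergence: subpopulation allele
frequencies are Beta-distributed around a shared ancestral frequency
(default Fst 0.15, 3 subpopulations, 10 chromosomes, mean marker spacing
2 kb). LD comes from an AR(1) latent process per haplotype whose
correlation decays as exp(−d/(L/2)) within blocks of length L (default
20 kb) and resets at block edges. This produces exactly the two
confounders the Q+K model must correct — structure (top PCs separate
subpopulations with silhouette > 0.5) and kinship — plus realized-MAF
filtering at 0.05. It does not emulate realistic maize demography,
recombination hotspots or genotyping error.

**Metabolome.** Log-normal intensities (baseline ln-intensity N(12, 1),
biological noise sd 0.4 — chosen to give single-condition CVs in the
range typical of population-scale LC-MS data); SNP effects scaled to an
exact target PVE; drought shifts in log2 units (default mean magnitude
2.0, 80% upward, mirroring the predominance of drought-induced
accumulation in real maize leaf data); redundant duplicate features
(Poisson-mean `redundancy` per metabolite) share retention time within
the grouping tolerance, carry log-scale correlation > 0.95 and alternate
ionization modes, with explicit truth group labels; missingness is
completely at random (default 10%, a typical untargeted-LC-MS level;
real missingness is partly intensity-dependent, which is exactly what
this generator does *not* model — the missingness filter and half-min
imputation are therefore tested only under MCAR).

**Expression and hubs.** cis effects use a SNP within ±20 kb of the
target gene, trans effects one farther than 1 Mb or on another
chromosome; a configurable fraction of effects is active in one
condition only. Hub structure is injected by coupling selected genes
multiplicatively into the log intensities of many metabolites, most
hubs drought-specific (default 60%).

**Phenotype.** Survival rate is a logistic squash of a weighted sum of
`n_drivers` standardized DS metabolites plus Gaussian noise at variance
ratio h². The logistic keeps the trait in [0, 1] (the real trait is an
observed field proportion with no known generative form); it mildly
attenuates linear R² relative to h². Fresh weight and dry mass are
emitted per environment × replicate with genotype effects proportional
to the same latent score, for BLUP fitting. Drivers can be restricted to
the drought-shifted subset (`driver_pool`), which the pipeline uses so
that responsive metabolites out-predict random ones — the contrast the
prediction stage is designed to expose.

Passing tests on these generators show that each estimator recovers what
was injected under its own model assumptions at realistic sizes; they do
not show robustness to intensity-dependent missingness, shared-pathway
correlation structure among metabolites, batch drift, or non-Gaussian
phenotype noise.

## Problem sizes

The default pipeline configuration runs 120 lines × 2000 SNPs × 400
metabolites × 80 genes, completing in well under a minute on one CPU.
The verification runs use 385 lines (the panel scale the methods are
designed for) where the quantity being checked depends on n — mQTL power
at PVE 0.2, stepwise driver recovery at h² 0.65 over 200 candidate
metabolites — and 20 (power) or 10 (stepwise) independent seeds per
estimate; calibration of the genomic-inflation factor uses 5000 SNPs.

## Known limitations

- The MS/MS redundancy criterion is honored only through an external
  compatibility matrix; the package never inspects spectra.
- P3D estimates variance components once per trait; per-SNP exact REML
  would differ slightly for very large effects.
- PVE on the whitened scale is comparable within a scan, not across
  studies.
- The permutation hub null assumes edges are exchangeable across genes;
  correlated expression among genes violates this mildly.
- Single-kernel models only: no multi-locus conditioning, no epistasis,
  no GBLUP on SNPs.
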