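# Methods

## The animal model and its two covariance structures

All estimation and prediction is built on the single-random-effect animal
model y = Xb + Zu + e with u ~ N(0, K σ²ₐ) and e ~ N(0, I σ²ₑ). Fixed
effects are an intercept and sex only. Each phenotyped individual
contributes exactly one record, so Z is a selection matrix and the
marginal covariance of y is K σ²ₐ + I σ²ₑ restricted to the phenotyped
set; the implementation therefore subsets K directly instead of carrying
an explicit Z. Unphenotyped parents remain in K, where they connect
families and receive predicted breeding values.

K is either the pedigree numerator relationship matrix A, built by the
tabular recursion (A_ii = 1 + F_i; unknown parents contribute zero), or
the genomic relationship matrix G by VanRaden's first method,
G = WW′/2Σp(1−p) with W the dosage matrix centered at twice the allele
frequency. Frequencies default to the observed sample; founder-only
frequencies can be supplied (they put G on the base-population scale —
full sibs then average 0.5 — at the cost of larger sampling error when
founders are few, since frequency error inflates every entry by roughly
1/n_founders). Missing dosages are mean-imputed before centering, which
is unbiased at the mean. SNPs monomorphic at the centering frequencies
carry no information and are dropped with a warning. Because G is
singular whenever markers are fewer than individuals (and near-singular
otherwise), inversion adds a diagonal ridge (default 1e-6, escalating
tenfold to at most 1e-2) only when the raw Cholesky fails or the inverse
is inaccurate; the applied ridge is logged.

## REML

With one random effect the restricted likelihood can be profiled to a
single dimension: eigendecompose K = USU′ once, rotate y and X, profile
out σ²ₑ analytically, and maximize over the variance ratio
γ = σ²ₐ/σ²ₑ by bounded Brent search on log₁₀γ ∈ [−8, 8]
(convergence xatol 1e-10). This is exact for this model class, fast
(~50 ms at n = 534), and free of the step-size failures of general
AI-REML iterations. Estimates within 1e-3 of the bounds are flagged as
boundary solutions (σ²ₐ → 0 in the null case). If K has no eigenvalue
spread (e.g. K = I) the two components are not separately identifiable
and the fit raises a dedicated error instead of returning an arbitrary
point on the flat ridge. Standard errors come from the observed
information (central-difference Hessian of the restricted log-likelihood
in (σ²ₐ, σ²ₑ)); the heritability h² = σ²ₐ/σ²ₚ gets a delta-method SE.

## Association scan and SNP effects

The scan is the classical two-step mixed-model ("polygenic first") score
test: fix V̂ = σ̂²ₐK + σ̂²ₑI from the genomic REML fit, form the
fixed-effect projection P = V̂⁻¹ − V̂⁻¹X(X′V̂⁻¹X)⁻¹X′V̂⁻¹, and test each
centered dosage g with T = (g′Py)²/(g′Pg), χ² with 1 df. Monomorphic
SNPs are skipped with a reason. Significance thresholds are Bonferroni
0.05/N genome-wide and per chromosome; the genomic inflation factor is
the median observed statistic over the 1-df null median (0.4549).

One calibration caveat is intrinsic to the two-step design: when the
tested SNPs themselves contribute to G, part of each SNP's own signal is
absorbed into V̂ and the test becomes mildly conservative (we measure
type-I ≈ 0.036 and λ ≈ 0.89 in that regime). The calibration test
therefore separates the two roles — causal loci confined to chromosomes
1–5 generate the polygenic background and build G, while the unlinked
chromosomes 6–29 are scanned — and there the test is calibrated
(type-I ≈ 0.050, λ ≈ 1.00). Scans of a full panel remain the standard
procedure; their mild conservatism is the familiar price of the two-step
approximation.

Follow-up effects refit the SNP as a three-level fixed factor jointly
with sex by GLS under the same V̂ (sex is centered so genotype
coefficients are adjusted class means). α is half the difference of the
homozygote means with the major-allele homozygote first, δ the
heterozygote deviation from the homozygote midpoint; with only two
observed classes δ is undefined and α falls back to the dosage slope.
PVE = 2pq(α+δ(q−p))²/V_A uses V_A = σ̂²ₐ from the same-matrix REML fit
without the SNP, and drops the δ term for two-class markers.

## BLUP and cross-validation

Breeding values solve Henderson's mixed-model equations with K⁻¹λ
(λ = σ̂²ₑ/σ̂²ₐ) in the animal block. Validation individuals keep their
row in K but contribute no record — their phenotypes never enter the
right-hand side, which a test verifies by perturbing masked phenotypes —
so their EBVs are predicted purely through relationships. Cross-
validation partitions the phenotyped offspring into k = 5 folds (the
first n mod k folds take the extra animal), repeats the partition 5
times, and scores each fold as r(EBV, y)/h. Variance components are
reused from the full-data fit by default (refit-per-fold available); h
is the square root of the full-data REML h² under the predictor's own
relationship matrix. In the marker-density sweep this per-panel h would
add pure estimation noise — a sparse panel's G yields a downward-biased
h² whose square root inflates apparent accuracy — so the sweep instead
fixes one h per method (full-panel G-REML for GBLUP, A-REML for PBLUP)
and reuses identical fold partitions across methods and densities for a
paired comparison.

## The synthetic populations

The generator inverts the analysis model on a realistic design. Defaults
(chosen once, from the study design the package emulates): 28 sires and
60 dams crossed into 61 unique full-sib families (sires and dams cycle
over families, so one dam founds two families); 534 offspring total with
at least 6 per family, the remainder multinomially distributed; 29
chromosomes of 1 Morgan; 5,000 SNPs with uniform(0.05, 0.5) allele
frequencies grouped into short (~2-SNP) contigs; two traits, weight
(mean 112 g, SD 24 g, h² = 0.60) and length (mean 214.1 mm, SD 16.1 mm,
h² = 0.51), with genetic and environmental correlations of 0.96; a sex
effect of +6 g / +4 mm on males (a quarter phenotypic SD — the design
fits sex as a fixed effect, so only its presence matters, not its size).

Founders descend from a finite base population: 50 individuals random-
mate for 10 generations starting from linkage-equilibrium haplotypes,
and the 88 founders are offspring of random pairs from the final
generation. This matches the history of commercial Atlantic salmon
strains (founded around the early 1970s, generation interval 3–4 years,
reported effective sizes near 50) and gives founder haplotypes the
background LD and low-level relatedness through which genomic prediction
earns its advantage over the pedigree; `n_base_generations=0` switches
to independent founders for oracle tests with exact binomial/HWE
expectations. Offspring are produced by gamete dropping — Poisson
crossover counts per chromosome, uniform positions — so trios are
Mendelian-consistent by construction.

Phenotypes: 500 causal SNPs (an effectively polygenic architecture)
receive bivariate-normal effects; breeding values and environmental
deviations are rescaled by a per-trait scalar so the realized variances
across phenotyped offspring equal σ²ₐ = h²σ²ₚ and σ²ₑ = (1−h²)σ²ₚ
exactly (the scalar preserves the configured correlations), so every
replicate simulates the same true parameters. Optional switches confine
causal loci to chosen chromosomes (used for null-calibration designs)
or plant a single QTL with a specified share of σ²ₐ (used for power and
effect-recovery tests). Parents are genotyped but unphenotyped, as in
the emulated study.

What the generator does not emulate: genotyping error and missingness
(QC filters are exercised by injected corruption instead), selection or
multi-generation breeding, sequence-level mutation, and the exact LD
landscape of any real strain. Passing tests therefore demonstrate that
the estimators recover known truth under the assumed model and design,
not that real salmon data would yield the same numbers.

## Problem sizes and numerical choices

Test and acceptance runs use the matched design (534 offspring, 5K
SNPs) for heritability and cross-validation — 20 replicates for REML
recovery, 5 populations × 5 CV replicates × 5 folds for prediction — a
20K-SNP panel for the density sweep (full vs 5K vs 0.5K), and a 25K-SNP
panel for the ~20K-test null calibration; each piece runs in seconds to
a couple of minutes on one CPU. Ties in LD pruning resolve left-to-right
within chromosome, keeping the earlier SNP (higher MAF first at equal
positions); contig deduplication keeps the highest-MAF SNP. Dosages
always count the minor allele, with frequency-0.5 ties broken toward the
lexicographically smaller allele so PED round trips are exact.

## Known limitations

Single-trait REML only (the bivariate trait structure is simulated, but
genetic correlations are not estimated); no dominance or single-step
matrices; the score test's full-panel conservatism is reported, not
corrected (no GRAMMAR-γ rescaling); cross-validation assumes the
phenotyped set is the offspring generation. Observed CV accuracies on
the synthetic design run a few hundredths below the real-data values the
design emulates — the gap is the unrecoverable detail of the actual
broodstock's relatedness and LD.
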