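# Methods

## The problem

Enteric methane from cattle is costly to measure directly (respiration
chambers), so in fattening populations with routine performance recording
it can instead be *predicted* from on-farm traits, and the predicted
traits treated as phenotypes for genetic evaluation.  This package
implements that full chain for a progeny-testing design in beef cattle:
genotyped sires, ungenotyped steer progeny with fattening records.

1. **Trait engine.**  From longitudinal weighing/intake records it derives
   the period base traits — mean body weight (BW, kg, interval-weighted
   mean of successive weigh-in midpoints), daily gain (DG, kg/day, final
   minus initial weight over elapsed days), dry matter intake (DMI,
   kg/day, individual concentrate plus herd-unit-averaged roughage), TDN
   (% of DMI) and roughage rate (Rrate, %) — then the predicted methane
   traits:

   - CH4 (L/day) = −676.7 + 0.04194·BW + 29.88·DMI + 7.883·TDN + 4.367·Rrate
   - CH4S (L/day) = −17.766 + 42.793·DMI − 0.849·DMI² (the
     national-inventory quadratic)
   - CH4/DMI (L/kg) = −52.24 − 1.193×10⁻³·BW − 5.905·DG + 1.077·TDN + 0.5008·Rrate
   - MCF (%) = −11.43 − 5.308×10⁻⁴·BW − 1.223·DG + 0.2336·TDN + 0.1157·Rrate

   plus Koch-style feed-efficiency traits (FCR = DMI/DG; RFI = residual of
   DMI on BW^0.75 and DG; RG = residual of DG on BW^0.75 and DMI; RIG =
   z(RG) − z(RFI)).  Phenotypes are filtered to mean ± 3 SD per trait, in
   a single pass (mean/SD computed once on non-missing values, not
   iterated).

2. **Variance components.**  Animal model y = Xb + Zu + e with fixed
   contemporary-group classes (year-step-station-herd) and a linear age
   covariate, u ~ N(0, K σ²ᵤ) for K = A (pedigree NRM) or K = H
   (single-step), e ~ N(0, I σ²ₑ).  Heritability = σ²ᵤ/(σ²ᵤ+σ²ₑ).

3. **Single-step GWAS.**  GEBV under the H model, SNP effects backsolved
   as β̂ = D W′(W D W′)⁻¹ â_g, optional iterative SNP weighting
   (d_j ∝ β̂_j² 2p_j q_j), per-window percentage of genetic variance
   var(Σ W_j β̂_j)/σ²ₐ × 100 in overlapping 100-kbp windows, QTL regions
   from windows above 5%, and per-SNP frequentist p-values
   2(1 − Φ(|β̂_j|/sd(β̂_j))) with a Bonferroni genome-wide threshold.

## REML

Single-trait REML is average-information (AI) REML computed after a
one-off eigendecomposition of the record-level kinship M = Z K Z′.  In
the rotated basis both V̇ matrices (M and I) are diagonal, so the
likelihood, score and AI matrix cost O(n p²) per iteration after the
O(n³) decomposition.  Updates are AI steps; a step leaving the parameter
space is first rescaled to the boundary, and if no AI candidate increases
the likelihood, a damped EM-style step (a positive diagonal scaling of
the score, halved until the likelihood does not decrease) is taken, so
the log-likelihood trace is non-decreasing.  Convergence is
|Δ log L| < 1e-8, cap 200 iterations (error with the trace beyond that).
Standard errors come from the inverse AI matrix; h² SE by the delta
method.  Variances are floored at 1e-8 of the phenotypic variance, so a
null trait converges to the boundary rather than crossing it.

The two-trait model uses the same rotation: records decouple into 2×2
blocks Σᵢ = G₀λᵢ + R₀.  G₀ and R₀ are parameterised by Cholesky factors
(log-diagonals), which enforces positive semidefiniteness, and the REML
log-likelihood is maximised with L-BFGS-B on the six parameters after
standardising both traits to unit variance.  A quasi-Newton search was
chosen over AI iteration here because the rg → 1 boundary (reached
mechanically when one trait is a near-linear function of the other, as
with DMI and its quadratic CH4S prediction) makes the AI matrix singular;
L-BFGS-B with bounded log-diagonals walks into that corner without
failing.  SEs come from the numerical observed information plus the delta
method; exactly at the boundary they are unreliable and the duplicated
variance can drain into either G₀ or R₀ along the likelihood ridge —
the genetic correlation itself is stable.  Both traits must be recorded
on the same animals (complete cases); this matches the generator's
design, where every steer has every trait.

## Kinship matrices

A is built by the tabular method; A⁻¹ directly by Henderson's rules with
inbreeding from a memoised recursive kinship (the recursion the
Meuwissen–Luo algorithm unrolls); A₂₂ by dense subsetting.  G follows
VanRaden with observed allele frequencies among the genotyped animals and
optional diagonal SNP weights; because column-centering makes W D W′
singular by construction, G is blended as G* = (1−α)G + αA₂₂ (default
α = 0.05, configurable; α = 0 available for exactness tests).  H⁻¹ adds
(G*⁻¹ − A₂₂⁻¹) into the genotyped block of A⁻¹; the dense H itself is
assembled from the standard partitioned form when a REML fit needs K = H.
SNP QC drops markers with MAF < 0.01, call rate < 0.95 or Pearson
chi-square HWE p < 0.001 (computed on hard genotype calls only), then
mean-imputes remaining missing dosages to 2p_j — which preserves allele
frequencies and makes the filter idempotent.

## ssGWAS numerics

At fixed variance components the mixed-model equations for the
single-step model are solved in their GLS form over the phenotyped
records (V = H_pp σ²ₐ + I σ²ₑ; â_g = σ²ₐ H_gp V⁻¹(y − Xb̂)), which is
algebraically identical to Henderson's equations (asserted in tests) and
much cheaper when the weight-refinement loop rebuilds G(D) and H each
iteration.  The backsolve and the SNP-effect variances use the blended
relationship (W D W′ ≈ G*·Σ2p_jq_j), consistently with the G used in the
model; a pseudo-inverse path exists for raw W D W′.  Var(β̂) is the
quadratic form D W′(·)⁻¹ Var(â_g)(·)⁻¹ W D with
Var(â_g) = σ⁴ₐ H_gp P H_pg ≡ G*σ²ₐ − PEV; negative diagonals from
round-off are clipped to zero and logged.  p-values always come from the
single unweighted (D = I) run; effect/window tables from the configured
number of weight refinements (default 2).

Windows are anchored at every SNP and span [pos, pos + 100,000) bp
(half-open, 1-based positions); the window statistic is the sample
variance (ddof = 1) over genotyped animals of the summed member-SNP
contributions, divided by the REML σ²ₐ (not the realized GEBV variance).
QTL regions merge overlapping windows above the 5% threshold; a region
reports its maximum member-window percentage and the number of
consecutive map SNPs it spans.

## The synthetic population

The generator emulates the analysed design rather than any particular
dataset: a two-tier pedigree (unrelated founder sires and dams, each dam
mated once, default 362 sires × 13 steer progeny), contemporary groups
assigned uniformly at random (default 348 levels from an
11×10×2×3 year-step-station-herd layout), age at start ~ N(273, 15²) days.

Founder haplotypes come from a first-order Markov chain along each
chromosome.  Binary markers with mismatched allele frequencies have a
correlation ceiling, so the chain's decay exponent is calibrated by
bisection against the *analytically computed* mean r² between loci
~100 kbp apart until it hits the configured target (default r² = 0.2);
the realized LD then matches the target within Monte-Carlo noise.  MAF
are uniform on [0.05, 0.5] with random allele orientation.  Progeny
genotypes are gene-dropped with Haldane recombination at 1 cM/Mbp and
independent assortment across chromosomes.

Breeding values are the sum of (a) QTL effects at chosen SNPs absorbing
stated fractions of the additive variance, (b) an optional whole-genome
marker component, and (c) a gene-dropped multivariate-normal polygenic
remainder (Mendelian sampling variance 0.5 − 0.25(F_s + F_d) per known
parent pair).  Marker-derived components are rescaled so their realized
variance among phenotyped animals equals the target fraction
(`calibrate_genetic_variance`, on by default), so recovery studies test
the estimator, not the generator's sampling noise.  Phenotype = trait
mean + contemporary-group effect + age effect + breeding value +
residual.

Direct-trait defaults (means, additive and residual variances) are those
of the emulated Japanese Black fattening population — e.g. CH4:
251.3 L/day, σ²ᵤ = 148.3, σ²ₑ = 102.8 (h² = 0.59); DMI: 8.96 kg/day,
0.24/0.18 (h² = 0.57).  The contemporary-group effect SD per trait was
set once so the total phenotypic SD matches that population's printed SD
(for CH4, cg SD 15 gives total SD ≈ 21.9 vs 22.4).  Base-trait mode
additionally simulates BW/DG/TDN/Rrate (plausible stand-in
distributions; their source descriptives are not published in the main
trait table), builds the 8-weekly fattening records
(weeks {1, 9, 17, 25, 33, 41, 49, 52}, linear growth, individual
concentrate, roughage reported as the mean of 13-steer herd units), and
re-derives all traits through the trait engine.

What the generator does **not** emulate: selection and multi-generation
pedigree depth, realistic coalescent LD and allele-frequency spectra,
genotyping/imputation error, heterogeneous variances across groups, and
structured (confounded) contemporary groups.  Passing recovery tests
therefore show the estimators are correct under the stated model, not
that the model fits any particular real dataset.

## Problem sizes

The canned studies (`methagen.emulation`) use ~2,000 phenotyped progeny
of 200–334 sires and 2,000–3,000 SNPs: large enough that h² replicates
have SE ≈ 0.02–0.04 on the mean of 10–12 replicates and a 30%-variance
QTL is localized in ≥ 8/10 seeds, small enough that the whole suite runs
in minutes on one core.  All randomness flows through a single integer
seed per study.

## Known limitations

- Dense linear algebra throughout: fine to ~10⁴ animals, not a
  500K-marker national evaluation.
- Bivariate REML requires complete cases and pedigree kinship only
  (H-based bivariate models are out of scope).
- The p-value covariance treats the REML variance components as known.
- Exactly degenerate two-trait data (duplicated trait) leave the
  variance partition, though not the correlation, unidentified at the
  likelihood ridge.
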