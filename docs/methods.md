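# Methods

This note documents the statistical models, the numerical machinery, the
simulator's scope, and the design decisions behind `diallelgp`.

## Trait engineering

**Dry matter.** Tubers are weighed in air (`Wa`, kg) and under water
(`Ww`); dry-matter percentage uses the empirical specific-gravity
calibration `DM% = 214 (Wa/(Wa−Ww) − 0.988)`. The function rejects
non-positive buoyancy denominators. Extreme values (e.g. > 40%) are
*flagged, never removed*: degenerate clones drop out of populations for
other reasons, and deleting extremes without a measurement-level reason
biases variance estimates.

**Graded traits.** Ordinal 1–9 scores whose low end is sparsely used are
pooled onto 1–6: grades ≤ 4 map to 1, the rest shift down so 9 maps to 6.
Graded traits are then treated as Gaussian responses — defensible with
thousands of observations per trait, and it keeps every trait inside one
REML machinery. Ordinal/threshold models are deliberately out of scope.

**Dixon's Q filter.** Tuber length/diameter batches (3 ≤ n ≤ 200) are
cleaned iteratively: `Q = |suspect − nearest neighbour| / range` for the
more extreme end point, compared two-tailed against `Qcrit(n, conf)`.
Critical values for n ≤ 30 are the standard two-tailed tables at 90/95/99%
confidence (default 95%); for 30 < n ≤ 200 we extrapolate by least squares
with `Qcrit ≈ a + b/√n`, which fits the tabulated values to < 0.01 and
decays monotonically. Zero-range batches and batches below n = 3 pass
through unchanged (the latter with a warning on the report).

## Relationship matrices

**Tetrasomic pedigree A.** Coancestry θ_ij is the probability that random
alleles from i and j are identical by descent (with replacement for i = j),
and A = 4θ, so outbred founders have diagonal 1 and
F = (A_ii − 1)/3. The recursion for an offspring of sire s and dam d:

* cross terms: θ_k· = ½(θ_s· + θ_d·);
* gamete-internal IBD: φ_p = w + (1 − w) F_p, where w is the
  double-reduction rate (probability a gamete carries two copies of one
  parental homolog);
* offspring inbreeding: F_k = (φ_s + φ_d)/6 + (2/3) θ_sd — of the six
  allele pairs in a tetraploid, one falls inside each parental gamete and
  four across;
* θ_kk = (1 + 3F_k)/4.

Unknown parents are unrelated non-inbred founders (their gametes still
carry double reduction at rate w). The recursion is validated not against
printed values but against an independent **gene-dropping oracle**: four
uniquely labelled alleles per founder propagated through the same meiosis
model, with A estimated from label-match frequencies over 10^5 replicates.
Agreement is within ±0.01 for nested pedigrees with crosses, selfs and
backcrosses at w ∈ {0, 0.1}.

**VanRaden G for tetraploids.** Dosages are on 0–4 (non-integer allowed).
Missing entries are imputed to the marker mean computed from observed
entries only; allele frequencies come from the same observed entries;
`Z = dosage − 4p` and `G = ZZ'/(4 Σ p_j(1−p_j))` — the ploidy-4 analogue of
the diploid denominator. Monomorphic markers are dropped; an all-monomorphic
panel is an error. Genomic inbreeding reuses the pedigree formula on
`diag(G)`. Note that with frequencies estimated from an F1-heavy panel the
genomic F can be negative; it is reported as computed.

**Single-step H.** G is first rescaled so its mean diagonal equals that of
the pedigree block of the genotyped clones
(`G_adj = G · mean(diag A22)/mean(diag G)`); the scaling is idempotent. At
the default `tau = omega = 1` the direct block identity is used
(`H22 = G_adj`, `H12 = A12 A22⁻¹ G_adj`,
`H11 = A11 + A12 A22⁻¹ (G_adj − A22) A22⁻¹ A21`), which costs one solve
with A22 and is exact; other `tau`/`omega` go through the blended inverse.
Near-singular blocks get escalating diagonal jitter with a logged record;
failure beyond 1e-4 relative jitter raises. Positive semi-definiteness can
be enforced by eigenvalue clipping at −1e-8 (logged).

## REML estimation

All models are special cases of `y = Xb + Σ_r Z_r u_r + e` with
`u_r ~ N(0, C_r ⊗ K_r)` — `C_r` a 1×1 or 2×2 trait covariance, `K_r` a
relationship matrix or the identity — and residual either iid or, for
bivariate fits, a 2×2 per-plot covariance applied to observations sharing
a plot. Estimation maximises the restricted likelihood

```
−2 log L = log|R| + Σ_r (q_r log|C_r| + d_r log|K_r|) + log|C| + y'Py
```

evaluated through the mixed model equations (coefficient matrix `C`), so
no n×n covariance is ever inverted. Each iteration:

1. assemble and Cholesky-factorise `C`; solve for BLUE/BLUP;
2. score vector and **average-information** matrix from MME identities
   (traces via blocks of `C⁻¹`, quadratic forms via `Z_r'Py`);
3. Newton step `θ += AI⁻¹ s` with an **active set**: variances proposed
   below the floor are pinned there and the system re-solved for the rest;
   covariances sitting on the correlation cap (|r| ≤ 0.999) are held so the
   step moves along the constraint surface;
4. step halving guarded by the likelihood; if no AI step is acceptable, a
   monotone **EM-REML** step is taken instead.

Convergence: relative change of −2 log L below 1e-8 (at most 100
iterations; non-convergence raises a diagnostic error carrying the
iteration trace). Variance floors are 1e-6 of the phenotypic variance;
components ending at the floor are flagged as boundary estimates, not
errors. Standard errors come from the inverse AI matrix; correlation CIs
use the delta method on that matrix. The engine is validated against (a)
the explicit V-form REML likelihood maximised by Nelder-Mead on toy data
(agreement to 1e-4), (b) closed-form balanced one-way ANOVA estimators,
(c) statsmodels MixedLM on unbalanced random-intercept data, and (d)
brute-force score vectors for the bivariate parametrisation.

**Fixed effects.** One combined block-by-year factor plus cytoplasm type;
reference levels (first block-year, W/γ cytoplasm) are absorbed, so the
cytoplasm solutions are directly the contrasts against W/γ, reported with
SEs, percent-of-mean (100·|contrast|/trait mean) and a 95% CI significance
flag. Rank-deficient design columns are dropped by pivoted QR.

**BLUP outputs.** PEVs are the diagonal of the additive block of the
inverse MME coefficient matrix (variance scale); EBV intervals are
`â ± 1.96 √PEV`. A clone with no records and no relatives keeps EBV 0 and
PEV `σ_a² M_ii`.

**Double-reduction profile.** `profile_double_reduction` rebuilds A and
refits REML over a grid w ∈ [0, 0.25] and reports −2 log L with the argmin.
In a pure diallel the likelihood has little leverage on w — without selfing
w only inflates F1 diagonals by +w — so at a few hundred clones the profile
is nearly flat (spreads of ~1 unit); the test suite demonstrates recovery
on selfing-series pedigrees, where inbreeding accumulates at a w-dependent
rate, and flatness on null data. Detecting small w reliably requires
population sizes of the order of the original field experiment.

## Cross-validation

Clones are split into k = 8 equal folds (default), repeated (default 30;
smaller in tests), with fold membership derived from
`SeedSequence([seed, repeat])` for reproducibility. Variance components are
estimated once on the full data and held fixed as priors; per fold, the
validation clones' phenotype records are removed while their pedigree and
genomic links remain (the single-step use case), the MME are re-solved,
and validation EBVs are pooled within a repeat and correlated with the
clones' mean corrected phenotypes `ȳ_c = mean(y − x'b̂)` (fixed effects
from the full-data model being validated). By default only F1 clones are
validated; parents act as information donors. Prediction accuracy is
`r/√h²_design` with `h²_design = σ_a²/(σ_a² + σ_f² + σ_l² + σ_e²/n_rep)`;
n_rep is the median record count per clone. The dispersion slope regresses
`ȳ_c` on EBV, so slopes above 1 mean over-shrunk (deflated) EBVs.

A structural point the tests make explicit: E[slope] = 1 holds for an
additive-only generator. When family or line variance is present, the
corrected means contain effects that covary with the training information
behind each validation EBV, pushing the slope above 1 — the same pattern
the field data show. The calibration tests therefore use the
additive-only configuration, and interval coverage is checked at known
variance components (the property of the BLUP machinery, not of REML).

## Bivariate models and correlations

Trait pairs are stacked with block-diagonal fixed designs; additive
effects follow `N(0, C ⊗ M)`, family effects `N(0, C_f ⊗ I)`, line effects
a 2×2 covariance when both traits have replicates (a univariate term when
only one does; the cross-covariance is then not defined and the line term
is excluded from the phenotypic correlation). Residuals of the two traits
are correlated only for records from the same plot; when the traits share
no plots (e.g. recorded in disjoint years) the residual covariance is
fixed at 0, flagged non-estimable, and the phenotypic correlation is
reported undefined. Genetic correlation: `C12/√(C11 C22)`. Phenotypic
correlation: the sum of additive + line + family + residual covariances
over the geometric mean of the total variances — the exact composition of
the published formula is not recoverable from its source, so this standard
composition is an explicit assumption of the package.

## The simulator

`simdiallel` generates the study conditions end to end:

* **Parents** (default 12 at desk scale; `full_scale()` gives the
  18-parent layout) with cytoplasm types T/β : D : W/γ at 0.56/0.25/0.19
  by largest-remainder allocation; W/γ parents are always male-sterile,
  plus `extra_male_sterile` random others (male sterility in the field is
  not confined to W/γ).
* **Crossing plan**: one direction per unordered pair (reciprocals
  excluded by default; the real design contained almost none), sterile
  sires excluded, and a random `infertile_fraction` (default 0.35 at desk
  scale, chosen so 12 parents yield ≈ 40 families; the observed rate in
  the 18-parent experiment was ≈ 50%) of permitted crosses dropped.
  Default 25 offspring per family ≈ 1000 clones.
* **Genomes**: 500 biallelic markers, allele frequencies Beta(2, 2)
  (intermediate frequencies — a post-MAF-filter spectrum), founder
  homologs sampled independently, meiosis per marker (no linkage) with
  double-reduction rate w. Marker effects are standard normal, jointly
  drawn with any configured cross-trait correlation, and rescaled so the
  base-population additive variance equals σ_a² exactly at the generating
  frequencies. Breeding values are **genotypic** (sums of allele effects
  through gene dropping), which makes A, G and H mutually consistent by
  construction; the realized genetic correlation of a finite marker panel
  (recorded in `SimTruth`) deviates from the nominal setting by a few
  percent and is the correct recovery target.
* **Phenotypes**: `y = μ + block + cytoplasm + a + l + f + e` with blocks
  of 28 plots, block effects N(0, 0.5²) (modest soil heterogeneity),
  shared field layouts across traits so cross-trait residual covariances
  are identifiable from same-plot records, and jointly drawn plot
  residuals honouring configured residual correlations. The default trait
  mirrors the published dry-matter setting: mean 20.26, components
  2.42/0.38/4.61/0.70, one replicate in year 1 and two in year 2, line
  effect nested in year, cytoplasm shifts −2.24 (T/β) and −1.45 (D).
* **Genotyped panel**: parents plus a random 15% of offspring (the study's
  genotyped fraction), with 17% of dosage entries masked as missing.

What the simulator does **not** model: linkage and recombination maps,
dominance/epistasis as explicit marker interactions (family and line
effects are exchangeable Gaussian draws, which is exactly the fitted
model's assumption), genotype-by-environment interaction, inbreeding
depression, and selection/attrition of degenerate clones. Passing
recovery tests therefore demonstrates the estimation machinery is correct
under the model's own assumptions — not that the model captures every
feature of field data.

## Problem sizes used in tests and the acceptance script

Fits in the test suite run on diallels of roughly 300–500 clones (12–14
parents, 8–12 offspring per family, 2–3 replicates) — large enough that
component estimates have usable standard errors, small enough that a full
AI-REML fit takes a few seconds. Parameter-recovery checks use 20 seeds
(univariate) and 6 seeds (bivariate) and compare mean estimates against
the generating values within twice the empirical standard error. The
acceptance script runs the full default desk-scale population
(≈ 1060 clones, ≈ 3190 records) for the univariate/single-step analyses
and a 400-clone pair for the bivariate stage.

## Known limitations

* Dense linear algebra throughout: pedigrees beyond ~5000 clones make the
  MME factorisation the bottleneck; no sparse-inverse (APY-style)
  approximations are provided.
* Bivariate only — no joint > 2-trait models.
* The Dixon-Q regression beyond n = 30 is an extrapolation of the
  published tables; exact replication of any particular historical
  filtering run is not possible without the original coefficients.
* REML variance ratios for low-information designs (few parents) have
  large sampling variance; SCA/GCA ratios from single small simulations
  scatter widely around the generating value, as their standard errors
  indicate.
* Cytoplasm effects are confounded with dam identity in a diallel with
  few dams per type; contrasts carry honest (large) SEs.
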