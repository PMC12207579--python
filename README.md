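# diallelgp

Combining-ability analysis and genomic prediction for **autotetraploid
diallel populations**, built around the workflow used for elite tetraploid
potato (*Solanum tuberosum*) breeding trials: an incomplete diallel of elite
parents, thousands of F1 clones phenotyped for agronomic traits, a subset
genotyped by sequencing, and breeding values predicted with pedigree,
genomic or combined single-step relationship matrices.

## Who this is for

Quantitative geneticists and breeders who need to

* separate **additive** genetic variance (what parents transmit) from
  **non-additive** family-specific variance (SCA) and clone-specific "line"
  variance in a clonally propagated autotetraploid crop,
* predict breeding values (EBVs) for parent selection, with honest
  prediction error variances,
* quantify how much genotyping a panel of clones adds to prediction
  accuracy via single-step GBLUP, and
* estimate genetic and phenotypic correlations between traits.

## The model

Every analysis fits the linear mixed model

```
y = X b + Z_a a + Z_l l + Z_f f + e
```

* `b` — fixed block-by-year and cytoplasm-type effects,
* `a ~ N(0, M sigma_a^2)` — additive genetic effects over a relationship
  matrix `M`: tetrasomic pedigree `A` (with optional double-reduction rate
  `w`), VanRaden genomic `G` from 0–4 allele dosages
  (`G = ZZ' / (4 Σ p_j(1-p_j))`), or the single-step `H` combining both
  (Martini blend, `tau = omega = 1` default),
* `l ~ N(0, I sigma_l^2)` — repeatable clone ("line") effects, nested in
  year for multi-year traits,
* `f ~ N(0, I sigma_f^2)` — full-sib family (SCA) effects keyed by the
  unordered sire–dam pair,
* `e ~ N(0, I sigma_e^2)` — plot residuals.

Variance components are estimated by **average-information REML** with
EM fallback; BLUPs and PEVs come from Henderson's mixed model equations.
Derived statistics follow breeding convention: a parent's EBV equals twice
its general combining ability, the SCA/GCA ratio is
`sigma_f^2 / (sigma_a^2 / 4)`, plot heritability is
`sigma_a^2 / (sigma_a^2 + sigma_f^2 + sigma_l^2 + sigma_e^2)`, prediction
accuracy is the cross-validated correlation `r(EBV, ȳ_c)` divided by the
square root of the design heritability, and the dispersion slope of
corrected phenotype means on EBVs equals 1 for correctly scaled
predictions.

A bundled simulator (`diallelgp.simdiallel`) generates tetrasomic
incomplete diallels by **gene dropping** — maternal cytoplasm inheritance
with male-sterile W/γ types, per-marker tetrasomic meiosis with optional
double reduction, genotypic breeding values, and the full variance
structure above — so every stage is testable without external data.

## Worked example

```python
from diallelgp import simdiallel, kinship, lmm

cfg = simdiallel.SimConfig(n_parents=12, offspring_per_family=10,
                           infertile_fraction=0.35, n_markers=300)
sim = simdiallel.simulate_population(cfg, seed=7)
A = kinship.build_A_tetraploid(sim.pedigree, double_reduction=0.0)
cyto = sim.pedigree.set_index("clone_id")["cytoplasm_type"]

spec = lmm.ModelSpec(trait="dry_matter", line_nested_in_year=True)
vc = lmm.fit_reml(spec, sim.phenotypes, A, sim.pedigree, cyto)
h2 = lmm.heritability(vc, n_rep=3)
print(f"sigma2_a = {vc.sigma_a:.2f} +- {vc.se['sigma2_a']:.2f}")
print(f"h2 (plot) = {h2['h2_plot']:.2f}")
print(f"SCA/GCA ratio = {lmm.sca_gca_ratio(vc):.2f}")
sol = lmm.solve_mme(spec, sim.phenotypes, A, vc, sim.pedigree, cyto)
print(lmm.cytoplasm_contrasts(sol).round(2))
```

prints (352 clones, 1056 plot records; the generator's dry-matter-like
trait has true components 2.42 / 0.38 / 4.61 / 0.70 and cytoplasm shifts
−2.24 (T/β) and −1.45 (D) against the W/γ reference):

```
sigma2_a = 1.85 +- 0.55
h2 (plot) = 0.25
SCA/GCA ratio = 0.85
                contrast    se  percent_of_mean  significant
cytoplasm_type
W/g                 0.00  0.00             0.00        False
D                  -1.77  0.71             9.43         True
T/b                -2.72  0.63            14.50         True
```

The estimates sit within their standard errors of the generating values;
the cytoplasm contrasts recover the injected maternal effects with the
correct sign and magnitude.

The same analyses are available from the shell:

```bash
diallelgp simulate --out simdir --seed 7
diallelgp build a --ped simdir/pedigree.csv --out A.tsv
diallelgp fit --trait dry_matter --matrix h --pheno simdir/phenotypes.csv \
              --ped simdir/pedigree.csv --dosages simdir/dosages.tsv \
              --out fit.json
diallelgp cv --trait dry_matter --matrix a --pheno simdir/phenotypes.csv \
             --ped simdir/pedigree.csv --k 8 --repeats 30 --seed 17 \
             --out cv.json
diallelgp run --config run.yaml      # full pipeline from one YAML config
```

## Layout

| module | contents |
| --- | --- |
| `diallelgp.traitprep` | dry-matter formula, grade recoding, Dixon's Q filter, descriptive stats |
| `diallelgp.kinship` | tetrasomic `A`, VanRaden `G`, scaled `G`, single-step `H`, inbreeding |
| `diallelgp.lmm` | AI-REML, MME solutions, heritability, SCA/GCA, cytoplasm contrasts, double-reduction profile |
| `diallelgp.multitrait` | bivariate REML, genetic/phenotypic correlations |
| `diallelgp.crossval` | fold plans, corrected phenotype means, prediction accuracy, dispersion |
| `diallelgp.simdiallel` | tetrasomic diallel simulator and gene-dropping oracle |
| `diallelgp.pipeline` / `diallelgp.cli` | YAML-driven orchestration and the `diallelgp` command |

See `docs/methods.md` for the statistical methods, numerical choices and
known limitations.
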