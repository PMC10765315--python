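# targetmr

Cis-Mendelian-randomization (cis-MR) drug-target analysis for circulating
proteins, built for studies that ask whether genetically predicted plasma
protein levels causally influence a disease outcome — the motivating use
case being cardiovascular-disease-related proteins and the hypertensive
disorders of pregnancy (gestational hypertension and preeclampsia).

It is aimed at statistical geneticists and epidemiologists who have
region-level GWAS summary statistics for protein exposures (cis-pQTLs) and
binary outcomes, plus an LD correlation matrix for each cis region, and who
want the full drug-target MR workflow without genotype-level data.

## What it computes

**Instruments.** For each protein, cis variants within ±200 kb of the
encoding gene are filtered at *P* < 1×10⁻⁴ and greedily clumped at
*R*² < 0.4 (both configurable); instrument strength is summarised by the
mean per-variant *F* = (β/se)².

**Causal estimators.** With harmonized exposure effects *b_X*, outcome
effects *b_Y* and LD correlation ρ, the correlated-instrument IVW estimate
is the generalized-least-squares fit

θ̂ = (b_Xᵀ Ω⁻¹ b_X)⁻¹ b_Xᵀ Ω⁻¹ b_Y,  Ω_ij = se_{Y,i} se_{Y,j} ρ_ij,

with fixed effects for 2–3 variants and multiplicative random effects
(residual scale floored at 1) for more; a Wald ratio θ̂ = b_Y/b_X for a
single variant. Sensitivity estimators: MR-Egger (GLS with an intercept
absorbing directional pleiotropy, variants oriented to b_X ≥ 0) and
principal-components IVW on the eigenvectors covering 99% of the weighted
LD variance. Steiger filtering removes variants explaining more variance in
the outcome than the exposure, and reverse-direction MR (outcome as
exposure) guards against reverse causation. θ is reported per SD of
genetically predicted protein, with exp(θ) as the odds ratio for binary
outcomes.

**Pipeline.** Benjamini–Hochberg FDR over the protein–outcome panel; a
10-analysis sensitivity battery (IVW at *R*² ∈ {0.001, 0.01, 0.1, 0.2, 0.6,
0.8}, instrument *P* ∈ {1×10⁻⁶, 5×10⁻⁸}, PCA-IVW, MR-Egger); a
three-criterion robustness verdict (primary significant, all sensitivity
estimates directionally consistent, reverse-MR *p* > 0.05); a phenome-wide
scan at the lenient threshold *p* < 0.05/n_proteins with each significant
hit classified *beneficial* or *adverse* relative to the HDP-risk-lowering
direction of the protein.

**Colocalization.** Wakefield approximate Bayes factors per variant and
enumeration posteriors PP0–PP4 over the five region hypotheses; PP(H4) >
0.80 is the usual strong-evidence convention for a shared causal variant.

**Gestational trends.** Study-level log₁₀ ratios of mean protein
concentration (hypertensive vs normotensive pregnancy) regressed on
gestational week, weighted by study sample size, with t-based inference —
the meta-regression used to ask whether a biomarker's association with HDPs
reverses across gestation.

**Synthetic data.** A generator for region-level summary statistics under
AR(1) LD with known sparse pQTL effects, a known causal effect and optional
pleiotropy, and for observational study tables with a known per-week trend,
so that every stage is testable end-to-end without any data download.

## Worked example

```python
import targetmr as t

# a 50-variant cis region with 3 true pQTLs and causal effect 0.25
h, truth = t.simulate_harmonized(t.SimConfig(theta=0.25, seed=7))
inst = t.select_instruments(h)          # P<1e-4, R2<0.4
est = t.estimate_auto(inst.harmonized)  # Wald / fixed IVW / random IVW
prof = t.run_sensitivity_battery(h)
```

This prints (via the CLI or your own formatting):

```
instrument: 13 variants, mean F = 146.4
ivw_random: theta=0.256 se=0.012 95%CI [0.232, 0.280] p=1.7e-93 OR=1.29
battery: 10 analyses; verdict: robust
```

The instrument is strong (mean F ≫ 15, so weak-instrument bias is
negligible), the random-effects IVW recovers the simulated causal effect
0.25 within one standard error, every sensitivity analysis agrees in sign
and the pair is graded robust. On a region simulated with a *single* shared
causal variant for both traits, colocalization concentrates on H4:

```
coloc PP0..PP4: [0.0, 0.001, 0.0, 0.0, 0.999]
```

while the three-causal-variant region above correctly favours H3 (distinct
variants), since enumeration coloc assumes at most one causal variant per
trait. A 30-study synthetic review table generated with a 0.039/week trend
gives:

```
trend: slope=0.0403/week 95%CI [0.0377, 0.0429] p=1.4e-23
```

The same workflow is scriptable from the shell: `targetmr simulate`,
`targetmr run`, `targetmr sensitivity`, `targetmr phewas`, `targetmr coloc`,
`targetmr trend` (see `targetmr --help`).

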