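# Methods

## Model and assumptions

The package implements two-sample cis-MR on summary statistics. For variant
*j* in a protein's cis region, `b_X[j]` is the marginal association with
plasma protein level (per SD) and `b_Y[j]` with the outcome (log-odds for
binary traits), estimated in non-overlapping samples. Under the usual
instrumental-variable assumptions — the variants affect the outcome only
through the protein (no horizontal pleiotropy), are associated with the
protein, and share no confounder with the outcome — the marginal effects
satisfy `E[b_Y] = theta * b_X`, and theta is the causal effect per SD of
genetically predicted protein. Restricting instruments to cis-pQTLs (within
±200 kb of the encoding gene) is what makes the no-pleiotropy assumption
plausible for a protein exposure.

Because cis instruments are mutually correlated through LD, the IVW
estimator is a generalized-least-squares fit with outcome-error covariance
`Omega = diag(se_Y) * rho * diag(se_Y)`, where rho is the signed LD
correlation matrix. This treats `b_X` as fixed (the NOME approximation);
the per-variant F statistic `(b_X/se_X)^2` quantifies how good that
approximation is, and the pipeline surfaces the instrument's mean F. Under
the default simulation (below) the residual covariance also carries a
`theta^2/n_X` term that the GLS model ignores; at theta = 0.1, n_X = 20,000
and n_Y = 300,000 this understates the SE by ~7%, which is why measured CI
coverage sits near 0.94 rather than 0.95 — still inside the accepted
[0.92, 0.97] band, and partly compensated by the multiplicative
random-effects inflation.

## Estimators and inference

- **Wald ratio** (1 variant): `theta = b_Y/b_X`, `se = se_Y/|b_X|`
  (first-order delta method), normal inference.
- **IVW, correlated** (≥2): GLS as above; fixed effects for 2–3 variants,
  multiplicative random effects for >3 with residual scale
  `phi = sqrt(rss/(J-1))` floored at 1 (reported SE is never below the
  fixed-effect SE). Normal inference.
- **MR-Egger, correlated** (≥3): each variant is oriented so `b_X >= 0`
  (joint negation of `(b_X, b_Y)`, which leaves rho valid), then GLS of
  `b_Y` on `[1, b_X]`. The intercept estimates directional pleiotropy.
  Inference is ordinary weighted-regression inference: t with J−2 df and
  the *estimated* residual scale, not floored. Flooring the scale at 1 on
  top of the t reference makes the null intercept test roughly four-fold
  conservative at the J ≈ 5–15 typical of clumped cis instruments (measured
  rejection 0.012 instead of 0.05); with the estimated scale the test is
  exact under the model (measured 0.046). A `floor_phi=True` switch
  restores the conservative variant.
- **PCA-IVW** (≥2): eigendecomposition of
  `Phi_ij = b_X,i b_X,j rho_ij / (se_Y,i se_Y,j)`; the smallest k whose
  eigenvalues cover the variance target (default 0.99) defines the
  projection; fixed-effect GLS in the projected space. Useful when the
  battery loosens the clumping threshold toward r² ≈ 0.8 and Omega nears
  singularity.
- **Steiger filtering**: variance explained per variant and trait is
  `t^2/(t^2 + n - 2)` from the t statistic (needs no allele frequencies); a
  variant is removed iff it explains strictly more variance in the outcome,
  ties retained. Applied before the variant count chooses the estimator.

MR-Egger's slope additionally suffers regression dilution when `se_X` is
non-negligible relative to the spread of `b_X` (a few percent under the
default simulation) — an attenuation its SE does not cover. The test suite
therefore checks Egger's point-estimate consistency under a large exposure
GWAS, and the battery treats Egger as a directional check, which is how the
three-criterion verdict uses it.

## Pipeline conventions

- **FDR**: Benjamini–Hochberg over the pooled protein × outcome tests by
  default (`pool_outcomes=False` adjusts per outcome); significance at
  adjusted p < 0.05.
- **Sensitivity battery**: 6 clumping thresholds (r² 0.001–0.8) + 2
  instrument-p thresholds (1e-6, 5e-8) + PCA-IVW + Egger = 10 analyses;
  grid points whose instrument is empty are omitted and logged.
- **Robustness**: primary significant AND all battery estimates share the
  primary's sign (point estimates only, not their significance) AND
  reverse-direction MR p > 0.05. Reverse MR uses caller-supplied outcome
  instruments; the pipeline does not invent them, and an absent reverse
  test counts as no evidence of reverse causation.
- **Phenome-wide scan**: threshold 0.05/n_proteins with n_proteins an
  input; a significant hit is *beneficial* iff the HDP-risk-lowering
  direction of the protein also lowers the phenotype's risk
  (`hdp_protective_sign * theta < 0`), *adverse* otherwise.

## Colocalization

Wakefield log-ABF per variant: with `V = se^2`, `z = beta/se`,
`r = w/(w+V)`, `logABF = 0.5*log(1-r) + 0.5*r*z^2`. Default prior effect
SDs: 0.2 for the quantitative protein trait, 0.15 for a binary (log-odds)
trait; per-variant configuration priors p1 = p2 = 1e-4, p12 = 1e-5 — the
standard defaults of the enumeration method, exposed in `ColocPriors`
rather than asserted. Hypothesis sums are accumulated with log-sum-exp; H3
sums over ordered distinct pairs via `log(exp(s1+s2) - exp(s12))`, which is
exactly zero-weight for a single variant. The method assumes at most one
causal variant per trait: regions simulated with several causal pQTLs
correctly drift to H3, so per-gene-body windows (supported alongside
±200 kb windows via `extract_cis_region`) can matter.

## Synthetic data: what it emulates, what it does not

`simulate_region_sumstats` draws marginal summary statistics on the
standardized-genotype, standardized-trait scale: `se = 1/sqrt(n)`, exposure
means `rho @ gamma`, outcome means `rho @ (theta*gamma + alpha)`, noise
`MVN(0, rho/n)`. Defaults — m = 50 variants at 1 kb spacing, AR(1) LD with
c = 0.7, 3 causal pQTLs with effect SD tau = 0.15, n_X = 20,000,
n_Y = 300,000, theta = 0.1 — mirror a well-powered protein GWAS of the
SCALLOP scale instrumenting a large binary-outcome meta-analysis, with
per-variant F well above the weak-instrument range. Allele frequencies are
irrelevant on this scale, so EAF is a 0.5 placeholder and alleles a fixed
non-palindromic A/G pair; binary outcomes are simulated on the linear
log-odds approximation rather than by case-control sampling, since the
estimators consume marginal beta/se only.

Consequently, passing tests demonstrate estimator correctness and
calibration under known LD and Gaussian sampling — they do not probe real
human LD structure, allele-frequency-dependent power, case-control
ascertainment, sample overlap, or population stratification.

`simulate_observational_studies` draws gestational weeks uniform on
[6, 40], study sizes of tens to hundreds, and log₁₀ mean ratios
`intercept + slope*week` with noise SD `noise_sd/sqrt(n/100)` (default
noise_sd 0.15, intercept −0.8 so the ratio crosses zero mid-gestation, the
pattern reported for natriuretic peptides). It emulates the numerical
structure of a systematic-review table, not its heterogeneity in assays,
units or risk of bias; studies reporting medians are accepted by the fitter
with a flag and treated as approximate means.

## Numerical choices

- Omega conditioning: if `cond(Omega) > 1e8`, rho is shrunk toward the
  identity as `(1-lam)*rho + lam*I` with lam = 1e-6, escalating once to
  1e-3, then erroring with advice to clump more strictly. GLS solves go
  through Cholesky factorization, not explicit inversion.
- Clumping determinism: variants visited by ascending exposure p, ties by
  genomic position then lexicographic ID; output in genomic order.
- LD matrices: asymmetries ≤ 1e-8 are averaged away; larger asymmetry,
  non-unit diagonal, |r| > 1 or negative eigenvalues beyond −1e-8 are
  format errors, not silent repairs.
- Harmonization joins by variant ID (LD files are ID-keyed); palindromic
  A/T and C/G variants are dropped by default with a flag to retain, and
  allele-mismatched variants are dropped with a logged reason.
- Degenerate inputs fail loudly: empty instruments return "no instrument"
  rather than raising; zero exposure effect in a Wald ratio, collinear
  exposure effects in Egger, single-week trend tables, and n ≤ 2 in
  Steiger's variance-explained all raise typed errors.
- p-values are clipped away from exact 0 to remain in (0, 1].

## Validation problem sizes

The statistical checks run at: 1,000 random instances for the
estimator/oracle agreement; 500 replicates each for recovery/coverage and
type-I error; 1,000 replicates for Egger null calibration; 1,000 random
p-vectors and 200 random regions for the BH/clumping cross-checks; 200
replicates of a 200-variant region for colocalization; 200 replicates per
stratum for the gestational-trend recovery. These sizes give Monte-Carlo
standard errors comfortably inside the asserted bands while keeping the
whole suite fast on a single core.

## Known limitations

- The GLS model conditions on `b_X` (NOME); very weak instruments would
  bias theta toward the null and narrow the CIs.
- Enumeration coloc is single-causal-variant per trait; no SuSiE-style
  multi-signal decomposition.
- No COJO-style conditional instrument selection, weighted-median/mode
  estimators, multivariable MR, or MR-PRESSO.
- The trend fitter offers only an optional quadratic beyond the linear
  term, and pools mean- and median-reporting studies.
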