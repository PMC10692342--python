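# Methods

`heatnorm` estimates how heat load late in gestation affects calf birth
weight (BiW), and whether the *genetic* architecture of BiW changes along the
heat-load gradient. This note records the model, the numerical choices, and
what the synthetic-data tests do and do not establish.

## Heat-load covariates

Hourly dry-bulb temperature T (°C) and relative humidity RH (%) from the
weather station nearest to each herd (great-circle distance, Earth radius
6371.0 km, ties broken by lowest station id) are combined into the
temperature-humidity index

    THI = (1.8·T + 32) − (0.55 − 0.0055·RH) · (1.8·T − 26).

THI is monotone in T; its RH-sensitivity changes sign at 1.8·T = 26 °C
(humidity amplifies heat above ≈14.4 °C and buffers cold below).

Daily THI is the mean of the day's hourly values. Each calf gets:

* **Weekly means WK1–WK12** over day offsets counted backwards from birth
  (day 0 = birth date). WK1 covers offsets 0–7 inclusive — *eight* days; the
  printed range is asymmetric and is kept as stated. WK2–WK12 cover the
  seven-day ranges 8–14, …, 78–84. A window needs ≥80 % daily coverage,
  otherwise it is reported missing (not zero).
* **PC1** of the daily THI over the last 56 days of gestation (offsets
  0–55; the "0–56 d" phrasing would give 57 values and is read as 56).
  The PCA is computed on the **correlation** matrix: with ~56 highly
  correlated daily columns, correlation-PCA scores scale like √56·z and
  span roughly ±15 — consistent with the fixed scaling anchors (−15, 11) —
  whereas covariance-PCA scores would scale with the seasonal THI SD and
  span ±100+. Rows with any missing day are dropped (count logged). The
  eigenvector sign is fixed so scores correlate positively with the row
  mean ("high PC1 = hot").

Both covariates are mapped onto [−1, 1] by v ↦ −1 + 2(v − min)/(max − min)
with anchors (17, 72) for weekly THI and (−15, 11) for PC1; values outside
the anchors are **clamped**, keeping reaction-norm evaluation inside the
estimated range. The midpoint of the THI map (44.5) is the thermoneutral
reference.

## Phenotype edits and factors

BiW outside (20, 60) kg is excluded (boundaries retained — the rule is
strict inequality); gestation lengths outside 260–300 d are excluded (the
class bins cover only that range); after those cuts only dams with ≥3
remaining offspring across ≥3 distinct parities are kept — repeated records
per dam are what identifies the maternal permanent-environmental (pe)
component. Twins are individual records; the sex × birth-type factor (4
classes) carries the twin effect. Factors: herd-birth-year (HY, fixed),
herd-birth-year-month (HYM, random contemporary group), gestation-length
class (six inclusive bins), dam parity class (1–6, >6 pooled).

## Relationship matrices

* **A**: Wright's numerator relationship matrix, tabular method with
  inbreeding; its sparse inverse by Henderson's rules with
  Mendelian-sampling variances from parental inbreeding.
* **SNP QC**: call rate > 0.95, MAF > 0.05, autosomes only, Hardy-Weinberg
  chi-square (1 df) at α = 1e−6 (the threshold is not reported by the
  source analysis; it is exposed in the config). Pairs with genomic
  relationship > 0.95 are pruned greedily (most violations first, ties drop
  the larger id).
* **G**: VanRaden method 1, G = ZZ′/(2Σp(1−p)), allele frequencies from the
  genotyped animals, missing genotypes mean-imputed (2p).
* **Gw = 0.95·G + 0.05·A22** (blend weight not reported; 0.95 is the
  conventional default, configurable), and the single-step matrix either as
  H⁻¹ = A⁻¹ + pad(Gw⁻¹ − A22⁻¹) or directly as
  H = A + A(:,g)A22⁻¹(Gw − A22)A22⁻¹A(g,:). The two routes are checked
  against each other in the tests. τ = ω = 1 (no extra scaling).

## Mixed models

**Model 1** (per covariate, 13 runs): y = Xb + Ks + Mh + Qc + e with
i.i.d. sire, dam and HYM effects; b contains the mean, HY, sex × birth
type, gestation-length class, parity class and one linear regression on a
scaled covariate. The dam and sire effects are i.i.d. (the source calls
them simply "random" effects; no pedigree structure is implied). Wald
tests with model-based SEs give the regression p-values.

**Model 2**: y = Xb + Zd + Wm + Sp_m + Qc + e. The direct additive effect
d is intercept-only (the covariate is nested only within the maternal
terms). Maternal genetic pairs (intercept, slope) have covariance
K_m ⊗ H; pe pairs have K_pe ⊗ I over dams; no direct–maternal covariance
(assumed zero, as in the source model); the residual is homogeneous along
the gradient.

### AI-REML

All variance parameters enter the record-level covariance linearly,
V(θ) = Σθ_iV_i + v_e·I, so the engine works with dense n×n structure
matrices and Cholesky factorisations (LAPACK dpotrf/dpotri) rather than
sparse mixed-model equations: with n records far below the number of
random-effect levels × 2, the dense record-level route is faster and
simpler at the scales this package targets (n up to a few thousand; memory
grows as ~10·n² doubles).

Iterations maximise the restricted likelihood with average-information
(AI) updates. Parameters are transformed to an unconstrained scale — log
scalar variances, Cholesky factors of each 2×2 covariance function — so
every iterate is inside the PSD cone without projections, and the AI step
is Levenberg-Marquardt damped (damping ×10 on rejection, ÷10 on
acceptance) with step extrapolation (doubling while logL rises) to follow
likelihood ridges near the boundary. Accepted iterations never decrease
logL. Convergence: max |Δφ| < 1e−8, or |ΔlogL| < 1e−6 on a lightly damped
step, or three consecutive sub-tolerance improvements. Starting values:
v_e = half the phenotypic variance, the rest spread equally across terms,
2×2 blocks diagonal. Non-convergence within `max_iter` raises with the
full trace attached.

`restricted_loglik` provides an independent route to the same quantity via
the mixed-model-equations factorisation (ln|V| + ln|X′V⁻¹X| =
ln|R| + ln|G| + ln|C|); the tests require the two routes to agree to 1e−8,
and the AI optimum to sit within one cell of a 51×51 likelihood grid on
two-component toys.

## Gradient parameters

For a 2×2 covariance function K, Var(x) = w′Kw with w = (1, x), and the
correlation between the effect expressed at x₁ and x₂ is the normalised
bilinear form. Heritabilities divide by
v_p(x) = v_d + Var_m(x) + Var_pe(x) + v_hym + v_e; HYM is **included** in
the denominator by default (it is a random model term; the source does not
state its denominator) with a flag to exclude it. SEs propagate the
inverse AI matrix through these functions by the delta method (central
finite differences); a Monte-Carlo propagation check in the tests agrees
within 10 %.

## Synthetic data

The generator emulates the study's data structure with known truths:

* **Weather**: annual (amplitude 16 °C around 8 °C) and diurnal (4 °C)
  temperature cycles plus day-level (SD 3) and hourly (SD 2) noise;
  RH = 70 − 0.5(T − mean) + noise, clipped to [5, 100]. Weekly THI spans
  ≈18–74 index units — close to the reported 10.4–74.3 range.
* **Population**: founder sires and founder dams → breeding dams (paternal
  half-sib families) → phenotyped calves; 3–10 progeny per dam (truncated
  geometric, mean ≈3.7, matching the reported 3.70) in distinct parities
  spread over years; ≈3 % twin calvings; gestation N(280, 5²) truncated to
  [260, 300] (−5 d for twins); calving dates uniform over the year so the
  gradient is well covered.
* **Genotypes**: HWE with allele frequencies U(0.05, 0.5) for the
  genotyped sires, 1 % missingness, 2 % sex-linked markers for QC to act
  on.
* **Phenotypes**: exactly the model-2 decomposition; direct and maternal
  genetic values follow K ⊗ A via Mendelian-sampling recursion through the
  pedigree; pe pairs i.i.d. per dam; the gradient x is taken from the
  simulated weather through the climate module, so the covariate stage sits
  inside every recovery loop.

`reference_regime_config()` returns the generating parameters matching the
published operating point: v_d = 6.6 kg², K_m = (1.4450, 0.0675, 0.0400)
(giving Var_m(−1) = 1.35, Var_m(1) = 1.62, r_mg(1,−1) = 0.950),
v_hym = 2.0 kg²; K_pe and v_e are solved at call time (scipy root finding,
PSD-checked, least-squares fallback with a warning) so that direct h² at
x = 0 is 0.33, the pe correlation between the extremes is 0.56, and the pe
variance share is 4.43 % at x = −1 and 3.22 % at x = 0.1. The solution is
K_pe ≈ (0.649, −0.030, 0.184), v_e ≈ 9.306 kg².

### What the generator does not emulate

Real herds have selection, assortative mating, genetic trend, seasonal
management confounding, in-barn microclimates that deviate from station
weather, and dams that also appear as phenotyped calves. A green recovery
test therefore establishes that the estimation chain is consistent for the
stated model, not that the model is adequate for any particular real herd.

## Experiment scale and precision

The recovery experiments run at ≈700–800 dams / ≈2,600–3,000 calves per
seed, 10 seeds, so the full acceptance computation finishes on one CPU in
tens of minutes. Structural ratios that drive identifiability (progeny per
dam, dams per sire family) follow the full-scale world. The source
analysis used 171,221 calves; at ~1.5 % of that size the maternal
covariance functions are weakly identified — single-seed estimates of K_m
and K_pe regularly hit the PSD boundary (cross-environment correlations of
±1), and the seed-averaged pe correlation and pe variance share carry
sampling noise comparable to or larger than the reported effect. The
direct and maternal heritabilities and the fixed heat-load regression are
recovered well. This is a property of the data size, not of the
estimator: the same engine matches closed-form and grid-search oracles
exactly on toys. Boundary estimates also degrade the AI-based asymptotic
intervals (pinned components report near-zero SE), so interval-coverage
summaries at this scale reflect the asymptotic approximation rather than
the estimator.

## Known limitations

* Dense n×n engine: memory ~10·n² doubles caps practical n around 10⁴ on a
  laptop; the record-level route was chosen deliberately over sparse MME
  for this regime.
* Model-1 sire/dam effects are i.i.d., not pedigree-structured (an open
  reading of the source; the pedigree-structured variant can be obtained by
  passing a relationship to the engine).
* Delta-method SEs are first-order; near the PSD boundary they
  underestimate the sampling spread.
* The direct–maternal genetic covariance is fixed at zero; the constructor
  flag exists for API stability but intentionally raises if enabled.
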