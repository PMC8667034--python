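# Methods

This note documents the models, the synthetic study design, the numerical
choices, and the known limitations of the pipeline.

## Photosynthesis models

The light-response stage fits the rectangular (Michaelis–Menten form)
hyperbola A(Q) = Φ·Q·A_max/(Φ·Q + A_max) − R_d by bounded nonlinear least
squares. The three free parameters (A_max, Φ, R_d) are identifiable on
ten-point curves; a nonrectangular hyperbola with curvature θ exists for
sensitivity checks but is not the default because θ is weakly identified
at that design size. Respiration parameters are stored positive and
subtracted by the models.

Two derived quantities are pure functions of the fit:

* **LCP** — the irradiance at which net assimilation crosses zero,
  R_d·A_max/(Φ·(A_max − R_d)); undefined when R_d ≥ A_max.
* **LSP** — there is no universally agreed operational definition on a
  hyperbola that saturates only asymptotically. This package defines LSP
  as the irradiance at which *gross* assimilation reaches a configurable
  fraction of A_max (default 0.90), giving f·A_max/((1 − f)·Φ). On a
  rectangular hyperbola this is a large number (≈ 9·A_max/Φ at f = 0.9);
  LSP values are therefore only comparable within a fixed f and the
  choice is logged with every fit table.

The A/Ci stage fits the FvCB model A = min(A_c, A_j) with J = J_max
(curves are measured at saturating light; a light-modulated J is
available but off). Kinetic constants default to the standard
tobacco-derived 25 °C values (Γ* = 42.75 µmol mol⁻¹, K_c = 404.9
µmol mol⁻¹, K_o = 278.4 mmol mol⁻¹, O = 210 mmol mol⁻¹); no temperature
scaling is applied because the measurement protocol holds leaves at
25 °C. Triose-phosphate limitation and mesophyll conductance are out of
scope. The Ci transition point is solved analytically from the fitted
parameters, and a curve whose observations all fall on one side of it has
the uninformed parameter flagged unidentifiable rather than silently
returned.

Both fitters use a deterministic multi-start grid seeded from slope
heuristics (8 starts for the A/Ci model), trust-region reflective least
squares with tolerances 1e-12, and break SSE ties toward the smaller
leading parameter. Exact-data recovery (noiseless simulated curves return
the generating parameters to solver tolerance) is part of the test suite.

## Trait derivation and adjustment

WUE = A/E (mmol CO2 mol⁻¹ H2O), g_lim = 1 − C_i/C_a, LTD = T_leaf −
T_air with the sign convention that negative LTD means transpiration
cooling. Supersaturated records (C_i > C_a) yield negative g_lim and are
returned, not rejected. Genotype summaries report mean ± SE (sample
sd/√n; SE is missing, not zero, for n = 1).

Covariance-adjusted genotype responses at a reference temperature
(default 27.74 °C, the thermal-response join point) come from a
fixed-effects common-slope ANCOVA (response ~ genotype + T_air) fit by
OLS. A mixed model with random plot effects would be the field-design
alternative; with the balanced synthetic designs generated here the two
coincide, and the fixed-effects form keeps the adjusted means exactly
reproducible by a normal-equations oracle, which the tests exploit.

Correlation matrices support Pearson and Spearman coefficients with
two-sided p-values from the t approximation; the granularity (raw
observations vs per-genotype means) is an explicit configuration choice,
default per-genotype means. No multiple-testing correction is applied by
default. Quadrant classification places boundaries at across-genotype
means with a ≥ tie rule (boundary points go upper/right).

## Genotype stress index

YR is kept on the ratio scale internally: the GSI numerator "1 − GM(YR₁,
YR₂)" is only dimensionally coherent for ratios (percent is output
formatting). Within each experiment the geometric mean of YR is exactly 1
by construction, which the tests assert exactly.

The printed composite (1 − GM(YR₁, YR₂))/SII is negative for
above-average genotypes, which conflicts with reading larger index values
as better adaptation. Both conventions are therefore reported:
`gsi_literal` evaluates the formula as printed, `gsi_oriented` = −literal
so that larger means more heat-resistant; the oriented form is the
default ordering and the identity literal = −oriented is property-tested.
Which year plays the stressed (numerator) role in SII = 1 − Ÿ_s/Ÿ_r is an
explicit configuration choice (default: the second year), never inferred
from the data. Genotypes missing a year are excluded from the index (NaN)
rather than imputed. When the two years' geometric means coincide
(SII = 0) the index is undefined and returned as NaN, except for
genotypes exactly at the population average, whose index is 0 in every
convention.

## Two-segment thermal response

The continuous parameterization y = β₀ + β₁·min(x, γ) + β₂·(x − γ)₊ is
the default: it nests the single line (β₁ = β₂), so the minimized SSE
never exceeds the best single-line SSE, and it treats γ as a genuine
threshold. The discontinuous indicator form y = β₀ + β₁·x·I(x < γ) +
β₂·x·I(x > γ) is available as `mode="literal"` for fidelity comparisons.

γ is estimated by exhaustive profile search on a regular grid (default
step 0.01 °C over the central 90% of the x range, trimmed so at least two
observations lie on each side of every candidate); for each candidate the
conditional 3-parameter least-squares problem is solved from
batched 3×3 normal equations, and ties break toward the smallest γ.
Truly linear data leave the SSE profile flat relative to the response's
total sum of squares and are flagged `unidentifiable_join_point`.
Standard errors for the upper slope are conditional on γ̂ (they do not
account for join-point estimation). Grid refinement can only decrease the
minimized SSE; both properties are tested.

## Typologies

Traits are standardized to mean 0, sd 1 (sample sd); constant traits are
dropped with a warning. Clustering uses Ward's minimum-variance criterion
on Euclidean distances in scipy's convention (squared merge costs, the
"Ward.D2" family), named here because dendrogram heights differ across
conventions. The group count is selected by maximum mean silhouette over
k = 2..8 — reproducing a three-group typology is a property of the data,
never hard-coded — with a `weak_structure` flag when the best silhouette
falls below 0.25. Group separation is the between-group fraction of total
variance; its null distribution comes from random relabelings preserving
group sizes, with p = (1 + #{perm ≥ obs})/(N + 1) (never 0, exact-level
under exchangeability). Default N = 999 with a mandatory seed.

## Climatology

Season windows are expressed in days after sowing (defaults 20 and 60,
both endpoints included) with calendar-date arithmetic, so leap years are
handled by construction. Exceedance uses strict inequality ("exceeded
30 °C"). VPD follows the FAO-56 daily convention — the mean of Tetens
saturation pressures at T_max and T_min times (1 − RH/100) — switchable
to an es(T_mean) form; VPD is zero exactly at RH = 100.

## Synthetic study design

The generator module defines the study conditions; all defaults live in
one `GeneratorSpec`:

* **Panel**: 64 genotypes in three water-use groups — EUW (n = 14),
  WUE (n = 30), OEUW (n = 20) — whose per-trait means and SEs encode the
  contrasting strategies (water spenders with high gs/E and negative LTD;
  water savers with high WUE/g_lim and positive LTD; intermediates with
  high Rd/LCP/V_cmax). Per-genotype trait values are drawn independently
  per trait from Normal(group mean, scale·SE·√n), the SE·√n factor
  converting group-level standard errors back to between-genotype
  standard deviations. The scale multiplier was calibrated by a
  k-selection recovery study: at 0.45 the silhouette criterion selects
  k = 3 in ≥ 92% of 50 seeds and Ward recovers the generating labels with
  ARI ≥ 0.94, while keeping the groups realistically diffuse
  (silhouette ≈ 0.35).
* **Curves**: ten-step 0–2000 µmol m⁻² s⁻¹ PAR grid and 15-step
  50–1600 ppm CO2 grid, Gaussian noise sd 0.5 µmol CO2 m⁻² s⁻¹ on both.
* **Thermal truth**: continuous two-segment model with join point
  27.74 °C and upper slope 0.63; the below-optimum slope (not fixed by
  any reported estimate) defaults to 2.0 µmol m⁻² s⁻¹ °C⁻¹, set by a
  recovery calibration so that the profile-search estimator attains its
  design precision (γ̂ within ±0.3 °C in ≥ 95% of 200 replicates at
  n = 500, noise sd 1.0) over the 22–34 °C sampling range.
* **Yields**: log-normal with genotype effect sd 0.30, residual sd 0.10,
  and a ×0.8 second-year multiplier, so the implied stress intensity is
  0.20 exactly at zero noise.
* **Weather**: annual sinusoid plus Gaussian day-to-day noise with
  T_max > T_min enforced and RH clipped to [40, 100]. The sinusoid mean
  and amplitude (28.8/1.8 °C for T_max, 21.0/1.0 °C for T_min) reproduce
  the study-site risk profile: about one third of seasons contain a
  >30 °C day in the 20–60 days-after-sowing window and every season has
  >20 °C nights.

Every generator is a pure function of (spec, seed) and emits its ground
truth beside the data; recovery tests consume only emitted artifacts.

### What the generators do not emulate

Trait draws are independent across traits within a genotype, whereas real
gas-exchange traits are strongly correlated; a correlation hook exists
but is off. Curve noise is Gaussian and homoscedastic; instrument
artifacts (leakage, match-valve offsets) and spatial plot structure are
not modelled. The weather sinusoid is unimodal, so bimodal hot-period
structure (two separate hot spells per year) and the associated annual
counts of hot calendar days are not matched. Consequently, passing tests
demonstrate correctness of the statistical machinery under the assumed
structure, not robustness to field-data pathologies.

## Problem sizes

The shipped study uses 64 genotypes × 3 replicates, 200-replicate
Monte-Carlo recovery studies for the curve and breakpoint estimators,
1000 random tables for stress-index exactness, 50 seeds for the
clustering study, and 2000 null simulations (99 permutations each) for
the permutation test's type-I error — sizes chosen so the full suite and
the acceptance script each run in about a minute on one CPU while keeping
Monte-Carlo error well below the margins being tested.

## Known limitations

* LSP depends entirely on the saturation fraction; cross-study
  comparisons require matching definitions.
* Slope inference in the segmented model is conditional on γ̂.
* The ANCOVA ignores plot-level random effects (coincides with the mixed
  model only for balanced designs).
* Permutation and silhouette computations are exact only up to
  Monte-Carlo error at their default sizes.
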