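# beanheat

Analysis pipeline for leaf gas-exchange studies of heat-stressed common
bean (*Phaseolus vulgaris*) genotype trials: photosynthesis curve fitting,
gasometric trait derivation, a genotype stress index for two-year yield
trials, segmented thermal-response modelling, water-use typology
discovery, and growing-season heat-risk climatology. It is written for
plant ecophysiologists and breeders who screen large genotype panels under
high-temperature field conditions and need the full statistical chain —
from raw instantaneous gas-exchange records to ranked stress indices and
trait typologies — as tested, reproducible code.

Because raw field campaigns are rarely shareable, the package ships a
first-class synthetic-data module that generates every input the pipeline
consumes (curves, records, yields, weather) with known ground truth, so
every stage is testable end-to-end by parameter recovery.

## Models

**Light response (A/PAR).** Net assimilation follows the rectangular
hyperbola with an explicit respiration offset

  A(Q) = Φ·Q·A_max / (Φ·Q + A_max) − R_d,

from which the light compensation point LCP = R_d·A_max / (Φ·(A_max − R_d))
and the light saturation point LSP = f·A_max / ((1 − f)·Φ) (default
f = 0.90 of gross saturated assimilation) follow in closed form.

**A/Ci (FvCB).** The Farquhar–von Caemmerer–Berry model takes the minimum
of the Rubisco-limited and RuBP-regeneration-limited rates,

  A_c = V_cmax·(C_i − Γ*) / (C_i + K_c·(1 + O/K_o)) − R_D
  A_j = J_max·(C_i − Γ*) / (4·C_i + 8·Γ*) − R_D,   A = min(A_c, A_j),

with standard 25 °C kinetic constants (Γ* = 42.75, K_c = 404.9 µmol mol⁻¹,
K_o = 278.4 mmol mol⁻¹), all overridable.

**Leaf traits.** Per observation: WUE = A/E, stomatal limitation
g_lim = 1 − C_i/C_a, and leaf temperature differential LTD = T_leaf − T_air
(negative when transpiration cools the leaf). Genotype responses are
covariance-adjusted to a reference ambient temperature by common-slope
ANCOVA (response ~ genotype + T_air).

**Genotype stress index.** For a two-year yield trial: per-experiment
yield ratio YR_j = Y_j/Ÿ (Ÿ the experiment geometric mean), stress
intensity SII = 1 − Ÿ_stressed/Ÿ_reference, and the composite
GSI = ±(1 − GM(YR₁, YR₂))/SII (both sign conventions are reported; the
oriented form, larger = more heat-resistant, is the default ordering).

**Thermal response.** Assimilation against ambient temperature is fit by
a continuous two-segment linear model, y = β₀ + β₁·min(x, γ) +
β₂·(x − γ)₊, with the join point γ found by exhaustive least-squares
profile search (default grid 0.01 °C).

**Typologies.** Genotypes are clustered on standardized trait profiles by
Ward/Euclidean linkage, the group count chosen by mean silhouette, and
the grouping tested by a Monte-Carlo permutation test on the
between-group fraction of total variance.

**Climatology.** Season heat risk counts days above the 30 °C day and
20 °C night thresholds in a 20–60 days-after-sowing window; daily VPD
uses the FAO-56 convention on the Tetens saturation curve.

## Worked example

Run the numbered drivers (each regenerates or consumes `results/`):

```
python analysis/01_simulate.py
python analysis/05_thermal_breakpoint.py
python analysis/06_typologies.py
```

which prints, for the default 64-genotype synthetic study (seed 1):

```
join point gamma = 27.78 C (generating truth 27.74 C)
  slopes: 1.97 below, 0.65 above (truth 2.00 / 0.63); SSE 534.4 vs single-line 1235.3

silhouette selects k = 3 (profile {2: 0.319, 3: 0.335, 4: 0.232, ...})
  ARI vs generating groups: 1.000
  grouping explains 53.3% of total variance; permutation p = 0.0010 (N = 999)
```

The breakpoint fit recovers the generating join temperature to within the
sampling error of 500 noisy points, and the segmented model halves the
residual sum of squares relative to a single line. The silhouette
criterion recovers the three generating water-use groups exactly
(adjusted Rand index 1.0), and the permutation test rejects exchangeable
relabelings at its smallest attainable p-value, 1/(N+1).

The same stages are available as CLI subcommands
(`beanheat simulate|fit-light|fit-aci|traits|gsi|fit-breakpoint|typology|climate-risk|run-all`),
sharing one YAML config.

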