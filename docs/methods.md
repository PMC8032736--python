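# Methods

This note documents the models inside `cflux`, the reasoning behind the
open design choices, and what the synthetic experiments do and do not
demonstrate.

## Severity chain

The chain is a faithful implementation of the published regressions; the
choices below concern only its edges.

* **Clamps.** CBI is clamped to its defined 0–3 scale and the combustion
  percentages to [0, 100]: both fitted lines leave their calibration range
  (the soil line is negative below CBI 1.2347, the canopy line exceeds
  100% above CBI 3.63), and extrapolated negative combustion is not
  meaningful. The soil-combustion zero crossing sits at
  dNBR = (63.49/51.42 − 0.5561)/0.0023 ≈ 295.06, which is why soils barely
  combust below dNBR ≈ 300.
* **Negative corrected dNBR** (raw below background) is retained in the
  record but floored at 0 before the CBI regression: it means "no
  detected burn", not negative combustion.
* **Inverse chain domain.** The dNBR→CBI→soil-fraction round trip is an
  identity only where no clamp engages, i.e. dNBR ∈ (295.06, 1062.58];
  above that the CBI ceiling absorbs information. The inverse itself is
  defined for any soil fraction in (0, 1].
* **Compositing window** Jul 15 – Sep 15 is compared on (month, day) and
  inclusive at both ends. The background buffer ring (1500–1800 m outside
  the perimeter) is computed with a Euclidean distance transform at the
  scene's pixel size; an empty ring (perimeter at the scene edge) falls
  back to the prior-year in-perimeter background with a logged warning.
* **Gap-fill** takes the unweighted mean of the ten fires nearest in
  area; ties break on fire id, and pools smaller than ten use all
  available fires.

## Ecosystem kernel

The simulator is a deliberately reduced monthly box model — four pools
per cohort (vegetation C, soil organic C, soil organic N, available
inorganic N) plus two physical diagnostics — chosen so that every
mechanism the analysis depends on is explicit and testable.

State update per month (explicit Euler; fluxes are ≲1% of pools at this
step, so no sub-stepping is needed; carbon balance
Δ(C_veg + C_soil) = NPP − R_H − emission holds to round-off):

* `NPP = NPP_max · f_fol · g_T · g_W · g_N · g_CO2`, with Gaussian
  `g_T(T_air)` (optimum 14 °C, width 13 °C), Michaelis–Menten `g_W`
  (half-saturation 30% moisture) and `g_N` (half-saturation 10 g N m⁻²),
  and `g_CO2 = 1 + 0.4·ln(CO2/280)`. Uptake is additionally hard-capped
  by available N; the half-saturations are sized so the smooth `g_N`
  does the limiting in steady state and the cap binds only transiently.
* `R_H = k_d · C_soil · Q10^((T_soil−10)/10) · h_W`, Q10 = 2. The
  moisture scalar `h_W` uses a weak half-saturation (300%), i.e. nearly
  linear in moisture, so that the small post-fire wetting measurably
  stimulates decomposition.
* Litterfall `k_lf · C_veg` feeds the soil pool; decomposed C is fully
  respired. Net N mineralization is `(1 − f_imm) · R_H · N_soil/C_soil`.
* Soil temperature is damped air temperature minus an insulation offset
  `0.09 °C cm⁻¹` of moss/organic layer; complete removal of the 15 cm
  layer warms the soil by ≈1.35 °C, inside the 0.9–1.5 °C band used to
  tune it. The post-fire soil-temperature effect is mediated solely by
  this layer.
* Soil moisture is a single bucket (400 mm capacity): + precipitation,
  − ET, where ET = 6 mm °C⁻¹ mo⁻¹ · max(T_air, 0) with only 3% of ET
  attributed to foliage (et_base = 0.97). Less foliage ⇒ slightly wetter
  soil; the first-year post-fire moisture change stays below one
  percentage point of porosity, keeping its role in the carbon budget
  secondary, as intended.
* Recovery: foliage rises linearly for 5 years (closing 25% of the gap),
  then along a logistic (midpoint 10 yr, steepness 0.35 yr⁻¹) normalized
  to be continuous at the junction and to asymptote at the pre-fire
  reference. Moss depth recovers exponentially with τ = 40 yr.

**Fire nitrogen.** Combusted canopy N is exported entirely (it burns in
the crown and leaves with the plume); of the combusted soil N, 70%
volatilizes and 30% remains on site as plant-available ash N. This
routing was chosen after experiments with alternatives: returning half of
*all* combusted N to the available pool over-fertilizes the burned run
(post-fire NPP exceeds the unburned twin for a decade), while routing the
residue into soil organic N locks it away so slowly that net N
mineralization never recovers within the chronosequence. The implemented
routing reproduces both signatures the model is meant to exhibit: a
mineralization dip at the fire followed by recovery (the ash N cycles
through vegetation back into litter), and convergence of the NEP
difference by year 25.

**Equilibrium and tuning.** Without fire the kernel conserves total N up
to a small deposition term, so equilibrium stocks are set by the initial
N inventory; initial pools are placed on the target manifold
(2200 g C m⁻² vegetation, 10100 g C m⁻² soil, C:N of 50 and 30). The
decomposition base rate corresponds to ≈2.5% yr⁻¹ effective soil
turnover, and litterfall to ≈0.11 yr⁻¹ vegetation turnover, which makes
those stocks the attractor of the 120-year spin-up (residual drift
< 0.01% yr⁻¹; doubling the spin-up changes stocks by < 0.3%). All
defaults were fixed once, together, and ship in
`src/cflux/data/default_params.yaml`.

**Severity response structure** (with defaults, deterministic
climatology): in the fire year, R_H rises slightly for dNBR 100–200
(wetter soil, intact soil C) and falls sharply for dNBR ≥ 400 (combusted
soil C overwhelms the warming); the soil share of direct emission rises
strictly with severity class (≈30% at dNBR 350 to ≈71% at 700 for the
default stocks); and |NEP difference| at year 25 is 7–17% of its year-1
magnitude.

**Known limitations.** Vapor pressure and cloudiness are carried in the
forcing but unused by the reduced kernel (ET is temperature-based). The
available-N pulse after severe fire drives an NPP overshoot in
post-fire years ~5–14 (regrowth outproducing the mature baseline before
nitrogen scarcity reasserts itself) — qualitatively consistent with
stand-age productivity peaks, but its magnitude is a property of the
single-vegetation-pool design. Severe burns (dNBR ≥ 400) remain
N-limited beyond 25 years, so their NPP deficit does not close within
the chronosequence; the deficit of the dominant low-severity classes
does. Permafrost hydrology, thermokarst, species succession and
microbial community shifts are out of scope.

## Regional engine

* Cohort overlay is rasterized (default 20×20 fine pixels per 0.5° cell)
  rather than polygonal; fraction error is bounded by the pixel size and
  checked against a pixel-counting oracle. Axis-aligned rectangular
  perimeters are sufficient because no result depends on perimeter shape.
* If two same-year fires overlap a pixel, the higher-dNBR fire is kept
  for that year, so fire years within a cohort are strictly increasing.
* Reburn severity applies to the current, partially recovered state.
* Spin-up is shared per cell: all cohorts of a cell (and both scenarios)
  start from the same equilibrated state.
* Fires are applied at the start of the July step of the fire year.
  Consequently chronosequence year 0 (the fire year) contains six
  pre-fire months: the fire-year annual NEP difference is diluted, and
  "first full post-fire year" comparisons use year 1.
* Units: regional totals are Σ (cohort value [g C m⁻²] × area fraction ×
  forested cell area [km²]) × 10⁻⁶ → Tg C, asserted in tests.

## Synthetic data

The generator reproduces the statistical structure the analysis assumes:
a sinusoidal seasonal climate with Gaussian interannual noise per
variable (boreal defaults: −3 °C mean, 19 °C amplitude, ~480 mm yr⁻¹
precipitation peaking in summer), a +1.7 ppm yr⁻¹ CO₂ ramp, Poisson
annual fire counts with log-normal areas, and per-fire mean dNBR from a
truncated normal (mean 272.5, SD 120, bounds [60, 1300]) so that the
area-weighted mean severity sits near 272.5 and the histogram mode falls
in the 200–400 band. A fraction 0.0053 of fires carries no imagery, to
exercise gap-filling at the archival rate. Scene pairs embed a prescribed
dNBR on a constant-albedo background (B4+B7 = 0.4) with per-pixel noise
and an optional scene-wide drift that the background correction must
remove; the severity chain recovers the embedded value to within ±1 dNBR.
Each generator draws from its own RNG stream split from the master seed.

What passing on these data does *not* show: the generators contain no
sensor physics, cloud/orbit gaps, terrain effects, ecozone-specific
severity relations, or spatial autocorrelation of climate and fire, so
agreement here validates the pipeline's arithmetic and structure, not its
fidelity to any real landscape. The fire-area distribution is a log-normal
stand-in; no distributional form is asserted by the analysis.

## Numerical details

* Severity grids use NaN for missing pixels (B4+B7 = 0, no imagery);
  means are NaN-aware.
* Gap-fill ties, cohort orderings and report groupings are all
  deterministic (fire-id tie-breaks, sorted signatures), so identical
  configurations and seeds reproduce byte-identical outputs; the run
  manifest records config hash, seed, version and output digests.
* The emission-partition and indirect-emission ratios are cumulative
  quantities: ratio(t) = (direct + ΣR_H,fire − ΣR_H,nofire)/direct. The
  cumulative reading is the only one under which the ratio starts at ~1
  where respiration is initially unchanged and declines smoothly as the
  ecosystem recovers. Zero-denominator classes report NaN, not 0.
* Chronosequence class means are unweighted across cohorts by default;
  an area-weighted variant is available behind a flag.
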