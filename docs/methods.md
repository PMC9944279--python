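# Methods

`aggsink` implements the quantitative chain used to characterise sinking
phytoplankton aggregates — from particle images and stopwatch settling
trials to size spectra, Stokes-law densities, fractal dimension, carbon
remineralization, and infection-census statistics — together with seeded
generators that simulate every input the chain consumes. This note
records the models, the defaults and their justification, the numerical
choices, and what the synthetic data can and cannot show.

## Settling physics

All internal computation is cgs (cm, g, s); boundaries accept the units
practitioners use (diameters in mm, velocities in m d⁻¹ via the factor
864 = 86400 s d⁻¹ × 0.01 m cm⁻¹, excess density reported in mg cm⁻³).

* **Excess density.** Stokes' law solved for the density contrast:
  Δρ = 18 U ν / (g d²), with ν = 1.085 × 10⁻² cm² s⁻¹ (water at 17 °C,
  the incubation temperature) and g = 981 cm s⁻². Ambient-fluid density
  never enters: this form yields the *excess* directly. The defaults are
  constructor arguments (`PhysicalConstants`), so other temperatures are
  a one-line change.
* **Porosity.** φ = 1 − Δρ/ρ_s, where ρ_s is the solid hydrated density
  of the particulate material measured by settling into a density
  gradient (six layers, 1.18–1.38 g cm⁻³ by default). The aggregate
  volume cancels algebraically; the mg→g conversion is internal because
  Δρ is conventionally reported in mg cm⁻³ and ρ_s in g cm⁻³. Δρ > ρ_s
  is rejected (it would imply negative porosity).
* **Re and C_D.** Re = dU/ν and the empirical sphere drag
  C_D = 24/Re + 6/(1 + √Re) + 0.4. Both are reported descriptors only;
  no drag-based velocity prediction is made.
* **Fractal dimension.** Mass–size scaling makes settling velocity scale
  as U ∝ d^(D₃−1); D₃ is the slope of the log₁₀U ~ log₁₀d OLS regression
  plus one, with the OLS slope standard error attached. D₃ = 3 is a
  solid sphere, lower values more tenuous structures. The estimator is
  always log–log OLS; the display fit of U(d) can instead use nonlinear
  least squares initialised from the log fit (`fit_power_law`,
  `method="nonlinear_ls"`), since the two weight large aggregates very
  differently.
* **Treatment comparison.** `compare_fits` is an extra-sum-of-squares
  F-test of one pooled power curve against per-group curves. It operates
  in log space by default so that it tests the same model family the D₃
  estimator uses; degrees of freedom are (2, n − 4) from the parameter
  counts. A perfect separate fit (zero residual) is refused rather than
  reported as F = ∞.

## Size spectra

Detections are binned into geometric size classes whose upper edge is
`ratio` (default 1.3) times the lower edge. The default anchor is
0.35 mm, making the smallest class 0.35–0.455 mm; eleven classes then
span up to 6.27 mm. (The anchor is configurable because descriptions of
this grid in the literature sometimes quote a rounded coverage such as
"0.4–5.6 mm", which no exact geometric grid reproduces; we keep exact
edges and compute Δd from them, never from rounded labels.) Membership
is lower-closed/upper-open. Per bin, N(d) is the number concentration
(# L⁻¹), n(d) = N(d)/Δd the size spectrum, and nVd = n(d)·V_agg·Δd the
volume spectrum, where V_agg is the mean single-aggregate volume of the
bin's *empirical members* ((π/6)ECD³, spherical geometry) — not the bin
midpoint, so Σ nVd equals the cumulative volume concentration exactly.
Out-of-range detections are counted and logged, never silently dropped.
For plotting, log₁₀ of an empty bin is set to exactly −1.0.

## Image analysis

The pipeline mirrors an ImageJ-style workflow and its order is fixed:
flatten background → (R − B channel subtraction for RGB) → invert +
global threshold → connected components → ECD size filter →
concentration conversion.

* **Background flattening** fits a low-order (default quadratic)
  polynomial surface to the frame by least squares, subtracts it, and
  restores the mean exactly. A surface, unlike a blur-based estimate,
  cannot dent locally around dark particles, so large aggregates produce
  no halo artefacts.
* **Channel arithmetic** is pixelwise max(R − B, 0): red-dominant
  (chlorophyll) areas are removed; blue-stained polymer stays darker
  than the (warm) background.
* **Thresholding**: Otsu by default, computed on the inverted image —
  Otsu is shift-equivariant, so masks are invariant to adding a constant
  offset. A fixed threshold (for regression tests and the trimodal
  stained-image histograms, where a two-class Otsu split is ambiguous)
  is specified in original intensity units: pixels darker than it are
  foreground. Otsu on a single-valued frame raises instead of returning
  an empty mask. An optional Gaussian pre-smooth (`smooth_sigma`,
  default off) suppresses pixel noise before the global threshold; with
  noise at 20% of the blob contrast, σ = 1.5 px restores ≥ 0.95 recall
  and precision on the synthetic scenes.
* **Measurement**: 8-connectivity by default (4 selectable),
  border-touching particles kept unless `exclude_border`;
  A = pixel count · pixel_scale², ECD = 2√(A/π) on every row.
* **Size filter**: closed lower bound — a particle exactly at the cutoff
  (3 µm for stained polymers, 0.4 mm for aggregates) is kept, since the
  exclusion rules are phrased as "below the cutoff". Filtering is
  idempotent, and unit mismatches between detections and configuration
  are errors.
* **Concentrations**: suspension imaging divides by the optically
  sampled volume (# L⁻¹); filter micrographs scale the imaged
  area-fraction to the whole filter before dividing by the filtered
  volume (# mL⁻¹).
* Manual curation of falsely outlined particles is out of scope; in
  synthetic mode the ground-truth table plays that role.

## Respiration and carbon loss

O₂ consumption of one vial is (ΔO₂ − mean ΔO₂ of controls) × vial
volume / duration (default 5.9 mL, 24 h), in µmol O₂ d⁻¹; a negative
control-corrected rate is clipped to zero with a warning rather than
propagated. Division by the respiratory quotient (RQ = 1.2 mol O₂ per
mol CO₂) and the aggregate's POC (µg C → µmol C with M_C = 12.011
g mol⁻¹) yields the carbon-specific rate k (d⁻¹): k = 0.1 d⁻¹ means 10%
of the aggregate's carbon respired per day. The remineralization length
scale is L = k/U (m⁻¹; × 100 for % m⁻¹), and the depth loss is L·z
(linear, the default — it matches the % m⁻¹ framing) or 1 − e^(−L·z)
(exponential, provided because the functional form of literature
depth-loss estimates is usually unstated). `loss_curve` evaluates this
across diameters from a fitted U(d), warning on extrapolation beyond
the fitted range.

## Census statistics

Host cells are staged as non-infected / early / mature / post-infected /
decaying. Prevalence is 100·(early + mature + post)/total; decaying
cells sit in the denominator but not the numerator (they show no signs
of infection). Enrichment is the aggregate:ambient prevalence ratio,
rounded only at reporting. Bacteria per aggregate is the stage-weighted
mean per-cell load times an assumed 20,000 host cells per aggregate.

Pairwise comparisons follow a decision tree: Shapiro–Wilk per group
(either rejection routes to Mann–Whitney — the conservative reading of
"non-normally distributed data"), otherwise a two-sided F-test on the
variances routes to Welch or Student's t. All tests two-sided, α = 0.05.
A constant sample (Shapiro undefined) routes to the rank test; two
identical constant samples are a declared degenerate case with no
p-value. Calibration: across 1000 simulated normal null pairs (n = 20),
the tree rejects at 5% ± 2%. Multi-group comparisons use Kruskal–Wallis
with Bonferroni-corrected pairwise Mann–Whitney post-hocs; the
compact-letter display uses insert-and-absorb in group-mean order
(pairs are only declared distinct when the omnibus test also rejects).
Error propagation is first-order Gaussian: absolute sds in quadrature
for sums/differences, relative sds for products/quotients, |k|× the
relative sd for powers.

## Synthetic data

The generators produce inputs with the statistical structure the
analysis assumes; they are pure functions of (parameters, seed).

* **Populations.** Diameters are log-uniform on 1.1–4.9 mm by default
  (the sampled single-aggregate size range; the log-uniform mean of
  2.5 mm sits near the observed 2.4 mm mean) or power-law with a
  configurable exponent (−3 default, a typical particle-spectrum slope)
  for spectrum work. Velocities are U = a·d^(D₃−1)·ε with ε lognormal
  (sd 0.1 default): multiplicative noise keeps U positive and is
  symmetric in log space, matching the log–log estimator, so the
  estimator is unbiased for the generating D₃. Defaults a = 60 m d⁻¹
  at 1 mm and D₃ = 2.37 reproduce ~201 m d⁻¹ at the 2.4 mm mean size
  (the infected analogue uses a = 34, D₃ = 2.64 → ~144 m d⁻¹). Δρ, φ,
  Re and C_D are derived per aggregate from the generated (d, U); POC
  is proportional to the Stokes-implied *solid* volume V(1 − φ)
  (porosities are ~0.999, so total volume would be a nonsense carbon
  proxy), with 1480 µg C mm⁻³ chosen to reproduce ~6–7 µg C per 2.4 mm
  aggregate; k defaults to 0.16 d⁻¹ (0.34 for the infected analogue).
  No within-treatment variance structure for POC or bacteria is
  published; these defaults are stated choices, not inferences.
* **Frames.** Dark discs on a light background (contrast 0.5 in [0, 1]
  units) with optional linear illumination gradient and Gaussian noise;
  placement is rejection-sampled to avoid overlap, at most 4 aggregates
  per 512 × 512 frame at 0.04 mm px⁻¹. A pixel belongs to a blob iff its
  center lies inside the disc; the truth table records the rasterized
  pixel count, so truth and clean-scene detections agree exactly.
  Stained RGB micrographs render polymer blue-dominant, cells
  red-dominant, and the background warm (R − B between the two) so that
  channel subtraction isolates the polymer phase.
* **Assays and trials.** O₂ end concentrations follow the forward model
  of the respiration module plus a common drift (default from the
  observed ~2% control shift) and optional noise; controls carry drift
  and noise only, so the inversion is exact at zero noise and unbiased
  in expectation otherwise. Settling times are distance/U plus Gaussian
  timing noise truncated to keep times positive.
* **Censuses.** Stage counts are multinomial. The aggregate compartment
  scales infected-stage fractions by the enrichment parameter and
  shrinks uninfected stages to fill the remainder, so the *prevalence
  ratio* equals the parameter by construction (an enrichment whose
  implied uninfected fraction would go negative is an error). Bacterial
  loads are negative binomial per cell (stage means default
  6.5/9.9/9.6/16.1/24.2 bacteria cell⁻¹, common dispersion r = 2 — wide,
  matching the broad observed distributions).

What the generators do **not** emulate: irregular, porous aggregate
shapes (discs only — so ECD is exact by construction rather than a
spherical-equivalent approximation), optical blur and depth-of-field
effects, touching/overlapping particles, stage-dependent cell
morphology, within-treatment correlation between size and respiration
rate, or coagulation dynamics of aggregate formation. Passing tests
demonstrate the correctness and internal consistency of the analysis
chain under the stated statistical structure, not segmentation
performance on real micrographs.

## Pipeline and determinism

`run_pipeline` executes simulate → image/analyze → bin → settle → fit →
respire → compare for every configured treatment and reports mean ± sd
(ddof = 1), range and n per characteristic, the D₃ fit, the spectra,
and the treatment comparisons. One global seed is fanned out to
per-stage child seeds drawn from a master generator, so runs are
deterministic end-to-end and adding a stage does not reshuffle earlier
ones. Exports carry exact values; rounding happens only in the
human-readable rendering. Problem sizes used by the bundled demo and
the reproduction script — 12 aggregates per treatment for the
single-aggregate table (matching the replicate counts of the settling
set), 200 for fractal-dimension recovery, 9 vials per treatment,
10⁵ cells per census compartment — are the package's standard sizes and
keep a full run in seconds.

## Known limitations

* Treatment-level means of nonlinear quantities (Re, C_D, porosity)
  computed from mean inputs differ from means of per-aggregate values;
  the pipeline always computes per aggregate first and summarises after.
* The Mann–Whitney branch uses scipy's exact method only where scipy
  does (small n, no ties); with ties it falls back to the asymptotic
  approximation.
* `flatten_background`'s polynomial surface cannot represent
  high-frequency vignetting; raise the degree or pre-correct such
  frames.
* The linear depth-loss mode saturates at 100% (min(L·z, 1)); for deep
  transects the exponential mode is the physically sensible choice.
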