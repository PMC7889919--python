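# Methods

## Physical model and conventions

The tissue column is planar and laterally infinite: stratum corneum (SC,
15 µm), viable epidermis + dermis treated as one electromagnetic layer
(ED, 1.396 mm for the reference adult), subcutaneous fat (4 mm), and
semi-infinite muscle.  For the thermal problem the ED is split into a
non-perfused viable epidermis and a perfused dermis, because only the
dermis carries blood; electromagnetically the two sublayers share the ED
permittivity.

Time convention `e^{+jωt}` with `ε* = ε′ − jε″` (`ε″ ≥ 0` stored
positive), refractive index `n = √ε*` on the principal branch
(`Re n > 0`, `Im n ≤ 0`), wavenumber `k = k₀ n`, so a forward wave
`e^{−jkz}` decays with depth.  Depth `z = 0` at the air/SC interface,
increasing into the tissue.  The incident-field normalisation is
`IPD = |E₀⁺|²/(2η₀)`, and `SAR = σ|E|²/(2ρ)` with `|E|` the peak
amplitude and `σ = 2πf ε₀ ε″`.

### Electromagnetic solution

Cascade reflection coefficients are built from the deepest interface
outward, `R_i = (r_i + R_{i+1}p)/(1 + r_i R_{i+1}p)` with
`p = e^{−2jk_{i+1}h_{i+1}}` and the terminal muscle reflection-free;
forward amplitudes follow from field continuity.  The per-layer power
budget uses time-averaged Poynting-flux differences (the muscle takes the
residual flux, consistent with all transmitted power being dissipated
there); by telescoping the fractions sum to one exactly, and they agree
with depth integrals of `σ|E|²/2` to quadrature accuracy (tested).

The peak SAR is searched on all interfaces plus a 1 µm within-layer grid
(configurable); in lossy layers the intensity decays monotonically so the
peak sits at an interface — for this stack, the SC/ED boundary — while
the grid guards against standing-wave maxima in low-loss layers.

The "no-reflection" diagnostic assigns the ED permittivity to the
incident half-space, removing the air/skin mismatch, and reports the
resulting peak SAR normalised by the with-reflection peak.

### Bioheat solution

Steady Pennes equation per layer, `λT″ = B(T − T_blood) − q(z)` with
`q = σ|E|²/2`.  The surface condition is convective,
`λ dT/dz|₀ = h(T(0) − T_air)` with `h = 7 W m⁻² °C⁻¹` and
`T_air = 20 °C`; the sign follows the outward normal so the skin surface
loses heat to cooler air (the baseline surface temperature computes to
33.4 °C).  The published value of `h` is sometimes printed with units
W m⁻¹ C⁻¹, which cannot be a surface-exchange coefficient; the value is a
standard still-air convective coefficient.

In each layer the homogeneous solution is `a e^{+mz} + b e^{−mz}` with
`m = √(B/λ)` (affine for `B = 0`), parameterised on the numerically
bounded basis `e^{−m(h−z)}, e^{−mz}`.  The EM source is an exact sum of
complex exponentials per layer (two real-exponent terms plus a conjugate
oscillatory pair), so particular solutions come from undetermined
coefficients; if a source exponent falls within 10⁻⁶ m⁻¹ of `±m` the
resonant `z e^{gz}` lift is used (never triggered by the tissue
parameters here, but handled).  The terminal layer keeps only the
decaying exponential, enforcing `T(∞) = T_blood` exactly.  The resulting
9×9 boundary system (Robin surface row, value/flux continuity at four
interfaces) is solved densely with one step of iterative refinement,
giving boundary residuals at the 10⁻¹⁰ level.

The temperature *rise* is obtained from the homogeneous-boundary
difference problem (equivalently, the full problem with `T_air = T_blood`
minus `T_blood`); a two-solve route (exposed minus baseline) agrees to
10⁻⁹ °C and is kept as a cross-check.  Thermoregulation is deliberately
absent: blood flow is treated as exposure-independent, valid for the
sub-degree heating at guideline exposure levels, and transient dynamics
are out of scope.

### Finite-volume reference

The numerical cross-check is a conservative finite-volume scheme on a
uniform grid truncated at 60 mm (Dirichlet `T = T_blood`): face
conductances are exact series (harmonic) conductances across any material
interface inside the face interval, perfusion and source terms are exact
cell averages (the exponential source integrates in closed form), and the
surface condition enters through the first half-cell flux balance.  This
makes the scheme insensitive to interface/grid misalignment, which a
plain central-difference stencil with nodal harmonic means is not.
Because the muscle temperature decay length is `√(λ/B) ≈ 14 mm`, the
60 mm truncation changes the peak rise by < 10⁻⁴ °C but leaves a ~10⁻³ °C
tail discrepancy at the domain bottom; profile-level comparisons against
the analytic solution therefore use a 120 mm domain (agreement ~2·10⁻⁵ °C),
while peak-level comparisons use the 60 mm default.

## Age models

* **Permittivity.**  Lichtenecker's law `ε′ = ε′_W^α ε′_T^{1−α}` with the
  unknown organic permittivity eliminated via the adult value gives
  `ε* = ε′_W^{(α−α_A)/(1−α_A)} ε′_A^{(1−α)/(1−α_A)} (1 − jε″_A/ε′_A)`.
  The loss tangent is exactly age-invariant by construction.  The
  hydration rate is `α = TBW·ρ` with TBW in L/kg and ρ in g/cm³ — the
  only reading that keeps α dimensionless in (0, 1).  The model applies
  to ED, fat and muscle with the single whole-body TBW curve; the SC is
  age-invariant (its permittivity is governed by environment, not
  systemic hydration).  `ε′_W` is taken from a single-Debye pure-water
  model at 25 °C (ε_s = 78.36, ε_∞ = 5.16, τ = 8.27 ps): 31.1 at 26 GHz
  and 12.0 at 60 GHz, shipped as overridable named constants.  Note that
  at 60 GHz muscle (ε′ = 12.86) is slightly *above* water, so its aged
  permittivity moves marginally upward; the skin-dominated outputs are
  unaffected.
* **Adult reference.**  `α_A` per tissue is defined as the hydration rate
  at the reference age 35 y evaluated from whichever TBW table is in use,
  which makes the age model reproduce the tabulated adult permittivities
  exactly at 35 y.
* **Thickness.**  The age table sets the ED total; the 15 µm SC is
  constant and additional.  For the thermal split the viable epidermis
  defaults to 60 µm with the remainder as perfused dermis.  The printed
  source table assigns 1.396 mm to the viable epidermis and 60 µm to the
  dermis, which is anatomically inverted (it would leave the blood supply
  in a 60 µm sliver); a `literal_table_split` switch reproduces that
  literal reading for comparison.
* **Blood flow.**  `BF_D(age) = 6.033·10⁻⁴ − 3.55·10⁻⁶·age` s⁻¹ (forearm,
  resting), converted to the Pennes coefficient with
  ρ_b = 1050 kg m⁻³, C_b = 3617 J kg⁻¹ °C⁻¹.  Valid for ages 0–120;
  the forearm is among the least perfused sites, so heating is a worst
  case.

## Synthetic age tables

The literature curves behind the skin-thickness and TBW age dependence
are not printed anywhere reproducible, so the `synthetic_data` module
generates them: anchor points interpolated with shape-preserving PCHIP
(piecewise-linear on request), exact at anchors and monotone between
monotone anchors.  The default fixture spans ages 5–70 with anchors at
{5, 7, 12, 30, 35, 45, 65, 70}: skin thickness rising from 0.96 mm at
5 y through 1.396 mm at 35 y then declining slightly to 1.29 mm at 70 y;
TBW falling from 0.62 to 0.50 L/kg; body weight following a standard
growth curve.  Only the 1.396 mm tie-point and the α_A construction are
anchored to published adult values — all other fixture numbers are
synthetic placeholders chosen once as physiologically plausible, and the
package's quantitative age-endpoint outputs therefore characterise the
fixture, not any measured population.  What passing tests show is that
the *mechanisms* are right (directions, magnitudes bounded at the ~10–20 %
level, solver cross-checks); they do not validate the specific literature
curves.  Inter-individual spread defaults to a 10 % coefficient of
variation when no SD is given, truncated to physical bounds
(thickness > 0.1 mm, 0.05 < TBW < 0.95, weight > 0) by rejection.

## Monte Carlo

At each anchor age (7, 12, 30, 45, 65 y by default) skin thickness, TBW
and body weight are drawn from truncated Gaussians and the EM (optionally
thermal) pipeline is rerun per trial; body weight is carried as a sampled
input but enters the model only through the TBW ratio.  The uncertainty
interval is the central 95 % (2.5th–97.5th percentiles) and the point
estimate the sample mean.  The production default is 10⁶ trials; the test
and acceptance profiles use 10⁴ with fixed seeds, which resolves the
interval endpoints to well under the reported precision.  Everything is
reproducible bit-for-bit given the seed.

## Numerical choices and problem sizes

* SAR profile grid 1 µm by default (5 µm inside Monte Carlo loops);
  terminal layers sampled over three field decay lengths.
* Bioheat peak search on a ≤ 2 µm per-layer grid; finite-volume oracle at
  5 µm step.
* Age sweeps in the shipped tests use 5-year spacing; all qualitative
  conclusions are insensitive to the spacing because every quantity is
  smooth in age.
* Degenerate inputs are rejected with diagnostics: hydration α ≥ 1,
  negative regression blood flow (age > ~170 y), non-perfused terminal
  layer, lossless media in penetration-depth calls (reported as infinite
  depth), transmission outside [0, 1].

## Known limitations

Normal incidence only (no oblique incidence, polarisation or interface
roughness); no antenna near fields or cm²-scale spatial averaging of the
exposure limits; two-frequency tabulated permittivities rather than a
dispersion model; steady state only; single body site (dorsal forearm
parameter set).
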