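# Methods

## Scope and model

`condsize` estimates the lumen diameter of a blood vessel from tetrapolar
guidewire impedance measured at two (or more) excitation frequencies,
without saline injections. The physical model is one-dimensional in the
radial coordinate and axially uniform over the sensing segment:

1. **Conductance decomposition.** The measured conductance G = 1/R splits
   into parallel axial pathways: the fluid annulus between guidewire shaft
   and lumen wall (G_b), the vessel-wall annulus (G_t) and the surrounding
   medium (G_bath). Each coaxial annulus between diameters d_i < d_o
   contributes σ·π·(d_o² − d_i²)/(4L) over the sensing separation L.
2. **Two-frequency resistance extraction.** The electrode–electrolyte
   interface is modelled as a polarization capacitance in series with the
   ohmic system resistance: |Z(ω)|² = R² + 1/(ωC)². Two magnitudes at
   distinct frequencies determine (R², 1/C²) exactly; longer spectra are
   pooled by linear least squares in the same variables (columns rescaled
   for conditioning; non-positive or unresolvable dispersion — below 1e-9
   of R² — is reported as a purely ohmic fit with unbounded C). A
   parallel-RC topology is rejected on physical grounds: measured |Z|
   falls *toward* R with frequency, never below it.
3. **Inversion.** With a non-conductive surrounding, solving
   G_b(d_b) + G_t(d_b) = 1/R gives the closed form
   d_b = sqrt[(4L + πRσ_b·d_GW²) / (πR(σ_b + 4σ_t·TR(1+TR)))]. With a
   conductive bath the estimator bisects on d_b over
   [1.05·d_GW, d/2] the signed mismatch between the measurement-side
   parallel conductance (G − G_b) and the field-model prediction; both
   sides grow monotonically with the candidate diameter, so the root is
   unique when it exists.

## Assumptions

- Circular lumen, axially uniform over the sensing segment. The
  cylindricity check warns (never errors) when the excitation separation
  is less than twice the lumen diameter.
- The wall-thickness ratio TR = t_w/d_b and the wall conductivity σ_t are
  *assumed inputs* at estimation time (0.4 S/m default, the value the
  ex-vivo calibration yields across 10–80 kHz); their influence is
  quantified by `sensitivity_analysis`.
- The lumen-fluid "ideal" conductivity σ_b(f, d) is an empirical lookup
  (apparent conductivity back-calculated from phantoms); it absorbs field
  non-uniformity and is not modelled further. Lookup is bilinear in
  (log10 f, diameter) with edge clamping, exact at grid nodes.

## Parameters and defaults

| parameter | default | units | rationale |
|---|---|---|---|
| guidewire 5-5-5 | L = 6 mm, d = 18 mm, d_GW = 0.889 mm | — | 5 mm gaps + 1 mm electrodes, centre-to-centre; 0.035″ shaft |
| guidewire 2-2-2 | L = 3 mm, d = 9 mm, d_GW = 0.3556 mm | — | 2 mm gaps + 1 mm electrodes; 0.014″ shaft |
| electrode width | 1.0 | mm | reproduces the stated excitation separations (18/9 mm) and the ex-vivo conductance cells to <2%; configurable |
| σ_t | 0.4 | S/m | ex-vivo wall calibration, flat over 10–80 kHz |
| σ_bath | 0.18 | S/m | conductivity of 0.1% NaCl at room temperature (≈1.8 S/m per 1% w/v) |
| working frequencies | 10, 20 | kHz | well-separated impedance magnitudes at small diameters; any pair accepted |
| convergence tol | 0.02 | relative | parallel-conductance mismatch at exit |
| C_pol (simulator) | 100 | nF | puts the capacitive term at ≈160 Ω vs ≈80 Ω at 10/20 kHz — clearly separated magnitudes |
| excitation current | 100 | µA rms | bench excitation level |

Units are SI internally; mm/mS/kHz at CSV, JSON and CLI surfaces.

## The parallel-field kernel

The bath term is G_bath = (π/L)·∫ σ_bath·w·2r dr over the bath annulus,
where the radial weight w ∈ [0, 1] models the decay of the excitation
field with distance x from the lumen wall. The wall annulus itself is
kept at weight 1: its conductance is exactly what the ex-vivo calibration
measures, so any field attenuation across the wall is already absorbed in
the effective σ_t, and the model reduces to the closed-form wall
conductance whenever the bath is absent.

Kernel families (one scale parameter each, fitted to a measured
bath-thickness series by bounded scalar least squares):

- **exponential** (default): w = exp(−x/s). Fitted to the bundled
  bovine-carotid series (s ≈ 7 mm) it reproduces the measured bath
  fractions within ≈7 percentage points at every thickness and frequency.
- **dipole**: w = (1 + x/s)⁻³, the far-field fall-off of a source–sink
  pair.
- **cylindrical**: w = r_b/(r_b + x)·exp(−x/s) — cylindrical spreading of
  a line source with axial leakage. Its shell contribution w·2r is
  non-increasing for every scale, which makes the bath-fraction surface
  provably monotone: non-decreasing in bath thickness and non-increasing
  in TR at *every* thickness.
- **uniform**: w = 1 (degenerate reference).

A real constraint worth stating plainly: the measured series implies
near-full field weight out to ≈4 mm beyond the wall (per-shell weights
≈0.88, 0.47, 0.19, 0.04), while strict TR-monotonicity of the bath
fraction at the smallest bath thickness requires the weighted shell
contribution to decay faster than the annulus area grows there. No
pointwise radial weight satisfies both. The fitted exponential kernel
therefore shows sub-percentage-point TR-ordering reversals at the two
smallest measured thicknesses, while preserving the ordering from the
third station outward and at the asymptote; the cylindrical kernel gives
the fully monotone surface at the price of a poorer quantitative fit.
Kernel scales are tied to the excitation separation: rescaling a kernel
from the 5-5-5 to the 2-2-2 wire halves the decay length
(`FieldKernel.scaled_for_guidewire`), which is what makes the shorter
wire lose a smaller fraction of current in 2–4 mm vessels.

## Synthetic-data generator

`synth` forward-simulates what the impedance console records:
V(f) = I·sqrt(R² + 1/(2πf·C_pol)²)·(1 + ε), ε ~ N(0, noise_cv), seeded
per scenario (child seeds drawn from the battery seed, kept below 2³¹).
Multiplicative Gaussian voltage noise is the simplest instrument-noise
proxy; it is a modelling choice, not a measured noise spectrum.

The ex-vivo battery emulates the bench validation design: n = 11 vessels
with lumen diameters on a centred grid over 1.7–8 mm and TR values on a
centred grid over 0.16–0.9, assigned by a seeded permutation so size and
wall ratio are not artificially correlated; 0.45% saline in the lumen
(conductivity from the bundled table at 10 kHz and the true diameter,
making the closed loop self-consistent with the estimator's iterative
lookup); a de-ionized water bath (σ_bath = 0, as in the validation
experiments — the conductive 0.1% bath belongs to the separate
parallel-conductance study); 2-2-2 wire below 4 mm, 5-5-5 above. A
duplicates mode simulates each vessel twice with independent noise for
repeatability analyses.

What passing closed-loop tests do **not** show about real data: the
simulator and estimator share the same field kernel and conductivity
table, so the closed loop validates the inversion, not the kernel's
physical truth; real measurements add electrode-contact artifacts, drift
and mains interference that are deliberately out of scope.

Noise propagation is strongly diameter-dependent: large vessels have
R ≈ 50 Ω against a ≈160 Ω capacitive term at 10 kHz, so the series-RC
subtraction amplifies 1% voltage noise to ≈5% in R, i.e. ≈3% in
diameter, whereas small vessels sit near 0.7%. In a Bland–Altman analysis
over the full 1.7–8 mm range the largest vessels therefore dominate the
SD of differences and can exceed twice the pooled SD even when every
relative error is in spec.

## Numerical choices

- Bisection (max 100 iterations) rather than Newton: guaranteed once a
  sign change is bracketed; convergence requires both the relative
  parallel-conductance mismatch ≤ tol and a bracket below 0.1% of the
  diameter. Infeasibly *small* measured conductance raises
  `InfeasibleMeasurementError`; absence of a sign change raises
  `NoSolutionError`.
- Bath quadrature: trapezoid with 1000 radial steps; halving the step
  changes G_p by < 1e-6 relative (tested).
- Kernel fitting: bounded scalar minimization on log-scale,
  scale ∈ [0.1, 200] mm, residuals stacked over all frequency rows.
- Bland–Altman uses the sample (n−1) SD, which doubles as the
  repeatability coefficient; the within-k·SD fractions count from the
  mean difference by default (`center="zero"` switches to counting from
  zero); limits of agreement are also emitted as mean ± 1.96·SD.
- Degenerate fits: constant y in the least-squares diagnostic returns
  slope 0, r² 0; constant x raises `FitError`.

## Known limitations

- The parallel-field kernel is a one-parameter effective model calibrated
  on one vessel geometry; it is not a field solution, and its TR-ordering
  caveat is described above.
- Wall mechanics are ignored: TR is taken at the no-load state, while in
  vivo the wall thins as the lumen distends.
- The bundled conductivity table is 0.45% saline at room temperature with
  the 5-5-5 wire; blood at body temperature needs a user-supplied table
  (haematocrit and temperature corrections are out of scope).
- Non-circular lumens, axial tapering within the sensing segment, and
  real-time acquisition (ECG gating, pulsatility) are out of scope.
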