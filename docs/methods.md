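# Methods

## Models and procedure

The package treats one H-transfer step at a time. Observed rate constants
are assumed mono-exponential in time (one kinetic phase per trace) and are
modelled in two orthogonal directions:

* **Temperature.** Eyring form `k(T) = (k_B T/h)·exp(ΔS‡/R)·exp(−ΔH‡/RT)`,
  or equivalently Arrhenius `A·exp(−E_a/RT)`. Fitted as a weighted linear
  regression of `ln(k/T)` (or `ln k`) on `1/T`; the two parameterisations
  are related by `E_a = ΔH‡ + RT` and `A = (k_B T e/h)·exp(ΔS‡/R)` at the
  reference temperature.
* **Pressure.** Exponential–quadratic form
  `k(p) = k₀·exp(−ΔV‡ p/RT)·exp(Δβ‡ p²/2RT)`, so `ln k` is quadratic in
  pressure with slope `−ΔV‡/RT` at p = 0 and curvature `Δβ‡/RT` (per kbar).
  The same form, with the same sign conventions, describes the pressure
  dependence of a dissociation constant `K_d(p)`.

The KIE's pressure dependence is summarised by (KIE₀, ΔΔV‡, ΔΔβ‡), obtained
either by fitting the pointwise ratio profile `k_H/k_D` directly to the
exponential–quadratic form ("direct"), or by differencing the two
per-isotope fits ("difference", the default). The ratio of two
exponential–quadratic curves is itself one, so on noiseless data the two
routes coincide; on real data they differ slightly because the weights
differ. Thermal differences follow the field's convention D − H
(ΔΔH‡, ΔΔS‡); pressure differences are H − D (ΔΔV‡, ΔΔβ‡). Errors of
differences and ratios are combined in quadrature (first-order
propagation; validated against Monte-Carlo sampling in the tests for
relative errors up to 15%).

Two closed-form forward models are provided for interpreting
pressure-dependent KIEs. The Bell-correction (Northrop-type) form
`KIE(p) = KIE₀ + KIE₀(Q_H/Q_D − 1)·exp(−ΔV_Q p/RT)` treats the observed KIE
as a semiclassical limit plus a tunnelling component squeezed out by
pressure; note that at p = 0 it reads `KIE₀·Q_H/Q_D`, so KIE₀ here is the
infinite-pressure (semiclassical) limit, not the zero-pressure intercept of
the fit above. The approximate vibronic form

    KIE(p,T) = KIE₀ · exp(−2E·k_B T/(κ₀ + Δκ·p)) · exp(E·(r₀ − Δr·p)²)

couples the KIE to a promoting vibration: κ is the mode force constant
(kJ·mol⁻¹·Å⁻², stiffening with pressure), r the equilibrium donor–acceptor
distance (Å, compressing with pressure), and `E = (μ_h ω_h − μ_l ω_l)/2ħ`
(Å⁻²) the isotope mass–frequency term. The published typesetting of this
expression is ambiguous about whether `k_B T` multiplies or divides the
force-constant term; this package uses the division form because it is the
only dimensionally consistent reading (`k_B T/κ` has units Å², matching
`E`'s Å⁻²) and it reproduces the qualitative physics (stiffening raises the
KIE, heating lowers it). The multiplication reading is *not* implemented.
`k_B T` is evaluated as the molar `RT` in kJ·mol⁻¹ to match κ's molar units.

## Units and constants

Pressures are bar everywhere in the API; coefficients quoted per kbar
(Δβ‡, Δκ, Δr) are converted internally. Volumes are cm³·mol⁻¹,
compressibilities cm³·mol⁻¹·kbar⁻¹, energies kJ·mol⁻¹, entropies
J·mol⁻¹·K⁻¹ — the units the field tabulates. The gas constant is carried as
8.31446 J·mol⁻¹·K⁻¹ for thermal terms and 83.1446 cm³·bar·mol⁻¹·K⁻¹ for
pressure terms (CODATA values via scipy). The default temperature is
298.15 K, the condition of the packaged pressure series.

## Fitting choices

* **Weighting.** All series fits are weighted 1/σ² using the tabulated
  standard errors by default, with an unweighted fallback flag; the source
  tables do not state which was used, so both modes are exercised in the
  tests. Fits are performed in direct k-space (not ln k) by default; the
  ln-space quadratic solution is used as the starting point, which makes
  the optimiser start at the exact ln-space optimum and converge in a few
  steps.
* **Standard errors** come from the covariance scaled by the reduced
  chi-square (`scipy.optimize.curve_fit` with `absolute_sigma=False`),
  the common convention in kinetics software. Simulation tests show the
  resulting 1-SE intervals cover the truth ~60–75% of the time at the
  experimental noise level, consistent with the few residual degrees of
  freedom.
* **Transient fits** seed `k` from a log-linear regression of the deviation
  from the tail plateau over its first decade, and normalise the signal to
  O(1) before optimising, making `k_obs` exactly invariant under affine
  rescaling of the signal. A plain offset is floated; no baseline-drift
  term is included. Replicate traces are fitted individually and pooled as
  mean ± SD, matching how the tabulated points were produced, rather than
  globally. A trace spanning fewer than three fitted half-lives is flagged
  `under_sampled`.
* **Binding titrations** are fitted to a plain hyperbola
  `base + amp·[E]/(K_d + [E])` with K_d seeded at the half-maximal
  concentration. No ligand-depletion (tight-binding) correction is applied
  even though the ligand concentration can be comparable to K_d — this
  replicates the source analysis; apparent K_d values should be read with
  that caveat. Titrations whose maximum concentration is below the fitted
  K_d are flagged non-saturating.
* **Degenerate inputs.** Pressure fits require ≥ 4 points (3 free
  parameters), Eyring fits ≥ 3 distinct temperatures, hyperbolic fits ≥ 4
  concentrations; flat titrations (amplitude within 2 SE of zero) and
  non-positive optima raise a structured fit-failure error rather than
  returning garbage.

## Cross-system correlation

The correlation module fits error-weighted straight lines between signature
parameters across systems, typically against ΔΔH‡ as the
temperature-dependence proxy. Weights use y-errors only (1/σ_y²); x-errors
are tabulated but ignored — a deliberate simplification, not an
errors-in-variables treatment, so slopes are mildly attenuated when
x-errors are large. The weighted R² is computed about the weighted mean and
adjusted as `1 − (1−R²)(n−1)/(n−2)`. Rows whose y-parameter was frozen in
the source fits (zero quoted error, e.g. Δβ fixed to 0 in the model-chemistry
rows) would otherwise carry infinite weight; their weight is capped at the
largest finite weight in the column, and rows missing the requested
parameter (no thermal data) are skipped and reported.

## Synthetic data

The generators emulate the experimental design of the packaged dataset: a
9-point pressure grid (1 bar, then 250–2000 bar in 250-bar steps), 298.15 K,
multiplicative Gaussian noise on rate constants and K_d values (matching
the roughly proportional tabulated errors), additive noise on transients,
and 3 replicates averaged per tabulated point (reported error = replicate
SD). Default noise is 8% relative per shot for rates — chosen so that the
replicate SDs match the magnitude of the tabulated errors — 5% for
transients and K_d series, and 3% for titration responses. A single global
seed is expanded into per-stream child seeds (`SeedSequence.spawn`), so
adding a stream never shifts existing draws and every output is
byte-reproducible for a fixed seed.

What the generators do *not* emulate: photophysics of the excited pigment,
baseline drift or correlated instrument noise in transients, pressure
dependence of the enzyme concentration needed to keep the ternary complex
saturated, multi-exponential kinetics, or conformational heterogeneity.
Passing round-trip tests therefore demonstrate estimator correctness and
calibration under the stated noise model, not robustness to every artefact
of real high-pressure data.

## Problem sizes

The simulation-based checks use 100–200 seeded replicates (transient
recovery, K_d recovery, coverage calibration) and 10⁴–10⁵ draws for noise
calibration and Monte-Carlo error-propagation cross-checks; these sizes
give comfortable margins on the asserted medians and rates while keeping
the whole suite fast.

## Known limitations

* The pressure model is phenomenological: ΔV‡ and Δβ‡ summarise ln k's
  first two pressure derivatives and carry no mechanistic guarantee.
* KIE₀, ΔΔV‡ and ΔΔβ‡ may themselves be temperature dependent; the package
  fits single-temperature pressure series and does not model a full p–T
  matrix (no such matrix exists for the packaged system).
* The vibronic form is an approximation to the full vibronic rate
  expression (no Marcus term or Franck–Condon integrals); it is intended
  for qualitative forward simulation, not fitting of absolute rates.
* On the packaged proton-transfer D₂O series, the weighted refit yields
  ΔV‡ ≈ 10.7 and Δβ‡ ≈ 8.6 against published 7.5 ± 2.3 and 4.9 ± 2.5
  (~1.1–1.2 combined SE away). The ln-space fit is an exact quadratic
  regression with a unique optimum, and unweighted/ln-space variants agree
  with the weighted result, so the refit is the least-squares optimum of
  the tabulated nine points; the published pair is consistent with a fit
  excluding the anomalous 2-kbar uptick of that series, but no such
  exclusion is documented, so this package reports the full-data optimum.
  The isotope-difference parameters built on this column remain within one
  combined SE of the published values.
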