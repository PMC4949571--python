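# ptkie — pressure–temperature analysis of kinetic isotope effects

`ptkie` is a Python library for analysing the combined pressure and
temperature dependence of kinetic isotope effects (KIEs) in enzymatic and
chemical H-transfer reactions. It is aimed at enzymologists running
high-pressure stopped-flow or laser-photolysis experiments who want to go
from raw kinetic traces to the five-parameter p–T signature of a reaction
and compare that signature across systems.

## The models

Observed rate constants are described by transition-state-theory forms.
The temperature dependence follows the Eyring (or Arrhenius) equation,

    k(T) = (k_B·T/h) · exp(ΔS‡/R) · exp(−ΔH‡/RT)  =  A · exp(−E_a/RT)

and the pressure dependence by an exponential–quadratic form in which the
activation volume ΔV‡ (cm³·mol⁻¹) is the first-order and the activation
isothermal compressibility Δβ‡ (cm³·mol⁻¹·kbar⁻¹) the second-order pressure
coefficient of ln k:

    k(p) = k₀ · exp(−ΔV‡·p/RT) · exp(Δβ‡·p²/2RT)

Binding equilibria follow the same form for K_d(p). Fitting each isotope's
series separately and differencing gives the p–T signature of the KIE:

    KIE₀ = k₀ᴴ/k₀ᴰ,  ΔΔH‡ = ΔH‡ᴰ−ΔH‡ᴴ,  ΔΔS‡ = ΔS‡ᴰ−ΔS‡ᴴ,
    ΔΔV‡ = ΔV‡ᴴ−ΔV‡ᴰ,  ΔΔβ‡ = Δβ‡ᴴ−Δβ‡ᴰ

Two forward models for pressure-dependent KIEs are included for
interpretation: a Bell-correction (Northrop-type) form in which pressure
squeezes out a tunnelling component Q, and an approximate vibronic
(Marcus-like) form in which a promoting vibration of force constant κ
samples the donor–acceptor distance r, with κ₀ + Δκ·p and r₀ − Δr·p under
pressure.

The package ships the published reference dataset for the light-activated
enzyme protochlorophyllide oxidoreductase (POR) — sequential hydride and
proton transfer rate constants for both isotopes over 1 bar–2 kbar at
298 K, the corresponding fitted parameters, and an eight-system summary
table — plus seeded synthetic-data generators that emulate the full
experimental design (exponential transients, binding titrations, replicate
rate tables).

## Worked example

```python
from ptkie import (load_table1_rates, fit_pressure_series,
                   compute_kie_profile, fit_kie_pressure)

series = load_table1_rates()                     # 4 series × 9 pressures
fit_h = fit_pressure_series(series[("hydride", "H")])
print(fit_h.params)
prof = compute_kie_profile(series[("hydride", "H")], series[("hydride", "D")])
print(fit_kie_pressure(prof, method="direct"))
```

prints

```
PressureParams(k0=2298519.659354363, dV_act=6.5605399763560674, dBeta_act=4.625070207589386)
KIEPressureFit(kie0=2.1702354491265914, kie0_err=0.08760821891137073,
ddV=-0.4815560771304623, ddV_err=2.3533243700197777, ddBeta=-6.8982693354020315,
ddBeta_err=2.3879426037369003, method='direct')
```

i.e. the protiated hydride transfer slows under pressure with
ΔV‡ ≈ 6.6 cm³·mol⁻¹ and curvature Δβ‡ ≈ 4.6 cm³·mol⁻¹·kbar⁻¹, and the
hydride KIE extrapolates to ≈ 2.17 at zero pressure, falling with pressure
(negative ΔΔβ‡). The `examples/` directory has one short script per
capability (pressure fits, KIE profiles, binding/K_d pipeline, synthetic
round trips, tunnelling forward models, cross-system correlation); each
prints its numbers with a line of interpretation.

A thin CLI mirrors the library: `ptkie simulate|fit-transients|fit-pressure|
fit-eyring|kie|fit-kd|correlate|reproduce-por`. `ptkie reproduce-por` refits
the packaged rate table and reports, parameter by parameter, agreement with
the published fits at a configurable combined-standard-error tolerance.

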