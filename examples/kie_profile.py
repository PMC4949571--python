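"""Build the hydride-transfer KIE pressure profile and fit its signature.

The pointwise ratio k_H/k_D of the packaged rate table gives the observed
KIE at each pressure with propagated errors. Its pressure dependence is
summarised two ways: fitting the profile directly to the
exponential-quadratic form, and differencing the two per-isotope fits
(KIE0 = k0H/k0D, ddV = dV_H - dV_D, ddBeta = dBeta_H - dBeta_D). On real
data the two differ slightly because the weights differ.
"""

from ptkie import (
    compute_kie_profile,
    fit_kie_pressure,
    fit_pressure_series,
    load_table1_rates,
)

series = load_table1_rates()
h, d = series[("hydride", "H")], series[("hydride", "D")]
prof = compute_kie_profile(h, d)

print("pressure (bar)   KIE")
for p, k, e in zip(prof.pressure, prof.kie, prof.kie_err):
    print(f"{p:10.0f}   {k:5.2f} ± {e:4.2f}")

direct = fit_kie_pressure(prof, method="direct")
diff = fit_kie_pressure(
    method="difference", fit_h=fit_pressure_series(h), fit_d=fit_pressure_series(d)
)
for fit in (direct, diff):
    print(
        f"\n{fit.method:>10s}: KIE0 = {fit.kie0:.2f} ± {fit.kie0_err:.2f}, "
        f"ddV = {fit.ddV:+.2f} ± {fit.ddV_err:.2f} cm^3/mol, "
        f"ddBeta = {fit.ddBeta:+.2f} ± {fit.ddBeta_err:.2f} cm^3/mol/kbar"
    )

print(
    "\nThe KIE falls from ~2.2 toward ~1.3 by 2 kbar: pressure compresses the"
    "\ndonor-acceptor geometry differently for H and D transfer."
)
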