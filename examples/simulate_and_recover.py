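"""Round-trip check of the rate-table pipeline on seeded synthetic data.

Generates an H/D rate table from known pressure-model parameters under the
experimental design (9 pressures, 8% relative noise, 3 replicates averaged
per point), refits both series, and prints recovered versus true parameters.
"""

from ptkie import PressureParams, fit_pressure_series
from ptkie.synthetic_data import SimulationConfig, simulate_rate_table

truth = {
    "H": PressureParams(k0=2.30e6, dV_act=6.6, dBeta_act=4.7),
    "D": PressureParams(k0=1.03e6, dV_act=5.0, dBeta_act=9.5),
}
cfg = SimulationConfig(truth=truth, sigma=0.08, replicates=3, seed=20240925)
h, d = simulate_rate_table(cfg)

for s in (h, d):
    fit = fit_pressure_series(s)
    t = truth[s.isotope]
    print(
        f"{s.isotope}: k0 {fit.params.k0:.3e} (true {t.k0:.2e}), "
        f"dV {fit.params.dV_act:+.2f} ± {fit.dV_err:.2f} (true {t.dV_act}), "
        f"dBeta {fit.params.dBeta_act:+.2f} ± {fit.dBeta_err:.2f} (true {t.dBeta_act})"
    )

print(
    "\nWith tabulated-like noise the volume terms carry ~2-3 cm^3/mol "
    "uncertainties —\nthe same order as the published standard errors."
)
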