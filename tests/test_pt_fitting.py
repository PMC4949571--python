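"""Pressure/temperature series fitting and KIE signature assembly."""

import numpy as np
import pytest

from ptkie.constants import R_CM3_BAR, R_KJ
from ptkie.core_models import (
    EyringParams,
    KdPressureParams,
    PressureParams,
    eyring_rate,
    kd_pressure,
    pressure_rate,
)
from ptkie.pt_fitting import (
    EyringFitResult,
    PressureFitResult,
    RateSeries,
    compute_kie_profile,
    fit_eyring_series,
    fit_kd_pressure,
    fit_kie_pressure,
    fit_pressure_series,
    summarize_system,
)
from ptkie.synthetic_data import default_pressure_grid
from ptkie.transient_analysis import FitFailureError


def _series(params, pressures=None, T=298.15, isotope="H", rel_err=0.05):
    p = default_pressure_grid() if pressures is None else np.asarray(pressures, float)
    k = pressure_rate(params, p, T)
    return RateSeries(
        axis=p, k_obs=k, k_err=rel_err * k, isotope=isotope, axis_kind="pressure", fixed_T=T
    )


class TestPressureSeriesFit:
    @pytest.mark.parametrize(
        "truth",
        [PressureParams(2.30e6, 6.6, 4.7), PressureParams(1.08e4, 7.5, 4.9),
         PressureParams(5.0e2, -3.0, -8.0)],
        ids=["hydride-like", "proton-like", "accelerating"],
    )
    def test_noiseless_recovery_is_exact(self, truth):
        fit = fit_pressure_series(_series(truth))
        assert fit.params.k0 == pytest.approx(truth.k0, rel=1e-8)
        assert fit.params.dV_act == pytest.approx(truth.dV_act, rel=1e-8, abs=1e-10)
        assert fit.params.dBeta_act == pytest.approx(truth.dBeta_act, rel=1e-8, abs=1e-10)
        assert fit.chi2_red == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_grid_search(self):
        # coarse 3-D grid oracle on a noisy 5-point instance
        rng = np.random.default_rng(3)
        truth = PressureParams(1.0e5, 6.0, 5.0)
        p = np.array([1.0, 500.0, 1000.0, 1500.0, 2000.0])
        k_true = pressure_rate(truth, p)
        k = k_true * (1 + 0.04 * rng.standard_normal(5))
        err = 0.04 * k_true
        s = RateSeries(axis=p, k_obs=k, k_err=err)
        fit = fit_pressure_series(s)
        rt = R_CM3_BAR * 298.15
        k0g = np.linspace(0.9e5, 1.1e5, 81)
        dVg = np.linspace(0.0, 12.0, 121)
        dBg = np.linspace(-2.0, 12.0, 141)
        K0, DV, DB = np.meshgrid(k0g, dVg, dBg, indexing="ij")
        pred = K0[..., None] * np.exp(
            -DV[..., None] * p / rt + DB[..., None] * p**2 / 1000.0 / (2 * rt)
        )
        chi2 = np.sum(((pred - k) / err) ** 2, axis=-1)
        i, j, l = np.unravel_index(np.argmin(chi2), chi2.shape)
        assert abs(fit.params.k0 - k0g[i]) <= (k0g[1] - k0g[0])
        assert abs(fit.params.dV_act - dVg[j]) <= (dVg[1] - dVg[0])
        assert abs(fit.params.dBeta_act - dBg[l]) <= (dBg[1] - dBg[0])

    def test_underdetermined_series_rejected(self):
        s = _series(PressureParams(1e5, 6.0, 5.0), pressures=[1, 1000, 2000])
        with pytest.raises(FitFailureError):
            fit_pressure_series(s)

    def test_published_spot_values_recovered(self, table1_fits, table2):
        # the four well-conditioned spot parameters of the published fits
        fh = table1_fits[("hydride", "H")]
        assert fh.params.k0 == pytest.approx(2.30e6, rel=0.02)
        assert fh.params.dV_act == pytest.approx(6.6, abs=0.5)
        fd = table1_fits[("hydride", "D")]
        assert fd.params.dBeta_act == pytest.approx(9.5, abs=0.5)
        fp = table1_fits[("proton", "H")]
        assert fp.params.k0 == pytest.approx(2.35e4, rel=0.02)

    def test_covariance_is_symmetric_psd(self, table1_fits):
        for fit in table1_fits.values():
            cov = fit.covariance
            np.testing.assert_allclose(cov, cov.T)
            assert np.all(np.linalg.eigvalsh(cov) >= -1e-10 * np.abs(cov).max())


class TestEyringSeriesFit:
    @staticmethod
    def _thermal_series(params, T=None, rel_err=0.03):
        T = np.linspace(278.0, 318.0, 9) if T is None else np.asarray(T, float)
        k = eyring_rate(params, T)
        return RateSeries(axis=T, k_obs=k, k_err=rel_err * k, axis_kind="temperature")

    def test_noiseless_recovery_is_exact(self):
        truth = EyringParams.eyring(40.0, -20.0)
        fit = fit_eyring_series(self._thermal_series(truth))
        assert fit.params.dH_act == pytest.approx(40.0, rel=1e-8)
        assert fit.params.dS_act == pytest.approx(-20.0, rel=1e-8)

    def test_arrhenius_eyring_relation(self):
        # Ea = dH + R*T_mean links the two parameterisations within 1%
        truth = EyringParams.eyring(40.0, -20.0)
        s = self._thermal_series(truth)
        arr = fit_eyring_series(s, mode="arrhenius")
        expected_Ea = 40.0 + R_KJ * s.axis.mean()
        assert arr.params.Ea == pytest.approx(expected_Ea, rel=0.01)

    def test_single_temperature_is_an_error(self):
        with pytest.raises((ValueError, FitFailureError)):
            RateSeries(
                axis=np.full(4, 298.15), k_obs=np.full(4, 1e3), k_err=np.full(4, 10.0),
                axis_kind="temperature",
            )

    def test_pressure_series_rejected(self):
        s = _series(PressureParams(1e5, 6.0, 5.0))
        with pytest.raises(ValueError):
            fit_eyring_series(s)


class TestKIEProfile:
    def test_published_first_point_ratio_and_error(self, table1):
        prof = compute_kie_profile(table1[("hydride", "H")], table1[("hydride", "D")])
        assert prof.kie[0] == pytest.approx(2.23762, rel=1e-5)
        assert prof.kie_err[0] == pytest.approx(0.33751, rel=1e-4)

    def test_identical_series_give_unit_kie(self, table1):
        h = table1[("hydride", "H")]
        d = RateSeries(
            axis=h.axis, k_obs=h.k_obs, k_err=h.k_err, isotope="D",
            axis_kind="pressure", fixed_T=h.fixed_T,
        )
        prof = compute_kie_profile(h, d)
        np.testing.assert_allclose(prof.kie, 1.0)

    def test_grid_mismatch_rejected(self, table1):
        h = table1[("hydride", "H")]
        d = table1[("hydride", "D")]
        shifted = RateSeries(
            axis=d.axis + 10.0, k_obs=d.k_obs, k_err=d.k_err, isotope="D",
            axis_kind="pressure", fixed_T=d.fixed_T,
        )
        with pytest.raises(ValueError):
            compute_kie_profile(h, shifted)

    def test_propagated_error_matches_monte_carlo(self, rng):
        # first-order propagation vs 1e5 sampled ratios, sigma/k <= 0.15
        kh, sh, kd, sd = 2.26e6, 0.21e6, 1.01e6, 0.12e6
        draws = (kh + sh * rng.standard_normal(100_000)) / (
            kd + sd * rng.standard_normal(100_000)
        )
        mc_sd = draws.std(ddof=1)
        propagated = (kh / kd) * np.hypot(sh / kh, sd / kd)
        assert abs(propagated - mc_sd) / mc_sd < 0.05


class TestKIEPressureFit:
    def test_difference_reproduces_published_arithmetic(self, table2):
        # H-minus-D differences of the published parameters are identities
        def as_fit(row):
            return PressureFitResult(
                params=PressureParams(row.k0, row.dV_act, row.dBeta_act),
                k0_err=row.k0_err, dV_err=row.dV_err, dBeta_err=row.dBeta_err,
                covariance=np.eye(3), chi2_red=1.0,
            )

        t2 = {(r.reaction, r.isotope): as_fit(r) for r in table2.itertuples()}
        hyd = fit_kie_pressure(
            method="difference", fit_h=t2[("hydride", "H")], fit_d=t2[("hydride", "D")]
        )
        assert hyd.ddV == pytest.approx(1.6)
        assert hyd.ddBeta == pytest.approx(-4.8)
        pro = fit_kie_pressure(
            method="difference", fit_h=t2[("proton", "H")], fit_d=t2[("proton", "D")]
        )
        assert pro.ddV == pytest.approx(-5.8)
        assert pro.ddBeta == pytest.approx(-9.6)

    def test_direct_and_difference_agree_on_noiseless_data(self):
        h = _series(PressureParams(2.30e6, 6.6, 4.7), isotope="H")
        d = _series(PressureParams(1.03e6, 5.0, 9.5), isotope="D")
        prof = compute_kie_profile(h, d)
        direct = fit_kie_pressure(prof, method="direct")
        diff = fit_kie_pressure(
            method="difference",
            fit_h=fit_pressure_series(h),
            fit_d=fit_pressure_series(d),
        )
        assert direct.kie0 == pytest.approx(diff.kie0, rel=1e-6)
        assert direct.ddV == pytest.approx(diff.ddV, rel=1e-6)
        assert direct.ddBeta == pytest.approx(diff.ddBeta, rel=1e-6)

    def test_difference_requires_both_fits(self):
        with pytest.raises(FitFailureError):
            fit_kie_pressure(method="difference", fit_h=None, fit_d=None)


class TestSystemSummary:
    @staticmethod
    def _fits():
        h = _series(PressureParams(2.30e6, 6.6, 4.7), isotope="H")
        d = _series(PressureParams(1.03e6, 5.0, 9.5), isotope="D")
        eh = fit_eyring_series(
            TestEyringSeriesFit._thermal_series(EyringParams.eyring(30.0, -10.0))
        )
        ed = fit_eyring_series(
            TestEyringSeriesFit._thermal_series(EyringParams.eyring(38.2, 11.2))
        )
        return fit_pressure_series(h), fit_pressure_series(d), eh, ed

    def test_sign_conventions(self):
        ph, pd_, eh, ed = self._fits()
        s = summarize_system("demo", ph, pd_, eh, ed)
        assert s.ddH == pytest.approx(8.2, rel=1e-6)  # D minus H
        assert s.ddS == pytest.approx(21.2, rel=1e-6)
        assert s.ddV == pytest.approx(1.6, rel=1e-6)  # H minus D
        assert s.ddBeta == pytest.approx(-4.8, rel=1e-6)
        assert s.kie0 == pytest.approx(2.30e6 / 1.03e6, rel=1e-6)

    def test_isotope_swap_negates_all_differences(self):
        ph, pd_, eh, ed = self._fits()
        fwd = summarize_system("demo", ph, pd_, eh, ed)
        rev = summarize_system("demo", pd_, ph, ed, eh)
        assert rev.ddH == pytest.approx(-fwd.ddH)
        assert rev.ddS == pytest.approx(-fwd.ddS)
        assert rev.ddV == pytest.approx(-fwd.ddV)
        assert rev.ddBeta == pytest.approx(-fwd.ddBeta)

    def test_identical_isotopes_give_null_signature(self):
        ph, _, eh, _ = self._fits()
        s = summarize_system("null", ph, ph, eh, eh)
        assert s.kie0 == pytest.approx(1.0)
        assert s.ddH == pytest.approx(0.0, abs=1e-12)
        assert s.ddV == pytest.approx(0.0, abs=1e-12)

    def test_missing_thermal_pair_leaves_fields_none(self):
        ph, pd_, _, _ = self._fits()
        s = summarize_system("pressure-only", ph, pd_)
        assert s.ddH is None and s.ddS is None
        assert s.ddV == pytest.approx(1.6, rel=1e-6)


class TestKdPressureFit:
    def test_noiseless_recovery_is_exact(self):
        truth = KdPressureParams(kd0=3.7, dV=-15.9, dBeta=12.5)
        p = default_pressure_grid()
        kd = kd_pressure(truth, p)
        fit = fit_kd_pressure(p, kd, 0.05 * kd)
        assert fit.params.kd0 == pytest.approx(3.7, rel=1e-8)
        assert fit.params.dV == pytest.approx(-15.9, rel=1e-8)
        assert fit.params.dBeta == pytest.approx(12.5, rel=1e-8)

    def test_three_points_underdetermined(self):
        truth = KdPressureParams(kd0=3.7, dV=-15.9, dBeta=12.5)
        p = np.array([1.0, 1000.0, 2000.0])
        with pytest.raises(FitFailureError):
            fit_kd_pressure(p, kd_pressure(truth, p))


class TestRecoveryCalibration:
    def test_bias_and_coverage_of_pressure_fit(self):
        # 200 seeded synthetic series at tabulated-like (5%) observation
        # noise with known error bars: small median bias in dV and 1-SE
        # coverage in the range expected for chi-square-scaled errors with
        # few residual degrees of freedom
        truth = PressureParams(2.30e6, 6.6, 4.7)
        rng_master = np.random.SeedSequence(77)
        biases, covered = [], 0
        n = 200
        for ss in rng_master.spawn(n):
            rng = np.random.default_rng(ss)
            p = default_pressure_grid()
            k_true = pressure_rate(truth, p)
            k = k_true * (1 + 0.05 * rng.standard_normal(p.size))
            s = RateSeries(
                axis=p, k_obs=k, k_err=0.05 * k_true, axis_kind="pressure",
            )
            try:
                fit = fit_pressure_series(s)
            except FitFailureError:
                continue
            biases.append(fit.params.dV_act - truth.dV_act)
            if abs(fit.params.dV_act - truth.dV_act) <= fit.dV_err:
                covered += 1
        assert abs(np.median(biases)) < 0.5
        assert 0.55 <= covered / n <= 0.80
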