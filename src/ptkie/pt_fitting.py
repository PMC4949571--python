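"""Fitting pressure/temperature rate series and assembling KIE signatures.

The pipeline mirrors standard high-pressure kinetics practice: observed rate
constants for each isotope are fitted to the exponential-quadratic pressure
model (activation volume dV and activation compressibility dBeta), thermal
series to the Eyring (or Arrhenius) equation, and the isotope effect is
summarised by five parameters:

* KIE0        -- the KIE extrapolated to zero pressure,
* ddH, ddS    -- isotope differences of the activation enthalpy/entropy,
                 by convention D minus H,
* ddV, ddBeta -- isotope differences of the activation volume and
                 compressibility, by convention H minus D.

Fits are error-weighted (weights 1/sigma^2) by default, with parameter
standard errors taken from the covariance scaled by the reduced chi-square.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy.optimize import curve_fit

from .constants import H as PLANCK_H
from .constants import KB, R_CM3_BAR, R_J, T_DEFAULT
from .core_models import EyringParams, KdPressureParams, PressureParams
from .transient_analysis import FitFailureError

__all__ = [
    "RateSeries",
    "PressureFitResult",
    "EyringFitResult",
    "KIEProfile",
    "KIEPressureFit",
    "SystemSummary",
    "fit_pressure_series",
    "fit_eyring_series",
    "compute_kie_profile",
    "fit_kie_pressure",
    "summarize_system",
    "fit_kd_pressure",
    "KdFitResult",
]

_BAR_PER_KBAR = 1000.0


@dataclass
class RateSeries:
    """Observed rate constants on a pressure (or temperature) grid.

    axis : strictly increasing grid, bar for ``axis_kind="pressure"`` or
        K for ``axis_kind="temperature"``.
    k_obs, k_err : rate constants (1/s) and their standard errors.
    isotope : "H" or "D".
    fixed_T : the temperature (K) a pressure series was collected at.
    """

    axis: np.ndarray
    k_obs: np.ndarray
    k_err: np.ndarray
    isotope: str = "H"
    axis_kind: str = "pressure"
    fixed_T: float = T_DEFAULT
    label: str = ""

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        self.k_obs = np.asarray(self.k_obs, dtype=float)
        self.k_err = np.asarray(self.k_err, dtype=float)
        if not (self.axis.shape == self.k_obs.shape == self.k_err.shape):
            raise ValueError("axis, k_obs and k_err must have equal length")
        if self.axis.size < 3:
            raise ValueError(f"need >= 3 points, got {self.axis.size}")
        if np.any(np.diff(self.axis) <= 0):
            raise ValueError("axis must be strictly increasing")
        if np.any(self.k_obs <= 0):
            raise ValueError("rate constants must be positive")
        if np.any(self.k_err < 0):
            raise ValueError("standard errors must be non-negative")
        if self.axis_kind not in ("pressure", "temperature"):
            raise ValueError(f"axis_kind must be pressure|temperature, got {self.axis_kind!r}")
        if self.isotope not in ("H", "D"):
            raise ValueError(f"isotope must be H or D, got {self.isotope!r}")


@dataclass
class PressureFitResult:
    """Three-parameter pressure fit of one isotope's rate series."""

    params: PressureParams
    k0_err: float
    dV_err: float
    dBeta_err: float
    covariance: np.ndarray
    chi2_red: float
    weighted: bool = True

    def __post_init__(self) -> None:
        self.covariance = np.asarray(self.covariance, dtype=float)
        if self.covariance.shape != (3, 3):
            raise ValueError("covariance must be 3x3")
        if not np.allclose(self.covariance, self.covariance.T, rtol=1e-8, atol=0):
            raise ValueError("covariance must be symmetric")


@dataclass
class EyringFitResult:
    """Weighted linear Eyring (or Arrhenius) fit of a thermal rate series."""

    params: EyringParams
    dH_err: float | None = None
    dS_err: float | None = None
    A_err: float | None = None
    Ea_err: float | None = None
    chi2_red: float = float("nan")


@dataclass
class KIEProfile:
    """Pointwise KIE = k_H/k_D over a pressure grid with propagated errors."""

    pressure: np.ndarray
    kie: np.ndarray
    kie_err: np.ndarray
    fixed_T: float = T_DEFAULT

    def __post_init__(self) -> None:
        self.pressure = np.asarray(self.pressure, dtype=float)
        self.kie = np.asarray(self.kie, dtype=float)
        self.kie_err = np.asarray(self.kie_err, dtype=float)
        if not (self.pressure.shape == self.kie.shape == self.kie_err.shape):
            raise ValueError("pressure, kie and kie_err must have equal length")
        if np.any(self.kie <= 0):
            raise ValueError("KIE values must be positive")


@dataclass
class KIEPressureFit:
    """Pressure signature of a KIE profile: (KIE0, ddV, ddBeta) with errors."""

    kie0: float
    kie0_err: float
    ddV: float
    ddV_err: float
    ddBeta: float
    ddBeta_err: float
    method: str = "difference"


@dataclass
class SystemSummary:
    """Five-parameter p-T KIE signature of one system.

    Sign conventions: thermal differences are D minus H (ddH, ddS); pressure
    differences are H minus D (ddV, ddBeta). Thermal fields are None when no
    temperature-dependence data exist for the system.
    """

    system: str
    kie0: float
    kie0_err: float
    ddV: float
    ddV_err: float
    ddBeta: float
    ddBeta_err: float
    ddH: float | None = None
    ddH_err: float | None = None
    ddS: float | None = None
    ddS_err: float | None = None

    def __post_init__(self) -> None:
        if self.kie0 <= 0:
            raise ValueError("kie0 must be positive")


def _pressure_model_factory(T: float):
    rt = R_CM3_BAR * T

    def model(p, k0, dV, dBeta):
        return k0 * np.exp(-dV * p / rt) * np.exp(dBeta * p * p / _BAR_PER_KBAR / (2.0 * rt))

    return model


def _fit_pressure_model(
    p: np.ndarray,
    y: np.ndarray,
    y_err: np.ndarray | None,
    T: float,
    weighted: bool,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Shared engine for all exponential-quadratic pressure fits.

    Returns (popt, perr, cov, chi2_red) for y(p) = y0*exp(-dV p/RT)*
    exp(dBeta p^2/2RT). Initial values come from an (unweighted) quadratic
    regression of ln y on p, which is the exact ln-space solution.
    """
    p = np.asarray(p, dtype=float)
    y = np.asarray(y, dtype=float)
    if p.size < 4:
        raise FitFailureError(
            f"need >= 4 points to fit 3 parameters, got {p.size}"
        )
    if np.ptp(p) == 0:
        raise FitFailureError("all pressures equal; Jacobian is singular")
    rt = R_CM3_BAR * T
    c2, c1, c0 = np.polyfit(p, np.log(y), 2)
    p0 = [float(np.exp(c0)), float(-c1 * rt), float(c2 * 2.0 * rt * _BAR_PER_KBAR)]
    sigma = None
    if weighted and y_err is not None:
        if np.any(y_err <= 0):
            sigma = None  # zero/absent errors: fall back to unweighted
        else:
            sigma = y_err
    model = _pressure_model_factory(T)
    try:
        popt, pcov = curve_fit(
            model, p, y, p0=p0, sigma=sigma, absolute_sigma=False, maxfev=20000
        )
    except (RuntimeError, ValueError) as exc:
        raise FitFailureError(f"pressure fit did not converge: {exc}", {"p0": p0}) from exc
    if popt[0] <= 0 or not np.all(np.isfinite(pcov)):
        raise FitFailureError(
            "pressure fit converged to an invalid optimum", {"popt": list(popt)}
        )
    perr = np.sqrt(np.diag(pcov))
    resid = y - model(p, *popt)
    dof = p.size - 3
    if sigma is not None:
        chi2_red = float(np.sum((resid / sigma) ** 2) / dof)
    else:
        chi2_red = float(np.sum(resid**2) / dof)
    return popt, perr, pcov, chi2_red


def fit_pressure_series(s: RateSeries, weighted: bool = True) -> PressureFitResult:
    """Fit a pressure series to k(p) = k0*exp(-dV p/RT)*exp(dBeta p^2/2RT).

    Weighted (1/sigma^2) nonlinear least squares in direct rate space by
    default; parameter SEs are from the covariance scaled by the reduced
    chi-square. ``weighted=False`` gives the ordinary least-squares variant.
    """
    if s.axis_kind != "pressure":
        raise ValueError("fit_pressure_series needs a pressure series")
    if s.axis.size < 4:
        raise FitFailureError(f"need >= 4 pressures, got {s.axis.size}")
    popt, perr, pcov, chi2 = _fit_pressure_model(
        s.axis, s.k_obs, s.k_err, s.fixed_T, weighted
    )
    return PressureFitResult(
        params=PressureParams(
            k0=float(popt[0]), dV_act=float(popt[1]), dBeta_act=float(popt[2])
        ),
        k0_err=float(perr[0]),
        dV_err=float(perr[1]),
        dBeta_err=float(perr[2]),
        covariance=pcov,
        chi2_red=chi2,
        weighted=weighted and np.all(s.k_err > 0),
    )


def fit_eyring_series(
    s: RateSeries, mode: str = "eyring", weighted: bool = True
) -> EyringFitResult:
    """Fit a thermal series to the Eyring (default) or Arrhenius equation.

    Eyring: weighted linear regression of ln(k/T) on 1/T; the slope gives
    dH = -slope*R (kJ/mol) and the intercept dS = R*(intercept - ln(kB/h))
    (J/(mol*K)). Arrhenius: ln k on 1/T, giving Ea and A. Weights are
    1/sigma_ln^2 with sigma_ln = k_err/k_obs.
    """
    if s.axis_kind != "temperature":
        raise ValueError("fit_eyring_series needs a temperature series")
    T = s.axis
    if np.unique(T).size < 3:
        raise FitFailureError(
            f"need >= 3 distinct temperatures, got {np.unique(T).size}"
        )
    if mode not in ("eyring", "arrhenius"):
        raise ValueError(f"mode must be eyring|arrhenius, got {mode!r}")
    yv = np.log(s.k_obs / T) if mode == "eyring" else np.log(s.k_obs)
    x = sm.add_constant(1.0 / T)
    sig_ln = s.k_err / s.k_obs
    if weighted and np.all(sig_ln > 0):
        w = 1.0 / sig_ln**2
    else:
        w = np.ones_like(yv)
    res = sm.WLS(yv, x, weights=w).fit()
    intercept, slope = res.params
    se_i, se_s = res.bse
    chi2 = float(res.scale) if weighted else float(np.sum(res.resid**2) / res.df_resid)
    if mode == "arrhenius":
        return EyringFitResult(
            params=EyringParams.arrhenius(A=float(np.exp(intercept)), Ea=float(-slope * R_J * 1e-3)),
            A_err=float(np.exp(intercept) * se_i),
            Ea_err=float(se_s * R_J * 1e-3),
            chi2_red=chi2,
        )
    dH = -slope * R_J * 1e-3
    dS = R_J * (intercept - np.log(KB / PLANCK_H))
    return EyringFitResult(
        params=EyringParams.eyring(dH_act=float(dH), dS_act=float(dS)),
        dH_err=float(se_s * R_J * 1e-3),
        dS_err=float(R_J * se_i),
        chi2_red=chi2,
    )


def compute_kie_profile(h: RateSeries, d: RateSeries) -> KIEProfile:
    """Pointwise KIE = k_H/k_D with first-order error propagation.

    Both series must share the same pressure grid and temperature; the
    propagated error is kie*sqrt((s_H/k_H)^2 + (s_D/k_D)^2).
    """
    if h.axis_kind != "pressure" or d.axis_kind != "pressure":
        raise ValueError("KIE profiles are built from pressure series")
    if h.axis.shape != d.axis.shape or not np.allclose(h.axis, d.axis):
        raise ValueError("H and D series must share the same pressure grid")
    if h.fixed_T != d.fixed_T:
        raise ValueError("H and D series must share the same temperature")
    kie = h.k_obs / d.k_obs
    kie_err = kie * np.sqrt((h.k_err / h.k_obs) ** 2 + (d.k_err / d.k_obs) ** 2)
    return KIEProfile(pressure=h.axis.copy(), kie=kie, kie_err=kie_err, fixed_T=h.fixed_T)


def fit_kie_pressure(
    prof: KIEProfile | None = None,
    method: str = "difference",
    fit_h: PressureFitResult | None = None,
    fit_d: PressureFitResult | None = None,
    weighted: bool = True,
) -> KIEPressureFit:
    """Pressure signature (KIE0, ddV, ddBeta) of an isotope-effect profile.

    method="difference" (default): KIE0 = k0_H/k0_D, ddV = dV_H - dV_D and
    ddBeta = dBeta_H - dBeta_D from the two isotope fits, errors in
    quadrature. Because the ratio of two exponential-quadratic pressure
    curves is itself such a curve, this is algebraically the same curve the
    direct method fits.

    method="direct": weighted fit of the exponential-quadratic form to the
    KIE profile itself.
    """
    if method == "difference":
        if fit_h is None or fit_d is None:
            raise FitFailureError("difference method needs both isotope fits")
        h, d = fit_h.params, fit_d.params
        kie0 = h.k0 / d.k0
        kie0_err = kie0 * np.hypot(fit_h.k0_err / h.k0, fit_d.k0_err / d.k0)
        return KIEPressureFit(
            kie0=float(kie0),
            kie0_err=float(kie0_err),
            ddV=float(h.dV_act - d.dV_act),
            ddV_err=float(np.hypot(fit_h.dV_err, fit_d.dV_err)),
            ddBeta=float(h.dBeta_act - d.dBeta_act),
            ddBeta_err=float(np.hypot(fit_h.dBeta_err, fit_d.dBeta_err)),
            method="difference",
        )
    if method != "direct":
        raise ValueError(f"method must be direct|difference, got {method!r}")
    if prof is None:
        raise FitFailureError("direct method needs a KIE profile")
    if prof.pressure.size < 4:
        raise FitFailureError("direct method needs >= 4 profile points")
    popt, perr, _, _ = _fit_pressure_model(
        prof.pressure, prof.kie, prof.kie_err, prof.fixed_T, weighted
    )
    return KIEPressureFit(
        kie0=float(popt[0]),
        kie0_err=float(perr[0]),
        ddV=float(popt[1]),
        ddV_err=float(perr[1]),
        ddBeta=float(popt[2]),
        ddBeta_err=float(perr[2]),
        method="direct",
    )


def summarize_system(
    label: str,
    pfit_h: PressureFitResult,
    pfit_d: PressureFitResult,
    eyring_h: EyringFitResult | None = None,
    eyring_d: EyringFitResult | None = None,
) -> SystemSummary:
    """Assemble the five-parameter p-T KIE signature of one system.

    Applies the field's sign conventions -- thermal differences D minus H,
    pressure differences H minus D -- with errors added in quadrature. The
    thermal pair may be absent, in which case ddH/ddS are None.
    """
    kfit = fit_kie_pressure(method="difference", fit_h=pfit_h, fit_d=pfit_d)
    ddH = ddH_err = ddS = ddS_err = None
    if eyring_h is not None and eyring_d is not None:
        ddH = eyring_d.params.dH_act - eyring_h.params.dH_act
        ddH_err = float(np.hypot(eyring_h.dH_err, eyring_d.dH_err))
        ddS = eyring_d.params.dS_act - eyring_h.params.dS_act
        ddS_err = float(np.hypot(eyring_h.dS_err, eyring_d.dS_err))
    return SystemSummary(
        system=label,
        kie0=kfit.kie0,
        kie0_err=kfit.kie0_err,
        ddV=kfit.ddV,
        ddV_err=kfit.ddV_err,
        ddBeta=kfit.ddBeta,
        ddBeta_err=kfit.ddBeta_err,
        ddH=ddH,
        ddH_err=ddH_err,
        ddS=ddS,
        ddS_err=ddS_err,
    )


@dataclass
class KdFitResult:
    """Pressure fit of a dissociation-constant series."""

    params: KdPressureParams
    kd0_err: float
    dV_err: float
    dBeta_err: float
    covariance: np.ndarray
    chi2_red: float


def fit_kd_pressure(
    pressure,
    kd,
    kd_err=None,
    T: float = T_DEFAULT,
    weighted: bool = True,
) -> KdFitResult:
    """Fit Kd(p) = Kd0*exp(-dV p/RT)*exp(dBeta p^2/2RT) to a Kd series.

    Same weighted engine as :func:`fit_pressure_series`; with a negative dV
    the Kd grows with pressure (weakened binding under compression).
    """
    pressure = np.asarray(pressure, dtype=float)
    kd = np.asarray(kd, dtype=float)
    kd_err = None if kd_err is None else np.asarray(kd_err, dtype=float)
    if np.any(kd <= 0):
        raise ValueError("Kd values must be positive")
    popt, perr, pcov, chi2 = _fit_pressure_model(pressure, kd, kd_err, T, weighted)
    return KdFitResult(
        params=KdPressureParams(
            kd0=float(popt[0]), dV=float(popt[1]), dBeta=float(popt[2])
        ),
        kd0_err=float(perr[0]),
        dV_err=float(perr[1]),
        dBeta_err=float(perr[2]),
        covariance=pcov,
        chi2_red=chi2,
    )
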