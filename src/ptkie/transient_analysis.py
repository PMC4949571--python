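"""Rate-constant extraction from kinetic traces and binding titrations.

Laser-photolysis or stopped-flow transients of a single kinetic step are
fitted to a single exponential, ``S(t) = offset + amplitude*exp(-k*t)``,
where a positive amplitude is a decay towards the offset and a negative one
a rise. Binding titrations (here, the red-shift of the pigment absorbance on
ternary-complex formation, read out as an A642/A630 peak ratio versus enzyme
concentration) are fitted to a plain hyperbola to give an apparent Kd.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "Transient",
    "ExpFitResult",
    "BindingTitration",
    "HyperbolaFitResult",
    "FitFailureError",
    "fit_single_exponential",
    "fit_binding_hyperbola",
]

_LN2 = float(np.log(2.0))


class FitFailureError(RuntimeError):
    """A nonlinear fit failed to converge or converged to an invalid optimum.

    Carries a ``diagnostics`` dict with whatever the fitter knew at failure.
    """

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


@dataclass
class Transient:
    """A single kinetic trace: absorbance signal versus time.

    time is in seconds (strictly increasing, >= 10 points, time[0] >= 0);
    signal in absorbance units. Metadata records the conditions the trace was
    collected under.
    """

    time: np.ndarray
    signal: np.ndarray
    pressure_bar: float = 1.0
    temperature_K: float = 298.15
    isotope: str = "H"
    wavelength_nm: float = 696.0

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.time.ndim != 1 or self.time.shape != self.signal.shape:
            raise ValueError("time and signal must be 1-D arrays of equal length")
        if self.time.size < 10:
            raise ValueError(f"need >= 10 points, got {self.time.size}")
        if self.time[0] < 0:
            raise ValueError("time must start at or after zero")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")


@dataclass
class ExpFitResult:
    """Single-exponential fit of one transient."""

    k_obs: float
    k_obs_err: float
    amplitude: float  # signed: > 0 decay, < 0 rise
    amplitude_err: float
    offset: float
    offset_err: float
    direction: str  # "rise" | "decay"
    residual_rms: float
    under_sampled: bool = False  # window shorter than 3 fitted half-lives

    def __post_init__(self) -> None:
        if self.k_obs <= 0:
            raise ValueError("k_obs must be positive")
        expected = "decay" if self.amplitude >= 0 else "rise"
        if self.direction != expected:
            raise ValueError(
                f"direction {self.direction!r} inconsistent with amplitude sign"
            )


@dataclass
class BindingTitration:
    """A binding isotherm: response versus enzyme concentration (uM)."""

    enzyme_conc: np.ndarray
    response: np.ndarray
    response_err: np.ndarray | None = None
    pressure_bar: float = 1.0

    def __post_init__(self) -> None:
        self.enzyme_conc = np.asarray(self.enzyme_conc, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.enzyme_conc.shape != self.response.shape:
            raise ValueError("enzyme_conc and response must have equal length")
        if np.any(self.enzyme_conc < 0):
            raise ValueError("concentrations must be non-negative")
        if np.any(np.diff(self.enzyme_conc) <= 0):
            raise ValueError("concentrations must be strictly increasing")
        if self.response_err is not None:
            self.response_err = np.asarray(self.response_err, dtype=float)
            if self.response_err.shape != self.response.shape:
                raise ValueError("response_err length mismatch")


@dataclass
class HyperbolaFitResult:
    """Hyperbolic binding fit: response = base + amp*[E]/(Kd + [E])."""

    kd: float
    kd_err: float
    amplitude: float
    amplitude_err: float
    base: float
    base_err: float
    residual_rms: float
    non_saturating: bool = False  # max concentration below the fitted Kd


def _seed_exponential(t: np.ndarray, s: np.ndarray) -> tuple[float, float, float]:
    """Deterministic starting values (offset, amplitude, k) for the exp fit.

    The plateau is taken from the tail of the trace and k from a log-linear
    regression of |S - S_inf| over the first decade of the approach.
    """
    n_tail = max(3, t.size // 10)
    s_inf = float(np.mean(s[-n_tail:]))
    a0 = float(s[0] - s_inf)
    dev = np.abs(s - s_inf)
    top = np.abs(a0)
    if top == 0:
        top = float(np.max(dev)) or 1.0
        a0 = top
    mask = dev >= 0.1 * top
    # need at least 3 points in the regression window
    if mask.sum() < 3:
        mask = np.zeros_like(mask)
        mask[: max(3, t.size // 4)] = True
    with np.errstate(divide="ignore"):
        logdev = np.log(np.where(dev[mask] > 0, dev[mask], np.nan))
    ok = np.isfinite(logdev)
    if ok.sum() >= 3:
        slope = np.polyfit(t[mask][ok], logdev[ok], 1)[0]
        k0 = -float(slope)
    else:
        k0 = 0.0
    if not np.isfinite(k0) or k0 <= 0:
        k0 = 1.0 / max(t[-1] - t[0], np.finfo(float).tiny)
    return s_inf, a0, k0


def fit_single_exponential(tr: Transient, direction: str = "auto") -> ExpFitResult:
    """Fit a transient to a single exponential and return k_obs with its SE.

    direction : "decay", "rise" or "auto" (sign of the end-minus-start
        change picks the direction). The fitted model is
        ``S(t) = offset + amplitude*exp(-k*t)`` with a signed amplitude.

    Parameter standard errors come from the covariance scaled by the reduced
    chi-square of the fit. If the time window spans fewer than three
    half-lives of the fitted k, the ``under_sampled`` flag is set and a
    warning emitted.

    Raises
    ------
    FitFailureError
        On non-convergence or a non-positive rate constant at the optimum.
    """
    if direction not in ("auto", "rise", "decay"):
        raise ValueError(f"unknown direction {direction!r}")
    t, s_raw = tr.time, tr.signal
    # normalise the signal so the optimiser sees O(1) numbers regardless of
    # the instrument scale; this also makes k_obs exactly invariant under
    # affine rescaling of the signal
    center = float(np.mean(s_raw))
    scale = float(np.ptp(s_raw)) or 1.0
    s = (s_raw - center) / scale
    s_inf, a0, k0 = _seed_exponential(t, s)
    if direction == "rise" and a0 > 0:
        a0 = -abs(a0)
    elif direction == "decay" and a0 < 0:
        a0 = abs(a0)

    def model(t, offset, amp, k):
        return offset + amp * np.exp(-k * t)

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # degenerate pcov handled below
            popt, pcov = curve_fit(
                model, t, s, p0=[s_inf, a0, k0], maxfev=20000,
                absolute_sigma=False, ftol=1e-13, xtol=1e-13,
            )
    except (RuntimeError, ValueError) as exc:
        raise FitFailureError(
            f"single-exponential fit did not converge: {exc}",
            {"p0": [s_inf, a0, k0], "n": t.size},
        ) from exc
    offset, amp, k = popt
    resid = s - model(t, *popt)
    if not np.all(np.isfinite(pcov)):
        # an exact (zero-residual) fit can leave the scaled covariance
        # undefined; report zero errors in that case, fail otherwise
        if np.sqrt(np.mean(resid**2)) <= 1e-10 * max(abs(amp), 1e-300):
            pcov = np.zeros((3, 3))
        else:
            raise FitFailureError(
                "single-exponential fit converged to an invalid optimum",
                {"popt": list(popt), "p0": [s_inf, a0, k0]},
            )
    if k <= 0:
        raise FitFailureError(
            "single-exponential fit converged to a non-positive rate",
            {"popt": list(popt), "p0": [s_inf, a0, k0]},
        )
    perr = np.sqrt(np.diag(pcov))
    # back to instrument units
    offset = center + scale * offset
    amp = scale * amp
    perr = np.array([scale * perr[0], scale * perr[1], perr[2]])
    resid = resid * scale
    fitted_dir = "decay" if amp >= 0 else "rise"
    if direction != "auto" and fitted_dir != direction:
        raise FitFailureError(
            f"requested a {direction} but the optimum is a {fitted_dir}",
            {"popt": list(popt)},
        )
    span = t[-1] - t[0]
    under = span * k < 3.0 * _LN2
    if under:
        warnings.warn(
            "transient spans fewer than 3 half-lives of the fitted rate; "
            "k_obs may be poorly determined",
            stacklevel=2,
        )
    return ExpFitResult(
        k_obs=float(k),
        k_obs_err=float(perr[2]),
        amplitude=float(amp),
        amplitude_err=float(perr[1]),
        offset=float(offset),
        offset_err=float(perr[0]),
        direction=fitted_dir,
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        under_sampled=bool(under),
    )


def fit_single_exponential_replicates(
    transients: Sequence[Transient], direction: str = "auto"
) -> tuple[float, float]:
    """Fit replicate traces individually and pool as mean +/- SD of k_obs.

    This is the replicate-averaging convention used for the tabulated rate
    constants (each published point is an average over separate samples and
    shots), as opposed to a global fit.
    """
    ks = [fit_single_exponential(tr, direction).k_obs for tr in transients]
    ks = np.asarray(ks)
    sd = float(np.std(ks, ddof=1)) if len(ks) > 1 else 0.0
    return float(np.mean(ks)), sd


def fit_binding_hyperbola(tit: BindingTitration) -> HyperbolaFitResult:
    """Fit a titration to ``response = base + amp*[E]/(Kd + [E])``.

    The Kd starting value is the concentration of half-maximal response.
    No ligand-depletion (tight-binding) correction is applied; the plain
    hyperbola is fitted as is conventional for this readout even when the
    ligand concentration is comparable to Kd (see docs/methods.md).

    Raises
    ------
    FitFailureError
        If fewer than 4 points are supplied, the fit does not converge, the
        optimum has a negative Kd, or the amplitude is indistinguishable
        from zero (response flat in concentration).
    """
    e, r = tit.enzyme_conc, tit.response
    if e.size < 4:
        raise FitFailureError(
            f"need >= 4 concentration points for a 3-parameter fit, got {e.size}"
        )
    base0 = float(np.min(r))
    amp0 = float(r[-1] - base0)
    if amp0 == 0:
        amp0 = max(float(np.ptp(r)), 1e-12)
    half = base0 + 0.5 * amp0
    above = np.nonzero(r >= half)[0]
    kd0 = float(e[above[0]]) if above.size else float(np.median(e))
    kd0 = max(kd0, float(np.min(e[e > 0], initial=1.0)))

    def model(e, base, amp, kd):
        return base + amp * e / (kd + e)

    sigma = tit.response_err if tit.response_err is not None else None
    try:
        popt, pcov = curve_fit(
            model, e, r, p0=[base0, amp0, kd0], sigma=sigma,
            absolute_sigma=False, maxfev=20000,
        )
    except (RuntimeError, ValueError) as exc:
        raise FitFailureError(
            f"hyperbolic fit did not converge: {exc}", {"p0": [base0, amp0, kd0]}
        ) from exc
    base, amp, kd = popt
    perr = np.sqrt(np.diag(pcov))
    if kd <= 0:
        raise FitFailureError(
            "hyperbolic fit converged to a non-positive Kd", {"popt": list(popt)}
        )
    if not np.all(np.isfinite(perr)) or abs(amp) <= 2.0 * perr[1]:
        raise FitFailureError(
            "saturation amplitude indistinguishable from zero; Kd unidentifiable",
            {"popt": list(popt), "perr": list(perr)},
        )
    resid = r - model(e, *popt)
    non_sat = float(np.max(e)) < kd
    if non_sat:
        warnings.warn(
            "titration does not reach the fitted Kd; apparent Kd is an "
            "extrapolation",
            stacklevel=2,
        )
    return HyperbolaFitResult(
        kd=float(kd),
        kd_err=float(perr[2]),
        amplitude=float(amp),
        amplitude_err=float(perr[1]),
        base=float(base),
        base_err=float(perr[0]),
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        non_saturating=bool(non_sat),
    )
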