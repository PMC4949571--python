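"""Closed-form forward models for pressure- and temperature-dependent kinetics.

Five models are provided:

* :func:`eyring_rate` -- transition-state-theory rate constant
  ``k(T) = (kB*T/h) * exp(dS/R) * exp(-dH/(R*T))``, with an Arrhenius
  alternative ``k(T) = A*exp(-Ea/(R*T))``.
* :func:`pressure_rate` -- pressure dependence of an observed rate constant,
  ``k(p) = k0 * exp(-dV*p/(R*T)) * exp(dBeta*p^2/(2*R*T))``, parameterised by
  an activation volume dV (cm^3/mol) and an activation isothermal
  compressibility dBeta (cm^3/(mol*kbar)).
* :func:`northrop_kie` -- semiclassical KIE plus a pressure-sensitive
  tunnelling component Q (Bell-correction picture).
* :func:`vibronic_kie` -- approximate Marcus-like (vibronic) KIE in which a
  promoting mode of force constant kappa samples the donor-acceptor distance
  around an equilibrium separation r0; pressure stiffens the mode
  (kappa0 + dKappa*p) and compresses the equilibrium distance (r0 - dR*p).
* :func:`kd_pressure` -- pressure perturbation of a binding equilibrium,
  same exponential-quadratic form as :func:`pressure_rate`.

All pressure arguments are in bar; coefficients quoted "per kbar" are
converted internally. Pressure inputs may be scalars or numpy arrays.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from typing import Any

import numpy as np

from .constants import H, HBAR, KB, R_CM3_BAR, R_J, R_KJ

__all__ = [
    "EyringParams",
    "PressureParams",
    "NorthropParams",
    "VibronicParams",
    "KdPressureParams",
    "eyring_rate",
    "pressure_rate",
    "northrop_kie",
    "vibronic_kie",
    "kd_pressure",
    "params_to_json",
    "params_from_json",
]

_BAR_PER_KBAR = 1000.0


def _check_finite(name: str, value: float) -> None:
    if value is None or not math.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value!r}")


@dataclass(frozen=True)
class EyringParams:
    """Activation parameters for the thermal dependence of a rate constant.

    Either the Eyring pair (``dH_act`` in kJ/mol, ``dS_act`` in J/(mol*K)) or
    the Arrhenius pair (``A`` in 1/s, ``Ea`` in kJ/mol) is populated; the
    ``mode`` flag selects which parameterisation :func:`eyring_rate` uses.
    """

    dH_act: float | None = None
    dS_act: float | None = None
    A: float | None = None
    Ea: float | None = None
    mode: str = "eyring"

    def __post_init__(self) -> None:
        if self.mode not in ("eyring", "arrhenius"):
            raise ValueError(f"mode must be 'eyring' or 'arrhenius', got {self.mode!r}")
        if self.mode == "eyring":
            _check_finite("dH_act", self.dH_act)
            _check_finite("dS_act", self.dS_act)
        else:
            _check_finite("A", self.A)
            _check_finite("Ea", self.Ea)
            if self.A <= 0:
                raise ValueError("pre-exponential factor A must be positive")

    @classmethod
    def eyring(cls, dH_act: float, dS_act: float) -> "EyringParams":
        return cls(dH_act=dH_act, dS_act=dS_act, mode="eyring")

    @classmethod
    def arrhenius(cls, A: float, Ea: float) -> "EyringParams":
        return cls(A=A, Ea=Ea, mode="arrhenius")


@dataclass(frozen=True)
class PressureParams:
    """Pressure signature of one isotope's rate constant.

    k0 : zero-pressure rate constant (1/s), k0 > 0.
    dV_act : activation volume (cm^3/mol); positive slows the rate with p.
    dBeta_act : activation isothermal compressibility (cm^3/(mol*kbar)),
        the curvature of ln k in p.
    """

    k0: float
    dV_act: float
    dBeta_act: float

    def __post_init__(self) -> None:
        _check_finite("k0", self.k0)
        _check_finite("dV_act", self.dV_act)
        _check_finite("dBeta_act", self.dBeta_act)
        if self.k0 <= 0:
            raise ValueError(f"k0 must be positive, got {self.k0}")


@dataclass(frozen=True)
class NorthropParams:
    """Semiclassical KIE with a pressure-squeezable tunnelling component.

    kie0 : semiclassical KIE (dimensionless), > 0.
    q_ratio : tunnelling-component ratio Q_H/Q_D (dimensionless), > 0.
    dV_Q : tunnelling activation volume (cm^3/mol).
    """

    kie0: float
    q_ratio: float
    dV_Q: float

    def __post_init__(self) -> None:
        for name in ("kie0", "q_ratio", "dV_Q"):
            _check_finite(name, getattr(self, name))
        if self.kie0 <= 0:
            raise ValueError("kie0 must be positive")
        if self.q_ratio <= 0:
            raise ValueError("q_ratio must be positive")


@dataclass(frozen=True)
class VibronicParams:
    """Parameters of the approximate vibronic (Marcus-like) KIE model.

    kie0 : pre-factor KIE (dimensionless), > 0.
    E : isotope mass-frequency term (1/Angstrom^2); for modes of reduced
        masses mu and angular frequencies omega, E = (mu_h*omega_h -
        mu_l*omega_l)/(2*hbar) (see :meth:`from_mode_frequencies`).
    kappa0 : promoting-mode force constant at zero pressure
        (kJ/(mol*Angstrom^2)).
    dKappa : pressure stiffening coefficient (kJ/(mol*Angstrom^2*kbar)).
    r0 : equilibrium donor-acceptor H-transfer distance at zero pressure
        (Angstrom).
    dR : pressure compression coefficient (Angstrom/kbar).
    """

    kie0: float
    E: float
    kappa0: float
    dKappa: float = 0.0
    r0: float = 0.0
    dR: float = 0.0

    def __post_init__(self) -> None:
        for name in ("kie0", "E", "kappa0", "dKappa", "r0", "dR"):
            _check_finite(name, getattr(self, name))
        if self.kie0 <= 0:
            raise ValueError("kie0 must be positive")

    @classmethod
    def from_mode_frequencies(
        cls,
        kie0: float,
        mu_h: float,
        omega_h: float,
        mu_l: float,
        omega_l: float,
        kappa0: float,
        dKappa: float = 0.0,
        r0: float = 0.0,
        dR: float = 0.0,
    ) -> "VibronicParams":
        """Build parameters with E derived from the isotope vibrational modes.

        mu_h, mu_l are reduced masses (kg) and omega_h, omega_l angular
        frequencies (rad/s) of the heavy/light isotope stretch; the derived
        E = (mu_h*omega_h - mu_l*omega_l)/(2*hbar) is converted from 1/m^2
        to 1/Angstrom^2. Requires mu_h*omega_h > mu_l*omega_l so E > 0.
        """
        E_m2 = (mu_h * omega_h - mu_l * omega_l) / (2.0 * HBAR)
        if E_m2 <= 0:
            raise ValueError(
                "mu_h*omega_h must exceed mu_l*omega_l for a positive mass-frequency term"
            )
        return cls(kie0=kie0, E=E_m2 * 1e-20, kappa0=kappa0, dKappa=dKappa, r0=r0, dR=dR)


@dataclass(frozen=True)
class KdPressureParams:
    """Pressure signature of a dissociation constant.

    kd0 : zero-pressure Kd (uM), > 0.
    dV : reaction volume (cm^3/mol); negative values mean Kd grows with p.
    dBeta : compressibility term (cm^3/(mol*kbar)).
    """

    kd0: float
    dV: float
    dBeta: float

    def __post_init__(self) -> None:
        for name in ("kd0", "dV", "dBeta"):
            _check_finite(name, getattr(self, name))
        if self.kd0 <= 0:
            raise ValueError("kd0 must be positive")


def _check_temperature(T: float) -> None:
    if not np.all(np.asarray(T) > 0):
        raise ValueError(f"temperature must be positive (K), got {T!r}")


def eyring_rate(params: EyringParams, T):
    """Rate constant (1/s) at temperature T (K) from activation parameters."""
    _check_temperature(T)
    T = np.asarray(T, dtype=float)
    if params.mode == "arrhenius":
        out = params.A * np.exp(-params.Ea * 1e3 / (R_J * T))
    else:
        out = (
            KB * T / H
            * np.exp(params.dS_act / R_J)
            * np.exp(-params.dH_act * 1e3 / (R_J * T))
        )
    return out if out.ndim else float(out)


def _pressure_factor(p, dV: float, dBeta: float, T: float):
    """exp(-dV*p/RT) * exp(dBeta*p^2/(2RT)) with p in bar, dBeta per kbar."""
    p = np.asarray(p, dtype=float)
    rt = R_CM3_BAR * T
    return np.exp(-dV * p / rt) * np.exp(dBeta * p * p / _BAR_PER_KBAR / (2.0 * rt))


def pressure_rate(params: PressureParams, p, T: float = 298.15):
    """Observed rate constant (1/s) at pressure p (bar) and temperature T (K).

    At p = 0 this returns exactly ``params.k0`` (both exponential factors are
    exactly 1).
    """
    _check_temperature(T)
    out = params.k0 * _pressure_factor(p, params.dV_act, params.dBeta_act, T)
    return out if np.ndim(out) else float(out)


def northrop_kie(params: NorthropParams, p, T: float = 298.15):
    """Observed KIE at pressure p (bar): KIE0 + KIE0*(Q_H/Q_D - 1)*exp(-dV_Q*p/RT).

    At p = 0 this equals KIE0*(Q_H/Q_D); as p -> inf with dV_Q > 0 the
    tunnelling component is squeezed out and the KIE tends to KIE0.
    """
    _check_temperature(T)
    p = np.asarray(p, dtype=float)
    out = params.kie0 + params.kie0 * (params.q_ratio - 1.0) * np.exp(
        -params.dV_Q * p / (R_CM3_BAR * T)
    )
    return out if out.ndim else float(out)


def vibronic_kie(params: VibronicParams, p, T: float = 298.15):
    """Observed KIE from the approximate vibronic model.

    KIE(p, T) = KIE0 * exp(-2*E*kB*T / (kappa0 + dKappa*p))
                     * exp(E * (r0 - dR*p)^2)

    with p converted to kbar for the per-kbar coefficients and kB*T expressed
    as a molar energy R*T (kJ/mol) so that kB*T/kappa has units Angstrom^2.
    Note the published typesetting of this expression is ambiguous; the
    division form used here is the dimensionally consistent reading (see
    docs/methods.md).
    """
    _check_temperature(T)
    p_kbar = np.asarray(p, dtype=float) / _BAR_PER_KBAR
    kappa = params.kappa0 + params.dKappa * p_kbar
    if np.any(kappa <= 0):
        raise ValueError(
            "effective force constant kappa0 + dKappa*p must stay positive "
            "over the requested pressure range"
        )
    rt_kj = R_KJ * T
    out = (
        params.kie0
        * np.exp(-2.0 * params.E * rt_kj / kappa)
        * np.exp(params.E * (params.r0 - params.dR * p_kbar) ** 2)
    )
    return out if out.ndim else float(out)


def kd_pressure(params: KdPressureParams, p, T: float = 298.15):
    """Dissociation constant (uM) at pressure p (bar).

    Kd(p) = Kd0 * exp(-dV*p/RT) * exp(dBeta*p^2/(2RT)); exactly Kd0 at p = 0.
    """
    _check_temperature(T)
    out = params.kd0 * _pressure_factor(p, params.dV, params.dBeta, T)
    return out if np.ndim(out) else float(out)


# --- JSON round-tripping -----------------------------------------------------

_PARAM_TYPES = {
    "EyringParams": EyringParams,
    "PressureParams": PressureParams,
    "NorthropParams": NorthropParams,
    "VibronicParams": VibronicParams,
    "KdPressureParams": KdPressureParams,
}

_UNITS: dict[str, dict[str, str]] = {
    "EyringParams": {
        "dH_act": "kJ/mol", "dS_act": "J/(mol*K)", "A": "1/s", "Ea": "kJ/mol",
    },
    "PressureParams": {
        "k0": "1/s", "dV_act": "cm^3/mol", "dBeta_act": "cm^3/(mol*kbar)",
    },
    "NorthropParams": {
        "kie0": "", "q_ratio": "", "dV_Q": "cm^3/mol",
    },
    "VibronicParams": {
        "kie0": "", "E": "1/angstrom^2", "kappa0": "kJ/(mol*angstrom^2)",
        "dKappa": "kJ/(mol*angstrom^2*kbar)", "r0": "angstrom", "dR": "angstrom/kbar",
    },
    "KdPressureParams": {
        "kd0": "uM", "dV": "cm^3/mol", "dBeta": "cm^3/(mol*kbar)",
    },
}


def params_to_json(params: Any) -> str:
    """Serialise any parameter set to JSON with explicit unit strings."""
    cls = type(params).__name__
    if cls not in _PARAM_TYPES:
        raise TypeError(f"not a known parameter type: {cls}")
    payload = {
        "type": cls,
        "values": dataclasses.asdict(params),
        "units": _UNITS[cls],
    }
    return json.dumps(payload, indent=2)


def params_from_json(text: str) -> Any:
    """Inverse of :func:`params_to_json`."""
    payload = json.loads(text)
    cls = _PARAM_TYPES[payload["type"]]
    return cls(**payload["values"])
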