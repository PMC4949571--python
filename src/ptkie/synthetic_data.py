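"""Seeded generators for every input the analysis pipeline consumes.

The generators emulate the high-pressure photolysis experimental design:
rate constants for an H/D isotope pair on a 1 bar - 2 kbar grid in 250-bar
steps, single-exponential absorbance transients, hyperbolic binding
titrations, and Kd-versus-pressure series — all produced from ground-truth
forward-model parameters with Gaussian noise.

Noise conventions: rates and Kd values carry multiplicative (relative)
Gaussian noise, matching the roughly proportional errors of the published
rate tables; transients carry additive noise scaled to the amplitude.
Replicates default to 3 (published points average two or three samples).

A single global seed is expanded into independent per-stream child seeds
(numpy ``SeedSequence.spawn``) so adding one stream never shifts another.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import T_DEFAULT
from .core_models import KdPressureParams, PressureParams, kd_pressure, pressure_rate
from .pt_fitting import RateSeries
from .transient_analysis import BindingTitration, Transient

__all__ = [
    "SimulationConfig",
    "default_pressure_grid",
    "simulate_rate_table",
    "simulate_transient",
    "simulate_kd_series",
    "simulate_kd_titrations",
]


def default_pressure_grid() -> np.ndarray:
    """The experimental grid: 1 bar, then 250-2000 bar in 250-bar steps."""
    return np.array([1, 250, 500, 750, 1000, 1250, 1500, 1750, 2000], dtype=float)


@dataclass
class SimulationConfig:
    """Ground truth and noise model for a simulated rate-table experiment.

    truth : mapping isotope -> PressureParams (needs both "H" and "D").
    pressures : bar grid (defaults to the 9-point experimental grid).
    temperature : K.
    sigma : relative Gaussian noise per shot (0.08 = 8%).
    replicates : shots averaged per tabulated point.
    seed : global integer seed.
    """

    truth: dict[str, PressureParams]
    pressures: np.ndarray = field(default_factory=default_pressure_grid)
    temperature: float = T_DEFAULT
    sigma: float = 0.08
    replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        self.pressures = np.asarray(self.pressures, dtype=float)
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if self.replicates < 1:
            raise ValueError("need at least one replicate")
        if self.pressures.size == 0:
            raise ValueError("pressure grid must be non-empty")


def _child_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def simulate_rate_table(cfg: SimulationConfig) -> tuple[RateSeries, RateSeries]:
    """Simulate the (H, D) rate-series pair of one pressure experiment.

    Each tabulated point is the mean over ``cfg.replicates`` draws of
    ``k_true*(1 + eps)``, eps ~ N(0, sigma^2) i.i.d., with the replicate SD
    reported as its error. With sigma = 0 the table equals the noiseless
    forward-model evaluations exactly (and the errors are zero).
    """
    if not {"H", "D"} <= set(cfg.truth):
        raise ValueError("truth must contain both 'H' and 'D' parameter sets")
    rngs = dict(zip(("H", "D"), _child_rngs(cfg.seed, 2)))
    out = []
    for iso in ("H", "D"):
        k_true = pressure_rate(cfg.truth[iso], cfg.pressures, cfg.temperature)
        k_true = np.atleast_1d(k_true)
        if cfg.sigma == 0:
            k_mean, k_sd = k_true.copy(), np.zeros_like(k_true)
        else:
            draws = k_true[None, :] * (
                1.0 + cfg.sigma * rngs[iso].standard_normal((cfg.replicates, k_true.size))
            )
            k_mean = draws.mean(axis=0)
            k_sd = (
                draws.std(axis=0, ddof=1)
                if cfg.replicates > 1
                else cfg.sigma * np.abs(draws[0])
            )
        out.append(
            RateSeries(
                axis=cfg.pressures.copy(),
                k_obs=k_mean,
                k_err=k_sd,
                isotope=iso,
                axis_kind="pressure",
                fixed_T=cfg.temperature,
            )
        )
    return out[0], out[1]


def simulate_transient(
    k_true: float,
    direction: str = "decay",
    window: float | None = None,
    n_points: int = 500,
    sigma: float = 0.05,
    seed: int = 0,
    amplitude: float = 1.0,
    offset: float = 0.0,
    pressure_bar: float = 1.0,
    temperature_K: float = T_DEFAULT,
    isotope: str = "H",
) -> Transient:
    """Simulate a single-exponential absorbance transient.

    window : trace length in seconds (default 5/k_true). sigma is the
    additive noise SD as a fraction of the amplitude. A window shorter than
    3/k_true under-samples the kinetics; the downstream fit flags it.
    """
    if k_true <= 0:
        raise ValueError("k_true must be positive")
    if direction not in ("rise", "decay"):
        raise ValueError("direction must be rise|decay")
    if window is None:
        window = 5.0 / k_true
    t = np.linspace(0.0, window, n_points)
    amp = amplitude if direction == "decay" else -amplitude
    s = offset + amp * np.exp(-k_true * t)
    if sigma > 0:
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        s = s + sigma * abs(amplitude) * rng.standard_normal(t.size)
    return Transient(
        time=t,
        signal=s,
        pressure_bar=pressure_bar,
        temperature_K=temperature_K,
        isotope=isotope,
    )


def simulate_kd_series(
    truth: KdPressureParams,
    pressures: np.ndarray | None = None,
    sigma: float = 0.05,
    seed: int = 0,
    T: float = T_DEFAULT,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Simulate an apparent-Kd-versus-pressure series.

    Returns (pressures, kd, kd_err) with kd = Kd_true*(1 + eps),
    eps ~ N(0, sigma^2), and kd_err = sigma*Kd_true (the known noise scale).
    """
    p = default_pressure_grid() if pressures is None else np.asarray(pressures, float)
    kd_true = np.atleast_1d(kd_pressure(truth, p, T))
    if sigma == 0:
        return p, kd_true.copy(), np.zeros_like(kd_true)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    kd = kd_true * (1.0 + sigma * rng.standard_normal(kd_true.size))
    return p, kd, sigma * kd_true


def simulate_kd_titrations(
    truth: KdPressureParams,
    pressures: np.ndarray | None = None,
    enzyme_conc: np.ndarray | None = None,
    sigma: float = 0.03,
    seed: int = 0,
    base: float = 1.0,
    amplitude: float = 1.0,
    T: float = T_DEFAULT,
) -> list[BindingTitration]:
    """Simulate per-pressure binding titrations from a Kd(p) ground truth.

    response = base + amplitude*[E]/(Kd(p) + [E]) + N(0, (sigma*amplitude)^2)
    at each enzyme concentration (uM). An enzyme grid that does not extend
    beyond the largest Kd on the pressure grid leaves the high-pressure
    titrations non-saturating; the downstream hyperbolic fit warns about it.
    Each pressure gets its own child seed.
    """
    p = default_pressure_grid() if pressures is None else np.asarray(pressures, float)
    e = (
        np.array([5, 10, 20, 40, 60, 100, 150, 200], dtype=float)
        if enzyme_conc is None
        else np.asarray(enzyme_conc, dtype=float)
    )
    rngs = _child_rngs(seed, p.size)
    out = []
    for pi, rng in zip(p, rngs):
        kd = kd_pressure(truth, pi, T)
        resp = base + amplitude * e / (kd + e)
        if sigma > 0:
            resp = resp + sigma * amplitude * rng.standard_normal(e.size)
        err = np.full(e.size, sigma * amplitude) if sigma > 0 else None
        out.append(
            BindingTitration(
                enzyme_conc=e.copy(), response=resp, response_err=err, pressure_bar=pi
            )
        )
    return out
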