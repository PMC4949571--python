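"""Cross-system correlation of p-T KIE signature parameters.

Given a table of per-system KIE signatures (KIE0, ddH, ddS, ddV, ddBeta with
standard errors), this module fits error-weighted straight lines between
pairs of parameters — typically each pressure parameter against the
temperature-dependence proxy ddH — and reports the slope, intercept and an
adjusted weighted R^2.

Only y-errors enter the weights (1/sigma_y^2); x-errors, although tabulated,
are ignored rather than treated with an errors-in-variables model. Rows with
an error fixed to zero (parameters frozen in the original fits) would get
infinite weight, so their weight is capped at the largest finite weight in
the column.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm

from .pt_fitting import SystemSummary

__all__ = [
    "LinearFitResult",
    "weighted_linear_fit",
    "correlate_summary_table",
    "PARAM_NAMES",
]

PARAM_NAMES = ("kie0", "ddH", "ddS", "ddV", "ddBeta")


@dataclass
class LinearFitResult:
    """Error-weighted straight-line fit y = intercept + slope*x."""

    slope: float
    slope_err: float
    intercept: float
    intercept_err: float
    r2_adj: float
    n: int
    skipped: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.r2_adj > 1 + 1e-12:
            raise ValueError("adjusted R^2 cannot exceed 1")


def weighted_linear_fit(x, y, y_err) -> LinearFitResult:
    """Weighted least-squares line with weights 1/sigma_y^2.

    The weighted R^2 is 1 - SS_res,w/SS_tot,w about the weighted mean of y,
    and the adjustment is 1 - (1 - R^2)*(n - 1)/(n - 2).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    y_err = np.asarray(y_err, dtype=float)
    if x.size != y.size or y.size != y_err.size:
        raise ValueError("x, y and y_err must have equal length")
    if x.size < 3:
        raise ValueError(f"need >= 3 points, got {x.size}")
    if np.any(y_err <= 0):
        raise ValueError("y_err must be positive (cap zero-error rows first)")
    if np.ptp(x) == 0:
        raise ValueError("x has zero variance; slope is undefined")
    w = 1.0 / y_err**2
    res = sm.WLS(y, sm.add_constant(x), weights=w).fit()
    return LinearFitResult(
        slope=float(res.params[1]),
        slope_err=float(res.bse[1]),
        intercept=float(res.params[0]),
        intercept_err=float(res.bse[0]),
        r2_adj=float(res.rsquared_adj),
        n=int(x.size),
    )


def _column(rows: Sequence[SystemSummary], name: str) -> tuple[np.ndarray, np.ndarray]:
    vals = np.array([getattr(r, name, None) for r in rows], dtype=object)
    errs = np.array([getattr(r, f"{name}_err", None) for r in rows], dtype=object)
    to_f = lambda a: np.array([np.nan if v is None else float(v) for v in a])
    return to_f(vals), to_f(errs)


def correlate_summary_table(
    rows: Sequence[SystemSummary], x_param: str, y_param: str
) -> LinearFitResult:
    """Error-weighted linear fit of one signature parameter against another.

    x_param, y_param are any of ``kie0, ddH, ddS, ddV, ddBeta``. Rows missing
    either value (e.g. systems with no temperature-dependence data) are
    skipped and listed in the result. Zero y-errors (parameters fixed in the
    source fits) are replaced by the smallest positive y-error in the column,
    i.e. their weight is capped at the largest finite weight.
    """
    for name in (x_param, y_param):
        if name not in PARAM_NAMES:
            raise ValueError(f"unknown parameter {name!r}; choose from {PARAM_NAMES}")
    xv, xe = _column(rows, x_param)
    yv, ye = _column(rows, y_param)
    ok = np.isfinite(xv) & np.isfinite(yv) & np.isfinite(ye)
    skipped = tuple(r.system for r, keep in zip(rows, ok) if not keep)
    if ok.sum() < 3:
        raise ValueError(
            f"fewer than 3 usable rows for {y_param} vs {x_param} "
            f"(skipped: {skipped})"
        )
    xv, yv, ye = xv[ok], yv[ok], ye[ok]
    pos = ye > 0
    if not pos.any():
        raise ValueError("all y-errors are zero; weights undefined")
    ye = np.where(pos, ye, ye[pos].min())
    fit = weighted_linear_fit(xv, yv, ye)
    fit.skipped = skipped
    return fit
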