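"""CSV/JSON readers and writers, and the packaged reference datasets.

Schemas
-------
Rate tables : CSV with columns ``reaction, isotope, pressure_bar,
    temperature_K, k_obs, k_err`` (one row per pressure point), grouped on
    read into :class:`~ptkie.pt_fitting.RateSeries` by (reaction, isotope).
Transients : two-column CSV ``time_s, signal_au`` plus a JSON sidecar with
    pressure/temperature/isotope metadata.
Titrations : CSV ``enzyme_uM, ratio_642_630, err``.
Summary tables : CSV matching the :class:`~ptkie.pt_fitting.SystemSummary`
    fields.

Numeric values are serialised in scientific notation with >= 6 significant
digits so write/read round trips are drift-free at the precision the data
carry.

The packaged fixtures are the published reference datasets: the 4 x 9 rate
table, the corresponding pressure-fit parameters, the 8-system KIE-signature
summary table and the pigment-binding Kd pressure parameters. Each is
checksummed; :func:`verify_fixtures` recomputes the hashes.
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core_models import KdPressureParams
from .pt_fitting import RateSeries, SystemSummary
from .transient_analysis import BindingTitration, Transient

__all__ = [
    "ParseError",
    "read_rate_table",
    "write_rate_table",
    "read_summary_table",
    "write_summary_table",
    "read_transient",
    "write_transient",
    "read_titration",
    "write_titration",
    "load_table1_rates",
    "load_table2_params",
    "load_table3_summaries",
    "load_kd_params",
    "verify_fixtures",
    "FIXTURE_SHA256",
]

_RATE_COLUMNS = ["reaction", "isotope", "pressure_bar", "temperature_K", "k_obs", "k_err"]
_SUMMARY_COLUMNS = [
    "system", "kie0", "kie0_err", "ddH", "ddH_err", "ddS", "ddS_err",
    "ddV", "ddV_err", "ddBeta", "ddBeta_err",
]

FIXTURE_SHA256 = {
    "table1_rates.csv": "8b0ca6dde80e14d06b6e03397d19426e7129e696e44a506572f66276309a6742",
    "table2_params.csv": "f5939de46a09e02fad2e5956043a09fe7f0b84a5e403144519c828036d65e965",
    "table3_summaries.csv": "78e8ee7edf4e4a10c5dd47a8d7b99432e4c3cd66c2aafccd9a3a22f094b88bce",
    "kd_params.json": "f1b89306762e63021ed14c27c89fc253e25135152288e60f16dff1ffb37275bc",
}


class ParseError(ValueError):
    """A data file did not match its schema; the message names the row."""


def _read_csv(path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {missing}")
    return df


def read_rate_table(path) -> dict[tuple[str, str], RateSeries]:
    """Read a rate-table CSV into series keyed by (reaction, isotope).

    Rows are re-ordered by pressure within each series; duplicate
    (reaction, isotope, pressure) rows or non-numeric cells raise
    :class:`ParseError` naming the offending row.
    """
    df = _read_csv(path, _RATE_COLUMNS)
    for col in ("pressure_bar", "temperature_K", "k_obs", "k_err"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if bad.any() or df[col].isna().any():
            row = int((bad | df[col].isna()).idxmax())
            raise ParseError(f"{path}: non-numeric or empty {col!r} at data row {row}")
        df[col] = vals
    out: dict[tuple[str, str], RateSeries] = {}
    for (rxn, iso), grp in df.groupby(["reaction", "isotope"], sort=False):
        dup = grp["pressure_bar"].duplicated()
        if dup.any():
            row = int(grp.index[dup][0])
            raise ParseError(
                f"{path}: duplicate pressure for ({rxn}, {iso}) at data row {row}"
            )
        grp = grp.sort_values("pressure_bar")
        temps = grp["temperature_K"].unique()
        if temps.size != 1:
            raise ParseError(f"{path}: mixed temperatures within series ({rxn}, {iso})")
        out[(str(rxn), str(iso))] = RateSeries(
            axis=grp["pressure_bar"].to_numpy(),
            k_obs=grp["k_obs"].to_numpy(),
            k_err=grp["k_err"].to_numpy(),
            isotope=str(iso),
            axis_kind="pressure",
            fixed_T=float(temps[0]),
            label=str(rxn),
        )
    return out


def write_rate_table(series: Sequence[RateSeries], path) -> None:
    rows = []
    for s in series:
        for p, k, e in zip(s.axis, s.k_obs, s.k_err):
            rows.append(
                {
                    "reaction": s.label or "reaction",
                    "isotope": s.isotope,
                    "pressure_bar": p,
                    "temperature_K": s.fixed_T,
                    "k_obs": f"{k:.6e}",
                    "k_err": f"{e:.6e}",
                }
            )
    pd.DataFrame(rows, columns=_RATE_COLUMNS).to_csv(path, index=False)


def read_summary_table(path) -> list[SystemSummary]:
    df = _read_csv(path, _SUMMARY_COLUMNS)
    out = []
    for _, row in df.iterrows():
        kwargs = {}
        for name in ("ddH", "ddH_err", "ddS", "ddS_err"):
            v = row[name]
            kwargs[name] = None if pd.isna(v) else float(v)
        out.append(
            SystemSummary(
                system=str(row["system"]),
                kie0=float(row["kie0"]),
                kie0_err=float(row["kie0_err"]),
                ddV=float(row["ddV"]),
                ddV_err=float(row["ddV_err"]),
                ddBeta=float(row["ddBeta"]),
                ddBeta_err=float(row["ddBeta_err"]),
                **kwargs,
            )
        )
    return out


def write_summary_table(rows: Sequence[SystemSummary], path) -> None:
    recs = []
    for r in rows:
        recs.append({c: getattr(r, c) for c in _SUMMARY_COLUMNS})
    pd.DataFrame(recs, columns=_SUMMARY_COLUMNS).to_csv(path, index=False)


def write_transient(tr: Transient, path) -> None:
    """Write a transient as CSV with a JSON metadata sidecar (same stem)."""
    path = Path(path)
    pd.DataFrame({"time_s": tr.time, "signal_au": tr.signal}).to_csv(
        path, index=False, float_format="%.8e"
    )
    meta = {
        "pressure_bar": tr.pressure_bar,
        "temperature_K": tr.temperature_K,
        "isotope": tr.isotope,
        "wavelength_nm": tr.wavelength_nm,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def read_transient(path) -> Transient:
    path = Path(path)
    df = _read_csv(path, ["time_s", "signal_au"])
    meta_path = path.with_suffix(".json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return Transient(
        time=df["time_s"].to_numpy(float),
        signal=df["signal_au"].to_numpy(float),
        pressure_bar=float(meta.get("pressure_bar", 1.0)),
        temperature_K=float(meta.get("temperature_K", 298.15)),
        isotope=str(meta.get("isotope", "H")),
        wavelength_nm=float(meta.get("wavelength_nm", 696.0)),
    )


def write_titration(tit: BindingTitration, path) -> None:
    err = (
        tit.response_err
        if tit.response_err is not None
        else np.full(tit.response.size, np.nan)
    )
    pd.DataFrame(
        {"enzyme_uM": tit.enzyme_conc, "ratio_642_630": tit.response, "err": err}
    ).to_csv(path, index=False, float_format="%.8e")


def read_titration(path, pressure_bar: float = 1.0) -> BindingTitration:
    df = _read_csv(path, ["enzyme_uM", "ratio_642_630"])
    err = None
    if "err" in df.columns and df["err"].notna().all():
        err = df["err"].to_numpy(float)
    return BindingTitration(
        enzyme_conc=df["enzyme_uM"].to_numpy(float),
        response=df["ratio_642_630"].to_numpy(float),
        response_err=err,
        pressure_bar=pressure_bar,
    )


# --- packaged fixtures -------------------------------------------------------

def _fixture_path(name: str):
    return resources.files("ptkie").joinpath("data", name)


def verify_fixtures() -> None:
    """Recompute fixture checksums; raise if any packaged file was altered."""
    for name, expect in FIXTURE_SHA256.items():
        got = hashlib.sha256(_fixture_path(name).read_bytes()).hexdigest()
        if got != expect:
            raise RuntimeError(f"fixture {name} checksum mismatch: {got}")


def load_table1_rates() -> dict[tuple[str, str], RateSeries]:
    """The published rate table: 4 series (hydride/proton x H/D), 9 pressures."""
    with resources.as_file(_fixture_path("table1_rates.csv")) as p:
        return read_rate_table(p)


def load_table2_params() -> pd.DataFrame:
    """Published pressure-fit parameters (k0, dV, dBeta with SEs) per series."""
    with resources.as_file(_fixture_path("table2_params.csv")) as p:
        return pd.read_csv(p)


def load_table3_summaries() -> list[SystemSummary]:
    """Published cross-system p-T KIE signatures (8 systems)."""
    with resources.as_file(_fixture_path("table3_summaries.csv")) as p:
        return read_summary_table(p)


def load_kd_params() -> tuple[KdPressureParams, dict[str, float]]:
    """Published pigment Kd(p) parameters; returns (params, standard errors)."""
    payload = json.loads(_fixture_path("kd_params.json").read_text())
    params = KdPressureParams(
        kd0=payload["kd0"], dV=payload["dV"], dBeta=payload["dBeta"]
    )
    errs = {
        "kd0": payload["kd0_err"],
        "dV": payload["dV_err"],
        "dBeta": payload["dBeta_err"],
    }
    return params, errs
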