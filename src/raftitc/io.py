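"""File readers and writers: CSV tables, YAML configs, JSON results.

One dialect per format, validated strictly: CSV with dot decimals and
required headers for tabular data, YAML for titration designs and
binding parameters, JSON for fit results.  Parse errors name the
offending row and column.
"""

from __future__ import annotations

import csv
import json
import math
import re
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .binding_models import (
    BindingParams,
    BindingParams1Site,
    BindingParams2Site,
    SiteParams,
    TitrationDesign,
)
from .fitting import FitResult
from .sar_analysis import SCAN_KINDS, ScanTable
from .spectro import CDSpectrum, EmissionSpectrum
from .thermogram import InjectionHeats, PowerTrace


class ParseError(ValueError):
    """Malformed input file."""


_COMMA_DECIMAL = re.compile(r"^-?\d+,\d+$")
_THOUSANDS = re.compile(r"^-?\d{1,3}(,\d{3})+(\.\d+)?$")


def _parse_float(cell: str, row: int, col: str, allow_thousands: bool = False) -> float:
    text = cell.strip().strip('"')
    if text == "":
        raise ParseError(f"empty cell at row {row}, column {col!r}")
    if allow_thousands and _THOUSANDS.match(text):
        text = text.replace(",", "")
    elif _COMMA_DECIMAL.match(text):
        raise ParseError(
            f"comma decimal {cell!r} at row {row}, column {col!r}: "
            "dot-decimal notation is enforced"
        )
    try:
        return float(text)
    except ValueError as exc:
        raise ParseError(f"non-numeric cell {cell!r} at row {row}, column {col!r}") from exc


# ---------------------------------------------------------------- heats CSV

HEATS_HEADER = ["injection_index", "heat_ucal"]


def write_heats(path: str | Path, heats: InjectionHeats) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(HEATS_HEADER)
        for i, q in enumerate(heats.heats_ucal, start=1):
            writer.writerow([i, format(q, ".17g")])


def read_heats(path: str | Path) -> InjectionHeats:
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    if not rows or [c.strip() for c in rows[0]] != HEATS_HEADER:
        raise ParseError(
            f"{path}: expected header {','.join(HEATS_HEADER)!r}, "
            f"got {','.join(rows[0]) if rows else '<empty file>'!r}"
        )
    heats = []
    for r, row in enumerate(rows[1:], start=2):
        if len(row) != 2:
            raise ParseError(f"{path}: row {r} has {len(row)} columns, expected 2")
        _parse_float(row[0], r, HEATS_HEADER[0])
        heats.append(_parse_float(row[1], r, HEATS_HEADER[1]))
    return InjectionHeats(np.array(heats))


# ------------------------------------------------------------- spectra CSV

_SPECTRUM_HEADERS = {
    "emission": ["wavelength_nm", "intensity"],
    "cd": ["wavelength_nm", "ellipticity_mdeg"],
}


def write_spectrum(path: str | Path, spectrum: EmissionSpectrum | CDSpectrum) -> None:
    kind = "emission" if isinstance(spectrum, EmissionSpectrum) else "cd"
    values = spectrum.intensity if kind == "emission" else spectrum.ellipticity_mdeg
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_SPECTRUM_HEADERS[kind])
        for wl, v in zip(spectrum.wavelength_nm, values):
            writer.writerow([format(wl, ".17g"), format(v, ".17g")])


def read_spectrum(path: str | Path, kind: str = "emission"):
    header = _SPECTRUM_HEADERS.get(kind)
    if header is None:
        raise ValueError(f"unknown spectrum kind {kind!r}")
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    if not rows or [c.strip() for c in rows[0]] != header:
        raise ParseError(f"{path}: expected header {','.join(header)!r}")
    wl, vals = [], []
    for r, row in enumerate(rows[1:], start=2):
        if len(row) != 2:
            raise ParseError(f"{path}: row {r} has {len(row)} columns, expected 2")
        wl.append(_parse_float(row[0], r, header[0]))
        vals.append(_parse_float(row[1], r, header[1]))
    cls = EmissionSpectrum if kind == "emission" else CDSpectrum
    return cls(np.array(wl), np.array(vals))


# --------------------------------------------------------------- trace CSV

TRACE_HEADER = ["time_s", "power_ucal_per_s"]


def write_trace(path: str | Path, trace: PowerTrace) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(TRACE_HEADER)
        for t, p in zip(trace.time_s, trace.power_ucal_per_s):
            writer.writerow([format(t, ".17g"), format(p, ".17g")])


def read_trace(path: str | Path, injection_times_s: np.ndarray) -> PowerTrace:
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    if not rows or [c.strip() for c in rows[0]] != TRACE_HEADER:
        raise ParseError(f"{path}: expected header {','.join(TRACE_HEADER)!r}")
    t, p = [], []
    for r, row in enumerate(rows[1:], start=2):
        if len(row) != 2:
            raise ParseError(f"{path}: row {r} has {len(row)} columns, expected 2")
        t.append(_parse_float(row[0], r, TRACE_HEADER[0]))
        p.append(_parse_float(row[1], r, TRACE_HEADER[1]))
    return PowerTrace(np.array(t), np.array(p), np.asarray(injection_times_s, dtype=float))


# ---------------------------------------------------------- scan table CSV

_SCAN_ALIASES = {
    "ala": "ala", "ala-scan": "ala", "alascan": "ala",
    "d": "d", "d-scan": "d", "dscan": "d",
    "beta": "beta", "beta-scan": "beta", "b-scan": "beta", "b3": "beta",
    "β": "beta", "β-scan": "beta", "β3": "beta",
}


def read_scan_table(
    path: str | Path,
    parent_kd_nm: float,
    sequence: str = "WYKYW",
    temperature_k: float = 308.15,
) -> ScanTable:
    """Read a positional-scan K_D matrix.

    Rows are scan kinds (Ala/D/beta aliases accepted), columns are
    position labels; cells are K_D in nM, ``n.f.`` marks a
    not-fittable titration, and thousands separators ("10,467") are
    accepted in quoted cells.
    """
    import pandas as pd

    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    if not rows or rows[0][0].strip().lower() != "scan":
        raise ParseError(f"{path}: first header column must be 'scan'")
    columns = [c.strip() for c in rows[0][1:]]
    data: dict[str, list[float]] = {}
    for r, row in enumerate(rows[1:], start=2):
        if len(row) != len(columns) + 1:
            raise ParseError(
                f"{path}: row {r} has {len(row)} columns, expected {len(columns) + 1}"
            )
        label = row[0].strip().lower()
        kind = _SCAN_ALIASES.get(label)
        if kind is None:
            raise ParseError(f"{path}: unknown scan label {row[0]!r} at row {r}")
        vals = []
        for col, cell in zip(columns, row[1:]):
            if cell.strip().lower() in {"n.f.", "nf", "n.f"}:
                vals.append(math.nan)
            else:
                v = _parse_float(cell, r, col, allow_thousands=True)
                vals.append(v)
        data[kind] = vals
    frame = pd.DataFrame.from_dict(data, orient="index", columns=columns)
    return ScanTable(parent_kd_nm, frame, sequence=sequence, temperature_k=temperature_k)


def load_wykyw_scan() -> ScanTable:
    """The packaged positional-scan K_D fixture for the WYKYW parent.

    Parent K_D 23.8 nM; one not-fittable cell (Ala-scan, N-terminal
    Trp).  All values in nM at 308.15 K.
    """
    path = resources.files("raftitc").joinpath("data/wykyw_scan_kd.csv")
    with resources.as_file(path) as p:
        return read_scan_table(p, parent_kd_nm=23.8)


# ------------------------------------------------------------- YAML configs

def write_design(path: str | Path, design: TitrationDesign) -> None:
    payload = {
        "cell_volume_ml": design.cell_volume_ml,
        "cell_conc_um": design.cell_conc_um,
        "syringe_conc_um": design.syringe_conc_um,
        "injection_volumes_ul": list(design.injection_volumes_ul),
        "injection_interval_s": design.injection_interval_s,
        "temperature_k": design.temperature_k,
        "syringe_capacity_ul": design.syringe_capacity_ul,
        "perfusion": design.perfusion,
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def read_design(path: str | Path) -> TitrationDesign:
    payload = yaml.safe_load(Path(path).read_text())
    if not isinstance(payload, dict):
        raise ParseError(f"{path}: design file must be a YAML mapping")
    try:
        if "injection_volumes_ul" in payload:
            payload["injection_volumes_ul"] = tuple(payload["injection_volumes_ul"])
        return TitrationDesign(**payload)
    except (TypeError, ValueError) as exc:
        raise ParseError(f"{path}: invalid titration design: {exc}") from exc


def write_params(path: str | Path, params: BindingParams) -> None:
    if isinstance(params, BindingParams1Site):
        payload = {
            "model": "one_site", "n": params.n, "kd_nm": params.kd_nm,
            "dh_kcal_per_mol": params.dh_kcal_per_mol, "q_dil_ucal": params.q_dil_ucal,
        }
    else:
        payload = {
            "model": "two_site",
            "site1": {"n": params.site1.n, "kd_nm": params.site1.kd_nm,
                      "dh_kcal_per_mol": params.site1.dh_kcal_per_mol},
            "site2": {"n": params.site2.n, "kd_nm": params.site2.kd_nm,
                      "dh_kcal_per_mol": params.site2.dh_kcal_per_mol},
            "q_dil_ucal": params.q_dil_ucal,
        }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def read_params(path: str | Path) -> BindingParams:
    payload = yaml.safe_load(Path(path).read_text())
    if not isinstance(payload, dict) or "model" not in payload:
        raise ParseError(f"{path}: params file must be a YAML mapping with a 'model' key")
    model = payload["model"]
    try:
        if model == "one_site":
            return BindingParams1Site(
                n=payload["n"], kd_nm=payload["kd_nm"],
                dh_kcal_per_mol=payload["dh_kcal_per_mol"],
                q_dil_ucal=payload.get("q_dil_ucal", 0.0),
            )
        if model == "two_site":
            return BindingParams2Site(
                SiteParams(**payload["site1"]), SiteParams(**payload["site2"]),
                q_dil_ucal=payload.get("q_dil_ucal", 0.0),
            )
    except (KeyError, TypeError, ValueError) as exc:
        raise ParseError(f"{path}: invalid binding parameters: {exc}") from exc
    raise ParseError(f"{path}: unknown model {model!r}")


# ------------------------------------------------------------- JSON results

def fit_result_to_dict(fit: FitResult) -> dict:
    return {
        "model": fit.model,
        "params": fit.param_dict,
        "se_jackknife": fit.se_jackknife,
        "sse_ucal2": fit.sse,
        "converged": fit.converged,
        "n_used": fit.n_used,
        "residuals_ucal": [float(r) for r in fit.residuals],
        "warnings": list(fit.warnings),
    }


def write_fit_result(path: str | Path, fit: FitResult) -> None:
    Path(path).write_text(json.dumps(fit_result_to_dict(fit), indent=2) + "\n")
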