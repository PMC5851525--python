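"""CSV/JSON/YAML I/O and the fitted-vs-published comparison report.

Two plain-text schemas are used throughout:

* ``itc_series``: columns ``injection_index, injection_volume_uL,
  heat_ucal`` (binding runs add ``molar_ratio``), one row per injection.
* ``dsc_trace``: columns ``temperature_C, cp_excess_kcal_per_mol_K``,
  one row per grid point, strictly increasing temperature.

Files are strict UTF-8 CSV with a period decimal point; malformed cells
are rejected with the offending row named, never silently coerced.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .dsc import Thermogram
from .result import FitResult
from .series import InjectionSeries
from .thermo import celsius_to_kelvin, kelvin_to_celsius

__all__ = [
    "read_dsc_csv",
    "write_dsc_csv",
    "read_itc_csv",
    "write_itc_csv",
    "read_params",
    "run_report",
]

ITC_COLUMNS = ("injection_index", "injection_volume_uL", "heat_ucal")
DSC_COLUMNS = ("temperature_C", "cp_excess_kcal_per_mol_K")


class SchemaError(ValueError):
    """A file does not conform to its declared schema."""


def _load_strict(path: str | Path, required: tuple[str, ...]) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, encoding="utf-8")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    for col in required:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = int(vals.index[vals.isna()][0])
            raise SchemaError(
                f"{path}: non-numeric cell in column {col!r} at data row {row} "
                f"(value {df[col].iloc[row]!r}) — decimal commas are not accepted"
            )
        df[col] = vals
    return df


def write_dsc_csv(trace: Thermogram, path: str | Path) -> None:
    pd.DataFrame(
        {
            "temperature_C": kelvin_to_celsius(trace.temperature),
            "cp_excess_kcal_per_mol_K": trace.excess_cp,
        }
    ).to_csv(path, index=False)


def read_dsc_csv(
    path: str | Path,
    total_subunit_conc: Optional[float] = None,
    scan_rate: Optional[float] = None,
) -> Thermogram:
    df = _load_strict(path, DSC_COLUMNS)
    t_c = df["temperature_C"].to_numpy(dtype=float)
    diffs = np.diff(t_c)
    if np.any(diffs <= 0):
        row = int(np.nonzero(diffs <= 0)[0][0]) + 1
        raise SchemaError(
            f"{path}: temperature grid not strictly increasing at data row {row}"
        )
    return Thermogram(
        temperature=celsius_to_kelvin(t_c),
        excess_cp=df["cp_excess_kcal_per_mol_K"].to_numpy(dtype=float),
        total_subunit_conc=total_subunit_conc,
        scan_rate=scan_rate,
    )


def write_itc_csv(series: InjectionSeries, path: str | Path) -> None:
    data = {
        "injection_index": np.arange(1, len(series) + 1),
        "injection_volume_uL": series.injection_volumes * 1e6,
        "heat_ucal": series.heats_ucal,
    }
    if series.molar_ratio is not None:
        data["molar_ratio"] = series.molar_ratio
    pd.DataFrame(data).to_csv(path, index=False)


def read_itc_csv(
    path: str | Path,
    kind: str = "dilution",
    syringe_conc: Optional[float] = None,
) -> InjectionSeries:
    """Read an ``itc_series`` file.

    ``syringe_conc`` (mol/L of titrant in the syringe) is needed to
    recover per-injection moles and normalized heats; without it those
    fields are filled with NaN (fitting uses raw heats only).
    """
    df = _load_strict(path, ITC_COLUMNS)
    vols = df["injection_volume_uL"].to_numpy(dtype=float) * 1e-6
    heats = df["heat_ucal"].to_numpy(dtype=float)
    if syringe_conc is not None:
        moles = syringe_conc * vols
        normalized = heats * 1e-9 / moles
    else:
        moles = np.full_like(vols, np.nan)
        normalized = np.full_like(vols, np.nan)
    ratio = None
    if "molar_ratio" in df.columns:
        ratio = pd.to_numeric(df["molar_ratio"], errors="coerce").to_numpy(float)
    return InjectionSeries(
        heats_ucal=heats,
        injection_volumes=vols,
        moles_injected=moles,
        normalized_heat=normalized,
        cell_conc_after=np.full_like(vols, np.nan),
        kind=kind,
        molar_ratio=ratio,
    )


def read_params(path: str | Path) -> dict:
    """Parameter file in YAML (or JSON, a YAML subset)."""
    with open(path, "r", encoding="utf-8") as fh:
        params = yaml.safe_load(fh)
    if not isinstance(params, dict):
        raise SchemaError(f"{path}: parameter file must be a mapping")
    return params


# ---------------------------------------------------------------------------
# comparison report


def run_report(
    fits: dict[tuple[str, str], FitResult],
    registry: dict[tuple[str, str], dict],
) -> dict:
    """Compare fitted parameters with published values.

    ``fits`` maps (protein, experiment) to fit results; ``registry`` maps
    the same keys to published entries of the form
    ``{param: (printed_value, printed_uncertainty, citation)}`` in the
    fitted parameter's units.  Returns a dict with per-row flags plus a
    rendered markdown table; rows without a fit are marked absent rather
    than fabricated.
    """
    rows = []
    for key, printed in registry.items():
        protein, experiment = key
        fit = fits.get(key)
        for pname, (pval, perr, citation) in printed.items():
            if fit is None or pname not in fit.params:
                rows.append(
                    {
                        "protein": protein,
                        "experiment": experiment,
                        "parameter": pname,
                        "fitted": None,
                        "printed": pval,
                        "uncertainty": perr,
                        "citation": citation,
                        "within_uncertainty": None,
                        "absent": True,
                    }
                )
                continue
            fitted = fit.params[pname]
            rows.append(
                {
                    "protein": protein,
                    "experiment": experiment,
                    "parameter": pname,
                    "fitted": float(fitted),
                    "printed": pval,
                    "uncertainty": perr,
                    "citation": citation,
                    "within_uncertainty": bool(abs(fitted - pval) <= perr),
                    "absent": False,
                }
            )

    lines = [
        "| protein | experiment | parameter | fitted | printed ± unc. | within | source |",
        "|---|---|---|---|---|---|---|",
    ]
    for r in rows:
        fitted = "absent" if r["absent"] else f"{r['fitted']:.4g}"
        within = {None: "—", True: "yes", False: "no"}[r["within_uncertainty"]]
        lines.append(
            f"| {r['protein']} | {r['experiment']} | {r['parameter']} | {fitted} "
            f"| {r['printed']:.4g} ± {r['uncertainty']:.2g} | {within} "
            f"| {r['citation']} |"
        )
    return {"rows": rows, "markdown": "\n".join(lines)}


def write_report(report: dict, json_path: str | Path, md_path: str | Path) -> None:
    Path(json_path).write_text(json.dumps({"rows": report["rows"]}, indent=2) + "\n")
    Path(md_path).write_text(report["markdown"] + "\n")
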