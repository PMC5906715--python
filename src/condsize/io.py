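"""CSV readers/writers, packaged reference data and JSON reporting.

Bench conventions at this surface: mm, mS, kHz in human-facing fields; SI
inside the library.  All CSVs are comma-separated UTF-8 with a header row.
"""
from __future__ import annotations

import hashlib
import json
import re
from importlib import resources

import numpy as np
import pandas as pd

from .agreement import AgreementStats
from .calibration import ConductivityTable
from .errors import InputError
from .geometry import ConductanceDecomposition
from .parallel_field import BathSeries
from .sizing import DiameterEstimate
from .twofreq import SpectrumMeasurement

SCHEMA_VERSION = 1

# sha256 of the packaged reference CSVs; load_* verify byte-for-byte.
_FIXTURE_SHA256 = {
    "saline_045_conductivity_5_5_5.csv":
        "8c739ed93a0cb929652d02cef39ea11f5e50b1407e366529f7a654831c6f61f5",
    "exvivo_bath_series_5_5_5.csv":
        "f3079fd6105fba121f01a13c6314b103a0591ef0c38d43adefdfe637f92dbf37",
}


def _fixture_bytes(name: str) -> bytes:
    data = resources.files("condsize.data").joinpath(name).read_bytes()
    digest = hashlib.sha256(data).hexdigest()
    if digest != _FIXTURE_SHA256[name]:
        raise InputError(f"packaged reference file {name} is corrupted (checksum mismatch)")
    return data


def load_saline_conductivity_table() -> ConductivityTable:
    """Packaged ideal-conductivity table for 0.45% saline, 5-5-5 guidewire.

    Measured in rigid phantoms (1.75–8 mm diameter, 10–80 kHz, room
    temperature).  Users measuring blood or other fluids supply their own
    table via :func:`read_conductivity_table_csv`.
    """
    import io as _io

    return read_conductivity_table_csv(
        _io.BytesIO(_fixture_bytes("saline_045_conductivity_5_5_5.csv"))
    )


def load_exvivo_bath_series() -> BathSeries:
    """Packaged bath-thickness series: bovine carotid artery, 5-5-5 guidewire.

    Total conductance (mS) at 10/20/40 kHz for a vessel of 3.2 mm lumen
    diameter and TR = 0.79, perfused with 0.45% saline, immersed in a
    0.1% saline bath of varying radial width (0–20.868 mm).
    """
    import io as _io

    return read_bath_series_csv(
        _io.BytesIO(_fixture_bytes("exvivo_bath_series_5_5_5.csv"))
    )


def read_conductivity_table_csv(path) -> ConductivityTable:
    """Read a conductivity table: column ``frequency_hz``, then one column
    per diameter headed by the diameter in mm."""
    df = pd.read_csv(path)
    if "frequency_hz" not in df.columns:
        raise InputError("conductivity table must have a 'frequency_hz' column")
    diam_cols = [c for c in df.columns if c != "frequency_hz"]
    if not diam_cols:
        raise InputError("conductivity table has no diameter columns")
    try:
        diameters = [float(c) * 1e-3 for c in diam_cols]
    except ValueError as exc:
        raise InputError(f"diameter column headers must be numeric mm values: {exc}") from exc
    order = np.argsort(diameters)
    sigma = df[diam_cols].to_numpy(dtype=float)[:, order]
    freqs = df["frequency_hz"].to_numpy(dtype=float)
    forder = np.argsort(freqs)
    return ConductivityTable(
        frequencies=tuple(freqs[forder]),
        diameters=tuple(np.asarray(diameters)[order]),
        sigma=sigma[forder],
    )


_BATH_COL = re.compile(r"^g_total_ms_(\d+(?:\.\d+)?)khz$")


def read_bath_series_csv(path) -> BathSeries:
    """Read a bath series: column ``bath_thickness_mm``, then one
    ``g_total_ms_<f>khz`` column per frequency."""
    df = pd.read_csv(path)
    if "bath_thickness_mm" not in df.columns:
        raise InputError("bath series must have a 'bath_thickness_mm' column")
    freqs, cols = [], []
    for c in df.columns:
        m = _BATH_COL.match(c)
        if m:
            freqs.append(float(m.group(1)) * 1e3)
            cols.append(c)
    if not cols:
        raise InputError("bath series has no 'g_total_ms_<freq>khz' columns")
    return BathSeries(
        bath_thicknesses=tuple(df["bath_thickness_mm"].to_numpy(dtype=float) * 1e-3),
        frequencies=tuple(freqs),
        g_total=df[cols].to_numpy(dtype=float).T * 1e-3,
    )


# accepted spectrum column spellings -> (canonical, multiplier to SI)
_SPECTRUM_UNITS = {
    "frequency_hz": ("frequency", 1.0),
    "frequency_khz": ("frequency", 1e3),
    "current_a_rms": ("current", 1.0),
    "current_ma_rms": ("current", 1e-3),
    "current_ua_rms": ("current", 1e-6),
    "voltage_v_rms": ("voltage", 1.0),
    "voltage_mv_rms": ("voltage", 1e-3),
}


def read_spectrum_csv(path) -> list:
    """Read measurements: columns frequency_hz, current_a_rms, voltage_v_rms.

    Unit-suffixed variants (``frequency_khz``, ``current_ma_rms``,
    ``current_ua_rms``, ``voltage_mv_rms``) are converted.  Malformed or
    non-physical rows raise :class:`InputError` naming the data row.
    """
    df = pd.read_csv(path)
    found: dict = {}
    for col in df.columns:
        key = col.strip().lower()
        if key in _SPECTRUM_UNITS:
            canonical, mult = _SPECTRUM_UNITS[key]
            if canonical in found:
                raise InputError(f"duplicate {canonical} column: {col!r}")
            found[canonical] = (col, mult)
    for needed in ("frequency", "current", "voltage"):
        if needed not in found:
            raise InputError(f"spectrum file is missing a {needed} column "
                             f"(e.g. '{needed}_{'hz' if needed == 'frequency' else ('a_rms' if needed == 'current' else 'v_rms')}')")
    out = []
    for i, row in df.iterrows():
        vals = {}
        for canonical, (col, mult) in found.items():
            raw = row[col]
            try:
                vals[canonical] = float(raw) * mult
            except (TypeError, ValueError) as exc:
                raise InputError(f"row {i + 1}: non-numeric {canonical} value {raw!r}") from exc
        try:
            out.append(SpectrumMeasurement(**vals))
        except InputError as exc:
            raise InputError(f"row {i + 1}: {exc}") from exc
    if not out:
        raise InputError("spectrum file contains no data rows")
    return out


def _sig4(x: float) -> float:
    return float(f"{x:.4g}")


def report_json(obj) -> str:
    """Serialize an estimate or agreement stats to a schema-versioned report.

    The ``summary`` block carries bench units rounded to 4 significant
    figures; the ``machine`` block is full precision and round-trips
    through :func:`from_report_json`.
    """
    if isinstance(obj, DiameterEstimate):
        dec = obj.decomposition
        doc = {
            "schema_version": SCHEMA_VERSION,
            "kind": "diameter_estimate",
            "summary": {
                "d_b_mm": _sig4(obj.d_b * 1e3),
                "converged": obj.converged,
                "iterations": obj.iterations,
                "G_mS": _sig4(dec.G * 1e3),
                "Gb_mS": _sig4(dec.G_b * 1e3),
                "Gp_mS": _sig4(dec.G_p * 1e3),
                "sigma_b_used_s_per_m": _sig4(obj.sigma_b_used),
            },
            "machine": {
                "d_b_m": obj.d_b,
                "iterations": obj.iterations,
                "converged": obj.converged,
                "mismatch": obj.mismatch,
                "G_b_s": dec.G_b,
                "G_t_s": dec.G_t,
                "G_bath_s": dec.G_bath,
                "sigma_b_used_s_per_m": obj.sigma_b_used,
            },
        }
        if not obj.converged:
            doc["warning"] = "estimate did not converge within the iteration budget"
    elif isinstance(obj, AgreementStats):
        doc = {
            "schema_version": SCHEMA_VERSION,
            "kind": "agreement_stats",
            "summary": {
                "mean_diff_mm": _sig4(obj.mean_diff),
                "sd_diff_mm": _sig4(obj.sd_diff),
                "repeatability_mm": _sig4(obj.repeatability),
                "frac_within_1sd": _sig4(obj.frac_within_1sd),
                "frac_within_2sd": _sig4(obj.frac_within_2sd),
                "r2": _sig4(obj.r2),
            },
            "machine": {k: getattr(obj, k) for k in (
                "mean_diff", "sd_diff", "repeatability", "frac_within_1sd",
                "frac_within_2sd", "loa_low", "loa_high", "slope",
                "intercept", "r2", "n")},
        }
    else:
        raise InputError(f"cannot serialize object of type {type(obj).__name__}")
    return json.dumps(doc, indent=2, sort_keys=False)


def from_report_json(text: str):
    """Parse a report back into its dataclass (from the machine block)."""
    doc = json.loads(text)
    if doc.get("schema_version") != SCHEMA_VERSION:
        raise InputError("unsupported report schema version")
    m = doc["machine"]
    if doc["kind"] == "diameter_estimate":
        dec = ConductanceDecomposition(G_b=m["G_b_s"], G_t=m["G_t_s"], G_bath=m["G_bath_s"])
        return DiameterEstimate(
            d_b=m["d_b_m"], iterations=m["iterations"], converged=m["converged"],
            mismatch=m["mismatch"], decomposition=dec,
            sigma_b_used=m["sigma_b_used_s_per_m"],
        )
    if doc["kind"] == "agreement_stats":
        return AgreementStats(**m)
    raise InputError(f"unknown report kind {doc['kind']!r}")
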