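"""Readers and writers for the package's plain-text data dialects.

All files are CSV-like with '#' comment lines carrying metadata
(key=value).  Numeric output uses '.' decimal separator at full double
precision, so write -> read round trips are bit-exact.  Malformed files
are rejected with line-numbered diagnostics.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np

from .engine import AnisotropyTable, RadialDoseModel
from .patterns import PatternReport, QaPointPattern
from .setups import DosePlane
from .tables import AlongAwayTable, DiffMap

__all__ = [
    "read_anisotropy_csv", "write_anisotropy_csv",
    "read_radial_table_csv", "write_radial_table_csv",
    "read_radial_polynomial", "write_radial_polynomial",
    "read_alongaway_csv", "write_alongaway_csv",
    "read_dose_plane_csv", "write_dose_plane_csv",
    "write_diffmap_csv", "write_pattern_json", "read_pattern_json",
    "write_report_json",
]

REPORT_SCHEMA_VERSION = "1.0"

_FMT = "%.17g"


def _fmt(x: float) -> str:
    return _FMT % x


class FileFormatError(ValueError):
    """Malformed input file; message carries the offending line number."""

    def __init__(self, path, lineno: int, message: str) -> None:
        super().__init__(f"{path}:{lineno}: {message}")
        self.lineno = lineno


def _read_lines(path) -> list[tuple[int, str]]:
    """Non-empty, non-comment lines with their 1-based line numbers."""
    out = []
    meta = {}
    for i, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if "=" in body:
                k, _, v = body.partition("=")
                meta[k.strip()] = v.strip()
            continue
        out.append((i, line))
    return out, meta


def _parse_floats(path, lineno: int, fields: Sequence[str]) -> list[float]:
    vals = []
    for f in fields:
        f = f.strip()
        try:
            vals.append(float(f))
        except ValueError:
            raise FileFormatError(path, lineno, f"not a number: {f!r}") from None
    return vals


# -- anisotropy tables -------------------------------------------------------

def write_anisotropy_csv(table: AnisotropyTable, path) -> None:
    """Row 1: 'r_cm' + ascending angles; rows: radius then F values."""
    lines = [
        f"# provenance={table.provenance}",
        f"# theta_zero={table.theta_zero}",
        "r_cm," + ",".join(_fmt(a) for a in table.angles),
    ]
    for r, row in zip(table.radii, table.values):
        lines.append(_fmt(r) + "," + ",".join(_fmt(v) for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_anisotropy_csv(path) -> AnisotropyTable:
    rows, meta = _read_lines(path)
    if not rows:
        raise FileFormatError(path, 1, "empty anisotropy file")
    lineno, header = rows[0]
    fields = header.split(",")
    if fields[0].strip() != "r_cm":
        raise FileFormatError(path, lineno, "header must start with 'r_cm'")
    angles = _parse_floats(path, lineno, fields[1:])
    if any(b <= a for a, b in zip(angles, angles[1:])):
        raise FileFormatError(path, lineno, "angles must be strictly ascending")
    radii, values = [], []
    for lineno, line in rows[1:]:
        vals = _parse_floats(path, lineno, line.split(","))
        if len(vals) != len(angles) + 1:
            raise FileFormatError(
                path, lineno,
                f"expected {len(angles) + 1} fields, got {len(vals)}",
            )
        if radii and vals[0] <= radii[-1]:
            raise FileFormatError(path, lineno, "radii must be strictly ascending")
        if any(v <= 0 for v in vals[1:]):
            raise FileFormatError(path, lineno, "F values must be > 0")
        radii.append(vals[0])
        values.append(vals[1:])
    try:
        return AnisotropyTable(
            radii=radii, angles=angles, values=values,
            provenance=meta.get("provenance", ""),
            theta_zero=meta.get("theta_zero", "tip"),
        )
    except ValueError as exc:
        raise FileFormatError(path, rows[0][0], str(exc)) from None


# -- radial dose -------------------------------------------------------------

def write_radial_table_csv(model: RadialDoseModel, path) -> None:
    if model.form != "table":
        raise ValueError("write_radial_table_csv needs a table-form model")
    lines = [f"# interpolation={model.interpolation}", "r_cm,g"]
    for r, g in zip(model.table_r, model.table_g):
        lines.append(f"{_fmt(r)},{_fmt(g)}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_radial_table_csv(path, normalize: bool = False) -> RadialDoseModel:
    rows, meta = _read_lines(path)
    if not rows:
        raise FileFormatError(path, 1, "empty radial-dose file")
    lineno, header = rows[0]
    if [f.strip() for f in header.split(",")] != ["r_cm", "g"]:
        raise FileFormatError(path, lineno, "header must be 'r_cm,g'")
    rr, gg = [], []
    for lineno, line in rows[1:]:
        vals = _parse_floats(path, lineno, line.split(","))
        if len(vals) != 2:
            raise FileFormatError(path, lineno, "expected two fields r_cm,g")
        if rr and vals[0] <= rr[-1]:
            raise FileFormatError(path, lineno, "radii must be strictly ascending")
        if vals[1] <= 0:
            raise FileFormatError(path, lineno, "g values must be > 0")
        rr.append(vals[0])
        gg.append(vals[1])
    try:
        return RadialDoseModel.from_table(
            rr, gg, interpolation=meta.get("interpolation", "linear"),
            normalize=normalize,
        )
    except ValueError as exc:
        raise FileFormatError(path, rows[-1][0], str(exc)) from None


def write_radial_polynomial(model: RadialDoseModel, path) -> None:
    """Single line: 'degree,c0,c1,...' (ascending powers)."""
    if model.form != "polynomial":
        raise ValueError("write_radial_polynomial needs a polynomial-form model")
    c = model.coefficients
    line = ",".join([str(len(c) - 1)] + [_fmt(v) for v in c])
    Path(path).write_text(
        f"# valid_range={_fmt(model.valid_range[0])}:{_fmt(model.valid_range[1])}\n"
        + line + "\n"
    )


def read_radial_polynomial(path, normalize: bool = False) -> RadialDoseModel:
    rows, meta = _read_lines(path)
    if not rows:
        raise FileFormatError(path, 1, "empty polynomial file")
    lineno, line = rows[0]
    vals = _parse_floats(path, lineno, line.split(","))
    degree = int(vals[0])
    coeffs = vals[1:]
    if len(coeffs) != degree + 1:
        raise FileFormatError(
            path, lineno, f"degree {degree} needs {degree + 1} coefficients"
        )
    vr = (0.1, 15.0)
    if "valid_range" in meta:
        lo, _, hi = meta["valid_range"].partition(":")
        vr = (float(lo), float(hi))
    return RadialDoseModel.from_polynomial(coeffs, valid_range=vr, normalize=normalize)


# -- along-away and dose planes ---------------------------------------------

def _write_matrix(path, header_cols, row_axis, matrix, extra_meta=()):
    lines = list(extra_meta)
    lines.append(header_cols)
    for rv, row in zip(row_axis, matrix):
        lines.append(_fmt(rv) + "," + ",".join(_fmt(v) for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


def write_alongaway_csv(table: AlongAwayTable, path) -> None:
    """Row 1: 'z_cm' + y values; rows: z then dose-rate-per-Sk values."""
    _write_matrix(
        path,
        "z_cm," + ",".join(_fmt(y) for y in table.y_values),
        table.z_values,
        table.values,
        extra_meta=(f"# label={table.label}", f"# n_points={table.n_points}"),
    )


def read_alongaway_csv(path) -> AlongAwayTable:
    rows, meta = _read_lines(path)
    if not rows:
        raise FileFormatError(path, 1, "empty along-away file")
    lineno, header = rows[0]
    fields = header.split(",")
    if fields[0].strip() != "z_cm":
        raise FileFormatError(path, lineno, "header must start with 'z_cm'")
    y = _parse_floats(path, lineno, fields[1:])
    z, vals = [], []
    for lineno, line in rows[1:]:
        v = _parse_floats(path, lineno, line.split(","))
        if len(v) != len(y) + 1:
            raise FileFormatError(path, lineno, f"expected {len(y) + 1} fields")
        if z and v[0] <= z[-1]:
            raise FileFormatError(path, lineno, "z values must be strictly ascending")
        z.append(v[0])
        vals.append(v[1:])
    try:
        return AlongAwayTable(
            y_values=y, z_values=z, values=vals, label=meta.get("label", "")
        )
    except ValueError as exc:
        raise FileFormatError(path, rows[0][0], str(exc)) from None


def write_dose_plane_csv(plane: DosePlane, path) -> None:
    _write_matrix(
        path,
        "z_cm," + ",".join(_fmt(y) for y in plane.y_axis),
        plane.z_axis,
        plane.values,
        extra_meta=(
            f"# spacing={_fmt(plane.spacing)}",
            f"# origin={plane.origin}",
            f"# units={plane.units}",
        ),
    )


def read_dose_plane_csv(path) -> DosePlane:
    rows, meta = _read_lines(path)
    if not rows:
        raise FileFormatError(path, 1, "empty dose-plane file")
    lineno, header = rows[0]
    fields = header.split(",")
    if fields[0].strip() != "z_cm":
        raise FileFormatError(path, lineno, "header must start with 'z_cm'")
    y = _parse_floats(path, lineno, fields[1:])
    z, vals = [], []
    for lineno, line in rows[1:]:
        v = _parse_floats(path, lineno, line.split(","))
        if len(v) != len(y) + 1:
            raise FileFormatError(path, lineno, f"expected {len(y) + 1} fields")
        z.append(v[0])
        vals.append(v[1:])
    spacing = float(meta.get("spacing", "0")) or float(np.diff(y[:2])[0])
    try:
        return DosePlane(
            y_axis=y, z_axis=z, values=vals, spacing=spacing,
            origin=meta.get("origin", ""), units=meta.get("units", "cGy/h/U"),
        )
    except ValueError as exc:
        raise FileFormatError(path, rows[0][0], str(exc)) from None


def write_diffmap_csv(diff: DiffMap, path) -> None:
    label = "r_cm" if diff.kind == "polar" else "z_cm"
    _write_matrix(
        path,
        f"{label}," + ",".join(_fmt(a) for a in diff.axis2),
        diff.axis1,
        diff.values,
        extra_meta=(
            f"# kind={diff.kind}",
            f"# reference={diff.reference_label}",
            f"# comparison={diff.comparison_label}",
            f"# denominator={diff.denominator}",
        ),
    )


# -- patterns and reports ----------------------------------------------------

def write_pattern_json(pattern: QaPointPattern, path) -> None:
    payload = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "name": pattern.name,
        "symmetry": pattern.symmetry,
        "rays": [{"angle_deg": a, "radii_cm": radii} for a, radii in pattern.rays],
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_pattern_json(path) -> QaPointPattern:
    payload = json.loads(Path(path).read_text())
    return QaPointPattern(
        name=payload["name"],
        rays=[(ray["angle_deg"], list(ray["radii_cm"])) for ray in payload["rays"]],
        symmetry=payload.get("symmetry", "none"),
    )


def write_report_json(report: PatternReport, path) -> None:
    payload = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "pattern": report.pattern,
        "investigation_level": report.investigation_level,
        "intervention_level": report.intervention_level,
        "worst_level": report.worst_level,
        "n_flagged": report.n_flagged,
        "max_abs_diff_pct": report.max_abs_diff_pct,
        "rows": report.rows,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
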