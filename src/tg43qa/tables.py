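"""Anisotropy-table comparison, along-away extraction, and ODIN detection.

A commissioning physicist compares the vendor-supplied TG-43 tables of a
planning system against a reference data set.  Tables rarely share axes,
so one is bilinearly resampled onto the other's grid before taking
percent differences; discrepancies above the 2% AAPM action level that
are caused purely by interpolation over sparse table nodes are "outcome
discrepancies due to interpolation" (ODIN).  The reverse route — pulling
an anisotropy function back out of a published along-away dose-rate
table via the formal TG-43 definition — validates an independent dose
engine against that table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .engine import (
    AnisotropyTable,
    CartesianPoint,
    PolarPoint,
    RadialDoseModel,
    SourceModel,
    geometry_factor,
    radial_dose,
)

__all__ = [
    "AlongAwayTable",
    "DiffMap",
    "OdinReport",
    "ExtractedAnisotropy",
    "cartesian_to_polar",
    "polar_to_cartesian",
    "resample_table",
    "compare_tables",
    "transverse_axis_dose",
    "extract_anisotropy",
    "odin_detect",
    "angular_coverage",
]

log = logging.getLogger(__name__)

#: AAPM-recommended investigation threshold for table discrepancies (%)
INVESTIGATION_LEVEL = 2.0
#: TRS-430 / NCS-13 intervention threshold (%)
INTERVENTION_LEVEL = 5.0
#: default singular-zone margin beyond L/2 (cm) excluded from extraction
SINGULAR_MARGIN = 0.05


@dataclass
class AlongAwayTable:
    """Dose rate per unit Sk on a Cartesian (away y, along z) grid.

    ``values`` has shape (len(z_values), len(y_values)) in cGy/h/U; points
    inside the source singular zone are NaN and do not count toward
    ``n_points``.
    """

    y_values: np.ndarray
    z_values: np.ndarray
    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.y_values = np.asarray(self.y_values, float)
        self.z_values = np.asarray(self.z_values, float)
        self.values = np.asarray(self.values, float)
        if np.any(np.diff(self.y_values) <= 0) or np.any(np.diff(self.z_values) <= 0):
            raise ValueError("y and z axes must be strictly ascending")
        if self.values.shape != (self.z_values.size, self.y_values.size):
            raise ValueError(
                f"values shape {self.values.shape} != "
                f"({self.z_values.size}, {self.y_values.size})"
            )
        finite = np.isfinite(self.values)
        if np.any(self.values[finite] <= 0):
            raise ValueError("dose-rate values must be > 0 where defined")

    @property
    def n_points(self) -> int:
        return int(np.sum(np.isfinite(self.values)))


@dataclass
class DiffMap:
    """Signed percent differences between two fields on a shared grid.

    ``axis1``/``axis2`` are the grid coordinate vectors; for anisotropy
    tables these are (radii, angles), for dose planes (z, y).  ``values``
    is 100*(b-a)/denominator; NaN marks masked points.
    """

    axis1: np.ndarray
    axis2: np.ndarray
    values: np.ndarray
    kind: Literal["polar", "cartesian"] = "polar"
    reference_label: str = ""
    comparison_label: str = ""
    denominator: str = "a"

    def __post_init__(self) -> None:
        self.axis1 = np.asarray(self.axis1, float)
        self.axis2 = np.asarray(self.axis2, float)
        self.values = np.asarray(self.values, float)
        if self.values.shape != (self.axis1.size, self.axis2.size):
            raise ValueError("diff grid does not match coordinate axes")

    @property
    def finite_values(self) -> np.ndarray:
        return self.values[np.isfinite(self.values)]


@dataclass
class OdinReport:
    """Flagged interpolation-discrepancy regions with action-level classes."""

    flagged: list  # (axis1 value, axis2 value, diff %) triples
    investigation: list
    intervention: list
    angular_bands: list  # (theta_lo, theta_hi) degrees, flagged contiguous runs
    angular_coverage_fraction: float  # of the [0, 180] polar-angle domain
    solid_angle_coverage_fraction: float  # secondary definition
    investigation_level: float
    intervention_level: float
    summary: dict = field(default_factory=dict)

    @property
    def worst_level(self) -> int:
        """0 = clean, 3 = investigation findings, 4 = intervention findings."""
        if self.intervention:
            return 4
        if self.investigation:
            return 3
        return 0


def cartesian_to_polar(
    point: CartesianPoint | tuple,
    theta_zero: Literal["+z", "-z"] = "+z",
) -> PolarPoint:
    """Along-away (y, z) -> polar (r, theta), theta from the chosen axis end.

    ``theta_zero='+z'`` measures theta from the +z direction (the engine
    convention when the tip points toward +z); ``'-z'`` measures from the
    opposite end, e.g. to quote an angle from the nearer pole.
    """
    y, z = (point.y, point.z) if isinstance(point, CartesianPoint) else point
    if y == 0 and z == 0:
        raise ValueError("origin has no polar representation")
    r = float(np.hypot(y, z))
    zz = z if theta_zero == "+z" else -z
    theta = float(np.degrees(np.arctan2(abs(y), zz)))
    return PolarPoint(r=r, theta=theta)


def polar_to_cartesian(
    point: PolarPoint | tuple,
    theta_zero: Literal["+z", "-z"] = "+z",
) -> CartesianPoint:
    """Inverse of :func:`cartesian_to_polar`; returns (|y|, z)."""
    r, theta = (point.r, point.theta) if isinstance(point, PolarPoint) else point
    th = np.radians(theta)
    y = float(r * np.sin(th))
    z = float(r * np.cos(th))
    if theta_zero == "-z":
        z = -z
    return CartesianPoint(y=abs(y), z=z)


def resample_table(
    source_table: AnisotropyTable,
    target_radii: Sequence[float],
    target_angles: Sequence[float],
) -> AnisotropyTable:
    """Bilinearly resample an anisotropy table onto new axes.

    Uses the standard lookup (radial clamp + linear pole extrapolation),
    so target angles beyond the source's angular range are permitted.
    Provenance records the route as ``int-<src>2<dst>``.
    """
    from .engine import anisotropy_lookup

    tr = np.asarray(target_radii, float)
    ta = np.asarray(target_angles, float)
    if tr.size == 0 or ta.size == 0:
        raise ValueError("target axes must be non-empty")
    R, A = np.meshgrid(tr, ta, indexing="ij")
    vals = anisotropy_lookup(R.ravel(), A.ravel(), source_table).reshape(R.shape)
    src = source_table.provenance or "src"
    return AnisotropyTable(
        radii=tr,
        angles=ta,
        values=vals,
        provenance=f"int-{src}2target",
        theta_zero=source_table.theta_zero,
    )


def compare_tables(
    a: AnisotropyTable,
    b: AnisotropyTable,
    denominator: Literal["a", "b"] = "a",
) -> DiffMap:
    """Cell-wise signed percent difference 100*(b-a)/denominator.

    Both tables must share axes (resample one first if not).  The
    convention 'a = reference' with denominator 'a' reproduces the usual
    commissioning report; take abs() of the values for display-style
    absolute maps.
    """
    if not (np.array_equal(a.radii, b.radii) and np.array_equal(a.angles, b.angles)):
        raise ValueError("tables must share identical axes; resample first")
    den = a.values if denominator == "a" else b.values
    vals = 100.0 * (b.values - a.values) / den
    return DiffMap(
        axis1=a.radii,
        axis2=a.angles,
        values=vals,
        kind="polar",
        reference_label=a.provenance,
        comparison_label=b.provenance,
        denominator=denominator,
    )


def transverse_axis_dose(r, source: SourceModel, g: RadialDoseModel):
    """Dose rate per unit Sk on the transverse axis, cGy/h/U.

    Lambda * G_L(r, theta0)/G_L(r0, theta0) * g_L(r): the anisotropy
    function is identically 1 at theta0, so no table interpolation enters.
    """
    L = source.active_length
    Gr = geometry_factor(r, np.full_like(np.asarray(r, float), source.theta0), L)
    G0 = geometry_factor(source.r0, source.theta0, L)
    return source.dose_rate_constant * (Gr / G0) * radial_dose(r, g)


@dataclass
class ExtractedAnisotropy:
    """F values recovered from an along-away table, indexed by (y, z).

    Each Cartesian grid node keeps its polar equivalent (r, theta) in the
    engine convention; NaNs mark skipped singular-zone points.
    """

    y_values: np.ndarray
    z_values: np.ndarray
    F: np.ndarray
    r: np.ndarray
    theta: np.ndarray


def extract_anisotropy(
    table: AlongAwayTable,
    source: SourceModel,
    g: RadialDoseModel,
    singular_margin: float = SINGULAR_MARGIN,
) -> ExtractedAnisotropy:
    """Recover F(r, theta) from an along-away dose-rate table.

    Applies the formal TG-43 anisotropy definition

        F = [D(r,theta)/Sk] * G_L(r,theta0) / ([D(r,theta0)/Sk] * G_L(r,theta))

    with the transverse-axis denominator computed analytically from
    Lambda, G_L and g(r) (no interpolation in the denominator).  Points
    within ``L/2 + singular_margin`` of the source centre are skipped.
    The tip is taken toward +z.
    """
    Y, Z = np.meshgrid(table.y_values, table.z_values, indexing="xy")
    R = np.hypot(Y, Z)
    TH = np.degrees(np.arctan2(np.abs(Y), Z))
    ok = np.isfinite(table.values) & (R > source.active_length / 2 + singular_margin)
    n_skipped = int(np.sum(np.isfinite(table.values)) - np.sum(ok))
    if n_skipped:
        log.info("extract_anisotropy: skipped %d singular-zone points", n_skipped)
    F = np.full_like(table.values, np.nan)
    r_ok = R[ok]
    th_ok = TH[ok]
    G = geometry_factor(r_ok, th_ok, source.active_length)
    denom = transverse_axis_dose(r_ok, source, g)  # per unit Sk
    G0 = geometry_factor(r_ok, np.full_like(r_ok, source.theta0), source.active_length)
    F[ok] = table.values[ok] * G0 / (denom * G)
    return ExtractedAnisotropy(
        y_values=table.y_values, z_values=table.z_values, F=F, r=R, theta=TH
    )


def angular_coverage(bands: Sequence[tuple[float, float]]) -> float:
    """Fraction of the polar-angle domain [0, 180] deg covered by bands.

    Bands are (lo, hi) in degrees; overlaps are merged before summing.
    The two 15-deg pole bands [0,15] and [165,180] jointly cover 30/180,
    i.e. about 17% of the domain.
    """
    if not bands:
        return 0.0
    ivals = sorted((min(b), max(b)) for b in bands)
    merged = [list(ivals[0])]
    for lo, hi in ivals[1:]:
        if lo <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    return sum(hi - lo for lo, hi in merged) / 180.0


def _solid_angle_fraction(bands: Sequence[tuple[float, float]]) -> float:
    """Secondary coverage definition: fraction of 4*pi solid angle."""
    total = 0.0
    for lo, hi in bands:
        lo_r, hi_r = np.radians(min(lo, hi)), np.radians(max(lo, hi))
        total += 0.5 * (np.cos(lo_r) - np.cos(hi_r))
    return float(total)


def odin_detect(
    diff: DiffMap,
    investigation: float = INVESTIGATION_LEVEL,
    intervention: float = INTERVENTION_LEVEL,
) -> OdinReport:
    """Flag cells whose |percent difference| exceeds the action levels.

    Cells in (investigation, intervention] are classified as
    investigation-level findings and cells above ``intervention`` as
    intervention-level.  For polar maps the report also gives the
    contiguous angular bands containing flagged cells and the fraction of
    the [0, 180]-deg polar domain they span.
    """
    if not 0 < investigation <= intervention:
        raise ValueError("need 0 < investigation <= intervention")
    vals = diff.values
    finite = np.isfinite(vals)
    flag_mask = finite & (np.abs(vals) > investigation)
    inter_mask = finite & (np.abs(vals) > intervention)

    def _collect(mask):
        i1, i2 = np.nonzero(mask)
        return [
            (float(diff.axis1[i]), float(diff.axis2[j]), float(vals[i, j]))
            for i, j in zip(i1, i2)
        ]

    flagged = _collect(flag_mask)
    intervention_pts = _collect(inter_mask)
    investigation_pts = _collect(flag_mask & ~inter_mask)

    bands: list[tuple[float, float]] = []
    cov = 0.0
    solid = 0.0
    if diff.kind == "polar":
        angles = diff.axis2
        col_flagged = np.any(flag_mask, axis=0)
        start = None
        for j, on in enumerate(col_flagged):
            if on and start is None:
                start = j
            if (not on or j == angles.size - 1) and start is not None:
                end = j if on else j - 1
                bands.append((float(angles[start]), float(angles[end])))
                start = None
        cov = angular_coverage(bands)
        solid = _solid_angle_fraction(bands)

    fv = diff.finite_values
    summary = {
        "n_cells": int(finite.sum()),
        "n_flagged": len(flagged),
        "mean": float(np.mean(fv)) if fv.size else np.nan,
        "sd": float(np.std(fv, ddof=1)) if fv.size > 1 else np.nan,
        "min": float(np.min(fv)) if fv.size else np.nan,
        "max": float(np.max(fv)) if fv.size else np.nan,
        "median": float(np.median(fv)) if fv.size else np.nan,
        "p25": float(np.percentile(fv, 25)) if fv.size else np.nan,
        "p75": float(np.percentile(fv, 75)) if fv.size else np.nan,
    }
    return OdinReport(
        flagged=flagged,
        investigation=investigation_pts,
        intervention=intervention_pts,
        angular_bands=bands,
        angular_coverage_fraction=cov,
        solid_angle_coverage_fraction=solid,
        investigation_level=investigation,
        intervention_level=intervention,
        summary=summary,
    )
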