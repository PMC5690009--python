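"""Clinical dwell configurations and dose-plane superposition.

Five stylised HDR treatment setups probe a planning system across the
geometries met in practice: a single dwell (contact / balloon
treatments), short and long single applicators (vaginal cylinder,
tandem-and-cylinder), a Fletcher tandem-plus-ovoids arrangement with the
ABS reporting points, and a multi-applicator interstitial array.  Dose
planes are computed by superposing the single-dwell TG-43 dose of each
dwell position, once with a reference-table engine and once with the
vendor-table engine; their percent-difference map localises the
table-interpolation (ODIN) regions in a clinically meaningful frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .engine import TG43Engine
from .tables import DiffMap, SINGULAR_MARGIN

__all__ = [
    "DwellSet",
    "DosePlane",
    "AbsPointSet",
    "GridSpec",
    "make_setup",
    "compute_dose_plane",
    "percent_diff_plane",
    "setup_summary",
    "evaluate_abs_points",
]

SETUP_KINDS = ("one_dwell", "short_applicator", "long_applicator",
               "fletcher", "multi_applicator")


@dataclass(frozen=True)
class Applicator:
    """Capsule-shaped exclusion region: segment (y1,z1)-(y2,z2) + radius."""

    y1: float
    z1: float
    y2: float
    z2: float
    radius: float

    def contains(self, Y: np.ndarray, Z: np.ndarray) -> np.ndarray:
        dy, dz = self.y2 - self.y1, self.z2 - self.z1
        L2 = dy * dy + dz * dz
        if L2 == 0:
            d2 = (Y - self.y1) ** 2 + (Z - self.z1) ** 2
        else:
            t = np.clip(((Y - self.y1) * dy + (Z - self.z1) * dz) / L2, 0.0, 1.0)
            d2 = (Y - (self.y1 + t * dy)) ** 2 + (Z - (self.z1 + t * dz)) ** 2
        return d2 < self.radius**2


@dataclass
class DwellSet:
    """Ordered dwell positions in the evaluation plane.

    Positions are (y, z) cm of each active-core centre; ``axes`` are unit
    vectors (per dwell) pointing from cable to tip; ``weights`` are
    relative dwell times.  ``applicators`` mask plane points lying inside
    applicator material.
    """

    name: str
    positions: np.ndarray  # (n, 2) of (y, z)
    axes: np.ndarray  # (n, 2) unit vectors
    weights: np.ndarray  # (n,)
    applicators: tuple[Applicator, ...] = ()

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, float))
        self.axes = np.atleast_2d(np.asarray(self.axes, float))
        self.weights = np.atleast_1d(np.asarray(self.weights, float))
        n = self.positions.shape[0]
        if n < 1:
            raise ValueError("need at least one dwell")
        if self.axes.shape != (n, 2) or self.weights.shape != (n,):
            raise ValueError("positions, axes and weights must agree in length")
        if np.any(self.weights <= 0):
            raise ValueError("dwell weights must be > 0")
        norms = np.linalg.norm(self.axes, axis=1)
        if np.any(norms == 0):
            raise ValueError("axis vectors must be nonzero")
        self.axes = self.axes / norms[:, None]

    @property
    def n_dwells(self) -> int:
        return self.positions.shape[0]

    @property
    def centroid(self) -> tuple[float, float]:
        c = self.positions.mean(axis=0)
        return float(c[0]), float(c[1])


@dataclass
class AbsPointSet:
    """Named ABS-style reporting points, (y, z) cm in the evaluation plane."""

    points: dict[str, tuple[float, float]]


@dataclass(frozen=True)
class GridSpec:
    """Square evaluation plane centred on a point, uniform spacing (cm)."""

    half_width: float = 6.0
    spacing: float = 0.05
    center: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.spacing <= 0 or self.half_width <= 0:
            raise ValueError("spacing and half_width must be > 0")

    def axes(self) -> tuple[np.ndarray, np.ndarray]:
        n = int(round(2 * self.half_width / self.spacing)) + 1
        y = self.center[0] + np.linspace(-self.half_width, self.half_width, n)
        z = self.center[1] + np.linspace(-self.half_width, self.half_width, n)
        return y, z


@dataclass
class DosePlane:
    """Dose rate (per unit Sk unless noted) on a uniform (y, z) grid.

    ``values`` has shape (len(z_axis), len(y_axis)); masked points are NaN.
    """

    y_axis: np.ndarray
    z_axis: np.ndarray
    values: np.ndarray
    spacing: float
    origin: str = ""
    units: str = "cGy/h/U"

    def __post_init__(self) -> None:
        self.y_axis = np.asarray(self.y_axis, float)
        self.z_axis = np.asarray(self.z_axis, float)
        self.values = np.asarray(self.values, float)
        if self.spacing <= 0:
            raise ValueError("spacing must be > 0")
        if self.values.shape != (self.z_axis.size, self.y_axis.size):
            raise ValueError("values shape does not match axes")
        finite = np.isfinite(self.values)
        if np.any(self.values[finite] < 0):
            raise ValueError("dose values must be >= 0 where defined")

    @property
    def mask(self) -> np.ndarray:
        """True where the plane carries no value."""
        return ~np.isfinite(self.values)

    def congruent_with(self, other: "DosePlane") -> bool:
        return (
            np.array_equal(self.y_axis, other.y_axis)
            and np.array_equal(self.z_axis, other.z_axis)
            and self.spacing == other.spacing
        )


def _line_of_dwells(
    span: float, n: int, y: float = 0.0, z_center: float = 0.0
) -> np.ndarray:
    """Equally spaced dwells including both endpoints (step = span/(n-1))."""
    if n == 1:
        z = np.array([z_center])
    else:
        z = z_center + np.linspace(-span / 2, span / 2, n)
    return np.column_stack([np.full(n, y), z])


def make_setup(
    kind: str,
    *,
    short_span: float = 3.5,
    short_n: int = 6,
    long_span: float = 9.0,
    long_step: float = 0.5,
    tandem_length: float = 6.0,
    tandem_step: float = 0.5,
    ovoid_diameter: float = 2.0,
    ovoid_offset: float = 1.5,
    n_applicators: int = 5,
    pitch: float = 1.0,
    applicator_radius: float = 0.15,
    abs_config: dict[str, tuple[float, float]] | None = None,
) -> DwellSet | tuple[DwellSet, AbsPointSet]:
    """Build one of the five standard commissioning dwell configurations.

    one_dwell: a single dwell at the origin.  short_applicator: ``short_n``
    dwells spanning ``short_span`` cm.  long_applicator: dwells at
    ``long_step`` spacing spanning ``long_span`` cm.  fletcher: a tandem of
    ``tandem_length`` cm plus two lateral ovoids of ``ovoid_diameter`` cm,
    one dwell at each ovoid centre with axis parallel to the tandem;
    returns (DwellSet, AbsPointSet).  multi_applicator: ``n_applicators``
    parallel lines at ``pitch`` cm lateral spacing.

    All source axes point toward +z (the tip direction).
    """
    if kind not in SETUP_KINDS:
        raise ValueError(f"unknown setup kind {kind!r}; choose from {SETUP_KINDS}")
    up = np.array([0.0, 1.0])

    if kind == "one_dwell":
        pos = np.array([[0.0, 0.0]])
        return DwellSet("one_dwell", pos, np.tile(up, (1, 1)), np.ones(1))

    if kind == "short_applicator":
        if short_span <= 0 or short_n < 1:
            raise ValueError("short applicator needs span > 0 and n >= 1")
        pos = _line_of_dwells(short_span, short_n)
        app = Applicator(0.0, -short_span / 2, 0.0, short_span / 2, applicator_radius)
        return DwellSet(
            "short_applicator", pos, np.tile(up, (short_n, 1)), np.ones(short_n),
            applicators=(app,),
        )

    if kind == "long_applicator":
        if long_span <= 0 or long_step <= 0:
            raise ValueError("long applicator needs positive span and step")
        n = int(round(long_span / long_step)) + 1
        pos = _line_of_dwells(long_span, n)
        app = Applicator(0.0, -long_span / 2, 0.0, long_span / 2, applicator_radius)
        return DwellSet(
            "long_applicator", pos, np.tile(up, (n, 1)), np.ones(n),
            applicators=(app,),
        )

    if kind == "fletcher":
        if tandem_length <= 0 or ovoid_diameter <= 0:
            raise ValueError("fletcher needs positive tandem length and ovoid size")
        # tandem spans z in [0, tandem_length]; cervical os at z = 0,
        # tip at the top; ovoids sit laterally near the os
        nt = int(round(tandem_length / tandem_step)) + 1
        tandem = _line_of_dwells(tandem_length, nt, z_center=tandem_length / 2)
        ov_r = ovoid_diameter / 2
        ovoids = np.array([[-ovoid_offset, 0.0], [ovoid_offset, 0.0]])
        pos = np.vstack([tandem, ovoids])
        n = pos.shape[0]
        apps = (
            Applicator(0.0, 0.0, 0.0, tandem_length, applicator_radius),
            Applicator(-ovoid_offset, 0.0, -ovoid_offset, 0.0, ov_r),
            Applicator(ovoid_offset, 0.0, ovoid_offset, 0.0, ov_r),
        )
        dwells = DwellSet(
            "fletcher", pos, np.tile(up, (n, 1)), np.ones(n), applicators=apps
        )
        pts = {
            "point_A_right": (2.0, 2.0),
            "point_A_left": (-2.0, 2.0),
            "tandem_tip": (0.0, tandem_length + 1.8),
            "ovoid_surface_right": (ovoid_offset + ov_r, 0.0),
            "ovoid_surface_left": (-(ovoid_offset + ov_r), 0.0),
            "ovoid_plus_5mm_right": (ovoid_offset + ov_r + 0.5, 0.0),
            "ovoid_plus_5mm_left": (-(ovoid_offset + ov_r + 0.5), 0.0),
            # organ-at-risk points sit near-perpendicular to the applicator
            # axes (anterior/posterior of the ovoids), outside the pole cones
            "rectal": (2.8, -0.7),
            "bladder": (-3.0, -0.9),
        }
        if abs_config:
            pts.update(abs_config)
        abs_points = AbsPointSet(points=pts)
        for name, (py, pz) in abs_points.points.items():
            for app in apps:
                if bool(app.contains(np.asarray(py), np.asarray(pz))):
                    raise ValueError(f"ABS point {name!r} lies inside an applicator")
        return dwells, abs_points

    # multi_applicator
    if n_applicators < 1 or pitch <= 0:
        raise ValueError("multi_applicator needs n >= 1 and pitch > 0")
    span, step = 5.0, 0.5
    nd = int(round(span / step)) + 1
    offsets = (np.arange(n_applicators) - (n_applicators - 1) / 2) * pitch
    pos = np.vstack([_line_of_dwells(span, nd, y=off) for off in offsets])
    apps = tuple(
        Applicator(off, -span / 2, off, span / 2, applicator_radius)
        for off in offsets
    )
    n = pos.shape[0]
    return DwellSet(
        "multi_applicator", pos, np.tile(up, (n, 1)), np.ones(n), applicators=apps
    )


def compute_dose_plane(
    dwells: DwellSet,
    grid: GridSpec,
    engine: TG43Engine,
    per_sk: bool = True,
    singular_margin: float = SINGULAR_MARGIN,
) -> DosePlane:
    """Superpose single-dwell TG-43 dose over the dwell set on a plane.

    Each plane point is transformed into every dwell's local polar frame
    (theta from the dwell's tip direction) and the engine dose rates are
    summed with the dwell weights.  Points inside an applicator or within
    ``L/2 + singular_margin`` of any dwell are masked NaN.
    """
    y, z = grid.axes()
    Y, Z = np.meshgrid(y, z, indexing="xy")
    mask = np.zeros(Y.shape, dtype=bool)
    for app in dwells.applicators:
        mask |= app.contains(Y, Z)
    rmin = engine.source.active_length / 2 + singular_margin
    for (dy, dz) in dwells.positions:
        mask |= np.hypot(Y - dy, Z - dz) < rmin

    total = np.zeros(Y.shape)
    yf, zf = Y[~mask], Z[~mask]
    acc = np.zeros(yf.shape)
    for (dy, dz), (uy, uz), w in zip(dwells.positions, dwells.axes, dwells.weights):
        vy, vz = yf - dy, zf - dz
        r = np.hypot(vy, vz)
        along = vy * uy + vz * uz
        perp = np.abs(vy * uz - vz * uy)
        theta = np.degrees(np.arctan2(perp, along))
        acc += w * engine.dose_rate(r, theta)
    if per_sk:
        acc = acc / engine.source.air_kerma_strength
    total[~mask] = acc
    total[mask] = np.nan
    return DosePlane(
        y_axis=y, z_axis=z, values=total, spacing=grid.spacing,
        origin=f"{dwells.name} centred at {grid.center}",
        units="cGy/h/U" if per_sk else "cGy/h",
    )


def percent_diff_plane(a: DosePlane, b: DosePlane) -> DiffMap:
    """Signed percent difference 100*(a-b)/b per unmasked point.

    Convention: ``a`` is the plane under test (vendor-table engine), ``b``
    the reference; a negative value is an underestimate by ``a``.
    """
    if not a.congruent_with(b):
        raise ValueError("planes must share identical grids")
    both = np.isfinite(a.values) & np.isfinite(b.values)
    vals = np.full(a.values.shape, np.nan)
    vals[both] = 100.0 * (a.values[both] - b.values[both]) / b.values[both]
    return DiffMap(
        axis1=a.z_axis,
        axis2=a.y_axis,
        values=vals,
        kind="cartesian",
        reference_label=b.origin,
        comparison_label=a.origin,
        denominator="b",
    )


def setup_summary(diff: DiffMap) -> dict:
    """Box-plot statistics of a difference map's unmasked values.

    Returns amplitude (min, max), mean, SD (n-1 denominator), median and
    the 25th/75th percentiles, in percent.
    """
    v = diff.finite_values
    if v.size == 0:
        raise ValueError("difference map has no unmasked values")
    return {
        "n": int(v.size),
        "min": float(np.min(v)),
        "max": float(np.max(v)),
        "mean": float(np.mean(v)),
        "sd": float(np.std(v, ddof=1)) if v.size > 1 else 0.0,
        "median": float(np.median(v)),
        "p25": float(np.percentile(v, 25)),
        "p75": float(np.percentile(v, 75)),
    }


def _plane_interp(diff: DiffMap, py: float, pz: float) -> float:
    """Bilinear interpolation of a Cartesian diff map at one point."""
    z_axis, y_axis = diff.axis1, diff.axis2
    if not (y_axis[0] <= py <= y_axis[-1] and z_axis[0] <= pz <= z_axis[-1]):
        raise ValueError(f"point ({py}, {pz}) outside the plane bounds")
    iy = int(np.clip(np.searchsorted(y_axis, py, side="right") - 1, 0, y_axis.size - 2))
    iz = int(np.clip(np.searchsorted(z_axis, pz, side="right") - 1, 0, z_axis.size - 2))
    ty = (py - y_axis[iy]) / (y_axis[iy + 1] - y_axis[iy])
    tz = (pz - z_axis[iz]) / (z_axis[iz + 1] - z_axis[iz])
    cell = diff.values[iz : iz + 2, iy : iy + 2]
    w = np.array(
        [
            [(1 - ty) * (1 - tz), ty * (1 - tz)],
            [(1 - ty) * tz, ty * tz],
        ]
    )
    # masked corners are tolerable only when they carry zero weight
    if np.any((w > 0) & ~np.isfinite(cell)):
        raise ValueError(f"point ({py}, {pz}) touches masked plane cells")
    return float(np.sum(np.where(w > 0, w * cell, 0.0)))


def evaluate_abs_points(points: AbsPointSet, diff: DiffMap) -> dict[str, float]:
    """Percent difference at each named reporting point (bilinear)."""
    if diff.kind != "cartesian":
        raise ValueError("need a Cartesian (dose-plane) difference map")
    return {
        name: _plane_interp(diff, py, pz)
        for name, (py, pz) in points.points.items()
    }
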