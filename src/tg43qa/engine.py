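"""TG-43 line-source dose engine.

Implements the AAPM TG-43 line-source approximation (LSA): the dose rate
around a sealed cylindrical source is factorised as

    D(r, theta) = Sk * Lambda * [G_L(r,theta) / G_L(r0,theta0)]
                  * g_L(r) * F(r,theta)

where ``Sk`` is the air-kerma strength (U), ``Lambda`` the dose-rate
constant (cGy/h/U), ``G_L`` the line-source geometry function (1/cm^2),
``g_L`` the radial dose function and ``F`` the 2D anisotropy function.
Distances are in cm and polar angles in degrees; the engine measures the
polar angle from the source long axis with 0 deg toward the source tip
(the AAPM coordinate frame).  Vendor anisotropy tables are often stored
with 0 deg on the cable end; :class:`AnisotropyTable` records which
convention a table uses and lookups convert transparently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "SourceModel",
    "RadialDoseModel",
    "AnisotropyTable",
    "PolarPoint",
    "CartesianPoint",
    "TG43Engine",
    "geometry_factor",
    "radial_dose",
    "anisotropy_lookup",
    "pole_extrapolate",
    "dose_rate",
]

log = logging.getLogger(__name__)

#: angular tolerance (degrees) inside which the pole branch of G_L is used
DEFAULT_POLE_EPS = 1e-4
#: positivity floor applied to pole-extrapolated anisotropy values
DEFAULT_POLE_FLOOR = 1e-3


class DomainError(ValueError):
    """Query point outside the physical domain of a TG-43 factor."""


@dataclass(frozen=True)
class PolarPoint:
    """Point in source-centred polar coordinates (r in cm, theta in degrees)."""

    r: float
    theta: float

    def __post_init__(self) -> None:
        if not self.r > 0:
            raise ValueError(f"r must be > 0, got {self.r}")
        if not 0.0 <= self.theta <= 180.0:
            raise ValueError(f"theta must lie in [0, 180], got {self.theta}")


@dataclass(frozen=True)
class CartesianPoint:
    """Point in along-away coordinates: y away from the axis, z along it (cm)."""

    y: float
    z: float


@dataclass(frozen=True)
class SourceModel:
    """Physical description of a cylindrical HDR source.

    Parameters
    ----------
    active_length :
        Active-core length L in cm.
    dose_rate_constant :
        Lambda in cGy/h per U.
    air_kerma_strength :
        Sk in U (uGy m^2 / h).
    r0, theta0 :
        TG-43 reference point, default (1 cm, 90 deg).
    theta_zero_orientation :
        Which physical end of the source the engine's 0 deg polar angle
        points to.  The AAPM frame ('tip') is the default.
    """

    active_length: float
    dose_rate_constant: float
    air_kerma_strength: float = 1.0
    r0: float = 1.0
    theta0: float = 90.0
    theta_zero_orientation: Literal["tip", "cable"] = "tip"

    def __post_init__(self) -> None:
        if not self.active_length > 0:
            raise ValueError("active_length must be > 0")
        if not self.dose_rate_constant > 0:
            raise ValueError("dose_rate_constant must be > 0")
        if not self.air_kerma_strength > 0:
            raise ValueError("air_kerma_strength must be > 0")
        if not self.r0 > self.active_length / 2:
            raise ValueError("r0 must exceed half the active length")
        if not 0 < self.theta0 <= 90:
            raise ValueError("theta0 must lie in (0, 90]")
        if self.theta_zero_orientation not in ("tip", "cable"):
            raise ValueError("theta_zero_orientation must be 'tip' or 'cable'")


def geometry_factor(
    r,
    theta,
    L: float,
    pole_eps: float = DEFAULT_POLE_EPS,
):
    """Line-source geometry function G_L(r, theta) in 1/cm^2.

    For theta away from the poles,

        G_L = beta / (L * r * sin(theta))

    with ``beta`` the angle subtended at the field point by the active
    core, evaluated from the two arccos terms of the TG-43 formulation.
    Within ``pole_eps`` degrees of 0 or 180 deg the limiting on-axis form
    ``1 / (r^2 - L^2/4)`` is used (the 180-deg case follows by symmetry).

    Raises :class:`DomainError` for theta outside [0, 180] or for points
    lying on the active-core segment itself.
    """
    r = np.asarray(r, dtype=float)
    theta = np.asarray(theta, dtype=float)
    r, theta = np.broadcast_arrays(r, theta)
    if np.any(theta < 0) or np.any(theta > 180):
        raise DomainError("theta must lie in [0, 180] degrees")
    if np.any(r <= 0):
        raise DomainError("r must be > 0")

    th = np.radians(theta)
    half = L / 2.0
    on_pole = (theta <= pole_eps) | (theta >= 180.0 - pole_eps)
    # on the source segment: sin(theta)=0 with |r cos(theta)| <= L/2
    if np.any(on_pole & (r <= half)):
        raise DomainError("point lies on the active-core segment")

    rcos = r * np.cos(th)
    rsin = r * np.sin(th)
    # distances to the tip (+L/2) and cable (-L/2) ends of the core
    d_tip = np.sqrt(r * r + half * half - L * rcos)
    d_cab = np.sqrt(r * r + half * half + L * rcos)
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = np.arccos(np.clip((rcos - half) / d_tip, -1.0, 1.0)) - np.arccos(
            np.clip((rcos + half) / d_cab, -1.0, 1.0)
        )
        general = beta / (L * rsin)
    pole = 1.0 / (r * r - half * half)
    out = np.where(on_pole, pole, general)
    if out.ndim == 0:
        return float(out)
    return out


@dataclass(frozen=True)
class RadialDoseModel:
    """Radial dose function g_L(r), as polynomial coefficients or a table.

    ``coefficients`` are ascending powers of r (c0 + c1*r + ...), the form
    vendors ship as a Meisberger-style fit.  Table form interpolates either
    linearly or log-linearly (ln g linear in ln r, recommended close to the
    source).  g(r0) must equal 1 within 1e-6; construct with
    ``normalize=True`` via the factory methods to enforce it.
    """

    form: Literal["polynomial", "table"]
    valid_range: tuple[float, float]
    coefficients: tuple[float, ...] | None = None
    table_r: tuple[float, ...] | None = None
    table_g: tuple[float, ...] | None = None
    interpolation: Literal["linear", "log-linear"] = "linear"
    out_of_range: Literal["reject", "clamp"] = "reject"
    r0: float = 1.0

    def __post_init__(self) -> None:
        lo, hi = self.valid_range
        if not lo < hi:
            raise ValueError("valid_range must be (r_min, r_max) with r_min < r_max")
        if self.form == "polynomial":
            if self.coefficients is None or len(self.coefficients) < 2:
                raise ValueError("polynomial form needs degree >= 1")
        elif self.form == "table":
            if self.table_r is None or self.table_g is None:
                raise ValueError("table form needs table_r and table_g")
            rr = np.asarray(self.table_r, float)
            gg = np.asarray(self.table_g, float)
            if rr.size != gg.size or rr.size < 2:
                raise ValueError("table needs >= 2 (r, g) pairs of equal length")
            if np.any(np.diff(rr) <= 0):
                raise ValueError("table radii must be strictly increasing")
            if np.any(gg <= 0):
                raise ValueError("all g values must be > 0")
        else:
            raise ValueError(f"unknown form {self.form!r}")
        g0 = float(self._evaluate(np.asarray(self.r0)))
        if abs(g0 - 1.0) > 1e-6:
            raise ValueError(
                f"g(r0={self.r0}) = {g0:.8f}; model must be normalized to 1 within 1e-6"
            )

    @classmethod
    def from_polynomial(
        cls,
        coefficients: Sequence[float],
        valid_range: tuple[float, float] = (0.1, 15.0),
        r0: float = 1.0,
        normalize: bool = False,
        out_of_range: Literal["reject", "clamp"] = "reject",
    ) -> "RadialDoseModel":
        c = np.asarray(coefficients, dtype=float)
        if normalize:
            c = c / np.polyval(c[::-1], r0)
        return cls(
            form="polynomial",
            coefficients=tuple(c),
            valid_range=valid_range,
            out_of_range=out_of_range,
            r0=r0,
        )

    @classmethod
    def from_table(
        cls,
        r: Sequence[float],
        g: Sequence[float],
        interpolation: Literal["linear", "log-linear"] = "linear",
        r0: float = 1.0,
        normalize: bool = False,
        out_of_range: Literal["reject", "clamp"] = "reject",
        valid_range: tuple[float, float] | None = None,
    ) -> "RadialDoseModel":
        rr = np.asarray(r, dtype=float)
        gg = np.asarray(g, dtype=float)
        if normalize:
            if interpolation == "log-linear":
                g0 = np.exp(np.interp(np.log(r0), np.log(rr), np.log(gg)))
            else:
                g0 = np.interp(r0, rr, gg)
            gg = gg / g0
        vr = valid_range if valid_range is not None else (float(rr[0]), float(rr[-1]))
        return cls(
            form="table",
            table_r=tuple(rr),
            table_g=tuple(gg),
            interpolation=interpolation,
            valid_range=vr,
            out_of_range=out_of_range,
            r0=r0,
        )

    def _evaluate(self, r: np.ndarray) -> np.ndarray:
        if self.form == "polynomial":
            c = np.asarray(self.coefficients, float)
            return np.polyval(c[::-1], r)
        rr = np.asarray(self.table_r, float)
        gg = np.asarray(self.table_g, float)
        if self.interpolation == "log-linear":
            return np.exp(np.interp(np.log(r), np.log(rr), np.log(gg)))
        return np.interp(r, rr, gg)


def radial_dose(r, model: RadialDoseModel):
    """Evaluate g_L(r); out-of-range radii follow the model's policy."""
    r = np.asarray(r, dtype=float)
    scalar = r.ndim == 0
    r = np.atleast_1d(r)
    lo, hi = model.valid_range
    oor = (r < lo) | (r > hi)
    if np.any(oor):
        if model.out_of_range == "reject":
            bad = r[oor][0]
            raise DomainError(
                f"r={bad:g} cm outside the radial-dose valid range [{lo:g}, {hi:g}] cm"
            )
        log.warning(
            "clamping %d radial-dose queries to valid range [%g, %g] cm",
            int(np.sum(oor)), lo, hi,
        )
        r = np.clip(r, lo, hi)
    out = model._evaluate(r)
    return float(out[0]) if scalar else out


class AnisotropyTable:
    """2D anisotropy function F(r, theta) on a rectangular (radius, angle) grid.

    ``theta_zero`` declares the table's own angular convention: which
    physical end of the source its 0-deg column refers to.  ``values`` has
    shape (len(radii), len(angles)).  If 90 deg is tabulated, F(r, 90)
    must equal 1 within 1e-3 for every radius.
    """

    def __init__(
        self,
        radii: Sequence[float],
        angles: Sequence[float],
        values,
        provenance: str = "",
        theta_zero: Literal["tip", "cable"] = "tip",
    ) -> None:
        self.radii = np.asarray(radii, dtype=float)
        self.angles = np.asarray(angles, dtype=float)
        self.values = np.asarray(values, dtype=float)
        self.provenance = provenance
        if theta_zero not in ("tip", "cable"):
            raise ValueError("theta_zero must be 'tip' or 'cable'")
        self.theta_zero = theta_zero
        if self.radii.ndim != 1 or self.radii.size < 1:
            raise ValueError("radii must be a non-empty 1D sequence")
        if self.angles.ndim != 1 or self.angles.size < 1:
            raise ValueError("angles must be a non-empty 1D sequence")
        if np.any(np.diff(self.radii) <= 0):
            raise ValueError("radii must be strictly increasing")
        if np.any(np.diff(self.angles) <= 0):
            raise ValueError("angles must be strictly increasing")
        if np.any(self.angles < 0) or np.any(self.angles > 180):
            raise ValueError("angles must lie in [0, 180] degrees")
        if self.values.shape != (self.radii.size, self.angles.size):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"({self.radii.size}, {self.angles.size})"
            )
        if np.any(~np.isfinite(self.values)) or np.any(self.values <= 0):
            raise ValueError("all F values must be finite and > 0")
        i90 = np.nonzero(np.isclose(self.angles, 90.0))[0]
        if i90.size:
            col = self.values[:, i90[0]]
            if np.any(np.abs(col - 1.0) > 1e-3):
                raise ValueError("F(r, 90 deg) must equal 1 within 1e-3")

    def __eq__(self, other) -> bool:  # value equality, used in round-trip tests
        if not isinstance(other, AnisotropyTable):
            return NotImplemented
        return (
            np.array_equal(self.radii, other.radii)
            and np.array_equal(self.angles, other.angles)
            and np.array_equal(self.values, other.values)
            and self.theta_zero == other.theta_zero
        )

    def __repr__(self) -> str:
        return (
            f"AnisotropyTable({self.radii.size} radii x {self.angles.size} angles, "
            f"theta_zero={self.theta_zero!r}, provenance={self.provenance!r})"
        )


def pole_extrapolate(
    table: AnisotropyTable,
    r,
    target_theta: float,
    floor: float = DEFAULT_POLE_FLOOR,
):
    """Extrapolate F to a pole angle (0 or 180 deg, table convention).

    A straight line through the two tabulated angles nearest the pole
    (on that side of 90 deg) is evaluated at the pole; the result is
    floored at ``floor`` to preserve positivity.  Radii are interpolated
    linearly between tabulated values (clamped at the radial range ends).
    """
    if target_theta not in (0, 180, 0.0, 180.0):
        raise ValueError("target_theta must be 0 or 180")
    if target_theta == 0:
        side = np.nonzero(table.angles < 90.0)[0]
        if side.size < 2:
            raise ValueError("need >= 2 tabulated angles below 90 deg")
        i1, i2 = side[0], side[1]
    else:
        side = np.nonzero(table.angles > 90.0)[0]
        if side.size < 2:
            raise ValueError("need >= 2 tabulated angles above 90 deg")
        i1, i2 = side[-1], side[-2]
    a1, a2 = table.angles[i1], table.angles[i2]
    r = np.asarray(r, dtype=float)
    scalar = r.ndim == 0
    rq = np.clip(np.atleast_1d(r), table.radii[0], table.radii[-1])
    f1 = np.interp(rq, table.radii, table.values[:, i1])
    f2 = np.interp(rq, table.radii, table.values[:, i2])
    slope = (f2 - f1) / (a2 - a1)
    out = np.maximum(f1 + slope * (float(target_theta) - a1), floor)
    return float(out[0]) if scalar else out


def _extended_grid(
    table: AnisotropyTable, floor: float
) -> tuple[np.ndarray, np.ndarray]:
    """Angle grid and value matrix with pole columns appended if absent.

    Pole columns come from :func:`pole_extrapolate`, so bilinear lookup
    beyond the tabulated angular range follows the linear-fit policy.
    """
    angles = table.angles
    values = table.values
    if angles[0] > 0.0:
        try:
            pole0 = pole_extrapolate(table, table.radii, 0.0, floor=floor)
        except ValueError:  # fewer than two angles on that side: clamp
            pole0 = values[:, 0]
        angles = np.concatenate(([0.0], angles))
        values = np.column_stack([pole0, values])
    if angles[-1] < 180.0:
        try:
            pole180 = pole_extrapolate(table, table.radii, 180.0, floor=floor)
        except ValueError:
            pole180 = values[:, -1]
        angles = np.concatenate((angles, [180.0]))
        values = np.column_stack([values, pole180])
    return angles, values


def _bilinear(xg: np.ndarray, yg: np.ndarray, zz: np.ndarray, x, y) -> np.ndarray:
    """Vectorised bilinear interpolation on a rectangular grid (exact at nodes)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ix = np.clip(np.searchsorted(xg, x, side="right") - 1, 0, max(xg.size - 2, 0))
    iy = np.clip(np.searchsorted(yg, y, side="right") - 1, 0, max(yg.size - 2, 0))
    if xg.size == 1:
        tx = np.zeros_like(x)
        ix1 = ix
    else:
        tx = (x - xg[ix]) / (xg[ix + 1] - xg[ix])
        ix1 = ix + 1
    if yg.size == 1:
        ty = np.zeros_like(y)
        iy1 = iy
    else:
        ty = (y - yg[iy]) / (yg[iy + 1] - yg[iy])
        iy1 = iy + 1
    z00 = zz[ix, iy]
    z10 = zz[ix1, iy]
    z01 = zz[ix, iy1]
    z11 = zz[ix1, iy1]
    return (
        z00 * (1 - tx) * (1 - ty)
        + z10 * tx * (1 - ty)
        + z01 * (1 - tx) * ty
        + z11 * tx * ty
    )


def anisotropy_lookup(
    r,
    theta,
    table: AnisotropyTable,
    pole_floor: float = DEFAULT_POLE_FLOOR,
):
    """Bilinear F(r, theta) lookup in the table's own angular convention.

    Node queries return stored values exactly.  Radii outside the
    tabulated range are clamped to the nearest tabulated radius; angles
    beyond the tabulated range use the linear pole-extrapolation policy.
    """
    r = np.asarray(r, dtype=float)
    theta = np.asarray(theta, dtype=float)
    r, theta = np.broadcast_arrays(r, theta)
    scalar = r.ndim == 0
    if np.any(theta < 0) or np.any(theta > 180):
        raise DomainError("theta must lie in [0, 180] degrees")
    rq = np.atleast_1d(r)
    if np.any(rq < table.radii[0]) or np.any(rq > table.radii[-1]):
        log.debug("clamping anisotropy radial queries to [%g, %g] cm",
                  table.radii[0], table.radii[-1])
    rq = np.clip(rq, table.radii[0], table.radii[-1])
    angles, values = _extended_grid(table, pole_floor)
    out = _bilinear(table.radii, angles, values, rq, np.atleast_1d(theta))
    return float(out[0]) if scalar else out.reshape(np.shape(r))


def dose_rate(
    point: PolarPoint | tuple,
    source: SourceModel,
    g: RadialDoseModel,
    F: AnisotropyTable,
    pole_eps: float = DEFAULT_POLE_EPS,
):
    """TG-43 LSA dose rate at a polar point, in cGy/h.

    ``point`` may be a :class:`PolarPoint` or arrays ``(r, theta)`` with
    theta in the engine convention set by ``source.theta_zero_orientation``.
    """
    if isinstance(point, PolarPoint):
        r, theta = point.r, point.theta
    else:
        r, theta = point
    return TG43Engine(source, g, F, pole_eps=pole_eps).dose_rate(r, theta)


@dataclass
class TG43Engine:
    """Bundle of source model + g(r) + F(r, theta), vectorised over points."""

    source: SourceModel
    radial_model: RadialDoseModel
    anisotropy: AnisotropyTable
    pole_eps: float = DEFAULT_POLE_EPS
    pole_floor: float = DEFAULT_POLE_FLOOR
    label: str = ""
    _g_ref: float = field(init=False, repr=False, default=0.0)

    def __post_init__(self) -> None:
        self._g_ref = geometry_factor(
            self.source.r0, self.source.theta0, self.source.active_length,
            pole_eps=self.pole_eps,
        )

    def _table_theta(self, theta):
        """Engine polar angle -> the anisotropy table's own convention."""
        if self.anisotropy.theta_zero == self.source.theta_zero_orientation:
            return theta
        return 180.0 - np.asarray(theta, float)

    def anisotropy_at(self, r, theta):
        return anisotropy_lookup(
            r, self._table_theta(theta), self.anisotropy, pole_floor=self.pole_floor
        )

    def dose_rate(self, r, theta):
        """Dose rate (cGy/h) at (r [cm], theta [deg], engine convention)."""
        s = self.source
        G = geometry_factor(r, theta, s.active_length, pole_eps=self.pole_eps)
        gr = radial_dose(r, self.radial_model)
        F = self.anisotropy_at(r, theta)
        return s.air_kerma_strength * s.dose_rate_constant * (G / self._g_ref) * gr * F

    def dose_rate_per_sk(self, r, theta):
        return self.dose_rate(r, theta) / self.source.air_kerma_strength
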