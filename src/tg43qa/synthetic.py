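"""Synthetic TG-43 data with the structure real HDR Ir-192 sources show.

Monte Carlo anisotropy tables for cabled HDR sources are smooth, equal
to 1 on the transverse axis, and fall steeply within roughly 15 deg of
both poles — more steeply on the cable side, where the drive cable
perturbs the water medium.  Vendor input tables subsample such reference
data onto a sparse angle list with large gaps next to the poles, which
is precisely what creates interpolation discrepancies (ODIN) in a
planning system.  This module generates a dense "reference" table with
that structure, a sparse "vendor" subsample of it, and along-away
dose-rate tables from a known engine, so the entire commissioning
pipeline can be exercised end to end with known ground truth.

The default parameters are frozen as the package's study conditions: a
0.5 cm active length, Lambda = 1.10 cGy/h/U, cable-side depression
amplitude 0.55 with 6-deg width and tip-side amplitude 0.45 with 10-deg
width, vendor gaps (1.5, 25.5) and (155.5, 178.5) deg, and a 362-point
along-away reference grid.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Literal, Sequence

import numpy as np

from .engine import (
    AnisotropyTable,
    RadialDoseModel,
    SourceModel,
    TG43Engine,
    anisotropy_lookup,
    pole_extrapolate,
)
from .tables import AlongAwayTable, SINGULAR_MARGIN

__all__ = [
    "SyntheticAnisotropySpec",
    "make_reference_anisotropy",
    "subsample_vendor",
    "make_alongaway",
    "make_radial_model",
    "default_source",
    "default_engines",
    "DEFAULT_VENDOR_ANGLES",
    "DEFAULT_VENDOR_RADII",
    "DEFAULT_REFERENCE_RADII",
    "DEFAULT_ALONGAWAY_Y",
    "DEFAULT_ALONGAWAY_Z",
    "VENDOR_GAP_BANDS",
]

# vendor angle list: 17 entries incl. the mandatory 0 and 180 poles, with
# fine 1.5-deg sampling on the cable side, then wide gaps next to both poles
DEFAULT_VENDOR_ANGLES: tuple[float, ...] = (
    0.0, 1.5, 25.5, 35.5, 45.5, 60.5, 75.5, 90.0, 105.5, 120.5,
    135.5, 145.5, 155.5, 178.5, 179.0, 179.5, 180.0,
)
DEFAULT_VENDOR_RADII: tuple[float, ...] = (
    0.5, 0.7, 1.0, 2.0, 3.0, 3.5, 5.0, 7.0, 10.0, 15.0,
)
DEFAULT_REFERENCE_RADII: tuple[float, ...] = (
    0.5, 1.0, 1.5, 2.0, 3.0, 5.0, 7.0, 10.0, 15.0,
)
#: angular intervals (table convention, cable at 0 deg) with no vendor nodes
VENDOR_GAP_BANDS: tuple[tuple[float, float], ...] = ((1.5, 25.5), (155.5, 178.5))

# 14 x 26 Cartesian grid; two points fall in the singular zone, leaving 362
DEFAULT_ALONGAWAY_Y: tuple[float, ...] = (
    0.0, 0.25, 0.5, 0.75, 1.0, 1.25, 1.5, 2.0, 2.5, 3.0, 4.0, 5.0, 6.0, 7.0,
)
_half_z = (0.25, 0.5, 0.75, 1.0, 1.25, 1.5, 2.0, 2.5, 3.0, 4.0, 5.0, 6.0, 7.0)
DEFAULT_ALONGAWAY_Z: tuple[float, ...] = tuple(-z for z in reversed(_half_z)) + _half_z

#: slowly varying Meisberger-style quartic for g_L(r) (normalised at r0=1)
DEFAULT_RADIAL_COEFFS: tuple[float, ...] = (0.9934, 0.0086, -8.3e-4, -3.1e-5, 2.0e-7)


@dataclass(frozen=True)
class SyntheticAnisotropySpec:
    """Parameters of the synthetic anisotropy function.

    F(r, theta) = 1 - A_cable(r)*exp(-theta_c/w_cable)
                    - A_tip(r)*exp(-theta_t/w_tip),

    renormalised so F(r, 90) = 1 exactly, where theta_c and theta_t are
    the angular distances (deg) to the cable and tip poles.  Amplitudes
    may be constants in (0, 1) or callables of r.  With
    ``theta_zero='cable'`` (the default, matching the vendor-table
    convention being emulated) the cable pole sits at 0 deg.
    """

    amp_cable: float | Callable[[np.ndarray], np.ndarray] = 0.55
    width_cable: float = 6.0
    amp_tip: float | Callable[[np.ndarray], np.ndarray] = 0.45
    width_tip: float = 10.0
    radii: tuple[float, ...] = DEFAULT_REFERENCE_RADII
    angle_step: float = 3.0
    angle_start: float = 1.5
    theta_zero: Literal["tip", "cable"] = "cable"
    noise_sd: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        for amp in (self.amp_cable, self.amp_tip):
            if not callable(amp) and not 0 <= amp < 1:
                raise ValueError("pole depression amplitudes must lie in [0, 1)")
        if self.width_cable <= 0 or self.width_tip <= 0:
            raise ValueError("gradient widths must be > 0")
        if self.angle_step <= 0:
            raise ValueError("angle_step must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def _amp(self, amp, r: np.ndarray) -> np.ndarray:
        a = amp(r) if callable(amp) else np.full_like(r, float(amp))
        if np.any(a < 0) or np.any(a >= 1):
            raise ValueError("amplitude values must lie in [0, 1)")
        return a

    def evaluate(self, r, theta) -> np.ndarray:
        """Noise-free F at (r, theta) in the spec's table convention."""
        r = np.asarray(r, float)
        theta = np.asarray(theta, float)
        r, theta = np.broadcast_arrays(r, theta)
        theta_cable = theta if self.theta_zero == "cable" else 180.0 - theta
        theta_tip = 180.0 - theta_cable
        a_c = self._amp(self.amp_cable, r)
        a_t = self._amp(self.amp_tip, r)
        raw = (
            1.0
            - a_c * np.exp(-theta_cable / self.width_cable)
            - a_t * np.exp(-theta_tip / self.width_tip)
        )
        ref = (
            1.0
            - a_c * np.exp(-90.0 / self.width_cable)
            - a_t * np.exp(-90.0 / self.width_tip)
        )
        return raw / ref


def make_reference_anisotropy(spec: SyntheticAnisotropySpec) -> AnisotropyTable:
    """Dense reference anisotropy table from the synthetic spec.

    The angle grid runs from ``angle_start`` to ``180 - angle_start`` in
    ``angle_step`` increments and deliberately omits the 0/180 poles, as
    published Monte Carlo tables commonly do.  Optional multiplicative
    noise (relative SD ``noise_sd``) is applied with the stored seed and
    the transverse-axis column is re-pinned to 1.
    """
    angles = np.arange(spec.angle_start, 180.0 - spec.angle_start + 1e-9,
                       spec.angle_step)
    radii = np.asarray(spec.radii, float)
    R, A = np.meshgrid(radii, angles, indexing="ij")
    values = spec.evaluate(R, A)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        values = values * (1.0 + spec.noise_sd * rng.standard_normal(values.shape))
        i90 = np.argmin(np.abs(angles - 90.0))
        values = values / values[:, [i90]] * spec.evaluate(radii, 90.0)[:, None]
    return AnisotropyTable(
        radii=radii,
        angles=angles,
        values=values,
        provenance=f"reference(seed={spec.seed})",
        theta_zero=spec.theta_zero,
    )


def subsample_vendor(
    dense: AnisotropyTable,
    angles: Sequence[float] | None = None,
    radii: Sequence[float] | None = None,
) -> AnisotropyTable:
    """Vendor-style sparse subsample of a dense anisotropy table.

    Interior nodes are taken from the dense table (bilinear where a
    requested node is not tabulated); the mandatory 0/180-deg pole
    entries are filled by linear extrapolation from the dense table's two
    angles nearest each pole — the same first-order rule vendor pole
    entries have been observed to follow.
    """
    ang = np.asarray(
        DEFAULT_VENDOR_ANGLES if angles is None else angles, dtype=float
    )
    rad = np.asarray(DEFAULT_VENDOR_RADII if radii is None else radii, dtype=float)
    if ang.size == 0 or rad.size == 0:
        raise ValueError("vendor axes must be non-empty")
    values = np.empty((rad.size, ang.size))
    for j, a in enumerate(ang):
        if a == 0.0 and a < dense.angles[0]:
            values[:, j] = pole_extrapolate(dense, rad, 0.0)
        elif a == 180.0 and a > dense.angles[-1]:
            values[:, j] = pole_extrapolate(dense, rad, 180.0)
        else:
            # off-grid angles short of a pole ride the same extrapolation
            # line via the lookup's extended grid
            values[:, j] = anisotropy_lookup(rad, np.full_like(rad, a), dense)
    return AnisotropyTable(
        radii=rad,
        angles=ang,
        values=values,
        provenance="vendor",
        theta_zero=dense.theta_zero,
    )


def make_radial_model(
    kind: Literal["flat", "polynomial", "table"] = "polynomial",
    coefficients: Sequence[float] | None = None,
    table_radii: Sequence[float] | None = None,
    interpolation: Literal["linear", "log-linear"] = "linear",
    valid_range: tuple[float, float] = (0.1, 15.0),
    seed: int | None = None,
) -> RadialDoseModel:
    """Construct a normalised radial dose model g(r) with g(1 cm) = 1.

    'flat' gives g = 1 everywhere; 'polynomial' uses the supplied (or
    default quartic) coefficients; 'table' samples that polynomial at
    ``table_radii``.  ``seed`` is accepted for interface uniformity and
    recorded use in provenance-sensitive callers; the generator itself is
    deterministic.
    """
    if kind == "flat":
        return RadialDoseModel.from_polynomial(
            (1.0, 0.0), valid_range=valid_range, normalize=False
        )
    coeffs = DEFAULT_RADIAL_COEFFS if coefficients is None else tuple(coefficients)
    if kind == "polynomial":
        return RadialDoseModel.from_polynomial(
            coeffs, valid_range=valid_range, normalize=True
        )
    if kind == "table":
        rr = np.asarray(
            table_radii if table_radii is not None else np.linspace(*valid_range, 40),
            dtype=float,
        )
        c = np.asarray(coeffs, float)
        gg = np.polyval(c[::-1], rr)
        return RadialDoseModel.from_table(
            rr, gg, interpolation=interpolation, normalize=True,
            valid_range=valid_range,
        )
    raise ValueError(f"unknown radial model kind {kind!r}")


def default_source(
    active_length: float = 0.5,
    dose_rate_constant: float = 1.10,
    air_kerma_strength: float = 1.0,
) -> SourceModel:
    """Default synthetic source: 0.5 cm core, Lambda = 1.10 cGy/h/U."""
    return SourceModel(
        active_length=active_length,
        dose_rate_constant=dose_rate_constant,
        air_kerma_strength=air_kerma_strength,
    )


def make_alongaway(
    source: SourceModel,
    g: RadialDoseModel,
    F: AnisotropyTable,
    y_values: Sequence[float] | None = None,
    z_values: Sequence[float] | None = None,
    singular_margin: float = SINGULAR_MARGIN,
) -> AlongAwayTable:
    """Along-away dose-rate-per-Sk table from a known engine.

    The tip points toward +z.  Grid points within ``L/2 + singular_margin``
    of the source centre are masked NaN; the default grid then holds
    exactly 362 valid points.
    """
    y = np.asarray(DEFAULT_ALONGAWAY_Y if y_values is None else y_values, float)
    z = np.asarray(DEFAULT_ALONGAWAY_Z if z_values is None else z_values, float)
    eng = TG43Engine(source, g, F)
    Y, Z = np.meshgrid(y, z, indexing="xy")
    R = np.hypot(Y, Z)
    TH = np.degrees(np.arctan2(np.abs(Y), Z))
    ok = R > source.active_length / 2 + singular_margin
    vals = np.full(R.shape, np.nan)
    vals[ok] = eng.dose_rate_per_sk(R[ok], TH[ok])
    return AlongAwayTable(y_values=y, z_values=z, values=vals, label="synthetic")


def default_engines(
    spec: SyntheticAnisotropySpec | None = None,
    source: SourceModel | None = None,
    g: RadialDoseModel | None = None,
) -> tuple[TG43Engine, TG43Engine]:
    """(reference, vendor) engine pair under the default study conditions.

    Both engines share the source and g(r); they differ only in the
    anisotropy table (dense reference vs sparse vendor subsample), so any
    dose difference between them is pure table-interpolation error.
    """
    spec = spec if spec is not None else SyntheticAnisotropySpec()
    source = source if source is not None else default_source()
    g = g if g is not None else make_radial_model("polynomial")
    dense = make_reference_anisotropy(spec)
    vendor = subsample_vendor(dense)
    ref_eng = TG43Engine(source, g, dense, label="reference")
    ven_eng = TG43Engine(source, g, vendor, label="vendor")
    return ref_eng, ven_eng
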