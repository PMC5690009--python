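"""QA point patterns for checking a planning system's dose-rate output.

Classic commissioning documents (NCS report 13, ESTRO Booklet 8) check
the TPS on ray patterns that implicitly assume a source symmetric about
its transverse axis, with no ray inside the steep-gradient cones near
the poles — exactly where sparse vendor anisotropy tables interpolate
worst.  The half-star pattern adds control points in both near-pole
cones (one ray strictly inside (0, 15) deg of each pole region), forcing
the TPS to display results in the high-gradient zones.

Angles here are in the engine convention (0 deg toward the source tip).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .engine import PolarPoint, TG43Engine
from .tables import INVESTIGATION_LEVEL, INTERVENTION_LEVEL

__all__ = [
    "QaPointPattern",
    "PatternReport",
    "half_star_pattern",
    "legacy_pattern",
    "evaluate_pattern",
]


@dataclass
class QaPointPattern:
    """A named set of polar rays, each carrying several radii."""

    name: str
    rays: list[tuple[float, list[float]]]  # (angle deg, radii cm)
    symmetry: Literal["transverse-mirror", "none"] = "none"

    def __post_init__(self) -> None:
        for ang, radii in self.rays:
            if not 0 <= ang <= 180:
                raise ValueError(f"ray angle {ang} outside [0, 180]")
            if any(r <= 0 for r in radii):
                raise ValueError("pattern radii must be > 0")

    @property
    def points(self) -> list[PolarPoint]:
        return [
            PolarPoint(r=float(r), theta=float(ang))
            for ang, radii in self.rays
            for r in radii
        ]

    @property
    def n_points(self) -> int:
        return sum(len(radii) for _, radii in self.rays)

    def has_ray_in(self, lo: float, hi: float) -> bool:
        """True if any ray angle lies strictly inside (lo, hi) degrees."""
        return any(lo < ang < hi for ang, _ in self.rays)


DEFAULT_PATTERN_RADII = (0.5, 1.0, 2.0, 3.0, 5.0)


def half_star_pattern(
    radii: Sequence[float] = DEFAULT_PATTERN_RADII,
    near_tip_ray: float = 7.0,
    near_cable_ray: float = 172.0,
) -> QaPointPattern:
    """Six-ray half-star: 0, a ray in (0, 15), 45, 90, 135, a ray in (165, 180).

    The two free rays default to 7 and 172 deg and must stay strictly
    inside their open intervals — they are the pattern's whole point,
    probing the steep near-pole gradient cones on both source ends.
    """
    if not 0.0 < near_tip_ray < 15.0:
        raise ValueError("near-tip ray must lie strictly inside (0, 15) deg")
    if not 165.0 < near_cable_ray < 180.0:
        raise ValueError("near-cable ray must lie strictly inside (165, 180) deg")
    radii = [float(r) for r in radii]
    rays = [(a, list(radii)) for a in
            (0.0, near_tip_ray, 45.0, 90.0, 135.0, near_cable_ray)]
    return QaPointPattern(name="half_star", rays=rays, symmetry="none")


#: shipped defaults for the legacy ray patterns; both assume transverse-mirror
#: symmetry and place no ray strictly inside the (0, 15)-deg pole cones
_LEGACY_ANGLES = {
    "ncs": (0.0, 30.0, 60.0, 90.0, 120.0, 150.0, 180.0),
    "estro": (0.0, 45.0, 90.0, 135.0, 180.0),
}


def legacy_pattern(
    kind: Literal["ncs", "estro"],
    radii: Sequence[float] = DEFAULT_PATTERN_RADII,
    angles: Sequence[float] | None = None,
) -> QaPointPattern:
    """Legacy-style ray pattern with the transverse-mirror assumption.

    The shipped default angle sets are schematic stand-ins for the
    published report figures (which give no numeric coordinates) and are
    overridable via ``angles``.
    """
    if kind not in _LEGACY_ANGLES:
        raise ValueError("kind must be 'ncs' or 'estro'")
    ang = _LEGACY_ANGLES[kind] if angles is None else tuple(angles)
    if len(ang) == 0 or len(radii) == 0:
        raise ValueError("pattern needs at least one ray and one radius")
    radii = [float(r) for r in radii]
    rays = [(float(a), list(radii)) for a in ang]
    return QaPointPattern(name=kind, rays=rays, symmetry="transverse-mirror")


@dataclass
class PatternReport:
    """Per-point two-engine comparison over a QA pattern."""

    pattern: str
    rows: list[dict]  # r, theta, dose_a, dose_b, diff_pct, flag
    investigation_level: float
    intervention_level: float

    @property
    def n_flagged(self) -> int:
        return sum(1 for row in self.rows if row["flag"] != "ok")

    @property
    def max_abs_diff_pct(self) -> float:
        diffs = [abs(row["diff_pct"]) for row in self.rows
                 if np.isfinite(row["diff_pct"])]
        return max(diffs) if diffs else 0.0

    @property
    def worst_level(self) -> int:
        """0 clean, 3 investigation-level findings, 4 intervention-level."""
        levels = {"ok": 0, "investigation": 3, "intervention": 4}
        return max((levels[row["flag"]] for row in self.rows), default=0)


def evaluate_pattern(
    pattern: QaPointPattern,
    engine_a: TG43Engine,
    engine_b: TG43Engine,
    investigation: float = INVESTIGATION_LEVEL,
    intervention: float = INTERVENTION_LEVEL,
) -> PatternReport:
    """Compare two engines' dose rates at every pattern point.

    ``engine_a`` is the reference; the signed percent difference is
    100*(b-a)/a.  Engine domain errors at individual points (e.g. a
    radius inside the source) are recorded per point, not raised.
    """
    rows = []
    for pt in pattern.points:
        try:
            da = float(engine_a.dose_rate(pt.r, pt.theta))
            db = float(engine_b.dose_rate(pt.r, pt.theta))
            diff = 100.0 * (db - da) / da
        except Exception as exc:  # surface per point
            rows.append({
                "r_cm": pt.r, "theta_deg": pt.theta,
                "dose_a": np.nan, "dose_b": np.nan, "diff_pct": np.nan,
                "flag": "ok", "error": str(exc),
            })
            continue
        if abs(diff) > intervention:
            flag = "intervention"
        elif abs(diff) > investigation:
            flag = "investigation"
        else:
            flag = "ok"
        rows.append({
            "r_cm": pt.r, "theta_deg": pt.theta,
            "dose_a": da, "dose_b": db, "diff_pct": diff,
            "flag": flag, "error": "",
        })
    return PatternReport(
        pattern=pattern.name,
        rows=rows,
        investigation_level=investigation,
        intervention_level=intervention,
    )
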