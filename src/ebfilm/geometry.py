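"""Film geometries and the film-plane <-> source polar-coordinate mapping.

Three irradiation geometries are modeled:

* **polar** — the film plane contains the source's long axis (film parallel
  to and abutting the tandem).  The dwell position is a marked point in
  film-plane coordinates; the proximal direction (theta = 0) points toward
  -x, so the dome tip points toward +x.
* **azimuthal** — the film plane is orthogonal to the long axis, one of a
  four-film array threaded onto the tandem through a central punched hole,
  films separated by 1 cm.  Films sit on the proximal side of the dwell
  position at a known axial offset.
* **calibration** — film orthogonal to the axis on the distal side, a set
  axial distance beyond the tip (13 mm by default).

All film-plane lengths are mm; polar radii are cm (the dose engine's unit).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .source import PolarCoordinate

__all__ = [
    "PolarFilmGeometry",
    "AzimuthalFilmGeometry",
    "CalibrationFilmGeometry",
    "FlatFieldGeometry",
    "film_to_polar",
    "polar_to_film",
]


@dataclass(frozen=True)
class PolarFilmGeometry:
    """Film parallel to the tandem with the marked dwell position on-plane."""

    width_mm: float = 70.0
    height_mm: float = 50.0
    source_x_mm: float = 35.0
    source_y_mm: float = 10.0
    dpi: float = 150.0

    orientation = "polar"

    def __post_init__(self) -> None:
        if self.width_mm <= 0 or self.height_mm <= 0 or self.dpi <= 0:
            raise ValueError("film dimensions and dpi must be > 0")


@dataclass(frozen=True)
class AzimuthalFilmGeometry:
    """One film of the orthogonal four-film array.

    ``axial_offset_cm`` is the distance from the dwell position to the film
    plane along the proximal axis (> 0: the film is up the tandem from the
    source).  The tandem passes through a hole punched at the film centre.
    """

    width_mm: float = 70.0
    height_mm: float = 70.0
    axial_offset_cm: float = 1.0
    hole_radius_mm: float = 2.5
    film_index: int = 1
    film_separation_cm: float = 1.0
    dpi: float = 150.0

    orientation = "azimuthal"

    def __post_init__(self) -> None:
        if self.width_mm <= 0 or self.height_mm <= 0 or self.dpi <= 0:
            raise ValueError("film dimensions and dpi must be > 0")
        if self.hole_radius_mm < 0:
            raise ValueError("hole_radius_mm must be >= 0")
        if self.hole_radius_mm >= min(self.width_mm, self.height_mm) / 2:
            raise ValueError("hole radius must be smaller than the film half-extent")
        if not 1 <= self.film_index <= 4:
            raise ValueError("film_index must be 1..4")

    @property
    def center_mm(self) -> tuple[float, float]:
        return (self.width_mm / 2.0, self.height_mm / 2.0)


@dataclass(frozen=True)
class CalibrationFilmGeometry:
    """Film orthogonal to the axis, a set distance beyond the dome tip."""

    width_mm: float = 50.8
    height_mm: float = 50.8
    axial_offset_mm: float = 13.0
    dpi: float = 150.0

    orientation = "calibration"

    def __post_init__(self) -> None:
        if self.width_mm <= 0 or self.height_mm <= 0 or self.dpi <= 0:
            raise ValueError("film dimensions and dpi must be > 0")
        if self.axial_offset_mm <= 0:
            raise ValueError("axial_offset_mm must be > 0")

    @property
    def center_mm(self) -> tuple[float, float]:
        return (self.width_mm / 2.0, self.height_mm / 2.0)


@dataclass(frozen=True)
class FlatFieldGeometry:
    """Un-irradiated film used for scanner QA; 5 x 4 in by default."""

    width_mm: float = 127.0
    height_mm: float = 101.6
    dpi: float = 150.0

    orientation = "flat-field"


def film_to_polar(point_mm, geometry) -> PolarCoordinate:
    """Map a film-plane point (mm) to source-centred polar coordinates.

    The polar angle is measured from the proximal end of the source.  For
    polar films the proximal direction is the film's -x axis; for
    azimuthal/calibration films it is the out-of-plane axis toward the
    proximal side.
    """
    x, y = float(point_mm[0]), float(point_mm[1])
    if isinstance(geometry, PolarFilmGeometry):
        dx = x - geometry.source_x_mm
        dy = y - geometry.source_y_mm
        d = math.hypot(dx, dy)
        if d == 0.0:
            raise ValueError("point coincides with the source position")
        theta = math.degrees(math.acos(max(-1.0, min(1.0, -dx / d))))
        return PolarCoordinate(r_cm=d / 10.0, theta_deg=theta)
    if isinstance(geometry, AzimuthalFilmGeometry):
        cx, cy = geometry.center_mm
        rho = math.hypot(x - cx, y - cy)
        z = geometry.axial_offset_cm * 10.0
        d = math.hypot(rho, z)
        if d == 0.0:
            raise ValueError("point coincides with the source position")
        theta = math.degrees(math.acos(max(-1.0, min(1.0, z / d))))
        return PolarCoordinate(r_cm=d / 10.0, theta_deg=theta)
    if isinstance(geometry, CalibrationFilmGeometry):
        cx, cy = geometry.center_mm
        rho = math.hypot(x - cx, y - cy)
        z = geometry.axial_offset_mm
        d = math.hypot(rho, z)
        theta = math.degrees(math.acos(max(-1.0, min(1.0, -z / d))))
        return PolarCoordinate(r_cm=d / 10.0, theta_deg=theta)
    raise TypeError(f"unsupported geometry {type(geometry).__name__}")


def polar_to_film(
    geometry: PolarFilmGeometry, r_cm, theta_deg, side: int = +1
):
    """Film-plane point (mm) of (r, theta) for a polar-geometry film.

    The source axis lies in the film plane, so each (r, theta) has two
    mirror-image loci; ``side`` (+1 / -1) picks the half-plane.
    """
    if not isinstance(geometry, PolarFilmGeometry):
        raise TypeError("polar_to_film requires a PolarFilmGeometry")
    r = np.asarray(r_cm, dtype=float)
    t = np.radians(np.asarray(theta_deg, dtype=float))
    x = geometry.source_x_mm - 10.0 * r * np.cos(t)
    y = geometry.source_y_mm + side * 10.0 * r * np.sin(t)
    return x, y
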