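"""Dose maps: the pixel-value -> dose end of the analysis chain.

`dose_map_from_films` runs the film-analysis sequence on a scan pair
(invert -> 3x3 smooth -> scalar background ROI subtraction -> calibration
curve) and returns a :class:`DoseMap`, a 2D dose grid in film-plane mm
coordinates tied to its irradiation geometry.  Bilinear sampling on the
grid, guarded by the validity mask, supports the anisotropy extraction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .calibration import CalibrationCurve
from .geometry import AzimuthalFilmGeometry, PolarFilmGeometry, polar_to_film
from .image import FilmImage
from .processing import exclusion_mask, invert, roi_mean, smooth_3x3

__all__ = [
    "DoseMap",
    "MaskedRegionError",
    "dose_map_from_films",
    "sample_dose",
    "sample_azimuthal",
]

log = logging.getLogger(__name__)


class MaskedRegionError(ValueError):
    """A sampling locus falls in an excluded / invalid region."""


@dataclass
class DoseMap:
    """2D dose grid (cGy) on film-plane pixel-centre coordinates (mm)."""

    dose: np.ndarray
    x_mm: np.ndarray
    y_mm: np.ndarray
    geometry: object
    valid_mask: np.ndarray
    channel: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.dose = np.asarray(self.dose, dtype=float)
        self.x_mm = np.asarray(self.x_mm, dtype=float)
        self.y_mm = np.asarray(self.y_mm, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.dose.shape != (self.y_mm.size, self.x_mm.size):
            raise ValueError("dose grid shape must match coordinate axes")
        if self.valid_mask.shape != self.dose.shape:
            raise ValueError("valid_mask shape must match dose grid")
        if np.any(np.diff(self.x_mm) <= 0) or np.any(np.diff(self.y_mm) <= 0):
            raise ValueError("coordinate axes must be strictly increasing")
        if np.any(self.dose[self.valid_mask] < 0):
            raise ValueError("doses must be >= 0 on valid pixels")

    def sample(self, x_mm: float, y_mm: float) -> float:
        """Bilinear interpolation at a film-plane point.

        All four bracketing pixels must be valid; sampling in an excluded
        region raises :class:`MaskedRegionError`.
        """
        x, y = float(x_mm), float(y_mm)
        xs, ys = self.x_mm, self.y_mm
        if not (xs[0] <= x <= xs[-1] and ys[0] <= y <= ys[-1]):
            raise MaskedRegionError(
                f"point ({x:.2f}, {y:.2f}) mm outside the dose grid"
            )
        j = min(int(np.searchsorted(xs, x, side="right")) - 1, xs.size - 2)
        i = min(int(np.searchsorted(ys, y, side="right")) - 1, ys.size - 2)
        j = max(j, 0)
        i = max(i, 0)
        if not self.valid_mask[i : i + 2, j : j + 2].all():
            raise MaskedRegionError(
                f"point ({x:.2f}, {y:.2f}) mm touches an excluded region"
            )
        tx = (x - xs[j]) / (xs[j + 1] - xs[j])
        ty = (y - ys[i]) / (ys[i + 1] - ys[i])
        d = self.dose
        return float(
            d[i, j] * (1 - tx) * (1 - ty)
            + d[i, j + 1] * tx * (1 - ty)
            + d[i + 1, j] * (1 - tx) * ty
            + d[i + 1, j + 1] * tx * ty
        )


def dose_map_from_films(
    irradiated: FilmImage,
    background: FilmImage,
    curve: CalibrationCurve,
    channel: str | None = None,
    geometry=None,
    background_mode: str = "pixelwise",
    bg_roi_center_mm=None,
    bg_roi_side_mm: float = 5.0,
    exclusion_border_mm: float = 4.0,
) -> DoseMap:
    """Run the film-analysis chain on a scan pair and return a dose map.

    Steps, in order: invert both scans; 3x3-smooth both; subtract the
    background from the irradiated raster (clamped at 0); convert net
    pixel values to dose with the calibration curve.  Pixels that
    saturate the curve or fall outside its supported dose range, plus the
    4 mm border/cut exclusion zone, are flagged invalid.

    ``background_mode='pixelwise'`` subtracts the smoothed background scan
    pixel by pixel, which cancels the scanner's lateral-response field
    common to the two scans; ``'scalar'`` instead subtracts one ROI mean
    (``bg_roi_side_mm`` square at ``bg_roi_center_mm``, the film centre by
    default) from every pixel, matching the single-background-value
    bookkeeping used for calibration points.
    """
    channel = channel or curve.channel
    geometry = geometry if geometry is not None else irradiated.meta.get("geometry")
    log.info("dose map: invert")
    irr_inv = invert(irradiated)
    bg_inv = invert(background)
    log.info("dose map: 3x3 smooth (background)")
    bg_sm = smooth_3x3(bg_inv)
    log.info("dose map: 3x3 smooth (irradiated)")
    irr_sm = smooth_3x3(irr_inv)
    if background_mode == "pixelwise":
        log.info("dose map: pixel-wise background subtraction")
        net = irr_sm.channel(channel) - bg_sm.channel(channel)
    elif background_mode == "scalar":
        if bg_roi_center_mm is None:
            cx, cy = irradiated.width_mm / 2.0, irradiated.height_mm / 2.0
            if isinstance(geometry, AzimuthalFilmGeometry):
                # keep the 5 mm square clear of the punched hole
                cx = cx + geometry.hole_radius_mm + exclusion_border_mm + 6.0
            bg_roi_center_mm = (cx, cy)
        bg_scalar = roi_mean(
            bg_sm, channel, bg_roi_center_mm, shape="square",
            size_mm=bg_roi_side_mm,
        )
        log.info("dose map: background ROI mean = %.1f PV", bg_scalar)
        net = irr_sm.channel(channel) - bg_scalar
    else:
        raise ValueError("background_mode must be 'pixelwise' or 'scalar'")
    n_neg = int(np.count_nonzero(net < 0))
    if n_neg:
        log.debug("clamping %d negative net pixel(s) at 0", n_neg)
    net = np.maximum(net, 0.0)
    log.info("dose map: applying %s-channel calibration curve", channel)
    dose, curve_ok = curve.dose_map(net)
    valid = curve_ok & irradiated.valid_mask & background.valid_mask
    hole_kw = {}
    if isinstance(geometry, AzimuthalFilmGeometry):
        hole_kw = {
            "hole_center_mm": geometry.center_mm,
            "hole_radius_mm": geometry.hole_radius_mm,
        }
    valid &= exclusion_mask(irradiated, exclusion_border_mm, **hole_kw)
    dose = np.where(valid, dose, 0.0)
    return DoseMap(
        dose=dose,
        x_mm=irradiated.x_mm,
        y_mm=irradiated.y_mm,
        geometry=geometry,
        valid_mask=valid,
        channel=channel,
        meta=dict(irradiated.meta),
    )


def sample_dose(
    dmap: DoseMap, r_cm: float, theta_deg: float, side: int = +1
) -> float:
    """Dose at (r, theta) for a polar-geometry dose map (bilinear)."""
    if not isinstance(dmap.geometry, PolarFilmGeometry):
        raise TypeError("sample_dose requires a polar-geometry dose map")
    x, y = polar_to_film(dmap.geometry, r_cm, theta_deg, side=side)
    return dmap.sample(float(x), float(y))


def sample_azimuthal(
    dmap: DoseMap,
    radius_cm: float,
    phi_deg: float,
    arc_halfwidth_deg: float = 2.0,
    n_arc: int = 5,
) -> float:
    """Dose at (radius, phi) on an azimuthal film.

    The reading is the mean over a small arc (+-``arc_halfwidth_deg``)
    to reduce pixel noise; ``n_arc = 1`` samples the single point.
    """
    if not isinstance(dmap.geometry, AzimuthalFilmGeometry):
        raise TypeError("sample_azimuthal requires an azimuthal-geometry dose map")
    cx, cy = dmap.geometry.center_mm
    if n_arc < 1:
        raise ValueError("n_arc must be >= 1")
    offsets = (
        np.linspace(-arc_halfwidth_deg, arc_halfwidth_deg, n_arc)
        if n_arc > 1
        else np.array([0.0])
    )
    vals = []
    for dphi in offsets:
        ang = np.radians(phi_deg + dphi)
        x = cx + 10.0 * radius_cm * np.cos(ang)
        y = cy + 10.0 * radius_cm * np.sin(ang)
        vals.append(dmap.sample(x, y))
    return float(np.mean(vals))
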