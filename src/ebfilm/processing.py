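"""Scan QA and pixel-processing steps of the film analysis chain.

The chain applied to every scan mirrors standard radiochromic-film
practice with a flatbed transmission scanner: invert the 16-bit pixel
values (transmission scans darken with dose, so inversion makes signal
grow with dose), apply a 3 x 3 mean smoothing filter, reduce the paired
background scan to a scalar ROI mean in the area of interest, and subtract
it from the irradiated reading.  A 4 mm margin from every film edge or cut
(de-lamination region) is excluded from analysis throughout.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
from scipy.ndimage import uniform_filter

from .image import MAX_PV, FilmImage, channel_index

__all__ = [
    "invert",
    "smooth_3x3",
    "subtract_background",
    "locate_center",
    "roi_mean",
    "exclusion_mask",
    "uniformity_stats",
    "CenterDetectionError",
]

log = logging.getLogger(__name__)


class CenterDetectionError(RuntimeError):
    """Profile maxima too flat/ambiguous to define an exposure centre."""


def invert(img: FilmImage) -> FilmImage:
    """Invert pixel values (v -> 65535 - v), per channel; involution."""
    pixels = np.asarray(img.pixels)
    if pixels.dtype == np.uint16:
        out = (np.uint16(65535) - pixels).astype(np.uint16)
    else:
        out = MAX_PV - np.asarray(pixels, dtype=float)
    log.debug("invert: role=%s", img.role)
    return img.with_pixels(out)


def smooth_3x3(img: FilmImage) -> FilmImage:
    """3 x 3 average filter with mirror padding at the edges.

    Invalid pixels are excluded from every neighbourhood and the mean is
    renormalized over the valid members; fully invalid neighbourhoods keep
    the original value (and remain masked).  Output is float.
    """
    rows, cols = img.shape
    if rows < 3 or cols < 3:
        raise ValueError(f"image must be at least 3x3, got {rows}x{cols}")
    mask = img.valid_mask.astype(float)
    den = uniform_filter(mask, size=3, mode="mirror")
    out = np.empty(img.pixels.shape, dtype=float)
    for c in range(3):
        v = np.asarray(img.pixels[..., c], dtype=float)
        num = uniform_filter(v * mask, size=3, mode="mirror")
        with np.errstate(invalid="ignore", divide="ignore"):
            sm = np.where(den > 0, num / np.where(den > 0, den, 1.0), v)
        out[..., c] = sm
    log.debug("smooth_3x3: role=%s", img.role)
    return img.with_pixels(out)


def subtract_background(irradiated_pv, background_pv):
    """Net (inverted) pixel value: max(0, irradiated - background).

    Negative net exposure is unphysical; values are clamped at zero and a
    warning is emitted when clamping occurs.
    """
    irr = np.asarray(irradiated_pv, dtype=float)
    bg = np.asarray(background_pv, dtype=float)
    net = irr - bg
    if np.any(net < 0):
        warnings.warn(
            "background exceeds irradiated reading for "
            f"{int(np.count_nonzero(net < 0))} value(s); clamping net PV at 0",
            stacklevel=2,
        )
        net = np.maximum(net, 0.0)
    if np.isscalar(irradiated_pv) and np.isscalar(background_pv):
        return float(net)
    return net


#: Values within this fraction of the profile's dynamic range of the
#: maximum count as tied; the peak is the centroid of that plateau.  A
#: generous plateau makes the centroid of a symmetric exposure nearly
#: noise-free while exact ties still resolve to their midpoint.
PLATEAU_FRACTION = 0.25


def _profile_peak(profile: np.ndarray, coords: np.ndarray, what: str) -> float:
    finite = np.isfinite(profile)
    if not finite.any():
        raise CenterDetectionError(f"no valid pixels in {what} profile")
    vals = np.where(finite, profile, -np.inf)
    vmax = vals.max()
    vrange = vmax - profile[finite].min()
    tol = max(PLATEAU_FRACTION * vrange, 1e-9 * max(1.0, abs(vmax)))
    plateau = vals >= vmax - tol
    if plateau.sum() > 0.5 * finite.sum():
        raise CenterDetectionError(
            f"{what} profile is flat: maximum plateau spans "
            f"{int(plateau.sum())} of {int(finite.sum())} positions"
        )
    return float(coords[plateau].mean())


def _boxcar(profile: np.ndarray, width: int) -> np.ndarray:
    if width <= 1:
        return profile
    if width % 2 == 0:
        width += 1
    filled = np.where(np.isfinite(profile), profile, np.nan)
    # mirror-padded moving average, NaN-tolerant
    pad = width // 2
    padded = np.pad(filled, pad, mode="reflect")
    kernel = np.ones(width)
    num = np.convolve(np.nan_to_num(padded), kernel, mode="valid")
    den = np.convolve(np.isfinite(padded).astype(float), kernel, mode="valid")
    out = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    out[~np.isfinite(profile)] = np.nan
    return out


def locate_center(
    img: FilmImage, channel, profile_smooth_mm: float = 5.0
) -> tuple[float, float]:
    """Centre of the exposed region from the x/y profile maxima.

    Column- and row-collapsed profiles of the (inverted, smoothed) image
    are conditioned with a symmetric ``profile_smooth_mm`` moving average
    and scanned for their maxima; the centre is the intersection.  Tied
    plateaus resolve to the plateau centroid; a profile whose plateau
    covers more than half the extent raises :class:`CenterDetectionError`.
    Returns (x_mm, y_mm).
    """
    v = img.channel(channel)
    m = img.valid_mask
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        col_profile = np.where(
            m.any(axis=0), np.nansum(np.where(m, v, np.nan), axis=0) / m.sum(axis=0), np.nan
        )
        row_profile = np.where(
            m.any(axis=1), np.nansum(np.where(m, v, np.nan), axis=1) / m.sum(axis=1), np.nan
        )
    width = int(round(profile_smooth_mm / img.mm_per_pixel))
    x = _profile_peak(_boxcar(col_profile, width), img.x_mm, "x")
    y = _profile_peak(_boxcar(row_profile, width), img.y_mm, "y")
    log.debug("locate_center: (%.3f, %.3f) mm", x, y)
    return x, y


def _roi_selector(
    img: FilmImage, center_mm, shape: str, size_mm: float
) -> np.ndarray:
    cx, cy = float(center_mm[0]), float(center_mm[1])
    half = size_mm / 2.0
    if not (
        half <= cx <= img.width_mm - half and half <= cy <= img.height_mm - half
    ):
        raise ValueError(
            f"ROI ({shape}, {size_mm} mm) at ({cx:.2f}, {cy:.2f}) mm extends "
            "outside the film"
        )
    dx = img.x_mm[None, :] - cx
    dy = img.y_mm[:, None] - cy
    if shape == "circle":
        sel = dx**2 + dy**2 <= half**2
    elif shape == "square":
        sel = (np.abs(dx) <= half) & (np.abs(dy) <= half)
    else:
        raise ValueError(f"unknown ROI shape {shape!r}")
    if not sel.any():
        raise ValueError("ROI contains no pixel centres")
    return sel


def roi_mean(
    img: FilmImage,
    channel,
    center_mm,
    shape: str = "circle",
    size_mm: float = 2.0,
) -> float:
    """Mean pixel value over an ROI (circle diameter / square side in mm).

    A pixel belongs to the ROI when its centre falls inside the shape.  The
    ROI must lie entirely in the valid region: overlap with excluded pixels
    raises with the overlap size.
    """
    sel = _roi_selector(img, center_mm, shape, size_mm)
    bad = sel & ~img.valid_mask
    if bad.any():
        rows, cols = np.nonzero(bad)
        raise ValueError(
            f"ROI overlaps {int(bad.sum())} excluded pixel(s), e.g. row/col "
            f"({int(rows[0])}, {int(cols[0])})"
        )
    return float(img.channel(channel)[sel].mean())


def exclusion_mask(
    img: FilmImage,
    border_mm: float = 4.0,
    hole_center_mm=None,
    hole_radius_mm: float = 0.0,
) -> np.ndarray:
    """Validity raster excluding de-lamination margins.

    Pixels whose centres lie within ``border_mm`` of any film edge are
    invalid; when a punched hole is present, so is the disc of radius
    ``hole_radius_mm + border_mm`` around its centre (cut edges de-laminate
    just like film borders).  Returns True for usable pixels.
    """
    x = img.x_mm[None, :]
    y = img.y_mm[:, None]
    valid = (
        (x >= border_mm)
        & (x <= img.width_mm - border_mm)
        & (y >= border_mm)
        & (y <= img.height_mm - border_mm)
    )
    valid = np.broadcast_to(valid, img.shape).copy()
    if hole_center_mm is not None:
        hx, hy = float(hole_center_mm[0]), float(hole_center_mm[1])
        rr = (x - hx) ** 2 + (y - hy) ** 2
        valid &= rr > (hole_radius_mm + border_mm) ** 2
    if not valid.any():
        warnings.warn(
            f"film ({img.width_mm:.1f} x {img.height_mm:.1f} mm) smaller than "
            f"twice the {border_mm} mm exclusion border; nothing is analyzable",
            stacklevel=2,
        )
    return valid


def uniformity_stats(img: FilmImage, channel, axis: str = "landscape") -> float:
    """Relative standard deviation (%) of the axis-collapsed profile.

    'landscape' collapses rows, giving a profile across the width (the
    scanner's lateral direction); 'portrait' collapses columns.  Population
    SD over mean of the profile, over the valid mask, in percent.
    """
    v = img.channel(channel)
    m = img.valid_mask
    if axis == "landscape":
        counts = m.sum(axis=0)
        sums = np.where(m, v, 0.0).sum(axis=0)
    elif axis == "portrait":
        counts = m.sum(axis=1)
        sums = np.where(m, v, 0.0).sum(axis=1)
    else:
        raise ValueError(f"axis must be 'landscape' or 'portrait', got {axis!r}")
    keep = counts > 0
    if not keep.any():
        raise ValueError("no valid pixels to profile")
    profile = sums[keep] / counts[keep]
    mean = profile.mean()
    if mean == 0:
        raise ValueError("profile mean is zero; relative SD undefined")
    return float(100.0 * profile.std(ddof=0) / mean)
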