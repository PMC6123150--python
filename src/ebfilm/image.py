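"""Film-scan image container and TIFF I/O.

A film scan is a 3-channel (RGB) raster, nominally 16 bits per channel at
150 dpi in landscape orientation, as produced by a flatbed transmission
scanner.  Raw scans are unsigned 16-bit; processed images (inverted,
smoothed, background-subtracted) are carried as float rasters in the same
pixel-value units.  A boolean ``valid_mask`` travels with the pixels and
marks regions excluded from analysis (cut/border margins, the punched
hole of azimuthal films, saturated or out-of-model pixels).

Pixel (row, col) has its centre at ``((col + 0.5) * mm_per_pixel,
(row + 0.5) * mm_per_pixel)`` in film-plane mm coordinates, x along the
width (landscape axis) and y along the height.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["FilmImage", "CHANNELS", "channel_index", "write_film", "read_film"]

CHANNELS = {"red": 0, "green": 1, "blue": 2}

MAX_PV = 65535.0


def channel_index(channel) -> int:
    """Map a channel name (or index) to the raster index."""
    if isinstance(channel, str):
        try:
            return CHANNELS[channel.lower()]
        except KeyError:
            raise ValueError(f"unknown channel {channel!r}") from None
    idx = int(channel)
    if idx not in (0, 1, 2):
        raise ValueError(f"channel index must be 0, 1 or 2, got {idx}")
    return idx


@dataclass
class FilmImage:
    """One scanned (or synthesized) film.

    ``pixels`` has shape (rows, cols, 3); uint16 for raw scans, float for
    processed rasters.  ``role`` records provenance ('background' or
    'irradiated'); ``meta`` carries free-form provenance such as the
    synthetic ground truth sidecar.
    """

    pixels: np.ndarray
    dpi: float = 150.0
    orientation: str = "landscape"
    role: str = "irradiated"
    valid_mask: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must have shape (rows, cols, 3)")
        if self.dpi <= 0:
            raise ValueError("dpi must be > 0")
        if self.orientation not in ("landscape", "portrait"):
            raise ValueError(f"unknown orientation {self.orientation!r}")
        if self.role not in ("background", "irradiated"):
            raise ValueError(f"unknown role {self.role!r}")
        if self.valid_mask is None:
            self.valid_mask = np.ones(self.pixels.shape[:2], dtype=bool)
        else:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
            if self.valid_mask.shape != self.pixels.shape[:2]:
                raise ValueError("valid_mask shape must match pixels")

    # -- geometry helpers -----------------------------------------------
    @property
    def mm_per_pixel(self) -> float:
        return 25.4 / self.dpi

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    @property
    def width_mm(self) -> float:
        return self.pixels.shape[1] * self.mm_per_pixel

    @property
    def height_mm(self) -> float:
        return self.pixels.shape[0] * self.mm_per_pixel

    @property
    def x_mm(self) -> np.ndarray:
        """Pixel-centre x coordinates (mm), one per column."""
        return (np.arange(self.pixels.shape[1]) + 0.5) * self.mm_per_pixel

    @property
    def y_mm(self) -> np.ndarray:
        """Pixel-centre y coordinates (mm), one per row."""
        return (np.arange(self.pixels.shape[0]) + 0.5) * self.mm_per_pixel

    def channel(self, channel) -> np.ndarray:
        """One colour plane as float64."""
        return np.asarray(self.pixels[..., channel_index(channel)], dtype=float)

    def with_pixels(self, pixels: np.ndarray) -> "FilmImage":
        """Copy of this image with a new raster, same mask and metadata."""
        return replace(self, pixels=pixels, valid_mask=self.valid_mask.copy())

    def copy(self) -> "FilmImage":
        return replace(
            self, pixels=self.pixels.copy(), valid_mask=self.valid_mask.copy()
        )


def write_film(img: FilmImage, path) -> None:
    """Write a 48-bit RGB TIFF at the image's dpi plus a JSON sidecar.

    The sidecar preserves the role, orientation, validity mask extent and
    any synthetic ground-truth metadata.
    """
    path = Path(path)
    pixels = img.pixels
    if pixels.dtype != np.uint16:
        pixels = np.clip(np.rint(pixels), 0, MAX_PV).astype(np.uint16)
    tifffile.imwrite(
        path,
        pixels,
        photometric="rgb",
        resolution=(img.dpi, img.dpi),
        resolutionunit="INCH",
    )
    sidecar = {
        "dpi": img.dpi,
        "orientation": img.orientation,
        "role": img.role,
        "meta": img.meta,
        "invalid_pixels": np.argwhere(~img.valid_mask).tolist(),
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=1, default=float)
    )


def read_film(path) -> FilmImage:
    """Read a TIFF written by :func:`write_film` (sidecar optional)."""
    path = Path(path)
    pixels = tifffile.imread(path)
    dpi, orientation, role, meta = 150.0, "landscape", "irradiated", {}
    mask = None
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        dpi = float(sidecar.get("dpi", dpi))
        orientation = sidecar.get("orientation", orientation)
        role = sidecar.get("role", role)
        meta = sidecar.get("meta", {})
        invalid = sidecar.get("invalid_pixels", [])
        if invalid:
            mask = np.ones(pixels.shape[:2], dtype=bool)
            idx = np.asarray(invalid, dtype=int)
            mask[idx[:, 0], idx[:, 1]] = False
    return FilmImage(
        pixels=pixels,
        dpi=dpi,
        orientation=orientation,
        role=role,
        valid_mask=mask,
        meta=meta,
    )
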