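"""Seeded synthetic film-scan generator.

Every downstream stage of the analysis chain is exercised against scans
with a fully known ground truth: a TG-43 :class:`~ebfilm.source.SourceModel`
supplies the dose field, a per-channel saturating-exponential film
response converts dose to (inverted) pixel value, and a scanner model adds
a smooth lateral gain field, an optional offset and per-channel Gaussian
noise.  Raw scans come out *pre-inversion* (low pixel value = high dose,
as a transmission scanner darkens with dose), so the pipeline's inversion
step is exercised.

The scanner's lateral nonuniformity is a single-period cosine gain field
across a virtual scanner bed on which every film is centred (films are
scanned in the central region of a real flatbed).  Its amplitude is
parametrized by the flat-field QA statistic it should reproduce: the
relative SD of the landscape profile of a 5 x 4 in un-irradiated film,
~0.8% by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import (
    AzimuthalFilmGeometry,
    CalibrationFilmGeometry,
    FlatFieldGeometry,
    PolarFilmGeometry,
)
from .image import CHANNELS, MAX_PV, FilmImage
from .source import DEFAULT_RAMP_TIME_S, SourceModel, TableRangeError

__all__ = [
    "ChannelResponse",
    "CalibrationTruth",
    "ScannerModel",
    "forward_response",
    "generate_flat_field",
    "generate_calibration_film",
    "generate_polar_film",
    "generate_azimuthal_film_set",
]


@dataclass(frozen=True)
class ChannelResponse:
    """Forward film response of one colour channel on inverted pixel values:
    PV(D) = a * exp(-b * D) + c."""

    a: float
    b: float
    c: float

    def __post_init__(self) -> None:
        if self.b <= 0:
            raise ValueError("b must be > 0")
        if not 0.0 <= self.c <= MAX_PV:
            raise ValueError("c must lie in [0, 65535]")
        if not 0.0 <= self.a + self.c <= MAX_PV:
            raise ValueError("a + c must lie in [0, 65535]")

    def __call__(self, dose_cgy):
        d = np.asarray(dose_cgy, dtype=float)
        return np.clip(self.a * np.exp(-self.b * d) + self.c, 0.0, MAX_PV)


@dataclass(frozen=True)
class CalibrationTruth:
    """Ground-truth film response, one saturating exponential per channel.

    ``a < 0`` throughout: the inverted pixel value grows with dose from
    ``a + c`` at zero dose toward the asymptote ``c``.  The per-channel
    rate constants mirror the film's sensitivity ordering (red fastest,
    blue slowest).
    """

    red: ChannelResponse = ChannelResponse(-30000.0, 0.0030, 42000.0)
    green: ChannelResponse = ChannelResponse(-32000.0, 0.0006, 40000.0)
    blue: ChannelResponse = ChannelResponse(-25000.0, 0.00025, 43000.0)

    def response(self, channel) -> ChannelResponse:
        if isinstance(channel, int):
            channel = ("red", "green", "blue")[channel]
        return getattr(self, channel)

    def net_curve_params(self, channel) -> tuple[float, float, float]:
        """(a, b, c) of the expected *net* (background-subtracted) curve:
        net(D) = a e^{-bD} + c with c = -a, so net(0) = 0."""
        r = self.response(channel)
        return (r.a, r.b, -r.a)


def _gain_amplitude(target_rel_sd: float, film_mm: float, bed_mm: float,
                    border_mm: float = 4.0) -> float:
    """Cosine-field coefficient k such that the profile of a centred film
    (minus the 4 mm analysis border) has the target relative SD."""
    half_ratio = (film_mm - 2.0 * border_mm) / bed_mm
    u = np.linspace(-half_ratio, half_ratio, 4001)
    s = np.cos(np.pi * u)
    sd, mean = float(s.std(ddof=0)), float(s.mean())
    # rel SD of (1 + k s) is k sd / (1 + k mean); solve for k
    return target_rel_sd / (sd - target_rel_sd * mean)


@dataclass
class ScannerModel:
    """Flatbed transmission-scanner imperfections.

    ``noise_sd`` is additive Gaussian noise per channel in raw pixel-value
    units.  ``flat_field_rel_sd`` is the target relative SD of the lateral
    (landscape) profile of the reference un-irradiated film, which fixes
    the amplitude of the cosine gain field across the scanner bed;
    ``along_scan_rel_sd`` does the same for the along-scan direction.
    """

    noise_sd: tuple[float, float, float] = (100.0, 100.0, 100.0)
    flat_field_rel_sd: float = 0.0077
    along_scan_rel_sd: float = 0.002
    background_offset_pv: float = 0.0
    bed_mm: tuple[float, float] = (216.0, 297.0)
    reference_film_mm: tuple[float, float] = (127.0, 101.6)
    _kx: float = field(init=False, repr=False)
    _ky: float = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if any(s < 0 for s in self.noise_sd):
            raise ValueError("noise SDs must be >= 0")
        if self.flat_field_rel_sd < 0 or self.along_scan_rel_sd < 0:
            raise ValueError("nonuniformity amplitudes must be >= 0")
        self._kx = (
            _gain_amplitude(
                self.flat_field_rel_sd, self.reference_film_mm[0], self.bed_mm[0]
            )
            if self.flat_field_rel_sd > 0
            else 0.0
        )
        self._ky = (
            _gain_amplitude(
                self.along_scan_rel_sd, self.reference_film_mm[1], self.bed_mm[1]
            )
            if self.along_scan_rel_sd > 0
            else 0.0
        )

    @classmethod
    def noiseless(cls) -> "ScannerModel":
        """Ideal scanner: no noise, no lateral gain, no offset."""
        return cls(
            noise_sd=(0.0, 0.0, 0.0),
            flat_field_rel_sd=0.0,
            along_scan_rel_sd=0.0,
            background_offset_pv=0.0,
        )

    def gain_field(self, shape: tuple[int, int], mm_per_pixel: float) -> np.ndarray:
        """Multiplicative lateral-response field for an image centred on
        the scanner bed."""
        rows, cols = shape
        x = (np.arange(cols) + 0.5) * mm_per_pixel
        y = (np.arange(rows) + 0.5) * mm_per_pixel
        ux = (x - x.mean()) / (self.bed_mm[0] / 2.0)
        uy = (y - y.mean()) / (self.bed_mm[1] / 2.0)
        gain = (
            1.0
            + self._kx * np.cos(np.pi * ux)[None, :]
            + self._ky * np.cos(np.pi * uy)[:, None]
        )
        return gain

    def apply(
        self, raw: np.ndarray, rng: np.random.Generator, mm_per_pixel: float
    ) -> np.ndarray:
        """Gain field, offset and noise on a clean raw raster; returns uint16."""
        out = raw * self.gain_field(raw.shape[:2], mm_per_pixel)[..., None]
        out = out + self.background_offset_pv
        for c, sd in enumerate(self.noise_sd):
            if sd > 0:
                out[..., c] += rng.normal(0.0, sd, size=raw.shape[:2])
        return np.clip(np.rint(out), 0, MAX_PV).astype(np.uint16)


def forward_response(truth: CalibrationTruth, dose_cgy, channel):
    """Inverted pixel value for a dose, clipped to the 16-bit range."""
    d = np.asarray(dose_cgy, dtype=float)
    if np.any(d < 0):
        raise ValueError("dose must be >= 0")
    out = truth.response(channel)(d)
    return float(out) if np.isscalar(dose_cgy) else out


def _raw_from_dose(truth: CalibrationTruth, dose: np.ndarray) -> np.ndarray:
    """Clean raw (pre-inversion) RGB raster from a dose raster."""
    raw = np.empty(dose.shape + (3,), dtype=float)
    for name, c in CHANNELS.items():
        raw[..., c] = MAX_PV - truth.response(name)(dose)
    return raw


def _finish(
    raw: np.ndarray,
    scanner: ScannerModel,
    rng: np.random.Generator,
    dpi: float,
    role: str,
    valid_mask=None,
    meta=None,
) -> FilmImage:
    pixels = scanner.apply(raw, rng, 25.4 / dpi)
    return FilmImage(
        pixels=pixels,
        dpi=dpi,
        role=role,
        valid_mask=valid_mask,
        meta=meta or {},
    )


def generate_flat_field(
    truth: CalibrationTruth | None = None,
    scanner: ScannerModel | None = None,
    geometry: FlatFieldGeometry | None = None,
    seed: int = 0,
) -> FilmImage:
    """Un-irradiated film scan for scanner QA (uniformity statistics)."""
    truth = truth or CalibrationTruth()
    scanner = scanner if scanner is not None else ScannerModel()
    geometry = geometry or FlatFieldGeometry()
    rng = np.random.default_rng(seed)
    rows = int(round(geometry.height_mm / 25.4 * geometry.dpi))
    cols = int(round(geometry.width_mm / 25.4 * geometry.dpi))
    dose = np.zeros((rows, cols))
    raw = _raw_from_dose(truth, dose)
    meta = {"kind": "flat-field", "seed": seed, "dose_cgy": 0.0}
    return _finish(raw, scanner, rng, geometry.dpi, "background", meta=meta)


def _grid_mm(geometry) -> tuple[np.ndarray, np.ndarray, int, int]:
    mmpp = 25.4 / geometry.dpi
    rows = int(round(geometry.height_mm / mmpp))
    cols = int(round(geometry.width_mm / mmpp))
    x = (np.arange(cols) + 0.5) * mmpp
    y = (np.arange(rows) + 0.5) * mmpp
    return x, y, rows, cols


def _truth_meta(truth: CalibrationTruth) -> dict:
    return {
        ch: vars(truth.response(ch)) for ch in ("red", "green", "blue")
    }


def generate_calibration_film(
    truth: CalibrationTruth,
    dose_cgy: float,
    geometry: CalibrationFilmGeometry | None = None,
    scanner: ScannerModel | None = None,
    seed: int = 0,
    model: SourceModel | None = None,
) -> tuple[FilmImage, FilmImage]:
    """Calibration exposure plus its paired background scan.

    The lateral dose profile is the point-source falloff seen by a film
    orthogonal to the axis just beyond the dome tip, scaled so the film
    centre receives exactly ``dose_cgy``; the paired background is an
    un-irradiated scan from the same scanner.  Deterministic per seed.
    """
    if dose_cgy < 0:
        raise ValueError("dose_cgy must be >= 0")
    geometry = geometry or CalibrationFilmGeometry()
    scanner = scanner if scanner is not None else ScannerModel()
    if model is None:
        from .source import example_source_model

        model = example_source_model(0.0)
    rng = np.random.default_rng(seed)
    x, y, rows, cols = _grid_mm(geometry)
    cx, cy = geometry.center_mm
    z = geometry.axial_offset_mm
    rho = np.hypot(x[None, :] - cx, y[:, None] - cy)
    d_mm = np.hypot(rho, z)
    r_cm = d_mm / 10.0
    theta = np.degrees(np.arccos(np.clip(-z / d_mm, -1.0, 1.0)))
    rate = model.dose_rate(r_cm, theta)
    center_rate = model.dose_rate(z / 10.0, 180.0)
    dose = dose_cgy * rate / center_rate
    meta = {
        "kind": "calibration",
        "dose_cgy": dose_cgy,
        "seed": seed,
        "axial_offset_mm": geometry.axial_offset_mm,
        "truth": _truth_meta(truth),
    }
    irr = _finish(
        _raw_from_dose(truth, dose), scanner, rng, geometry.dpi, "irradiated",
        meta=meta,
    )
    bg = _finish(
        _raw_from_dose(truth, np.zeros_like(dose)), scanner, rng, geometry.dpi,
        "background", meta={**meta, "dose_cgy": 0.0},
    )
    return irr, bg


def generate_polar_film(
    model: SourceModel,
    truth: CalibrationTruth,
    geometry: PolarFilmGeometry | None = None,
    beam_on_time_s: float = 0.0,
    scanner: ScannerModel | None = None,
    seed: int = 0,
    ramp_time_s: float = DEFAULT_RAMP_TIME_S,
    on_out_of_range: str = "mask",
) -> tuple[FilmImage, FilmImage]:
    """Film parallel to the tandem, dwell position marked on-plane.

    Each pixel receives the delivered dose at its (r, theta) relative to
    the dwell position.  Pixels closer to the source than the radial
    table's minimum are flagged invalid (a film abutting the source always
    contains them); pixels beyond the table maximum raise a range error
    naming the pixel, or are masked when ``on_out_of_range='mask'``.
    """
    geometry = geometry or PolarFilmGeometry()
    scanner = scanner if scanner is not None else ScannerModel()
    rng = np.random.default_rng(seed)
    x, y, rows, cols = _grid_mm(geometry)
    dx = x[None, :] - geometry.source_x_mm
    dy = y[:, None] - geometry.source_y_mm
    d_mm = np.hypot(dx, dy)
    r_cm = d_mm / 10.0
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.degrees(
            np.arccos(np.clip(np.where(d_mm > 0, -dx / np.where(d_mm > 0, d_mm, 1.0), 0.0), -1, 1))
        )
    r_lo = max(model.radial_r_cm[0], model.anisotropy_r_cm[0])
    r_hi = min(model.radial_r_cm[-1], model.anisotropy_r_cm[-1])
    too_far = r_cm > r_hi
    if too_far.any():
        if on_out_of_range == "raise":
            row, col = map(int, np.argwhere(too_far)[0])
            raise TableRangeError(
                f"pixel (row {row}, col {col}) at r = {r_cm[row, col]:.2f} cm "
                f"exceeds the table range ({r_hi:g} cm)"
            )
        if on_out_of_range != "mask":
            raise ValueError("on_out_of_range must be 'mask' or 'raise'")
    in_range = (r_cm >= r_lo) & ~too_far
    dose = np.zeros((rows, cols))
    if in_range.any():
        dose[in_range] = model.delivered_dose(
            r_cm[in_range], theta[in_range],
            beam_on_time_s=beam_on_time_s, ramp_time_s=ramp_time_s,
        )
    meta = {
        "kind": "polar",
        "seed": seed,
        "beam_on_time_s": beam_on_time_s,
        "ramp_time_s": ramp_time_s,
        "source_x_mm": geometry.source_x_mm,
        "source_y_mm": geometry.source_y_mm,
        "dwell_offset_mm": model.dwell_offset_mm,
        "truth": _truth_meta(truth),
    }
    irr = _finish(
        _raw_from_dose(truth, dose), scanner, rng, geometry.dpi, "irradiated",
        valid_mask=in_range.copy(), meta=meta,
    )
    bg = _finish(
        _raw_from_dose(truth, np.zeros_like(dose)), scanner, rng, geometry.dpi,
        "background", valid_mask=np.ones_like(in_range), meta={**meta, "kind": "polar-background"},
    )
    return irr, bg


def generate_azimuthal_film_set(
    model: SourceModel,
    truth: CalibrationTruth,
    scanner: ScannerModel | None = None,
    seed: int = 0,
    depths_cm=(1.0, 2.0, 3.0, 4.0),
    width_mm: float = 70.0,
    height_mm: float = 70.0,
    hole_radius_mm: float = 2.5,
    dpi: float = 150.0,
    beam_on_time_s: float | None = None,
    ramp_time_s: float = DEFAULT_RAMP_TIME_S,
    modulation_amplitude: float = 0.0,
    modulation_phase_deg: float = 0.0,
    exclusion_border_mm: float = 4.0,
) -> list[tuple[FilmImage, FilmImage]]:
    """Four films orthogonal to the source axis at 1 cm spacing.

    ``depths_cm`` are the axial offsets of the film planes on the proximal
    side of the dwell position and must be four values spaced exactly by
    1 cm.  The punched hole (plus a 4 mm de-lamination annulus) is flagged
    invalid; hole pixels scan at full transmission.  An optional azimuthal
    modulation ``1 + A cos(phi - phase)`` can be injected for recovery
    tests.  When ``beam_on_time_s`` is omitted, the timer is set so the
    nearest film receives 1000 cGy at 1 cm from the axis, which keeps
    every sampled radius inside the calibrated dose range.
    """
    depths = np.asarray(depths_cm, dtype=float)
    if depths.size != 4:
        raise ValueError("the azimuthal array uses exactly 4 films")
    if np.any(depths <= 0):
        raise ValueError("film planes must sit off the source plane (depth > 0)")
    sep = 1.0
    if not np.allclose(np.diff(np.sort(depths)), sep, atol=1e-9):
        raise ValueError("films must be separated by exactly 1 cm")
    scanner = scanner if scanner is not None else ScannerModel()
    rng = np.random.default_rng(seed)
    if beam_on_time_s is None:
        z0 = float(depths.min())
        r0 = float(np.hypot(1.0, z0))
        theta0 = float(np.degrees(np.arccos(z0 / r0)))
        beam_on_time_s = model.beam_time_for_dose(
            1000.0, r0, theta0, ramp_time_s=ramp_time_s
        )
    out = []
    for idx, z_cm in enumerate(depths, start=1):
        geometry = AzimuthalFilmGeometry(
            width_mm=width_mm,
            height_mm=height_mm,
            axial_offset_cm=float(z_cm),
            hole_radius_mm=hole_radius_mm,
            film_index=idx,
            dpi=dpi,
        )
        x, y, rows, cols = _grid_mm(geometry)
        cx, cy = geometry.center_mm
        ex = x[None, :] - cx
        ey = y[:, None] - cy
        rho_mm = np.hypot(ex, ey)
        z_mm = z_cm * 10.0
        d_mm = np.hypot(rho_mm, z_mm)
        r_cm_grid = d_mm / 10.0
        theta = np.degrees(np.arccos(np.clip(z_mm / d_mm, -1.0, 1.0)))
        r_lo = max(model.radial_r_cm[0], model.anisotropy_r_cm[0])
        r_hi = min(model.radial_r_cm[-1], model.anisotropy_r_cm[-1])
        in_range = (r_cm_grid >= r_lo) & (r_cm_grid <= r_hi)
        dose = np.zeros((rows, cols))
        dose[in_range] = model.delivered_dose(
            r_cm_grid[in_range], theta[in_range],
            beam_on_time_s=beam_on_time_s, ramp_time_s=ramp_time_s,
        )
        if modulation_amplitude != 0.0:
            phi = np.degrees(np.arctan2(ey, ex))
            dose *= 1.0 + modulation_amplitude * np.cos(
                np.radians(phi - modulation_phase_deg)
            )
        raw = _raw_from_dose(truth, dose)
        hole = rho_mm <= hole_radius_mm
        raw[hole] = MAX_PV  # no film in the hole: full transmission
        annulus = rho_mm <= hole_radius_mm + exclusion_border_mm
        valid = in_range & ~annulus
        meta = {
            "kind": "azimuthal",
            "seed": seed,
            "film_index": idx,
            "axial_offset_cm": float(z_cm),
            "hole_radius_mm": hole_radius_mm,
            "beam_on_time_s": float(beam_on_time_s),
            "modulation_amplitude": modulation_amplitude,
            "modulation_phase_deg": modulation_phase_deg,
            "dwell_offset_mm": model.dwell_offset_mm,
            "truth": _truth_meta(truth),
        }
        irr = _finish(
            raw, scanner, rng, dpi, "irradiated", valid_mask=valid, meta=meta
        )
        bg_raw = _raw_from_dose(truth, np.zeros_like(dose))
        bg_raw[hole] = MAX_PV
        bg = _finish(
            bg_raw, scanner, rng, dpi, "background",
            valid_mask=valid.copy(), meta={**meta, "kind": "azimuthal-background"},
        )
        out.append((irr, bg))
    return out
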