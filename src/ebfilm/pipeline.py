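"""Study orchestration: calibration, polar and azimuthal analyses.

Each study generates (or loads) the film scans it needs, runs the full
analysis chain, and writes its outputs plus a reproducibility manifest
(seed, configuration hash, package version) to the output directory.
Every random draw descends from the single study seed, so a repeated run
is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .anisotropy import (
    azimuthal_anisotropy,
    azimuthal_stats,
    compare_to_model,
    polar_anisotropy,
)
from .calibration import CalibrationCurve, ExponentialOffsetModel, select_channel
from .dosemap import dose_map_from_films
from .geometry import AzimuthalFilmGeometry, CalibrationFilmGeometry, PolarFilmGeometry
from .image import CHANNELS
from .processing import invert, locate_center, roi_mean, smooth_3x3
from .source import SourceModel, example_source_model
from .synthetic import (
    CalibrationTruth,
    ScannerModel,
    generate_azimuthal_film_set,
    generate_calibration_film,
    generate_polar_film,
)

__all__ = [
    "DEFAULT_CALIBRATION_DOSES",
    "CalibrationStudyResult",
    "run_calibration_study",
    "PolarStudyResult",
    "run_polar_study",
    "AzimuthalStudyResult",
    "run_azimuthal_study",
]

log = logging.getLogger(__name__)

#: Calibration dose levels (cGy), spanning 3.7 up to 1198.1 cGy.
DEFAULT_CALIBRATION_DOSES = (
    3.7, 10.0, 25.0, 50.0, 100.0, 175.0, 290.0, 450.0,
    600.0, 800.0, 1000.0, 1198.1,
)


def _write_manifest(out_dir: Path, study: str, seed: int, config: dict) -> Path:
    payload = json.dumps(config, sort_keys=True, default=str)
    manifest = {
        "study": study,
        "seed": seed,
        "config_sha256": hashlib.sha256(payload.encode()).hexdigest(),
        "config": json.loads(payload),
        "ebfilm_version": __version__,
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return path


def _child_seeds(seed: int, n: int) -> list[int]:
    """Deterministic per-stage seeds below 2**31 derived from the study seed."""
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


# ---------------------------------------------------------------------------
# Calibration study
# ---------------------------------------------------------------------------


@dataclass
class CalibrationStudyResult:
    curves: dict[str, CalibrationCurve]
    points: pd.DataFrame  # dose_cGy, net_pv_red, net_pv_green, net_pv_blue
    report: pd.DataFrame  # per-channel R^2 and residual summary
    out_dir: Path | None = None


def run_calibration_study(
    seed: int,
    out_dir=None,
    doses_cgy=DEFAULT_CALIBRATION_DOSES,
    truth: CalibrationTruth | None = None,
    scanner: ScannerModel | None = None,
    model: SourceModel | None = None,
    geometry: CalibrationFilmGeometry | None = None,
    write_tiffs: bool = False,
) -> CalibrationStudyResult:
    """Generate calibration exposures and fit per-channel curves.

    For each dose level the irradiated/background pair is generated, the
    chain (invert, smooth, centre-finding on the exposure profile, 2 mm
    circular ROI, 5 mm-square background ROI, subtraction) produces one
    net pixel value per channel, a zero-dose point is appended, and the
    exponential-with-offset model is fitted per channel.
    """
    truth = truth or CalibrationTruth()
    scanner = scanner if scanner is not None else ScannerModel()
    model = model or example_source_model(0.0)
    geometry = geometry or CalibrationFilmGeometry()
    doses = [float(d) for d in doses_cgy]
    if any(d < 0 for d in doses):
        raise ValueError("calibration doses must be >= 0")
    seeds = _child_seeds(seed, len(doses))

    rows = []
    for dose, film_seed in zip(doses, seeds):
        irr, bg = generate_calibration_film(
            truth, dose, geometry=geometry, scanner=scanner, seed=film_seed,
            model=model,
        )
        if write_tiffs and out_dir is not None:
            from .image import write_film

            films_dir = Path(out_dir) / "films"
            films_dir.mkdir(parents=True, exist_ok=True)
            write_film(irr, films_dir / f"cal_{dose:07.1f}cGy.tif")
            write_film(bg, films_dir / f"cal_{dose:07.1f}cGy_bg.tif")
        irr_sm = smooth_3x3(invert(irr))
        bg_sm = smooth_3x3(invert(bg))
        # centre-finding on the background-corrected raster: the faintest
        # exposures would otherwise be swamped by the scanner's lateral tilt
        net_img = irr_sm.with_pixels(
            np.maximum(irr_sm.pixels - bg_sm.pixels, 0.0)
        )
        center = locate_center(net_img, select_channel(dose))
        log.info("calibration %.1f cGy: centre (%.2f, %.2f) mm", dose, *center)
        row = {"dose_cGy": dose}
        for channel in CHANNELS:
            irr_pv = roi_mean(irr_sm, channel, center, shape="circle", size_mm=2.0)
            bg_pv = roi_mean(bg_sm, channel, center, shape="square", size_mm=5.0)
            row[f"net_pv_{channel}"] = max(0.0, irr_pv - bg_pv)
        rows.append(row)
    points = pd.DataFrame(rows)
    zero = {"dose_cGy": 0.0, **{f"net_pv_{c}": 0.0 for c in CHANNELS}}
    points = pd.concat([pd.DataFrame([zero]), points], ignore_index=True)

    curves: dict[str, CalibrationCurve] = {}
    report_rows = []
    for channel in CHANNELS:
        fit = ExponentialOffsetModel(
            points["dose_cGy"].to_numpy(),
            points[f"net_pv_{channel}"].to_numpy(),
            channel=channel,
        ).fit()
        curves[channel] = fit
        report_rows.append(
            {
                "channel": channel,
                "a": fit.a,
                "b": fit.b,
                "c": fit.c,
                "r_squared": fit.r_squared,
                "max_abs_residual": float(np.abs(fit.residuals).max()),
                "rms_residual": float(np.sqrt((fit.residuals**2).mean())),
            }
        )
    report = pd.DataFrame(report_rows)

    result = CalibrationStudyResult(curves=curves, points=points, report=report)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        points.to_csv(out_dir / "calibration_points.csv", index=False)
        report.to_csv(out_dir / "calibration_report.csv", index=False)
        for channel, curve in curves.items():
            curve.to_json(out_dir / f"calibration_{channel}.json")
        _write_manifest(
            out_dir, "calibration", seed,
            {"doses_cgy": doses, "geometry": vars(geometry)},
        )
        result.out_dir = out_dir
    return result


# ---------------------------------------------------------------------------
# Polar anisotropy study
# ---------------------------------------------------------------------------


@dataclass
class PolarStudyResult:
    curves_frame: pd.DataFrame  # r_cm, theta_deg, F_measured, F_model, ...
    summary: pd.DataFrame  # per (distance, channel): mean/max percent error
    channel_by_radius: dict[float, list[str]]
    out_dir: Path | None = None


def run_polar_study(
    seed: int,
    calibration: dict[str, CalibrationCurve],
    out_dir=None,
    model: SourceModel | None = None,
    truth: CalibrationTruth | None = None,
    scanner: ScannerModel | None = None,
    geometry: PolarFilmGeometry | None = None,
    dose_at_1cm_cgy: float = 1150.0,
    radii_cm=(1.0, 2.0, 3.0),
    thetas_deg=tuple(np.arange(0.0, 181.0, 10.0)),
    channels: str | list = "auto",
) -> PolarStudyResult:
    """Polar-film study: dose maps -> F(r, theta) -> model comparison.

    ``channels='auto'`` picks the most sensitive channel per radius from
    the expected transverse dose; an explicit channel list analyses every
    radius with each channel (deliberate wrong-channel analyses are
    allowed — a warning is logged when the channel does not match the
    expected dose range).
    """
    model = model or example_source_model(0.0)
    truth = truth or CalibrationTruth()
    scanner = scanner if scanner is not None else ScannerModel()
    geometry = geometry or PolarFilmGeometry()
    beam_time = model.beam_time_for_dose(dose_at_1cm_cgy, 1.0, 90.0)
    irr, bg = generate_polar_film(
        model, truth, geometry=geometry, beam_on_time_s=beam_time,
        scanner=scanner, seed=_child_seeds(seed, 1)[0],
    )

    radii = [float(r) for r in radii_cm]
    thetas = np.asarray(thetas_deg, dtype=float)
    per_radius_channels: dict[float, list[str]] = {}
    for r in radii:
        expected = model.delivered_dose(r, 90.0, beam_on_time_s=beam_time)
        if channels == "auto":
            per_radius_channels[r] = [select_channel(expected)]
        else:
            chans = [channels] if isinstance(channels, str) else list(channels)
            per_radius_channels[r] = chans
            for ch in chans:
                if ch != select_channel(expected):
                    log.warning(
                        "channel %s at r = %g cm (expected dose %.0f cGy) is "
                        "outside its sensitive range", ch, r, expected,
                    )

    maps = {}

    def get_map(channel: str):
        if channel not in maps:
            maps[channel] = dose_map_from_films(
                irr, bg, calibration[channel], channel=channel,
                geometry=geometry,
            )
        return maps[channel]

    frames = []
    summary_rows = []
    for r in radii:
        for channel in per_radius_channels[r]:
            dmap = get_map(channel)
            f_meas = polar_anisotropy(dmap, r, thetas)
            comp = compare_to_model(thetas, f_meas, model, r, channel=channel)
            frames.append(comp.to_frame())
            summary_rows.append(
                {
                    "r_cm": r,
                    "channel": channel,
                    "mean_pct_error": comp.mean_percent_error,
                    "max_pct_error": comp.max_percent_error,
                }
            )
    curves_frame = pd.concat(frames, ignore_index=True)
    summary = pd.DataFrame(summary_rows)

    result = PolarStudyResult(
        curves_frame=curves_frame,
        summary=summary,
        channel_by_radius=per_radius_channels,
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        curves_frame.to_csv(out_dir / "polar_anisotropy.csv", index=False)
        # comparison table shaped rows = distance, columns = channel x mean/max
        pivot = summary.pivot_table(
            index="r_cm", columns="channel",
            values=["mean_pct_error", "max_pct_error"],
        )
        pivot.to_csv(out_dir / "polar_comparison.csv")
        _write_manifest(
            out_dir, "polar", seed,
            {
                "dose_at_1cm_cgy": dose_at_1cm_cgy,
                "radii_cm": radii,
                "thetas_deg": list(map(float, thetas)),
                "channels": channels,
                "dwell_offset_mm": model.dwell_offset_mm,
            },
        )
        result.out_dir = out_dir
    return result


# ---------------------------------------------------------------------------
# Azimuthal anisotropy study
# ---------------------------------------------------------------------------


@dataclass
class AzimuthalStudyResult:
    profiles: pd.DataFrame  # film, radius_cm, angle_deg, value, channel
    stats: object  # AzimuthalStats
    out_dir: Path | None = None


def run_azimuthal_study(
    seed: int,
    calibration: dict[str, CalibrationCurve],
    out_dir=None,
    model: SourceModel | None = None,
    truth: CalibrationTruth | None = None,
    scanner: ScannerModel | None = None,
    depths_cm=(1.0, 2.0, 3.0, 4.0),
    radii_cm=(1.0, 2.0, 3.0),
    angles_deg=tuple(np.arange(0.0, 360.0, 15.0)),
    modulation_amplitude: float = 0.0,
    modulation_phase_deg: float = 0.0,
    beam_on_time_s: float | None = None,
) -> AzimuthalStudyResult:
    """Four-film azimuthal study: A(phi) per film and radius plus stats."""
    model = model or example_source_model(0.0)
    truth = truth or CalibrationTruth()
    scanner = scanner if scanner is not None else ScannerModel()
    films = generate_azimuthal_film_set(
        model, truth, scanner=scanner, seed=_child_seeds(seed, 1)[0],
        depths_cm=depths_cm, beam_on_time_s=beam_on_time_s,
        modulation_amplitude=modulation_amplitude,
        modulation_phase_deg=modulation_phase_deg,
    )
    angles = np.asarray(angles_deg, dtype=float)
    rows = []
    for irr, bg in films:
        geom: AzimuthalFilmGeometry = AzimuthalFilmGeometry(
            width_mm=irr.width_mm,
            height_mm=irr.height_mm,
            axial_offset_cm=irr.meta["axial_offset_cm"],
            hole_radius_mm=irr.meta["hole_radius_mm"],
            film_index=irr.meta["film_index"],
        )
        beam_time = irr.meta["beam_on_time_s"]
        maps = {}
        for radius in radii_cm:
            z = geom.axial_offset_cm
            r3d = float(np.hypot(radius, z))
            theta = float(np.degrees(np.arccos(z / r3d)))
            expected = model.delivered_dose(r3d, theta, beam_on_time_s=beam_time)
            channel = select_channel(expected)
            if channel not in maps:
                maps[channel] = dose_map_from_films(
                    irr, bg, calibration[channel], channel=channel,
                    geometry=geom,
                )
            values = azimuthal_anisotropy(maps[channel], float(radius), angles)
            for phi, val in zip(angles, values):
                rows.append(
                    {
                        "film": geom.film_index,
                        "radius_cm": float(radius),
                        "angle_deg": float(phi),
                        "value": float(val),
                        "channel": channel,
                    }
                )
    profiles = pd.DataFrame(rows)
    stats = azimuthal_stats(profiles)

    result = AzimuthalStudyResult(profiles=profiles, stats=stats)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        profiles.to_csv(out_dir / "azimuthal_profiles.csv", index=False)
        stats.per_film_radius.to_csv(
            out_dir / "azimuthal_rel_sd.csv", index=False
        )
        (out_dir / "azimuthal_stats.json").write_text(
            json.dumps(
                {
                    "per_radius_mean_rel_sd_pct": {
                        f"{k:g}": float(v) for k, v in stats.per_radius.items()
                    },
                    "overall_mean_rel_sd_pct": stats.overall,
                    "max_angle_rel_sd_pct": stats.max_angle_rel_sd,
                },
                indent=1,
            )
        )
        _write_manifest(
            out_dir, "azimuthal", seed,
            {
                "depths_cm": list(map(float, depths_cm)),
                "radii_cm": list(map(float, radii_cm)),
                "angles_deg": list(map(float, angles)),
                "modulation_amplitude": modulation_amplitude,
                "dwell_offset_mm": model.dwell_offset_mm,
            },
        )
        result.out_dir = out_dir
    return result
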