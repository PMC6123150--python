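"""Polar and azimuthal anisotropy extraction from measured dose maps.

The polar anisotropy function is the transverse-normalized angular dose
profile at fixed radius,

    F(r, theta) = Ddot(r, theta) / Ddot(r, theta0),   theta0 = 90 deg,

sampled from a polar-geometry dose map and compared to a reference source
model as per-angle percent error (mean and max per distance, the shape of
the published comparison tables).  The azimuthal anisotropy at a radius is
each angle's dose normalized to the mean over all angles — unity for an
ideal axially symmetric source — summarized by relative-SD statistics
over films, radii and angles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dosemap import DoseMap, sample_azimuthal, sample_dose
from .source import SourceModel

__all__ = [
    "polar_anisotropy",
    "AnisotropyComparison",
    "compare_to_model",
    "azimuthal_anisotropy",
    "AzimuthalStats",
    "azimuthal_stats",
]


def polar_anisotropy(
    dmap: DoseMap,
    r_cm: float,
    thetas_deg,
    theta0_deg: float = 90.0,
    side: int = +1,
) -> np.ndarray:
    """Measured F(r, theta) over an angle grid, normalized at theta0."""
    thetas = np.asarray(thetas_deg, dtype=float)
    d0 = sample_dose(dmap, r_cm, theta0_deg, side=side)
    if d0 == 0.0:
        raise ValueError(
            f"dose at the normalization angle theta0 = {theta0_deg} deg is zero"
        )
    return np.array(
        [sample_dose(dmap, r_cm, t, side=side) / d0 for t in thetas]
    )


@dataclass
class AnisotropyComparison:
    """Percent-error summary of measured vs reference F at one distance."""

    r_cm: float
    channel: str
    thetas_deg: np.ndarray
    f_measured: np.ndarray
    f_model: np.ndarray
    percent_error: np.ndarray

    @property
    def mean_percent_error(self) -> float:
        return float(self.percent_error.mean())

    @property
    def max_percent_error(self) -> float:
        return float(self.percent_error.max())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "r_cm": self.r_cm,
                "theta_deg": self.thetas_deg,
                "F_measured": self.f_measured,
                "F_model": self.f_model,
                "pct_error": self.percent_error,
                "channel": self.channel,
            }
        )


def compare_to_model(
    thetas_deg,
    f_measured,
    model: SourceModel,
    r_cm: float,
    channel: str = "",
) -> AnisotropyComparison:
    """Per-angle percent error of a measured F curve against a model.

    percent error = 100 |F_meas - F_model| / F_model, with the reference
    model in the denominator.
    """
    thetas = np.asarray(thetas_deg, dtype=float)
    f_meas = np.asarray(f_measured, dtype=float)
    if thetas.size == 0:
        raise ValueError("empty angle grid")
    if thetas.shape != f_meas.shape:
        raise ValueError("angle grid and measured F must match")
    f_mod = np.asarray(
        [model.anisotropy_factor(r_cm, t) for t in thetas], dtype=float
    )
    pct = 100.0 * np.abs(f_meas - f_mod) / f_mod
    return AnisotropyComparison(
        r_cm=r_cm,
        channel=channel,
        thetas_deg=thetas,
        f_measured=f_meas,
        f_model=f_mod,
        percent_error=pct,
    )


def azimuthal_anisotropy(
    dmap_or_doses,
    radius_cm: float | None = None,
    angles_deg=None,
    arc_halfwidth_deg: float = 2.0,
    n_arc: int = 5,
) -> np.ndarray:
    """Azimuthal anisotropy A(phi): dose per angle over the angular mean.

    Accepts either an azimuthal dose map plus (radius, angles), or a bare
    dose vector already sampled over angles.  The mean of the output is 1
    by construction.
    """
    if isinstance(dmap_or_doses, DoseMap):
        if radius_cm is None or angles_deg is None:
            raise ValueError("radius_cm and angles_deg required with a dose map")
        angles = np.asarray(angles_deg, dtype=float)
        doses = np.array(
            [
                sample_azimuthal(
                    dmap_or_doses, radius_cm, phi,
                    arc_halfwidth_deg=arc_halfwidth_deg, n_arc=n_arc,
                )
                for phi in angles
            ]
        )
    else:
        doses = np.asarray(dmap_or_doses, dtype=float)
    if doses.size < 2:
        raise ValueError("need at least 2 angles")
    mean = doses.mean()
    if mean == 0.0:
        raise ValueError("angular mean dose is zero")
    return doses / mean


@dataclass
class AzimuthalStats:
    """Dispersion summary of azimuthal anisotropy across films and radii."""

    per_film_radius: pd.DataFrame  # columns: film, radius_cm, rel_sd_pct
    per_radius: pd.Series  # mean rel SD over films, indexed by radius
    overall: float  # mean rel SD over all (film, radius)
    max_angle_rel_sd: float  # per-(film, angle) SD across radii: max over
    # angles per film, averaged over films


def azimuthal_stats(profiles: pd.DataFrame) -> AzimuthalStats:
    """Relative-SD statistics of normalized azimuthal profiles.

    ``profiles`` must have columns ``film``, ``radius_cm``, ``angle_deg``
    and ``value`` (the normalized anisotropy).  Relative SD is the
    population SD over the mean, in percent.
    """
    required = {"film", "radius_cm", "angle_deg", "value"}
    missing = required - set(profiles.columns)
    if missing:
        raise ValueError(f"profiles missing columns {sorted(missing)}")

    def rel_sd(v: pd.Series) -> float:
        arr = v.to_numpy(dtype=float)
        if arr.size < 2:
            raise ValueError("need >= 2 angles per (film, radius)")
        return 100.0 * arr.std(ddof=0) / arr.mean()

    per_fr = (
        profiles.groupby(["film", "radius_cm"])["value"]
        .apply(rel_sd)
        .rename("rel_sd_pct")
        .reset_index()
    )
    per_radius = per_fr.groupby("radius_cm")["rel_sd_pct"].mean()
    overall = float(per_fr["rel_sd_pct"].mean())

    def rel_sd_loose(v: pd.Series) -> float:
        arr = v.to_numpy(dtype=float)
        return 100.0 * arr.std(ddof=0) / arr.mean() if arr.size > 1 else 0.0

    per_fa = (
        profiles.groupby(["film", "angle_deg"])["value"].apply(rel_sd_loose)
    )
    max_per_film = per_fa.groupby(level="film").max()
    return AzimuthalStats(
        per_film_radius=per_fr,
        per_radius=per_radius,
        overall=overall,
        max_angle_rel_sd=float(max_per_film.mean()),
    )
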