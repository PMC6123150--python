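"""Beam-quality utilities: half-value layer and filter attenuation.

The HVL of the kV beam is taken from in-air narrow-beam transmission
readings versus added aluminum (detector at a fixed distance, collimating
aperture and absorber midway between source and detector).  Between
tabulated points the transmission is interpolated log-linearly, which is
exact for mono-exponential attenuation — the standard convention in kV
dosimetry.  Filter (e.g. adhesive dressing) attenuation is the percent
reduction of the open-field reading.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["TransmissionCurve", "hvl", "attenuation_percent"]


@dataclass
class TransmissionCurve:
    """Normalized transmission vs added aluminum thickness (mm).

    Constructed from raw readings with :meth:`from_readings` (readings are
    normalized to the zero-thickness reading on load).  Thickness must be
    strictly increasing starting at 0, transmissions non-increasing in
    (0, 1] with T(0) = 1.
    """

    thickness_mm: np.ndarray
    transmission: np.ndarray
    source_detector_distance_cm: float = 30.0
    aperture_note: str = "lead aperture midway between source and detector"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.thickness_mm = np.asarray(self.thickness_mm, dtype=float)
        self.transmission = np.asarray(self.transmission, dtype=float)
        t, tr = self.thickness_mm, self.transmission
        if t.ndim != 1 or t.shape != tr.shape or t.size < 2:
            raise ValueError("need matched 1D thickness/transmission, >= 2 points")
        if t[0] != 0.0:
            raise ValueError("first point must be at zero added thickness")
        if abs(tr[0] - 1.0) > 1e-12:
            raise ValueError("transmission at zero thickness must be 1")
        if not np.all(np.diff(t) > 0):
            raise ValueError("thicknesses must be strictly increasing")
        if np.any(tr <= 0) or np.any(tr > 1):
            raise ValueError("transmissions must lie in (0, 1]")
        if np.any(np.diff(tr) > 0):
            raise ValueError("transmission must be non-increasing")

    @classmethod
    def from_readings(cls, thickness_mm, readings, **kwargs) -> "TransmissionCurve":
        """Build from raw detector readings; normalizes to the open field."""
        t = np.asarray(thickness_mm, dtype=float)
        r = np.asarray(readings, dtype=float)
        order = np.argsort(t)
        t, r = t[order], r[order]
        if r[0] <= 0:
            raise ValueError("open-field (zero-thickness) reading must be > 0")
        return cls(thickness_mm=t, transmission=r / r[0], **kwargs)

    @classmethod
    def from_csv(cls, path, **kwargs) -> "TransmissionCurve":
        df = pd.read_csv(path)
        for col in ("thickness_mmAl", "reading"):
            if col not in df.columns:
                raise ValueError(f"transmission CSV missing column {col!r}")
        return cls.from_readings(
            df["thickness_mmAl"].to_numpy(), df["reading"].to_numpy(), **kwargs
        )

    def hvl_mm(self) -> float:
        """Aluminum thickness (mm) at 50% transmission, log-linear."""
        t, tr = self.thickness_mm, self.transmission
        if tr[-1] > 0.5:
            raise ValueError(
                f"curve does not bracket 50% transmission "
                f"(minimum {tr[-1]:.3f} at {t[-1]:g} mm)"
            )
        idx = int(np.argmax(tr <= 0.5))
        if tr[idx] == 0.5:
            return float(t[idx])
        t1, t2 = t[idx - 1], t[idx]
        l1, l2 = math.log(tr[idx - 1]), math.log(tr[idx])
        return float(t1 + (l1 - math.log(0.5)) / (l1 - l2) * (t2 - t1))


def hvl(curve: TransmissionCurve) -> float:
    """Half-value layer (mmAl) of a transmission curve."""
    return curve.hvl_mm()


def attenuation_percent(open_reading: float, filtered_reading: float) -> float:
    """Percent attenuation of a filter: 100 (1 - filtered/open).

    A filtered reading exceeding the open one is physically anomalous;
    the negative percentage is returned with a warning rather than hidden.
    """
    if open_reading <= 0:
        raise ValueError("open-field reading must be > 0")
    pct = 100.0 * (1.0 - filtered_reading / open_reading)
    if pct < 0:
        warnings.warn(
            f"filtered reading exceeds open reading (attenuation {pct:.3f}%); "
            "check the measurement",
            stacklevel=2,
        )
    return float(pct)
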