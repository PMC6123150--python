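"""Pixel-value -> dose calibration for radiochromic film.

The net (background-subtracted, inverted) pixel value of radiochromic
film responds to dose as a saturating exponential; the calibration curve
fitted per colour channel is the exponential-with-offset family

    net_pv(D) = a * exp(-b * D) + c,        b > 0,

with ``a < 0`` expected for net values (signal grows with dose and
saturates at ``c``).  The fit is exposed statsmodels-style: build an
:class:`ExponentialOffsetModel` from the calibration points, call
``fit()``, and receive a :class:`CalibrationCurve` results object with the
parameters, per-point residuals, R², a ``summary()`` table and the
inverse map :meth:`CalibrationCurve.dose_from_net`.

Channel choice follows the film's dose-dependent sensitivity: the red
channel is most sensitive below 6 Gy, green from 6 to 35 Gy, and blue
above 35 Gy; :func:`select_channel` applies those ranges with half-open
boundaries (600 and 3500 cGy go to the higher-dose channel).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "CalibrationPoint",
    "CalibrationCurve",
    "ExponentialOffsetModel",
    "fit_exponential_offset",
    "select_channel",
    "pv_to_dose",
    "FitError",
    "SaturationError",
]


class FitError(RuntimeError):
    """The calibration fit failed or is degenerate."""


class SaturationError(ValueError):
    """A net pixel value lies outside the curve's attainable range."""


@dataclass(frozen=True)
class CalibrationPoint:
    """One calibration reading: dose (cGy) vs net pixel value."""

    dose_cgy: float
    net_pv: float
    channel: str = "red"

    def __post_init__(self) -> None:
        if self.dose_cgy < 0:
            raise ValueError("dose_cgy must be >= 0")


def select_channel(dose_estimate_cgy: float) -> str:
    """Most sensitive colour channel for an estimated dose (cGy)."""
    if dose_estimate_cgy < 0:
        raise ValueError(f"dose estimate must be >= 0, got {dose_estimate_cgy}")
    if dose_estimate_cgy < 600.0:
        return "red"
    if dose_estimate_cgy < 3500.0:
        return "green"
    return "blue"


def _exp_offset(d, a, b, c):
    return a * np.exp(-b * d) + c


@dataclass
class CalibrationCurve:
    """Fitted exponential-with-offset calibration curve for one channel."""

    channel: str
    a: float
    b: float
    c: float
    r_squared: float
    dose_cgy: np.ndarray
    net_pv: np.ndarray
    residuals: np.ndarray
    valid_dose_range: tuple[float, float] = (0.0, np.inf)
    restarts_used: int = 0

    def __post_init__(self) -> None:
        self.dose_cgy = np.asarray(self.dose_cgy, dtype=float)
        self.net_pv = np.asarray(self.net_pv, dtype=float)
        self.residuals = np.asarray(self.residuals, dtype=float)
        if self.b <= 0:
            raise ValueError("fitted b must be > 0 (monotonic response)")
        if self.r_squared > 1.0 + 1e-12:
            raise ValueError("R^2 cannot exceed 1")

    # -- forward / inverse ----------------------------------------------
    def predict(self, dose_cgy):
        """Net pixel value at a dose (forward evaluation of the fit)."""
        return _exp_offset(np.asarray(dose_cgy, dtype=float), self.a, self.b, self.c)

    def dose_from_net(self, net_pv: float) -> float:
        """Invert the curve: D = -ln((net - c)/a) / b.

        The net value must lie strictly between the zero-dose value
        ``a + c`` and the asymptote ``c`` (zero-dose value itself allowed).
        """
        ratio = (float(net_pv) - self.c) / self.a
        if ratio <= 0.0:
            bound = "saturation asymptote c" if self.a < 0 else "lower asymptote c"
            raise SaturationError(
                f"net_pv = {net_pv} at or beyond the {bound} ({self.c:.1f})"
            )
        if ratio > 1.0:
            raise SaturationError(
                f"net_pv = {net_pv} beyond the zero-dose value a + c "
                f"({self.a + self.c:.1f})"
            )
        return float(-np.log(ratio) / self.b)

    def dose_map(self, net_pv: np.ndarray, range_margin: float = 1.2):
        """Vectorized inverse for rasters.

        Values at or beyond the saturation asymptote, or mapping beyond
        ``range_margin`` times the calibrated dose maximum (where the
        inversion is no longer supported by data), are flagged invalid;
        values below the zero-dose level clamp to dose 0 (sub-background
        noise).  Returns ``(dose, valid)``.
        """
        net = np.asarray(net_pv, dtype=float)
        ratio = (net - self.c) / self.a
        valid = ratio > 0.0
        ratio_safe = np.where(valid, ratio, 1.0)
        dose = -np.log(ratio_safe) / self.b
        dose = np.where(dose < 0.0, 0.0, dose)
        lo, hi = self.valid_dose_range
        if np.isfinite(hi):
            valid &= dose <= hi * range_margin
        dose = np.where(valid, dose, 0.0)
        return dose, valid

    # -- reporting -------------------------------------------------------
    def summary(self) -> str:
        lines = [
            "Exponential-with-offset calibration fit",
            "=======================================",
            f"channel:          {self.channel}",
            f"n points:         {self.dose_cgy.size}",
            f"a  (PV):          {self.a:.6g}",
            f"b  (1/cGy):       {self.b:.6g}",
            f"c  (PV):          {self.c:.6g}",
            f"R^2:              {self.r_squared:.8f}",
            f"max |residual|:   {np.abs(self.residuals).max():.4g} PV",
            f"valid dose range: [{self.valid_dose_range[0]:g}, "
            f"{self.valid_dose_range[1]:g}] cGy",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "channel": self.channel,
            "a": self.a,
            "b": self.b,
            "c": self.c,
            "r_squared": self.r_squared,
            "dose_cgy": self.dose_cgy.tolist(),
            "net_pv": self.net_pv.tolist(),
            "residuals": self.residuals.tolist(),
            "valid_dose_range": list(self.valid_dose_range),
            "restarts_used": self.restarts_used,
        }

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationCurve":
        return cls(
            channel=d["channel"],
            a=d["a"],
            b=d["b"],
            c=d["c"],
            r_squared=d["r_squared"],
            dose_cgy=np.asarray(d["dose_cgy"]),
            net_pv=np.asarray(d["net_pv"]),
            residuals=np.asarray(d["residuals"]),
            valid_dose_range=tuple(d["valid_dose_range"]),
            restarts_used=d.get("restarts_used", 0),
        )

    @classmethod
    def from_json(cls, path) -> "CalibrationCurve":
        return cls.from_dict(json.loads(Path(path).read_text()))


class ExponentialOffsetModel:
    """Least-squares model net_pv(D) = a exp(-bD) + c for one channel.

    Requires at least 4 points with at least 3 distinct doses (the added
    zero-dose point included).  ``fit()`` initializes from the closed-form
    log-linear estimate, retries with jittered starts on non-convergence,
    and returns a :class:`CalibrationCurve`.
    """

    def __init__(self, dose_cgy, net_pv, channel: str = "red") -> None:
        self.dose_cgy = np.asarray(dose_cgy, dtype=float)
        self.net_pv = np.asarray(net_pv, dtype=float)
        self.channel = channel
        if self.dose_cgy.shape != self.net_pv.shape or self.dose_cgy.ndim != 1:
            raise ValueError("dose and net_pv must be matched 1D arrays")
        if self.dose_cgy.size < 4:
            raise FitError(
                f"need >= 4 calibration points, got {self.dose_cgy.size}"
            )
        if np.unique(self.dose_cgy).size < 3:
            raise FitError("need >= 3 distinct dose levels")
        if np.any(self.dose_cgy < 0):
            raise ValueError("doses must be >= 0")

    @classmethod
    def from_points(cls, points) -> "ExponentialOffsetModel":
        pts = list(points)
        channels = {p.channel for p in pts}
        if len(channels) != 1:
            raise ValueError("all points must belong to one channel")
        return cls(
            [p.dose_cgy for p in pts],
            [p.net_pv for p in pts],
            channel=channels.pop(),
        )

    def _initial_guess(self) -> tuple[float, float, float]:
        d, y = self.dose_cgy, self.net_pv
        increasing = np.corrcoef(d, y)[0, 1] >= 0
        span = y.max() - y.min()
        if increasing:
            # saturating growth: a < 0, c above the data
            c0 = 1.05 * y.max() if y.max() > 0 else y.max() + 1.0
            z = np.log(c0 - y)
            slope, intercept = np.polyfit(d, z, 1)
            return -float(np.exp(intercept)), -float(slope), float(c0)
        c0 = y.min() - 0.05 * max(span, 1.0)
        z = np.log(y - c0)
        slope, intercept = np.polyfit(d, z, 1)
        return float(np.exp(intercept)), -float(slope), float(c0)

    def fit(self, max_restarts: int = 3) -> CalibrationCurve:
        d, y = self.dose_cgy, self.net_pv
        ss_tot = float(((y - y.mean()) ** 2).sum())
        if ss_tot == 0.0:
            raise FitError(
                "all net pixel values are equal; b is unidentifiable"
            )
        a0, b0, c0 = self._initial_guess()
        if not np.isfinite(b0) or b0 <= 0:
            b0 = 1.0 / max(d.max(), 1.0)
        attempts = [(a0, b0, c0)]
        for k in range(max_restarts):
            fac = (0.3, 3.0, 10.0)[k]
            attempts.append((a0, b0 * fac, c0))
        last_err: Exception | None = None
        for i, p0 in enumerate(attempts):
            try:
                popt, _ = curve_fit(
                    _exp_offset, d, y, p0=p0, maxfev=20000,
                    xtol=1e-14, ftol=1e-14,
                )
            except (RuntimeError, ValueError) as exc:
                last_err = exc
                continue
            a, b, c = (float(v) for v in popt)
            if b <= 0 or a == 0:
                last_err = FitError(
                    f"non-monotonic fit (a = {a:.4g}, b = {b:.4g})"
                )
                continue
            resid = y - _exp_offset(d, a, b, c)
            r2 = 1.0 - float((resid**2).sum()) / ss_tot
            return CalibrationCurve(
                channel=self.channel,
                a=a,
                b=b,
                c=c,
                r_squared=min(r2, 1.0),
                dose_cgy=d,
                net_pv=y,
                residuals=resid,
                valid_dose_range=(0.0, float(d.max())),
                restarts_used=i,
            )
        raise FitError(
            f"calibration fit failed after {len(attempts)} starts "
            f"(last error: {last_err}); doses [{d.min():g}, {d.max():g}] cGy, "
            f"net PV [{y.min():g}, {y.max():g}]"
        )


def fit_exponential_offset(points) -> CalibrationCurve:
    """Fit a channel's calibration points (convenience wrapper)."""
    return ExponentialOffsetModel.from_points(points).fit()


def pv_to_dose(curve: CalibrationCurve, net_pv: float) -> float:
    """Dose (cGy) for one net pixel value via the fitted curve."""
    return curve.dose_from_net(net_pv)
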