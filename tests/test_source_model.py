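"""Dose-engine tests: table interpolation, the point-source dose equation,
timer handling and table I/O."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ebfilm import (
    PolarCoordinate,
    SourceModel,
    TableRangeError,
    example_source_model,
)
from ebfilm.source import DWELL_OFFSETS_MM


def flat_model(sk=1.0, lam=1.0, g=None, f=None, r=None):
    """Tiny model with controllable tables for closed-form checks."""
    r = np.array([0.5, 1.0, 2.0, 3.0]) if r is None else np.asarray(r, float)
    gvals = np.ones_like(r) if g is None else np.asarray(g, dtype=float)
    thetas = np.array([0.0, 90.0, 180.0])
    fgrid = np.ones((r.size, thetas.size)) if f is None else np.asarray(f)
    return SourceModel(
        dwell_offset_mm=0.0,
        air_kerma_strength=sk,
        dose_rate_constant=lam,
        radial_r_cm=r,
        radial_g=gvals,
        anisotropy_r_cm=r,
        anisotropy_theta_deg=thetas,
        anisotropy_f=fgrid,
    )


class TestRadialDose:
    @pytest.mark.parametrize(
        "table, r, expected",
        [
            ([(1.0, 1.0), (2.0, 0.5)], 1.0, 1.0),
            ([(1.0, 1.0), (2.0, 0.5)], 1.5, 0.75),
            ([(1.0, 1.0), (3.0, 0.4)], 2.0, 0.7),
        ],
    )
    def test_linear_interpolation(self, table, r, expected):
        rr = np.array([p[0] for p in table])
        gg = np.array([p[1] for p in table])
        m = SourceModel(
            dwell_offset_mm=0.0, air_kerma_strength=1.0, dose_rate_constant=1.0,
            radial_r_cm=rr, radial_g=gg,
            anisotropy_r_cm=rr, anisotropy_theta_deg=np.array([0.0, 90.0, 180.0]),
            anisotropy_f=np.ones((rr.size, 3)),
        )
        assert m.radial_dose(r) == pytest.approx(expected, abs=1e-12)

    def test_no_extrapolation(self):
        m = flat_model()
        with pytest.raises(TableRangeError):
            m.radial_dose(0.4)
        with pytest.raises(TableRangeError):
            m.radial_dose(3.5)


class TestAnisotropyFactor:
    def test_transverse_normalization(self, model):
        for r in model.anisotropy_r_cm:
            assert model.anisotropy_factor(float(r), 90.0) == pytest.approx(
                1.0, abs=1e-9
            )

    def test_linear_in_angle(self):
        f = np.tile([0.9, 1.0, 0.7], (4, 1))
        m = flat_model(f=f)
        # angles 0/90/180 with F 0.9/1.0/0.7: midway between 90 and 180
        assert m.anisotropy_factor(1.0, 135.0) == pytest.approx(0.85, abs=1e-12)

    def test_cell_center_equals_corner_mean(self, model, rng):
        """Bilinear interpolation at a cell centre is the 4-corner mean."""
        nr = model.anisotropy_r_cm.size
        nt = model.anisotropy_theta_deg.size
        for _ in range(25):
            i = rng.integers(0, nr - 1)
            j = rng.integers(0, nt - 1)
            rc = 0.5 * (model.anisotropy_r_cm[i] + model.anisotropy_r_cm[i + 1])
            tc = 0.5 * (
                model.anisotropy_theta_deg[j] + model.anisotropy_theta_deg[j + 1]
            )
            corners = model.anisotropy_f[i : i + 2, j : j + 2]
            assert model.anisotropy_factor(float(rc), float(tc)) == pytest.approx(
                corners.mean(), abs=1e-12
            )

    def test_bilinear_matches_brute_force_oracle(self, model, rng):
        """100 random in-hull queries against an explicit bilinear formula."""
        rg, tg, fg = (
            model.anisotropy_r_cm,
            model.anisotropy_theta_deg,
            model.anisotropy_f,
        )
        for _ in range(100):
            r = rng.uniform(rg[0], rg[-1])
            t = rng.uniform(tg[0], tg[-1])
            i = min(np.searchsorted(rg, r, side="right") - 1, rg.size - 2)
            j = min(np.searchsorted(tg, t, side="right") - 1, tg.size - 2)
            u = (r - rg[i]) / (rg[i + 1] - rg[i])
            v = (t - tg[j]) / (tg[j + 1] - tg[j])
            expected = (
                fg[i, j] * (1 - u) * (1 - v)
                + fg[i + 1, j] * u * (1 - v)
                + fg[i, j + 1] * (1 - u) * v
                + fg[i + 1, j + 1] * u * v
            )
            assert model.anisotropy_factor(r, t) == pytest.approx(
                expected, abs=1e-12
            )

    def test_out_of_grid_raises(self, model):
        with pytest.raises(TableRangeError):
            model.anisotropy_factor(0.1, 90.0)


class TestDoseRate:
    def test_reference_point_reduces_to_constants(self):
        m = flat_model(sk=3.0, lam=7.0)
        assert m.dose_rate(PolarCoordinate(1.0, 90.0)) == pytest.approx(21.0)

    def test_inverse_square(self):
        m = flat_model(sk=100.0, lam=1.0)
        assert m.dose_rate(2.0, 90.0) == pytest.approx(25.0)

    def test_product_of_factors_oracle(self):
        g = np.array([1.0, 1.0, 0.8, 0.8])
        f = np.tile([0.6, 1.0, 1.0], (4, 1))  # F = 0.6 at theta = 0
        m = flat_model(sk=100.0, lam=1.0, g=g, f=f)
        # independent product: 100 * (1/2)^2 * 0.8 * F(2, 30deg)
        f_30 = 0.6 + (1.0 - 0.6) * 30.0 / 90.0
        expected = 100.0 * 0.25 * 0.8 * f_30
        assert m.dose_rate(2.0, 30.0) == pytest.approx(expected, rel=1e-12)

    def test_inverse_square_ratio_property(self, rng):
        m = flat_model(sk=50.0, lam=2.0)
        for _ in range(20):
            r1, r2 = rng.uniform(0.5, 3.0, size=2)
            ratio = m.dose_rate(r1, 45.0) / m.dose_rate(r2, 45.0)
            assert ratio == pytest.approx((r2 / r1) ** 2, rel=1e-12)

    def test_continuity_at_knots(self, model):
        eps = 1e-9
        for r in model.radial_r_cm[1:-1]:
            lo = model.dose_rate(float(r) - eps, 47.0)
            hi = model.dose_rate(float(r) + eps, 47.0)
            assert lo == pytest.approx(hi, rel=1e-6)


class TestDeliveredDose:
    def test_ramp_consumes_all_time(self, model):
        p = PolarCoordinate(1.0, 90.0)
        assert model.delivered_dose(p, beam_on_time_s=2.0) == 0.0

    def test_arithmetic(self):
        m = flat_model(sk=3600.0, lam=1.0)  # 1 cGy/s at reference point
        assert m.delivered_dose(1.0, 90.0, beam_on_time_s=12.0) == pytest.approx(
            10.0
        )

    def test_zero_ramp_is_identity(self, model):
        rate = model.dose_rate(1.5, 60.0)
        d = model.delivered_dose(1.5, 60.0, beam_on_time_s=30.0, ramp_time_s=0.0)
        assert d == pytest.approx(rate / 3600.0 * 30.0, rel=1e-12)

    def test_negative_time_rejected(self, model):
        with pytest.raises(ValueError):
            model.delivered_dose(1.0, 90.0, beam_on_time_s=-1.0)

    @settings(max_examples=40, derandomize=True)
    @given(
        t1=st.floats(0.0, 500.0),
        dt=st.floats(0.0, 500.0),
    )
    def test_non_decreasing_in_time(self, t1, dt):
        m = example_source_model(3.0)
        d1 = m.delivered_dose(1.0, 90.0, beam_on_time_s=t1)
        d2 = m.delivered_dose(1.0, 90.0, beam_on_time_s=t1 + dt)
        assert d2 >= d1

    def test_beam_time_round_trip(self, model):
        t = model.beam_time_for_dose(500.0, 2.0, 120.0)
        assert model.delivered_dose(2.0, 120.0, beam_on_time_s=t) == pytest.approx(
            500.0, rel=1e-12
        )


class TestValidationAndIO:
    def test_example_models_satisfy_invariants(self):
        for offset in DWELL_OFFSETS_MM:
            m = example_source_model(offset)
            assert m.radial_dose(1.0) == pytest.approx(1.0, abs=1e-9)
            assert np.all(m.anisotropy_f > 0)
            assert "stand-in" in m.label

    def test_tip_suppression_strongest_for_most_extended_source(self):
        f0 = example_source_model(0.0).anisotropy_factor(1.0, 160.0)
        f12 = example_source_model(12.0).anisotropy_factor(1.0, 160.0)
        assert f0 < f12 < 1.0

    def test_non_increasing_radii_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            flat_model().__class__(
                dwell_offset_mm=0.0, air_kerma_strength=1.0,
                dose_rate_constant=1.0,
                radial_r_cm=np.array([1.0, 1.0, 2.0]),
                radial_g=np.array([1.0, 1.0, 0.5]),
                anisotropy_r_cm=np.array([1.0, 2.0]),
                anisotropy_theta_deg=np.array([0.0, 90.0, 180.0]),
                anisotropy_f=np.ones((2, 3)),
            )

    def test_unnormalized_tables_rejected(self):
        with pytest.raises(ValueError, match="g_p"):
            flat_model(g=[1.0, 1.1, 0.9, 0.8])
        with pytest.raises(ValueError, match=r"F\(r, 90\)"):
            flat_model(f=np.full((4, 3), 0.9))

    def test_json_round_trip(self, model, tmp_path):
        path = tmp_path / "model.json"
        model.to_json(path)
        back = SourceModel.from_json(path)
        assert np.allclose(back.anisotropy_f, model.anisotropy_f)
        assert back.dose_rate(1.7, 133.0) == pytest.approx(
            model.dose_rate(1.7, 133.0), rel=1e-12
        )

    def test_csv_round_trip(self, model, tmp_path):
        rad, ani = tmp_path / "g.csv", tmp_path / "F.csv"
        model.to_csv(rad, ani)
        back = SourceModel.from_csv(
            rad, ani, dwell_offset_mm=model.dwell_offset_mm,
            air_kerma_strength=model.air_kerma_strength,
            dose_rate_constant=model.dose_rate_constant,
        )
        assert back.dose_rate(2.3, 41.0) == pytest.approx(
            model.dose_rate(2.3, 41.0), rel=1e-12
        )

    def test_csv_missing_column_reported(self, model, tmp_path):
        rad, ani = tmp_path / "g.csv", tmp_path / "F.csv"
        model.to_csv(rad, ani)
        rad.write_text("radius,g\n1.0,1.0\n")
        with pytest.raises(ValueError, match="r_cm"):
            SourceModel.from_csv(
                rad, ani, dwell_offset_mm=0.0, air_kerma_strength=1.0,
                dose_rate_constant=1.0,
            )

    def test_polar_coordinate_validation(self):
        with pytest.raises(ValueError):
            PolarCoordinate(-1.0, 90.0)
        with pytest.raises(ValueError):
            PolarCoordinate(1.0, 190.0)
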