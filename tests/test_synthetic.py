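"""Synthetic film-scan generator tests: forward response, determinism,
geometry of the three film layouts, scanner QA emulation, TIFF I/O."""

import numpy as np
import pytest

from ebfilm import (
    AzimuthalFilmGeometry,
    CalibrationFilmGeometry,
    ChannelResponse,
    FilmImage,
    PolarFilmGeometry,
    exclusion_mask,
    forward_response,
    generate_azimuthal_film_set,
    generate_calibration_film,
    generate_flat_field,
    generate_polar_film,
    read_film,
    uniformity_stats,
    write_film,
)


class TestForwardResponse:
    def test_zero_dose_gives_a_plus_c(self, truth):
        r = truth.response("red")
        assert forward_response(truth, 0.0, "red") == pytest.approx(r.a + r.c)

    def test_asymptote(self, truth):
        assert forward_response(truth, 1e7, "green") == pytest.approx(
            truth.response("green").c, abs=1e-6
        )

    def test_half_decay_point(self):
        from ebfilm import CalibrationTruth

        t = CalibrationTruth(red=ChannelResponse(-30000.0, 0.001, 40000.0))
        assert forward_response(t, 693.147, "red") == pytest.approx(
            25000.0, abs=0.01
        )

    def test_negative_dose_rejected(self, truth):
        with pytest.raises(ValueError):
            forward_response(truth, -1.0, "red")

    def test_response_validation(self):
        with pytest.raises(ValueError):
            ChannelResponse(-30000.0, -0.001, 40000.0)
        with pytest.raises(ValueError):
            ChannelResponse(-30000.0, 0.001, 20000.0)  # a + c < 0


class TestCalibrationFilms:
    def test_seed_determinism_bit_identical(self, truth):
        a = generate_calibration_film(truth, 100.0, seed=7)
        b = generate_calibration_film(truth, 100.0, seed=7)
        assert np.array_equal(a[0].pixels, b[0].pixels)
        assert np.array_equal(a[1].pixels, b[1].pixels)

    def test_zero_dose_equals_background(self, truth, noiseless):
        irr, bg = generate_calibration_film(
            truth, 0.0, scanner=noiseless, seed=3
        )
        assert np.array_equal(irr.pixels, bg.pixels)

    def test_center_pixel_composition_oracle(self, truth, noiseless, model):
        """Noiseless pixel value is the forward response of the scaled
        point-source dose at that pixel's exact position."""
        from ebfilm import film_to_polar

        dose = 400.0
        geometry = CalibrationFilmGeometry()
        irr, _ = generate_calibration_film(
            truth, dose, geometry=geometry, scanner=noiseless, seed=1,
            model=model,
        )
        mmpp = irr.mm_per_pixel
        center_rate = model.dose_rate(geometry.axial_offset_mm / 10.0, 180.0)
        for row, col in [(150, 150), (120, 180), (60, 60)]:
            p = film_to_polar(((col + 0.5) * mmpp, (row + 0.5) * mmpp),
                              geometry)
            pixel_dose = dose * model.dose_rate(p.r_cm, p.theta_deg) / center_rate
            expected = 65535.0 - forward_response(truth, pixel_dose, "red")
            assert abs(float(irr.pixels[row, col, 0]) - expected) <= 1.0

    def test_pixel_range_and_resolution(self, truth):
        irr, _ = generate_calibration_film(truth, 1198.1, seed=2)
        assert irr.pixels.dtype == np.uint16
        assert irr.dpi == 150.0
        assert irr.mm_per_pixel == pytest.approx(25.4 / 150.0)

    def test_negative_dose_rejected(self, truth):
        with pytest.raises(ValueError):
            generate_calibration_film(truth, -5.0, seed=0)


class TestPolarFilms:
    def test_isotropic_model_is_radially_symmetric(self, truth, noiseless):
        """With F = 1 the noiseless raster is mirror-symmetric about a
        source placed at the exact raster centre, i.e. equidistant pixels
        read identical values."""
        from test_source_model import flat_model

        m = flat_model(sk=1000.0, lam=50.0)
        # 301 x 301 pixels -> the source sits on the central pixel centre
        mmpp = 25.4 / 150.0
        extent = 301 * mmpp
        c = 150.5 * mmpp
        geom = PolarFilmGeometry(width_mm=extent, height_mm=extent,
                                 source_x_mm=c, source_y_mm=c)
        t = m.beam_time_for_dose(300.0, 1.0, 90.0)
        irr, _ = generate_polar_film(
            m, truth, geometry=geom, beam_on_time_s=t, scanner=noiseless,
            seed=0,
        )
        px = irr.pixels[..., 0].astype(int)
        valid = irr.valid_mask & irr.valid_mask[::-1, :] & irr.valid_mask[:, ::-1]
        assert np.array_equal(px[valid], px[::-1, :][valid])
        assert np.array_equal(px[valid], px[:, ::-1][valid])

    def test_pixel_value_composition_oracle(self, model, truth, noiseless):
        geom = PolarFilmGeometry()
        t = model.beam_time_for_dose(290.0, 1.0, 90.0)
        irr, _ = generate_polar_film(
            model, truth, geometry=geom, beam_on_time_s=t, scanner=noiseless,
            seed=0,
        )
        # pixel nearest (r = 1 cm, theta = 90): directly below the source
        from ebfilm import film_to_polar

        mmpp = irr.mm_per_pixel
        col = int(round(geom.source_x_mm / mmpp - 0.5))
        row = int(round((geom.source_y_mm + 10.0) / mmpp - 0.5))
        p = film_to_polar(((col + 0.5) * mmpp, (row + 0.5) * mmpp), geom)
        assert p.r_cm == pytest.approx(1.0, abs=0.02)
        assert p.theta_deg == pytest.approx(90.0, abs=1.0)
        dose = model.delivered_dose(p.r_cm, p.theta_deg, beam_on_time_s=t)
        expected = 65535.0 - forward_response(truth, dose, "red")
        assert abs(float(irr.pixels[row, col, 0]) - expected) <= 1.0

    def test_ramp_only_exposure_is_background(self, model, truth, noiseless):
        irr, bg = generate_polar_film(
            model, truth, beam_on_time_s=2.0, scanner=noiseless, seed=0
        )
        assert np.array_equal(irr.pixels, bg.pixels)

    def test_near_source_pixels_masked(self, model, truth):
        geom = PolarFilmGeometry()
        irr, _ = generate_polar_film(
            model, truth, beam_on_time_s=10.0, seed=0, geometry=geom
        )
        mmpp = irr.mm_per_pixel
        col = int(geom.source_x_mm / mmpp)
        row = int(geom.source_y_mm / mmpp)
        assert not irr.valid_mask[row, col]

    def test_out_of_table_pixels_raise_when_requested(self, model, truth):
        geom = PolarFilmGeometry(width_mm=170.0, height_mm=60.0,
                                 source_x_mm=85.0, source_y_mm=10.0)
        from ebfilm import TableRangeError

        with pytest.raises(TableRangeError, match="row"):
            generate_polar_film(
                model, truth, geometry=geom, beam_on_time_s=10.0, seed=0,
                on_out_of_range="raise",
            )


class TestAzimuthalFilms:
    def test_four_films_spaced_one_cm(self, model, truth):
        films = generate_azimuthal_film_set(model, truth, seed=5)
        assert len(films) == 4
        offsets = [irr.meta["axial_offset_cm"] for irr, _ in films]
        assert np.allclose(np.diff(offsets), 1.0)

    def test_wrong_spacing_rejected(self, model, truth):
        with pytest.raises(ValueError, match="1 cm"):
            generate_azimuthal_film_set(
                model, truth, depths_cm=(1.0, 2.0, 3.5, 4.5), seed=0
            )

    def test_wrong_count_rejected(self, model, truth):
        with pytest.raises(ValueError, match="4 films"):
            generate_azimuthal_film_set(
                model, truth, depths_cm=(1.0, 2.0, 3.0), seed=0
            )

    def test_oversized_hole_rejected(self, model, truth):
        with pytest.raises(ValueError, match="hole"):
            generate_azimuthal_film_set(
                model, truth, hole_radius_mm=40.0, width_mm=70.0, seed=0
            )

    def test_hole_and_annulus_masked(self, model, truth):
        films = generate_azimuthal_film_set(model, truth, seed=5)
        irr, _ = films[0]
        mmpp = irr.mm_per_pixel
        cx = irr.width_mm / 2
        cy = irr.height_mm / 2
        xx = irr.x_mm[None, :] - cx
        yy = irr.y_mm[:, None] - cy
        rr = np.hypot(xx, yy)
        assert not irr.valid_mask[rr <= 6.4].any()
        assert irr.valid_mask[(rr > 6.6) & (rr < 10.0)].all()

    def test_isotropic_angular_profile_constant(self, truth, noiseless):
        """For an isotropic source the noiseless azimuthal raster is
        mirror-symmetric about both axes through the hole centre."""
        from test_source_model import flat_model

        m = flat_model(sk=3600.0, lam=100.0, r=np.linspace(0.25, 8.0, 32))
        # 301 x 301 raster so the hole centre is a pixel centre
        mmpp = 25.4 / 150.0
        extent = 301 * mmpp
        films = generate_azimuthal_film_set(
            m, truth, scanner=noiseless, seed=1, beam_on_time_s=12.0,
            width_mm=extent, height_mm=extent,
        )
        irr, _ = films[0]
        px = irr.pixels[..., 0].astype(int)
        valid = irr.valid_mask & irr.valid_mask[::-1, :] & irr.valid_mask[:, ::-1]
        assert valid.any()
        assert np.array_equal(px[valid], px[::-1, :][valid])
        assert np.array_equal(px[valid], px[:, ::-1][valid])


class TestScannerQA:
    def test_flat_field_landscape_relative_sd(self, truth):
        ff = generate_flat_field(truth, seed=42)
        ff.valid_mask = exclusion_mask(ff, border_mm=4.0)
        got = uniformity_stats(ff, "red", "landscape")
        assert got == pytest.approx(0.77, abs=0.1)

    def test_noiseless_scanner_perfectly_uniform(self, truth, noiseless):
        ff = generate_flat_field(truth, scanner=noiseless, seed=0)
        assert uniformity_stats(ff, "green", "landscape") == pytest.approx(
            0.0, abs=1e-12
        )


class TestFilmIO:
    def test_tiff_round_trip(self, truth, tmp_path):
        irr, _ = generate_calibration_film(truth, 150.0, seed=9)
        irr.valid_mask[10, 10] = False
        path = tmp_path / "film.tif"
        write_film(irr, path)
        back = read_film(path)
        assert np.array_equal(back.pixels, irr.pixels)
        assert back.dpi == irr.dpi
        assert back.role == "irradiated"
        assert not back.valid_mask[10, 10]
        assert back.meta["dose_cgy"] == 150.0

    def test_film_image_validation(self):
        with pytest.raises(ValueError, match="rows, cols, 3"):
            FilmImage(pixels=np.zeros((4, 4)))
        with pytest.raises(ValueError, match="valid_mask"):
            FilmImage(
                pixels=np.zeros((4, 4, 3), dtype=np.uint16),
                valid_mask=np.ones((3, 3), dtype=bool),
            )
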