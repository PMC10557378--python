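"""Grid assembly, quantitation, masking, S/N filtering and ROI statistics."""

import numpy as np
import pytest

from pgisomer import calibration as cal
from pgisomer import msi
from pgisomer import synthetic as syn
from pgisomer.spectra import HIGH_RES, LOW_RES, MassSpectrum, ProductIonChannel, ion_trap_channels


def _img(values, mask=None, pixel=(31.0, 100.0), units="counts"):
    return msi.IonImage(np.asarray(values, float), pixel, mask=mask, units=units)


class TestGridGeometry:
    def test_pixel_size_from_stated_geometry(self):
        geom = msi.GridGeometry(stage_speed=0.02, cycle_period=1.55, line_step=100)
        assert geom.pixel_size == (31.0, 100)

    def test_from_rate_converts_hz(self):
        geom = msi.GridGeometry.from_rate(0.02, 1.0 / 1.55, 100)
        assert geom.pixel_size[0] == pytest.approx(31.0)

    def test_positive_parameters_required(self):
        with pytest.raises(ValueError):
            msi.GridGeometry(0.0, 1.55, 100)


class TestAssembleGrid:
    def test_single_line_shape(self):
        scans = [
            MassSpectrum(np.array([333.2]), np.array([float(i)]), ms_level=3,
                         precursor_chain=(459.13, 441.12), scan_time=i * 1.55,
                         analyzer=LOW_RES)
            for i in range(7)
        ]
        geom = msi.GridGeometry(0.02, 1.55, 100, 1)
        images = msi.assemble_grid([scans], geom, ion_trap_channels())
        assert images["333"].shape == (1, 7)
        np.testing.assert_allclose(images["333"].values[0], np.arange(7.0))
        assert images["333"].pixel_size == (31.0, 100)

    def test_sim_channel_uses_nearest_ms1_scan(self):
        line = []
        for i in range(4):
            line.append(MassSpectrum(np.array([459.1295]), np.array([100.0 + i]),
                                     ms_level=1, scan_time=i * 1.55 + 0.6,
                                     analyzer=HIGH_RES))
            line.append(MassSpectrum(np.array([333.2]), np.array([50.0]), ms_level=3,
                                     precursor_chain=(459.13, 441.12),
                                     scan_time=i * 1.55, analyzer=LOW_RES))
        channels = [ProductIonChannel("prec", 459.1295, "ppm", 5.0, ms_level=1),
                    ProductIonChannel("333", 333.206, "amu", 0.4, ms_level=3)]
        geom = msi.GridGeometry(0.02, 1.55, 100, 1)
        images = msi.assemble_grid([line], geom, channels)
        np.testing.assert_allclose(images["prec"].values[0], [100, 101, 102, 103])

    def test_empty_line_rejected(self):
        geom = msi.GridGeometry(0.02, 1.55, 100, 1)
        with pytest.raises(ValueError):
            msi.assemble_grid([[]], geom, ion_trap_channels())


class TestQuantifyChannel:
    def test_unity_ratio_gives_standard_concentration(self):
        a = _img(np.full((4, 4), 200.0))
        out = msi.quantify_channel(a, a, standard_conc=0.5)
        np.testing.assert_allclose(out.values, 0.5)
        assert out.units == "uM"

    def test_zero_analyte_and_linearity(self):
        std = _img(np.full((2, 2), 50.0))
        zero = msi.quantify_channel(_img(np.zeros((2, 2))), std, 0.5)
        np.testing.assert_allclose(zero.values, 0.0)
        one = msi.quantify_channel(_img(np.full((2, 2), 10.0)), std, 0.5)
        two = msi.quantify_channel(_img(np.full((2, 2), 20.0)), std, 0.5)
        np.testing.assert_allclose(two.values, 2 * one.values)

    def test_scale_invariance(self):
        rng = np.random.default_rng(4)
        a = _img(rng.uniform(1, 100, (5, 5)))
        s = _img(rng.uniform(1, 100, (5, 5)))
        base = msi.quantify_channel(a, s, 0.5)
        scaled = msi.quantify_channel(_img(a.values * 7.3), _img(s.values * 7.3), 0.5)
        np.testing.assert_allclose(scaled.values, base.values, rtol=1e-12)

    def test_zero_standard_pixel_invalid(self):
        s = _img([[50.0, 0.0]])
        out = msi.quantify_channel(_img([[10.0, 10.0]]), s, 0.5)
        assert out.mask[0, 0] and not out.mask[0, 1]
        assert np.isnan(out.values[0, 1])

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            msi.quantify_channel(_img(np.ones((2, 2))), _img(np.ones((3, 2))), 0.5)


class TestTissueMask:
    def test_threshold_is_inclusive(self):
        below = msi.tissue_mask(_img(np.full((3, 3), 29.0)))
        at = msi.tissue_mask(_img(np.full((3, 3), 30.0)))
        assert not below.any()
        assert at.all()

    def test_idempotent_and_commutative_with_snr(self):
        rng = np.random.default_rng(12)
        vals = rng.uniform(0, 100, (10, 30))
        img = _img(vals)
        mask = msi.tissue_mask(img)
        # idempotence: masking the masked image again changes nothing
        np.testing.assert_array_equal(mask, msi.tissue_mask(img))
        off = ~mask
        if off.sum() >= 20:
            incl = msi.snr_filter({"c": img}, off)["c"]
            # order-commutative: combined retention is an intersection
            np.testing.assert_array_equal(mask & incl, incl & mask)


class TestSnrFilter:
    def _setup(self):
        vals = np.zeros((6, 10))
        vals[:3] = 10.0  # off-tissue rows: constant noise level 10
        vals[3] = 60.0   # S/N 6 -> included
        vals[4] = 40.0   # S/N 4 -> excluded
        vals[5] = 51.0   # S/N 5.1 -> included (strictly above 5)
        off = np.zeros((6, 10), dtype=bool)
        off[:3] = True
        return _img(vals), off

    def test_snr_cutoff_strictly_above_five(self):
        img, off = self._setup()
        incl = msi.snr_filter({"c": img}, off)["c"]
        assert incl[3].all() and incl[5].all()
        assert not incl[4].any()

    def test_all_zero_channel_fully_excluded(self):
        img = _img(np.zeros((6, 10)))
        off = np.zeros((6, 10), dtype=bool)
        off[:3] = True
        assert not msi.snr_filter({"c": img}, off)["c"].any()

    def test_requires_enough_off_tissue_pixels(self):
        img, _ = self._setup()
        off = np.zeros((6, 10), dtype=bool)
        off[0, :5] = True
        with pytest.raises(ValueError):
            msi.snr_filter({"c": img}, off)
        # explicit noise level bypasses the estimation requirement
        incl = msi.snr_filter({"c": img}, off, noise_levels={"c": 10.0})["c"]
        assert incl[3].all()

    def test_robust_noise_is_median_plus_mad(self):
        vals = np.array([8.0, 10.0, 12.0, 9.0, 11.0, 100.0])
        med = 10.5
        mad = np.median(np.abs(vals - med))
        assert msi.robust_noise(vals) == pytest.approx(med + 1.4826 * mad)


@pytest.fixture(scope="module")
def model():
    return cal.fit_model(syn.make_training_set(noise=syn.NOISELESS))


class TestPredictImage:
    def _images(self, model):
        comps = [
            cal.IsomerComposition.of(35, 15, 50),
            cal.IsomerComposition.of(100, 0, 0),
        ]
        shape = (2, 3)
        vals = {k: np.zeros(shape) for k in ("331", "333", "341")}
        for row, comp in enumerate(comps):
            t = syn.simulate_triplet(comp)
            vals["331"][row] = t.i331
            vals["333"][row] = t.i333
            vals["341"][row] = t.i341
        return {k: _img(v) for k, v in vals.items()}

    def test_valid_pixels_close_to_100(self, model):
        images = self._images(model)
        mask = np.ones((2, 3), dtype=bool)
        fractions, valid = msi.predict_image(model, images, mask)
        assert valid.all()
        total = sum(fractions[k].values for k in fractions)
        np.testing.assert_allclose(total[valid], 100.0, atol=1e-9)

    def test_pixel_failing_any_channel_invalid_everywhere(self, model):
        images = self._images(model)
        mask = np.ones((2, 3), dtype=bool)
        inclusion = {k: np.ones((2, 3), dtype=bool) for k in images}
        inclusion["341"][1, 2] = False
        fractions, valid = msi.predict_image(model, images, mask, inclusion)
        assert not valid[1, 2]
        for img in fractions.values():
            assert np.isnan(img.values[1, 2]) and not img.mask[1, 2]

    def test_render_clips_out_of_range_to_zero(self):
        img = _img([[50.0, 104.0, -3.0]], mask=np.array([[True, True, True]]))
        shown = msi.render_fraction(img)
        np.testing.assert_allclose(shown, [[50.0, 0.0, 0.0]])


class TestRoiStats:
    def _uniform_fraction_images(self, value=40.0, shape=(4, 5)):
        out = {}
        for iso, v in zip(("PGE2", "PGD2", "d12-PGD2"), (value, 100 - value - 10, 10.0)):
            out[iso] = _img(np.full(shape, float(v)), units="%")
        return out

    def test_uniform_roi(self):
        fr = self._uniform_fraction_images()
        res = msi.roi_stats(fr, np.ones((4, 5), dtype=bool))
        assert res.mean_pge2 == 40.0 and res.sd_pge2 == 0.0
        assert res.n_pixels == 20

    def test_whole_grid_roi_equals_grid_mean(self):
        rng = np.random.default_rng(6)
        fr = {iso: _img(rng.uniform(0, 100, (6, 6)), units="%")
              for iso in ("PGE2", "PGD2", "d12-PGD2")}
        res = msi.roi_stats(fr, np.ones((6, 6), dtype=bool))
        assert res.mean_pgd2 == pytest.approx(fr["PGD2"].values.mean())

    def test_roi_off_mask_rejected(self):
        fr = self._uniform_fraction_images()
        for img in fr.values():
            img.mask[:] = False
        with pytest.raises(ValueError):
            msi.roi_stats(fr, np.ones((4, 5), dtype=bool))
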