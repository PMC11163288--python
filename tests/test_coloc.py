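import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from skimage.draw import disk

from condenstat import (
    PairPCC,
    integrated_intensity_vs_size,
    pair_pcc,
    pcc_vs_size,
    radial_profile,
)


class TestRadialProfile:
    def test_uniform_image_is_flat(self):
        img = np.full((64, 64), 7.0)
        prof = radial_profile(img, [(3.2, 3.2, 0.8)], 0.1, normalize="none")
        vals = prof.mean[~np.isnan(prof.mean)]
        np.testing.assert_allclose(vals, 7.0)

    def test_annulus_peaks_at_unit_radius(self):
        img = np.zeros((128, 128))
        yy, xx = np.mgrid[0:128, 0:128]
        r = np.hypot(yy - 64, xx - 64)
        img[np.abs(r - 20) < 1.5] = 100.0
        prof = radial_profile(img, [(6.4, 6.4, 2.0)], 0.1)
        assert prof.peak_bin_center == pytest.approx(0.95, abs=0.101)

    def test_center_outside_roi_skipped_with_warning(self):
        from condenstat import CellROI
        img = np.ones((32, 32))
        mask = np.zeros((32, 32), bool)
        mask[:16] = True
        roi = CellROI("c", mask)
        with pytest.warns(UserWarning, match="skipped"):
            prof = radial_profile(img, [(0.5, 0.5, 0.3), (3.0, 1.6, 0.3)],
                                  0.1, roi=roi)
        assert prof.n_condensates == 1

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(ValueError):
            radial_profile(np.ones((8, 8)), [(0.4, 0.4, 0.0)], 0.1)


class TestPairPCC:
    img = np.zeros((4, 4))
    img[0, :2] = 1  # a = [1, 0, 1, 0] over the 2x2 block
    a = np.array([[1, 0], [1, 0]], float)
    b = np.array([[1, 0], [0, 1]], float)
    m = np.ones((2, 2), bool)

    def test_hand_computed_zero_case(self):
        assert pair_pcc(self.a, self.b, self.m, self.m).pcc == pytest.approx(0.0)

    def test_perfect_and_inverted_correlation(self):
        assert pair_pcc(self.a, 2 * self.a, self.m, self.m).pcc == pytest.approx(1.0)
        assert pair_pcc(self.a, -self.a + 3, self.m, self.m).pcc == pytest.approx(-1.0)

    def test_zero_variance_flagged_not_zero(self):
        out = pair_pcc(self.a, np.ones((2, 2)), self.m, self.m)
        assert not out.defined and np.isnan(out.pcc)

    def test_disjoint_objects_rejected(self):
        ma = np.zeros((16, 16), bool)
        mb = np.zeros((16, 16), bool)
        ma[0:2, 0:2] = True
        mb[10:12, 10:12] = True
        img = np.random.default_rng(0).random((16, 16))
        with pytest.raises(ValueError, match="contact"):
            pair_pcc(img, img, ma, mb)

    def test_touching_after_dilation_is_contact(self):
        ma = np.zeros((8, 8), bool)
        mb = np.zeros((8, 8), bool)
        ma[2, 2] = True
        mb[2, 5] = True  # 3 px apart: dilated masks touch but do not overlap
        img = np.arange(64, dtype=float).reshape(8, 8)
        out = pair_pcc(img, img**1, ma, mb)
        assert out.defined

    @given(
        gain_a=st.floats(0.1, 10), off_a=st.floats(-5, 5),
        gain_b=st.floats(0.1, 10), off_b=st.floats(-5, 5),
    )
    @settings(max_examples=40, derandomize=True, deadline=None)
    def test_affine_invariance(self, gain_a, off_a, gain_b, off_b):
        rng = np.random.default_rng(7)
        img_a = rng.random((6, 6))
        img_b = rng.random((6, 6))
        m = np.zeros((6, 6), bool)
        m[2:5, 2:5] = True
        base = pair_pcc(img_a, img_b, m, m).pcc
        scaled = pair_pcc(gain_a * img_a + off_a, gain_b * img_b + off_b, m, m).pcc
        assert scaled == pytest.approx(base, abs=1e-9)


class TestPCCvsSize:
    def test_identical_pccs_average_exactly(self):
        pairs = [PairPCC(r, 0.7, 20) for r in (0.2, 0.4, 1.1, 1.3)]
        out = pcc_vs_size(pairs, [0, 1, 2])
        assert out.mean_pcc.tolist() == [0.7, 0.7]
        np.testing.assert_allclose(out.se.fillna(0), 0.0)

    def test_empty_bins_omitted(self):
        pairs = [PairPCC(0.5, 0.5, 20)]
        out = pcc_vs_size(pairs, [0, 1, 2, 3])
        assert len(out) == 1 and out.bin_center_um[0] == 0.5

    def test_single_pair_bin_has_undefined_se(self):
        out = pcc_vs_size([PairPCC(0.5, 0.5, 20)], [0, 1])
        assert np.isnan(out.se[0])

    def test_increasing_trend_recovered(self, rng):
        radii = rng.uniform(0.1, 2.0, 200)
        pccs = np.clip(0.3 + 0.3 * radii + rng.normal(0, 0.05, 200), -1, 1)
        out = pcc_vs_size(pd.DataFrame({
            "equivalent_radius_um": radii, "pcc": pccs}), np.linspace(0, 2, 6))
        assert (np.diff(out.mean_pcc) > 0).all()


class TestRenderedPairTrend:
    def test_colabelled_large_aggregates_raise_pcc_with_size(self):
        """Pairs rendered with size-dependent overlap (small aggregates only
        touching the scaffold blob, large ones fully co-labelled) reproduce
        an increasing PCC-vs-radius trend."""
        from condenstat.simulate import render_contact_pair

        radii = np.linspace(0.3, 1.5, 24)
        pairs = []
        for i, r in enumerate(radii):
            overlap = min(1.0, (r - 0.3) / 1.2)
            img_a, img_b, ma, mb = render_contact_pair(r, overlap, seed=i)
            pairs.append(pair_pcc(img_a, img_b, ma, mb, equivalent_radius_um=r))
        out = pcc_vs_size(pairs, [0.2, 0.6, 1.0, 1.6])
        rho = np.corrcoef(out.bin_center_um, out.mean_pcc)[0, 1]
        assert rho > 0
        assert out.mean_pcc.iloc[-1] > out.mean_pcc.iloc[0] + 0.2


class TestIntegratedIntensityVsSize:
    def make_objects(self):
        areas = np.array([0.5, 1.0, 2.0, 4.0])
        return pd.DataFrame({
            "area_um2": areas,
            "intint_ub": 300.0 * areas,
            "intint_p62": 120.0 * areas,
        })

    def test_each_channel_max_is_exactly_one(self):
        out = integrated_intensity_vs_size(self.make_objects(), ["ub", "p62"])
        assert out.ub_norm.max() == 1.0 and out.p62_norm.max() == 1.0

    def test_intensity_proportional_to_area_normalizes_to_area_ratio(self):
        out = integrated_intensity_vs_size(self.make_objects(), ["ub"])
        np.testing.assert_allclose(out.ub_norm, out.area_um2 / out.area_um2.max())

    def test_single_object_gives_single_unit_point(self):
        df = self.make_objects().iloc[:1]
        out = integrated_intensity_vs_size(df, ["ub"])
        assert len(out) == 1 and out.ub_norm[0] == 1.0

    def test_zero_channel_maximum_rejected(self):
        df = self.make_objects()
        df["intint_ub"] = 0.0
        with pytest.raises(ValueError):
            integrated_intensity_vs_size(df, ["ub"])
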