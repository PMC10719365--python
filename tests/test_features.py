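"""Chrometric feature extraction: morphology, boundary curvature, intensity
statistics, image moments and the HC/EC partition."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sstats

from chromascope.features import (
    assemble_profile,
    boundary_features,
    feature_catalog,
    hc_ec_features,
    intensity_features,
    moment_features,
    morphology_features,
    quantify_marker,
    write_feature_dictionary,
)
from chromascope.io import AcquisitionSpec
from chromascope.segmentation import segment_nucleus_3d
from conftest import disc_mask, ellipsoid_mask
from test_segmentation import _record_from_mask


@pytest.fixture
def acq3():
    return AcquisitionSpec(channel_map={"DAPI": 0, "gH2AX": 1, "CD3": 2})


class TestMorphology:
    def test_volume_in_physical_units(self, acq):
        mask3d = np.zeros((10, 20, 20), bool)
        mask3d.ravel()[:1000] = True
        mask3d = mask3d.reshape(10, 20, 20)
        f = morphology_features(mask3d, mask3d.any(axis=0), acq)
        assert f["volume_um3"] == pytest.approx(1000 * 0.09 * 0.09 * 0.5)  # 4.05

    def test_convex_shape_has_zero_concavity(self, px_spec):
        disc = disc_mask((80, 80), (40, 40), 30)
        mask3d = np.broadcast_to(disc, (5, 80, 80)).copy()
        f = morphology_features(mask3d, disc, px_spec)
        # rasterization leaves a small residual hull excess (~2% at r=30)
        assert f["concavity_2d"] == pytest.approx(0.0, abs=0.03)

    def test_crescent_concavity_matches_hull_oracle(self, px_spec):
        from skimage.morphology import convex_hull_image

        crescent = disc_mask((80, 80), (40, 40), 25) & ~disc_mask((80, 80), (40, 52), 20)
        mask3d = np.broadcast_to(crescent, (4, 80, 80)).copy()
        f = morphology_features(mask3d, crescent, px_spec)
        expected = 1.0 - crescent.sum() / convex_hull_image(crescent).sum()
        assert f["concavity_2d"] == pytest.approx(expected, abs=1e-6)

    def test_ellipsoid_volume_close_to_analytic(self, acq):
        # semi-axes 2.7 x 2.7 x 2.0 um on the anisotropic grid
        a_px, c_px = 2.7 / 0.09, 2.0 / 0.5
        mask = ellipsoid_mask((17, 80, 80), (8, 40, 40), (c_px, a_px, a_px))
        f = morphology_features(mask, mask.any(axis=0), acq)
        analytic = 4 / 3 * math.pi * 2.7 * 2.7 * 2.0
        assert f["volume_um3"] == pytest.approx(analytic, rel=0.10)

    def test_translation_invariance(self, acq):
        m1 = ellipsoid_mask((15, 60, 60), (7, 25, 25), (4, 15, 18))
        m2 = np.roll(m1, (3, 5), axis=(1, 2))
        f1 = morphology_features(m1, m1.any(axis=0), acq)
        f2 = morphology_features(m2, m2.any(axis=0), acq)
        for k in f1:
            assert f1[k] == pytest.approx(f2[k], nan_ok=True), k

    def test_single_plane_mask_flags_3d_concavity(self, acq):
        m = np.zeros((5, 40, 40), bool)
        m[2] = disc_mask((40, 40), (20, 20), 10)
        f = morphology_features(m, m.any(axis=0), acq)
        assert math.isnan(f["concavity_3d"])
        assert f["height_um"] == pytest.approx(0.5)


class TestBoundary:
    def test_circle_curvature_is_inverse_radius(self, px_spec):
        r = 30
        circle = disc_mask((90, 90), (45, 45), r)
        f = boundary_features(circle, px_spec)
        assert f["curvature_mean_abs"] == pytest.approx(1 / r, rel=0.05)
        assert f["curvature_sd"] < 0.3 * f["curvature_mean_abs"]  # ~constant

    def test_ellipse_more_variable_than_circle(self, px_spec):
        circle = disc_mask((90, 90), (45, 45), 30)
        yy, xx = np.mgrid[:140, :140]
        ellipse = ((yy - 70) / 25) ** 2 + ((xx - 70) / 50) ** 2 <= 1
        assert (
            boundary_features(ellipse, px_spec)["curvature_sd"]
            > boundary_features(circle, px_spec)["curvature_sd"]
        )

    def test_physical_units_scale(self, acq, px_spec):
        circle = disc_mask((90, 90), (45, 45), 30)
        f_px = boundary_features(circle, px_spec)
        f_um = boundary_features(circle, acq)
        assert f_um["curvature_mean_abs"] == pytest.approx(f_px["curvature_mean_abs"] / 0.09, rel=1e-6)


class TestIntensity:
    def test_constant_nucleus(self):
        mask = np.ones((4, 5, 5), bool)
        f = intensity_features(np.full((4, 5, 5), 0.6), mask)
        assert f["intensity_mean"] == pytest.approx(0.6)
        assert f["intensity_sd"] == 0.0
        assert f["intensity_entropy"] == 0.0

    def test_two_level_entropy_one_bit(self):
        vals = np.concatenate([np.full(500, 0.2), np.full(500, 0.8)])
        crop = vals.reshape(10, 10, 10)
        f = intensity_features(crop, np.ones((10, 10, 10), bool))
        assert f["intensity_entropy"] == pytest.approx(1.0)

    def test_moments_match_direct_formulas(self, rng):
        vals = rng.random(1000)
        crop = vals.reshape(10, 10, 10)
        f = intensity_features(crop, np.ones((10, 10, 10), bool))
        assert f["intensity_mean"] == pytest.approx(vals.mean())
        assert f["intensity_sd"] == pytest.approx(vals.std())
        assert f["intensity_skew"] == pytest.approx(sstats.skew(vals))
        assert f["intensity_kurtosis"] == pytest.approx(sstats.kurtosis(vals))
        assert f["intensity_q50"] == pytest.approx(np.median(vals))


class TestMoments:
    def test_symmetric_blob_third_order_vanishes(self):
        disc = disc_mask((61, 61), (30, 30), 15).astype(float)
        f = moment_features(disc, disc > 0)
        for k in ("moment_mu30", "moment_mu03", "moment_mu21", "moment_mu12"):
            assert abs(f[k]) < 1e-6 * abs(f["moment_mu20"]) ** 1.5 + 1e-9

    def test_hu_invariant_under_rotation(self, rng):
        img = np.zeros((64, 64))
        img[20:40, 25:45] = rng.random((20, 20))
        mask = img > 0
        f0 = moment_features(img, mask)
        img90 = np.rot90(img)
        f90 = moment_features(img90, img90 > 0)
        for i in range(1, 7):  # hu7 is reflection-sensitive by design
            assert f0[f"moment_hu{i}"] == pytest.approx(f90[f"moment_hu{i}"], rel=1e-8, abs=1e-12)

    def test_central_moments_translation_invariant(self, rng):
        img = np.zeros((64, 64))
        img[10:30, 10:30] = rng.random((20, 20))
        shifted = np.roll(img, (15, 12), axis=(0, 1))
        f0 = moment_features(img, img > 0)
        f1 = moment_features(shifted, shifted > 0)
        for k in f0:
            assert f0[k] == pytest.approx(f1[k], rel=1e-9, abs=1e-12), k


class TestHcEc:
    def test_planted_two_level_texture(self, acq, rng):
        mask = np.ones((10, 10, 10), bool)
        vals = np.full(1000, 0.3)
        hi = rng.choice(1000, size=300, replace=False)
        vals[hi] = 0.9
        f = hc_ec_features(vals.reshape(10, 10, 10), mask, acq)
        assert f["hc_volume_fraction"] == pytest.approx(0.30, abs=0.01)
        assert f["hc_volume_um3"] == pytest.approx(300 * acq.voxel_volume_um3)

    def test_uniform_nucleus_flagged(self, acq):
        f = hc_ec_features(np.full((5, 5, 5), 0.5), np.ones((5, 5, 5), bool), acq)
        assert math.isnan(f["hc_volume_fraction"])

    def test_partition_conserves_volume(self, acq, rng):
        mask = rng.random((8, 12, 12)) > 0.4
        crop = rng.random((8, 12, 12))
        f = hc_ec_features(crop, mask, acq)
        total = mask.sum() * acq.voxel_volume_um3
        hc = f["hc_volume_um3"]
        ec = total - hc
        assert hc + ec == pytest.approx(total)
        assert f["hc_volume_fraction"] == pytest.approx(hc / total)


class TestMarkerQuant:
    def test_uniform_intensity(self):
        mask = disc_mask((30, 30), (15, 15), 6)
        mask = mask & (np.arange(900).reshape(30, 30) >= 0)
        img = np.full((30, 30), 5.0)
        # use exactly 100 in-mask pixels
        flat = np.zeros((30, 30), bool)
        flat.ravel()[:100] = True
        q = quantify_marker(img, flat, "CD3")
        assert q.total_intensity == pytest.approx(500.0)
        assert q.area_norm_intensity == pytest.approx(5.0)

    def test_outside_mask_ignored_and_linear(self, rng):
        img = rng.random((20, 20))
        mask = np.zeros((20, 20), bool)
        mask[5:10, 5:10] = True
        q1 = quantify_marker(img, mask)
        img_out = img.copy()
        img_out[~mask] = 999.0
        assert quantify_marker(img_out, mask).total_intensity == pytest.approx(q1.total_intensity)
        q2 = quantify_marker(2 * img, mask)
        assert q2.total_intensity == pytest.approx(2 * q1.total_intensity)
        assert q2.area_norm_intensity == pytest.approx(2 * q1.area_norm_intensity)

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError, match="empty mask"):
            quantify_marker(np.ones((5, 5)), np.zeros((5, 5), bool))


class TestAssembleProfile:
    def _passing_record(self, acq3, seed=0):
        rng = np.random.default_rng(seed)
        truth = ellipsoid_mask((15, 80, 80), (7, 40, 40), (5, 28, 28))
        rec = _record_from_mask(truth, spec=acq3)
        crop = np.zeros((3, 15, 80, 80))
        crop[0] = (0.4 + 0.5 * rng.random((15, 80, 80))) * truth
        crop[1] = 0.2 * truth
        crop[2] = 0.3 * truth
        rec.crop = crop
        return segment_nucleus_3d(rec)

    def test_deterministic_and_complete(self, acq3):
        rec = self._passing_record(acq3)
        p1, p2 = assemble_profile(rec), assemble_profile(rec)
        assert p1 == p2
        for name in feature_catalog():
            assert name in p1
        assert "marker_gH2AX_area_norm" in p1 and "marker_CD3_total" in p1
        # no missing values for a QC-passing nucleus (hc/ec defined here)
        numeric = {k: v for k, v in p1.items() if isinstance(v, float)}
        assert all(np.isfinite(v) for v in numeric.values())

    def test_rejected_record_raises(self, acq3):
        rec = self._passing_record(acq3)
        rec.qc_pass = False
        with pytest.raises(ValueError, match="QC-passing"):
            assemble_profile(rec)

    def test_table_round_trip(self, acq3, tmp_path):
        rows = [self._passing_record(acq3, s) for s in (0, 1)]
        df = pd.DataFrame([assemble_profile(r) for r in rows])
        assert len({len(assemble_profile(r)) for r in rows}) == 1  # stable length
        path = tmp_path / "t.csv"
        df.to_csv(path, index=False)
        back = pd.read_csv(path)
        feats = [c for c in df.columns if df[c].dtype.kind == "f"]
        np.testing.assert_allclose(back[feats].to_numpy(), df[feats].to_numpy(), rtol=1e-12)

    def test_feature_dictionary_export(self, tmp_path):
        import json

        path = write_feature_dictionary(tmp_path / "features.json")
        entries = json.loads(path.read_text())
        assert {e["category"] for e in entries} == {"morphology", "boundary", "intensity", "moments", "hc_ec"}
        assert {e["name"] for e in entries} == set(feature_catalog())
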