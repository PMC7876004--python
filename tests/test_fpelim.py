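"""Shape features, standardization, quadratic-kernel SVM filtering."""

import numpy as np
import pandas as pd
import pytest

from wm3dseg.fpelim import (FEATURE_NAMES, apply_fp_filter,
                            component_features, logo_evaluate, standardize,
                            train_fp_classifier)
from wm3dseg.volume import LabelVolume


def _feature_frame(points, fill=1.0):
    """2D point cloud embedded in the 6-feature table (other columns
    constant); lets classifier tests use controlled geometry."""
    n = len(points)
    arr = np.full((n, 6), fill)
    arr[:, 0] = points[:, 0]
    arr[:, 1] = points[:, 1]
    df = pd.DataFrame(arr, columns=FEATURE_NAMES)
    df["label"] = np.arange(1, n + 1)
    return df


class TestComponentFeatures:
    def test_cube_closed_forms(self):
        vol = np.zeros((42, 42, 42), np.int32)
        vol[6:36, 6:36, 6:36] = 1          # 30^3 cube, 3-aligned
        f = component_features(LabelVolume(vol), scale_factor=3).iloc[0]
        assert f.volume == 1000
        assert f.extent == pytest.approx(1.0)
        assert f.solidity == pytest.approx(1.0, abs=0.01)
        assert f.equivalent_diameter == pytest.approx((6000 / np.pi) ** (1 / 3),
                                                      rel=1e-6)

    def test_ball_extent_and_solidity(self):
        zz, yy, xx = np.indices((30, 30, 30))
        vol = (((zz - 15) ** 2 + (yy - 15) ** 2 + (xx - 15) ** 2) <= 81)
        f = component_features(LabelVolume(vol.astype(np.int32)),
                               scale_factor=3).iloc[0]
        assert f.solidity >= 0.95
        assert f.extent == pytest.approx(np.pi / 6, abs=0.08)

    def test_l_shape_not_convex(self):
        vol = np.zeros((30, 30, 30), np.int32)
        vol[3:27, 3:12, 3:12] = 1
        vol[3:12, 3:27, 3:12] = 1
        f = component_features(LabelVolume(vol), scale_factor=3).iloc[0]
        assert f.solidity < 0.95

    def test_invariance_to_renumbering_and_translation(self):
        vol = np.zeros((36, 36, 36), np.int32)
        vol[3:15, 3:15, 3:15] = 5
        f1 = component_features(LabelVolume(vol), 3)
        vol2 = np.zeros_like(vol)
        vol2[21:33, 21:33, 21:33] = 9
        f2 = component_features(LabelVolume(vol2), 3)
        a = f1[FEATURE_NAMES].to_numpy()
        b = f2[FEATURE_NAMES].to_numpy()
        assert np.allclose(a, b, rtol=0.05)


class TestStandardize:
    def test_two_value_column(self):
        df = _feature_frame(np.array([[1.0, 1.0], [3.0, 3.0]]))
        with pytest.warns(UserWarning):     # constant filler columns
            out, stats = standardize(df)
        assert out[FEATURE_NAMES[0]].tolist() == [-1.0, 1.0]

    def test_reuse_of_fit_stats(self):
        rng = np.random.default_rng(0)
        df = _feature_frame(rng.normal(5, 2, (20, 2)))
        with pytest.warns(UserWarning):
            out, stats = standardize(df)
        with pytest.warns(UserWarning):
            again, _ = standardize(df)
        reused, _ = standardize(df, fit_stats=stats)
        assert np.allclose(out[FEATURE_NAMES].to_numpy(),
                           reused[FEATURE_NAMES].to_numpy())

    def test_single_row_fit_rejected(self):
        df = _feature_frame(np.array([[1.0, 2.0]]))
        with pytest.raises(ValueError):
            standardize(df)


class TestClassifier:
    def test_separable_blobs_perfect(self):
        rng = np.random.default_rng(0)
        pts = np.vstack([rng.normal(0, 0.4, (30, 2)) + 3,
                         rng.normal(0, 0.4, (30, 2))])
        df = _feature_frame(pts)
        y = np.array([True] * 30 + [False] * 30)
        model = train_fp_classifier(df, y, seed=0)
        assert (model.decision(df) == y).mean() == 1.0

    def test_xor_needs_quadratic_kernel(self):
        rng = np.random.default_rng(1)
        a = np.vstack([rng.normal(0, 0.3, (25, 2)) + [2, 2],
                       rng.normal(0, 0.3, (25, 2)) - [2, 2]])
        b = np.vstack([rng.normal(0, 0.3, (25, 2)) + [2, -2],
                       rng.normal(0, 0.3, (25, 2)) + [-2, 2]])
        df = _feature_frame(np.vstack([a, b]))
        y = np.array([True] * 50 + [False] * 50)
        model = train_fp_classifier(df, y, seed=0)
        assert (model.decision(df) == y).mean() >= 0.95

    def test_seeded_determinism(self):
        rng = np.random.default_rng(2)
        df = _feature_frame(rng.normal(0, 1, (40, 2))
                            + np.repeat([[0], [2]], 20, axis=0))
        y = np.array([False] * 20 + [True] * 20)
        m1 = train_fp_classifier(df, y, seed=3)
        m2 = train_fp_classifier(df, y, seed=3)
        assert (m1.C, m1.sigma) == (m2.C, m2.sigma)

    def test_single_class_rejected(self):
        df = _feature_frame(np.zeros((4, 2)))
        with pytest.raises(ValueError):
            train_fp_classifier(df, [True] * 4)


class TestApplyFilter:
    def test_rejected_components_removed_survivors_untouched(self):
        vol = np.zeros((36, 36, 36), np.int32)
        vol[3:15, 3:15, 3:15] = 1
        vol[21:33, 21:33, 21:33] = 2
        labels = LabelVolume(vol)
        feats = component_features(labels, 3)

        class FakeModel:
            def decision(self, features):
                return features["label"].to_numpy() == 1

        out = apply_fp_filter(FakeModel(), labels, feats)
        assert np.array_equal(out.data == 1, vol == 1)
        assert not (out.data == 2).any()


class TestLogo:
    def test_identical_groups_perfect_f1(self):
        rng = np.random.default_rng(4)
        pts = np.vstack([rng.normal(0, 0.3, (20, 2)) + 3,
                         rng.normal(0, 0.3, (20, 2))] * 2)
        df = _feature_frame(pts)
        y = np.array(([True] * 20 + [False] * 20) * 2)
        groups = np.array([0] * 40 + [1] * 40)
        res = logo_evaluate(df, y, groups, seed=0)
        assert (res["f1"] >= 0.99).all()

    def test_label_flipped_group_scores_zero(self):
        rng = np.random.default_rng(5)
        pts = np.vstack([rng.normal(0, 0.3, (20, 2)) + 3,
                         rng.normal(0, 0.3, (20, 2))] * 2)
        df = _feature_frame(pts)
        y = np.array([True] * 20 + [False] * 20
                     + [False] * 20 + [True] * 20)   # group 1 flipped
        groups = np.array([0] * 40 + [1] * 40)
        res = logo_evaluate(df, y, groups, seed=0)
        assert res.loc[res.group == 1, "f1"].iloc[0] <= 0.1

    def test_single_group_rejected(self):
        df = _feature_frame(np.zeros((4, 2)))
        with pytest.raises(ValueError):
            logo_evaluate(df, [True, False, True, False], [0, 0, 0, 0])
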