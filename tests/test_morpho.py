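"""Axon morphometry: cross-sections, tortuosity, inter-mitochondrial
distances, densities."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wm3dseg.csd import SubSkeleton
from wm3dseg.morpho import (axon_cross_sections, densities,
                            inter_mito_distances_centroid,
                            inter_mito_distances_shortest, summarize_axon,
                            tortuosity)
from wm3dseg.volume import LabelVolume


def straight_psi(n=50, z0=5, radius=5.0):
    pts = np.stack((np.arange(z0, z0 + n, dtype=float),
                    np.full(n, 24.0), np.full(n, 24.0)), axis=1)
    return SubSkeleton(pts, np.full(n, radius), [0], [])


class TestTortuosity:
    def test_straight_segment_is_one(self):
        assert tortuosity(np.array([[0, 0, 0], [5, 5, 5.0]])) == \
            pytest.approx(1.0)

    def test_semicircle_closed_form(self):
        th = np.linspace(0, np.pi, 500)
        arc = np.stack((np.zeros_like(th), 10 * np.cos(th),
                        10 * np.sin(th)), axis=1)
        assert tortuosity(arc) == pytest.approx(np.pi / 2, rel=1e-3)

    def test_helix_closed_form(self):
        t = np.linspace(0, 2 * np.pi, 3000)
        helix = np.stack((t, np.cos(t), np.sin(t)), axis=1)
        assert tortuosity(helix) == pytest.approx(np.sqrt(2), rel=1e-3)

    def test_closed_loop_rejected(self):
        th = np.linspace(0, 2 * np.pi, 30)
        loop = np.stack((np.zeros_like(th), np.cos(th), np.sin(th)), axis=1)
        loop[-1] = loop[0]
        with pytest.raises(ValueError):
            tortuosity(loop)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_at_least_one_for_random_smooth_curves(self, seed):
        rng = np.random.default_rng(seed)
        steps = rng.normal(0, 1, (20, 3)).cumsum(axis=0)
        if np.linalg.norm(steps[-1] - steps[0]) < 1e-9:
            return
        assert tortuosity(steps) >= 1 - 1e-6


class TestCrossSections:
    def _cylinder(self, ry, rx):
        zz, yy, xx = np.indices((60, 48, 48))
        return ((yy - 24.0) / ry) ** 2 + ((xx - 24.0) / rx) ** 2 <= 1.0

    def test_circular_tube_diameter(self):
        mask = self._cylinder(5, 5)             # radius 0.25 um at 50 nm
        cs = axon_cross_sections(mask, straight_psi(), spacing_um=0.2)
        assert abs(cs["diameter_um"].median() - 0.5) <= 0.05
        assert cs["eccentricity"].median() <= 0.3

    def test_elliptic_tube_eccentricity(self):
        mask = self._cylinder(10, 5)            # 2:1 ellipse
        cs = axon_cross_sections(mask, straight_psi(), spacing_um=0.2)
        assert cs["eccentricity"].median() == pytest.approx(np.sqrt(1 - 0.25),
                                                            abs=0.05)

    def test_area_pi_um2_gives_diameter_2um(self):
        # closed form of the definition, independent of rasterization
        area = np.pi
        assert 2 * np.sqrt(area / np.pi) == pytest.approx(2.0)

    def test_diameter_bounded_by_major_axis(self):
        mask = self._cylinder(10, 5)
        cs = axon_cross_sections(mask, straight_psi(), spacing_um=0.2)
        # equivalent diameter of an ellipse <= its major axis length (1 um)
        assert (cs["diameter_um"] <= 1.0 + 0.05).all()


class TestInterMito:
    def _psi(self):
        return straight_psi(n=240, z0=5)

    def test_centroid_distance_arithmetic(self):
        psi = self._psi()
        mito = np.zeros((250, 48, 48), np.int32)
        for lab, z in ((1, 25), (2, 85), (3, 185)):   # arcs 20, 80, 180
            mito[z, 24, 24] = lab
        d = inter_mito_distances_centroid(psi, LabelVolume(mito), [1, 2, 3],
                                          vox_um=0.05)
        assert d == pytest.approx([60 * 0.05, 100 * 0.05])

    def test_single_mito_empty(self):
        psi = self._psi()
        mito = np.zeros((250, 48, 48), np.int32)
        mito[30, 24, 24] = 1
        assert inter_mito_distances_centroid(psi, LabelVolume(mito), [1]) == []

    def test_shortest_interval_arithmetic(self):
        psi = self._psi()
        mito = np.zeros((250, 48, 48), np.int32)
        mito[10:21, 24, 24] = 1        # arc interval [5, 15]
        mito[45:66, 24, 24] = 2        # arc interval [40, 60]
        d = inter_mito_distances_shortest(psi, LabelVolume(mito), [1, 2],
                                          vox_um=0.05)
        assert d == pytest.approx([25 * 0.05], abs=0.01)

    def test_overlapping_intervals_clamp_to_zero(self):
        psi = self._psi()
        mito = np.zeros((250, 48, 48), np.int32)
        mito[10:31, 24, 24] = 1
        mito[25:41, 23, 24] = 2
        d = inter_mito_distances_shortest(psi, LabelVolume(mito), [1, 2],
                                          vox_um=0.05)
        assert d == [0.0]

    def test_pointlike_mitos_agree_between_definitions(self):
        psi = self._psi()
        mito = np.zeros((250, 48, 48), np.int32)
        mito[30, 24, 24] = 1
        mito[90, 24, 24] = 2
        dc = inter_mito_distances_centroid(psi, LabelVolume(mito), [1, 2])
        ds = inter_mito_distances_shortest(psi, LabelVolume(mito), [1, 2])
        assert dc == pytest.approx(ds)


class TestDensities:
    def test_axon_density_arithmetic(self):
        shape = (10, 10, 10)
        axons = np.zeros(shape, np.int32)
        axons.ravel()[:300] = 1
        myelin = np.zeros(shape, bool)
        myelin.ravel()[300:1000] = True
        d = densities(LabelVolume(axons), myelin,
                      LabelVolume(np.zeros(shape, np.int32)))
        assert d.axon_density == pytest.approx(0.3)
        assert d.cell_density_per_um3 == 0.0

    def test_cell_density_units(self):
        shape = (20, 20, 20)     # 8000 voxels at 50 nm = 1 um^3
        nuc = np.zeros(shape, np.int32)
        nuc[2, 2, 2] = 1
        nuc[10, 10, 10] = 2
        ax = np.zeros(shape, np.int32)
        ax[0, 0, 0] = 1
        d = densities(LabelVolume(ax), np.zeros(shape, bool),
                      LabelVolume(nuc))
        assert d.cell_density_per_um3 == pytest.approx(2.0)

    def test_no_axons_or_myelin_rejected(self):
        shape = (4, 4, 4)
        with pytest.raises(ValueError):
            densities(LabelVolume(np.zeros(shape, np.int32)),
                      np.zeros(shape, bool),
                      LabelVolume(np.zeros(shape, np.int32)))


class TestSummary:
    def test_median_aggregation(self):
        zz, yy, xx = np.indices((60, 48, 48))
        mask = (yy - 24) ** 2 + (xx - 24) ** 2 <= 25
        rec = summarize_axon(1, mask, straight_psi())
        assert rec.tortuosity == pytest.approx(1.0, abs=1e-6)
        assert abs(rec.median_diameter_um - 0.5) < 0.06
        row = rec.as_row()
        assert np.isnan(row["mean_inter_mito_centroid_um"])
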