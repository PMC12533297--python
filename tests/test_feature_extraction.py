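import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lnmts import (
    LymphNodeFeatureExtractor,
    node_distance,
    node_volume,
    patient_features,
)
from lnmts.feature_extraction import equivalent_diameter, through_plane_distance

from conftest import build_volume


class TestNodeVolume:
    def test_single_slice_node_accumulated(self):
        # 10 voxels on one slice, 0.5 x 0.5 mm pixels -> N=10, V=2.5
        coords = [(1, 2, c) for c in range(10)]
        vol = build_volume({1: [(0, 0, 0)], 2: coords}, spacing=(0.5, 0.5))
        nf = node_volume(vol, 2, mode="accumulated")
        assert nf.pixel_count == 10
        assert nf.volume == pytest.approx(2.5)

    def test_modes_coincide_on_single_slice(self):
        coords = [(1, 2, c) for c in range(10)]
        vol = build_volume({1: [(0, 0, 0)], 2: coords}, spacing=(0.5, 0.5))
        acc = node_volume(vol, 2, mode="accumulated")
        mx = node_volume(vol, 2, mode="max_cross_section")
        assert (mx.pixel_count, mx.volume) == (acc.pixel_count, acc.volume)

    def test_multi_slice_modes(self):
        # 6 voxels on slice 1, 4 on slice 2; spacing 1mm, T=4, G=1
        coords = [(1, 2, c) for c in range(6)] + [(2, 2, c) for c in range(4)]
        vol = build_volume({1: [(0, 0, 0)], 2: coords})
        assert node_volume(vol, 2, "accumulated").volume == pytest.approx(10.0)
        assert node_volume(vol, 2, "max_cross_section").volume == pytest.approx(6.0)
        assert node_volume(vol, 2, "voxel_volume").volume == pytest.approx(10 * 5.0)

    def test_absent_label_is_error(self):
        vol = build_volume({1: [(0, 0, 0)], 2: [(1, 1, 1)]})
        with pytest.raises(ValueError, match="label 7 absent"):
            node_volume(vol, 7)

    def test_unknown_mode_is_error(self):
        vol = build_volume({1: [(0, 0, 0)], 2: [(1, 1, 1)]})
        with pytest.raises(ValueError, match="volume mode"):
            node_volume(vol, 2, mode="bogus")


class TestNodeDistance:
    def test_same_slice_reduces_to_in_plane_euclidean(self):
        vol = build_volume({1: [(1, 5, 5)], 2: [(1, 8, 9)]})
        nf = node_distance(vol, 2)
        assert nf.delta_S == 0
        assert nf.distance == pytest.approx(5.0, abs=1e-12)

    def test_through_plane_formula_hand_value(self):
        # dS=2, G=1, T=4, in-plane (3,4): term (2*1 + 1*4)^2 = 36 -> sqrt(61)
        vol = build_volume({1: [(1, 5, 5)], 2: [(3, 8, 9)]})
        nf = node_distance(vol, 2)
        assert nf.delta_S == 2
        assert nf.distance == pytest.approx(np.sqrt(61.0), abs=1e-9)

    def test_through_plane_term_values(self):
        assert through_plane_distance(0, 4.0, 1.0) == 0.0
        assert through_plane_distance(1, 4.0, 1.0) == 1.0   # one gap, zero thickness spans
        assert through_plane_distance(3, 4.0, 1.0) == 3 * 1.0 + 2 * 4.0
        with pytest.raises(ValueError):
            through_plane_distance(-1, 4.0, 1.0)

    def test_anisotropic_in_plane_spacing(self):
        vol = build_volume({1: [(1, 5, 5)], 2: [(1, 8, 9)]}, spacing=(2.0, 0.5))
        # offsets: rows 3 * 2mm = 6, cols 4 * 0.5mm = 2
        assert node_distance(vol, 2).distance == pytest.approx(np.sqrt(40.0))


class TestPatientFeatures:
    def test_totals_are_sums_over_nodes(self):
        vol = build_volume(
            {1: [(1, 5, 5)], 2: [(1, 8, 9)], 3: [(3, 8, 9)]},
        )
        pf = patient_features(vol)
        per_v = [node_volume(vol, l).volume for l in (2, 3)]
        per_d = [node_distance(vol, l).distance for l in (2, 3)]
        assert pf.tlnv == pytest.approx(sum(per_v), abs=0)
        assert pf.tlnd == pytest.approx(sum(per_d), abs=0)
        assert pf.node_count == 2

    def test_zero_nodes_gives_flagged_zeros(self):
        vol = build_volume({1: [(1, 5, 5)]})
        pf = patient_features(vol)
        assert (pf.tlnv, pf.tlnd, pf.node_count) == (0.0, 0.0, 0)
        assert pf.no_nodes_flag

    def test_adding_a_node_never_decreases_totals(self):
        base = build_volume({1: [(1, 5, 5)], 2: [(1, 8, 9)]})
        grown = build_volume({1: [(1, 5, 5)], 2: [(1, 8, 9)], 3: [(4, 15, 15)]})
        a, b = patient_features(base), patient_features(grown)
        assert b.tlnv >= a.tlnv and b.tlnd >= a.tlnd

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(
        ds=st.integers(0, 2),
        dr=st.integers(-3, 3),
        dc=st.integers(-3, 3),
    )
    def test_translation_invariance(self, ds, dr, dc):
        """Shifting all structures by a whole-voxel offset changes nothing."""
        placements = {1: [(1, 5, 5), (1, 5, 6)], 2: [(2, 8, 9)], 3: [(0, 3, 12)]}
        shifted = {
            lbl: [(s + ds, r + dr, c + dc) for s, r, c in coords]
            for lbl, coords in placements.items()
        }
        a = patient_features(build_volume(placements, shape=(6, 24, 24)))
        b = patient_features(build_volume(shifted, shape=(6, 24, 24)))
        assert b.tlnv == pytest.approx(a.tlnv, abs=0)
        assert b.tlnd == pytest.approx(a.tlnd, abs=1e-12)


class TestNodeClasses:
    def test_size_boundary_inclusive(self):
        # 25 voxels of 0.7854 mm^2 ~ area 19.63 mm^2 -> equivalent d = 5.0 mm
        area_target = np.pi * 2.5**2
        n = 25
        pixel_area = area_target / n
        assert equivalent_diameter(n, pixel_area) == pytest.approx(5.0)
        sp = np.sqrt(pixel_area)
        coords = [(1, 2 + i, 2 + j) for i in range(5) for j in range(5)]
        vol = build_volume({1: [(0, 0, 0)], 2: coords}, spacing=(sp, sp))
        pf = patient_features(vol)
        assert pf.nodes[0].size_class == "L-LN"

    def test_distance_boundary_inclusive(self):
        vol = build_volume(
            {1: [(1, 0, 0)], 2: [(1, 50, 0)], 3: [(1, 0, 49)]},
            shape=(3, 60, 60),
        )
        pf = patient_features(vol)
        by_label = {n.node_label: n for n in pf.nodes}
        assert by_label[2].distance == pytest.approx(50.0)
        assert by_label[2].distance_class == "D-LN"   # inclusive at 50 mm
        assert by_label[3].distance == pytest.approx(49.0)
        assert by_label[3].distance_class == "N-LN"


class TestOracleEquivalence:
    def test_features_match_independent_ground_truth(self, random_phantoms):
        """Volumes exact, distances to 1e-9 mm against the phantom oracle."""
        for vol, gt in random_phantoms:
            pf = patient_features(vol)
            nodes = {n.node_label: n for n in pf.nodes}
            assert set(nodes) == {g.node_label for g in gt.nodes}
            for g in gt.nodes:
                n = nodes[g.node_label]
                assert n.pixel_count == g.voxel_count
                assert n.volume == g.voxel_count * vol.pixel_area
                assert n.max_cross_section_count == g.max_cross_section_count
                assert n.delta_S == g.delta_S
                assert n.distance == pytest.approx(g.distance_mm, abs=1e-9)
            # totals are the exact sums of the per-node values
            assert pf.tlnv == sum(g.voxel_count * vol.pixel_area for g in gt.nodes)
            assert pf.tlnd == pytest.approx(gt.total_distance_mm, abs=1e-9)


class TestExtractorEstimator:
    def test_transform_returns_patient_indexed_frame(self, random_phantoms):
        vols = [v for v, _ in random_phantoms[:4]]
        table = LymphNodeFeatureExtractor().fit_transform(vols)
        assert list(table.columns[:3]) == ["tlnv", "tlnd", "node_count"]
        assert len(table) == 4

    def test_sklearn_contract(self):
        from sklearn.base import clone

        est = LymphNodeFeatureExtractor(mode="voxel_volume")
        cloned = clone(est)
        assert cloned.get_params()["mode"] == "voxel_volume"
        with pytest.raises(ValueError):
            LymphNodeFeatureExtractor(mode="bogus").fit([])
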