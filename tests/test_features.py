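"""Eigen-box morphometry and the 23-feature computation."""

import numpy as np
import pytest

from ovoseg.features import compute_features, eigen_box, feature_table, object_length
from ovoseg.model import CTVolume, ImageObject, LabelMap, SegClass
from ovoseg.phantom import BonePrimitive, _rod_mask

SPACING = 0.216032


def _cuboid_object(nx, ny, nz, spacing=SPACING):
    coords = np.argwhere(np.ones((nx, ny, nz), dtype=bool))
    return ImageObject(1, SegClass.SKELETON, coords, (spacing,) * 3)


def brute_force_covariance_edges(coords, spacing):
    """Oracle: Monte Carlo covariance of the solid voxel union."""
    rng = np.random.default_rng(0)
    pts = []
    for c in coords:
        pts.append((c + rng.random((200, 3)) - 0.5) * spacing)
    pts = np.concatenate(pts)
    cov = np.cov(pts, rowvar=False, bias=True)
    evals = np.sort(np.linalg.eigvalsh(cov))[::-1]
    volume = len(coords) * spacing ** 3
    k = (volume / np.sqrt(np.prod(evals))) ** (1 / 3)
    return k * np.sqrt(evals)


class TestEigenBox:
    def test_axis_aligned_cuboid_exact(self):
        box = eigen_box(_cuboid_object(10, 4, 2))
        assert box.edges == pytest.approx(
            (10 * SPACING, 4 * SPACING, 2 * SPACING), abs=1e-12)

    def test_matches_brute_force_covariance_oracle(self):
        obj = _cuboid_object(10, 4, 2)
        oracle = brute_force_covariance_edges(obj.coords, SPACING)
        assert eigen_box(obj).edges == pytest.approx(tuple(oracle), rel=0.02)

    def test_rotation_about_z_is_invariant(self):
        obj = _cuboid_object(10, 4, 2)
        rotated = ImageObject(2, SegClass.SKELETON,
                              obj.coords[:, [1, 0, 2]], (SPACING,) * 3)
        assert eigen_box(rotated).edges == pytest.approx(
            eigen_box(obj).edges, abs=1e-12)

    @pytest.mark.parametrize("angle_deg", [30, 45, 60])
    def test_oblique_rod_length_within_one_voxel(self, angle_deg):
        g = np.arange(64) + 0.5
        grids = np.meshgrid(g, g, g, indexing="ij")
        a = np.radians(angle_deg)
        rod = BonePrimitive("rod", "left", 40.0, 4.0, 4.0, (32, 32, 32),
                            (np.cos(a), np.sin(a), 0.0), bow_mm=0.0)
        mask = _rod_mask(rod, grids, 1.0)
        obj = ImageObject(1, SegClass.SKELETON, np.argwhere(mask), (1.0,) * 3)
        assert object_length(obj) == pytest.approx(40.0, abs=1.0)

    def test_volume_constraint_holds(self):
        rng = np.random.default_rng(2)
        coords = np.unique(rng.integers(0, 12, (300, 3)), axis=0)
        obj = ImageObject(1, SegClass.SKELETON, coords, (SPACING,) * 3)
        box = eigen_box(obj)
        assert np.prod(box.edges) == pytest.approx(obj.volume, rel=1e-6)
        e1, e2, e3 = box.edges
        assert e1 >= e2 >= e3 > 0

    def test_single_voxel_degenerates_to_spacing(self):
        obj = ImageObject(1, SegClass.SKELETON, [[3, 3, 3]], (SPACING,) * 3)
        assert eigen_box(obj).edges == (SPACING,) * 3


def _context(mask_list, hu_fill=700.0, shape=(40, 40, 40), spacing=1.0):
    arr = np.full(shape, int(SegClass.INTERIOR), dtype=np.uint8)
    arr[:, :, 0] = int(SegClass.SHELL)
    hu = np.full(shape, 40.0)
    objects = []
    for i, mask in enumerate(mask_list, start=1):
        arr[mask] = int(SegClass.SKELETON)
        hu[mask] = hu_fill
        objects.append(ImageObject(i, SegClass.SKELETON, np.argwhere(mask),
                                   (spacing,) * 3))
    return objects, LabelMap(arr, (spacing,) * 3), CTVolume(hu, (spacing,) * 3)


class TestComputeFeatures:
    def test_cube_closed_forms(self):
        cube = np.zeros((40, 40, 40), dtype=bool)
        cube[10:18, 10:18, 10:18] = True
        objects, labels, volume = _context([cube])
        f = compute_features(objects[0], objects, labels, volume, day=15)
        assert f["asymmetry"] == pytest.approx(0.0, abs=1e-9)
        assert f["rectangular_fit"] == pytest.approx(1.0)
        assert f["compactness"] == pytest.approx(1.0)
        assert f["shape_index"] == pytest.approx(1.0)
        assert f["relative_volume"] == 1.0
        assert f["length_thickness"] == pytest.approx(1.0)

    def test_ball_is_round_and_elliptical(self):
        g = np.arange(40)
        X, Y, Z = np.meshgrid(g, g, g, indexing="ij")
        ball = (X - 20) ** 2 + (Y - 20) ** 2 + (Z - 20) ** 2 <= 10 ** 2
        objects, labels, volume = _context([ball])
        f = compute_features(objects[0], objects, labels, volume, day=15)
        assert f["roundness"] >= 0.9
        assert f["elliptical_fit"] >= 0.9

    def test_twin_objects_share_volume_and_neighbor_each_other(self):
        a = np.zeros((40, 40, 40), dtype=bool)
        b = np.zeros((40, 40, 40), dtype=bool)
        a[5:9, 5:9, 5:9] = True
        b[20:24, 20:24, 20:24] = True
        objects, labels, volume = _context([a, b])
        fa = compute_features(objects[0], objects, labels, volume, day=15)
        fb = compute_features(objects[1], objects, labels, volume, day=15)
        assert fa["relative_volume"] == pytest.approx(0.5)
        assert fb["relative_volume"] == pytest.approx(0.5)
        assert fa["neighbor_count_50"] == 1.0  # centroids ~26 voxels apart
        assert fa["distance_nearest_skeleton"] == fb["distance_nearest_skeleton"]
        assert fa["distance_nearest_skeleton"] > 0

    def test_ratio_features_equal_their_quotients(self):
        rng = np.random.default_rng(3)
        blob = rng.random((12, 12, 12)) > 0.6
        blob[5:7, 5:7, 5:7] = True
        mask = np.zeros((40, 40, 40), dtype=bool)
        mask[4:16, 4:16, 4:16] = blob
        objects, labels, volume = _context([mask])
        f = compute_features(objects[0], objects, labels, volume, day=15)
        assert f["length_thickness"] == pytest.approx(
            f["length"] / f["thickness"], rel=1e-12)
        assert f["length_width"] == pytest.approx(
            f["length"] / f["width"], rel=1e-12)
        assert f["length"] >= f["width"] >= f["thickness"]

    def test_translation_invariance_of_geometry(self):
        base = np.zeros((40, 40, 40), dtype=bool)
        base[4:9, 6:12, 8:11] = True
        shifted = np.roll(base, (7, 5, 9), axis=(0, 1, 2))
        o1, l1, v1 = _context([base])
        o2, l2, v2 = _context([shifted])
        f1 = compute_features(o1[0], o1, l1, v1, day=15)
        f2 = compute_features(o2[0], o2, l2, v2, day=15)
        for key in ("length", "width", "thickness", "asymmetry", "compactness",
                    "rectangular_fit", "roundness", "border_length"):
            assert f1[key] == pytest.approx(f2[key], abs=1e-9), key

    def test_distance_to_shell_is_geometric(self):
        cube = np.zeros((40, 40, 40), dtype=bool)
        cube[10:14, 10:14, 10:14] = True  # nearest shell plane at z=0
        objects, labels, volume = _context([cube])
        f = compute_features(objects[0], objects, labels, volume, day=15)
        assert f["distance_to_shell"] == pytest.approx(10.0, abs=0.01)

    def test_feature_table_covers_all_objects(self, segmented_half):
        volume, _, _, labels, objects, _ = segmented_half
        table = feature_table(objects, labels, volume, day=15,
                              specimen_id="half")
        assert len(table) == len(objects)
        assert table["relative_volume"].sum() == pytest.approx(1.0)
        assert (table["distance_to_shell"] >= 0).all()
        assert table.notna().all().all()
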