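import numpy as np
import pytest

from seedling3d.cloud import LabeledPointCloud, STEM, LEAF, TRAY
from seedling3d.geometry import rot_axis
from seedling3d.io import load_dataset, load_scene, save_scene_array
from seedling3d.preprocess import (
    AUG_ORDER,
    augment_sample,
    align_to_z,
    apply_scale,
    convert_dataset,
    detect_ground_plane,
    invert_augmentation,
    partition_by_pot,
    purify_background,
    read_augmentation_ledger,
    scale_factor,
    split_scenes,
    write_augmentation_ledger,
)

from conftest import random_cloud


def labeled(sem):
    sem = np.asarray(sem)
    n = len(sem)
    inst = np.where(sem == 0, 0, 1)
    return LabeledPointCloud(
        np.arange(3 * n, dtype=float).reshape(n, 3),
        np.zeros((n, 3), int),
        np.tile([0.0, 0.0, 1.0], (n, 1)), sem, inst,
    )


class TestPurify:
    def test_filters_exactly_background(self):
        out = purify_background(labeled([0, 1, 2, 0]))
        assert out.sem_label.tolist() == [1, 2]

    def test_area1_census_retains_8011(self):
        # class counts of the densest-imbalance region: 134428 tray,
        # 6580 leaf, 1431 stem points
        sem = np.concatenate([
            np.zeros(134428, int), np.full(6580, LEAF), np.full(1431, STEM),
        ])
        out = purify_background(labeled(sem))
        assert out.n_points == 8011

    def test_no_background_is_identity(self):
        cloud = labeled([1, 2, 2])
        out = purify_background(cloud)
        np.testing.assert_array_equal(out.to_array(), cloud.to_array())

    def test_source_cloud_untouched_and_counts_add_up(self):
        cloud = labeled([0, 1, 0, 2, 0])
        before = cloud.to_array().copy()
        out = purify_background(cloud)
        np.testing.assert_array_equal(cloud.to_array(), before)
        assert out.n_points + int(np.sum(cloud.sem_label == TRAY)) == cloud.n_points

    def test_all_background_warns(self):
        with pytest.warns(UserWarning):
            out = purify_background(labeled([0, 0]))
        assert out.n_points == 0


class TestGroundAlignment:
    def _plane_cloud(self, n=200, seed=0):
        rng = np.random.default_rng(seed)
        pts = np.column_stack([rng.uniform(-1, 1, n), rng.uniform(-1, 1, n),
                               np.zeros(n)])
        pts = np.vstack([pts, rng.uniform(2, 3, (5, 3))])  # outliers
        m = len(pts)
        return LabeledPointCloud(pts, np.zeros((m, 3), int),
                                 np.tile([0, 0, 1.0], (m, 1)),
                                 np.zeros(m, int), np.zeros(m, int))

    def test_exact_plane_recovery_with_outliers(self):
        plane = detect_ground_plane(self._plane_cloud(), seed=0)
        np.testing.assert_allclose(plane.normal, [0, 0, 1], atol=1e-6)
        assert abs(plane.d) < 1e-6

    def test_seeded_runs_identical(self):
        cloud = self._plane_cloud()
        a = detect_ground_plane(cloud, seed=3)
        b = detect_ground_plane(cloud, seed=3)
        np.testing.assert_array_equal(a.normal, b.normal)

    def test_tray_scene_plane_dominates(self, tiny_scene):
        cloud, _ = tiny_scene
        plane = detect_ground_plane(cloud, iters=200, seed=0)
        assert plane.inlier_fraction > 0.5

    def test_realignment_after_known_rotation(self):
        cloud = self._plane_cloud()
        R = rot_axis("x", 30.0)
        rotated = cloud.copy()
        rotated.coords = cloud.coords @ R.T
        rotated.normals = cloud.normals @ R.T
        plane = detect_ground_plane(rotated, seed=1)
        aligned, Rb = align_to_z(rotated, plane)
        assert np.allclose(Rb @ Rb.T, np.eye(3), atol=1e-12)
        assert np.linalg.det(Rb) == pytest.approx(1.0)
        # z spread of the main plane collapses again
        z = aligned.coords[:-5, 2]
        assert np.ptp(z) < 1e-6
        norms = np.linalg.norm(aligned.normals, axis=1)
        np.testing.assert_allclose(norms, 1.0, atol=1e-9)

    def test_identity_when_already_aligned(self):
        cloud = self._plane_cloud()
        plane = detect_ground_plane(cloud, seed=0)
        _, R = align_to_z(cloud, plane)
        np.testing.assert_allclose(R, np.eye(3), atol=1e-9)

    def test_antiparallel_normal_handled(self):
        from seedling3d.geometry import rotation_aligning
        R = rotation_aligning(np.array([0, 0, -1.0]), np.array([0, 0, 1.0]))
        np.testing.assert_allclose(R @ np.array([0, 0, -1.0]), [0, 0, 1.0],
                                   atol=1e-12)


class TestScale:
    def test_tray_reference_factor(self):
        cal = scale_factor(25.0, 12.5)
        assert cal.k == 2.0

    def test_identity_factor(self):
        assert scale_factor(3.3, 3.3).k == 1.0

    def test_round_trip(self):
        cloud = random_cloud(20, seed=0)
        back = apply_scale(apply_scale(cloud, 2.0), 0.5)
        np.testing.assert_allclose(back.coords, cloud.coords, atol=1e-9)

    def test_scaling_doubles_distances(self):
        cloud = random_cloud(10, seed=1)
        out = apply_scale(cloud, 2.0)
        d0 = np.linalg.norm(cloud.coords[0] - cloud.coords[1])
        d1 = np.linalg.norm(out.coords[0] - out.coords[1])
        assert d1 == pytest.approx(2 * d0)

    @pytest.mark.parametrize("bad", [0.0, -1.0])
    def test_nonpositive_inputs_rejected(self, bad):
        with pytest.raises(ValueError):
            scale_factor(bad, 1.0)
        with pytest.raises(ValueError):
            apply_scale(random_cloud(3), bad)


class TestAugmentation:
    def test_empty_spec_is_identity(self):
        cloud = random_cloud(30, seed=0)
        out, record = augment_sample(cloud, spec=(), seed=0)
        np.testing.assert_array_equal(out.to_array(), cloud.to_array())
        assert record.ops == []

    def test_dropout_rate_within_range(self):
        cloud = random_cloud(1000, seed=1)
        out, record = augment_sample(cloud, spec=("dropout",), seed=2)
        rate = record.get("dropout")["rate"]
        assert 0.10 <= rate <= 0.20
        assert 0.75 * 1000 <= out.n_points <= 0.92 * 1000

    def test_scaling_ledger_round_trip(self):
        cloud = random_cloud(50, seed=2)
        out, record = augment_sample(cloud, spec=("scaling",), seed=3)
        s = record.get("scaling")["scale"]
        assert 0.7 <= s <= 1.3
        np.testing.assert_allclose(out.coords / s, cloud.coords, atol=1e-9)

    def test_rotation_rotates_normals_and_stays_unit(self):
        cloud = random_cloud(50, seed=3)
        out, record = augment_sample(cloud, spec=("rotation",), seed=4)
        angles = record.get("rotation")
        assert all(-10 <= angles[k] <= 10 for k in angles)
        np.testing.assert_allclose(
            np.linalg.norm(out.normals, axis=1), 1.0, atol=1e-9
        )

    def test_geometric_inverse_restores_coordinates(self):
        cloud = random_cloud(200, seed=4)
        out, record = augment_sample(
            cloud, spec=("rotation", "scaling", "translation", "shuffle"),
            seed=5,
        )
        back, irreversible = invert_augmentation(out, record)
        assert irreversible == []
        np.testing.assert_allclose(back.coords, cloud.coords, atol=1e-9)
        np.testing.assert_array_equal(back.sem_label, cloud.sem_label)

    def test_full_inverse_bounded_by_jitter_clip(self):
        cloud = random_cloud(400, seed=5)
        out, record = augment_sample(cloud, spec=AUG_ORDER, seed=6)
        back, irreversible = invert_augmentation(out, record)
        assert set(irreversible) == {"dropout", "jitter"}
        # surviving points recover up to the jitter clip, magnified by the
        # inverse scale and mixed across axes by the inverse rotation
        s = record.get("scaling")["scale"]
        diffs = np.linalg.norm(
            back.coords[:, None, :] - cloud.coords[None, :, :], axis=-1
        )
        nearest = diffs.min(axis=1)
        assert nearest.max() <= np.sqrt(3) * 0.05 / min(s, 1.0) + 1e-9

    def test_dropout_floor_enforced(self):
        with pytest.raises(ValueError, match="10 points"):
            augment_sample(random_cloud(11, seed=6), spec=("dropout",), seed=0)

    def test_ledger_file_round_trip(self, tmp_path):
        cloud = random_cloud(50, seed=7)
        _, r1 = augment_sample(cloud, seed=1, sample_id="s1")
        _, r2 = augment_sample(cloud, seed=2, sample_id="s2")
        path = tmp_path / "ledger.tsv"
        write_augmentation_ledger([r1, r2], path)
        back = read_augmentation_ledger(path)
        assert set(back) == {"s1", "s2"}
        assert back["s1"].get("scaling")["scale"] == pytest.approx(
            r1.get("scaling")["scale"]
        )
        assert [op for op, _ in back["s2"].ops] == [op for op, _ in r2.ops]


class TestPartition:
    def test_ten_pots_split_7_1_2(self):
        assignment = partition_by_pot([f"p{i}" for i in range(10)], seed=0)
        counts = {s: 0 for s in ("train", "val", "test")}
        for s in assignment.values():
            counts[s] += 1
        assert counts == {"train": 7, "val": 1, "test": 2}

    def test_144_pots_largest_remainder(self):
        assignment = partition_by_pot([f"p{i}" for i in range(144)], seed=1)
        counts = {s: 0 for s in ("train", "val", "test")}
        for s in assignment.values():
            counts[s] += 1
        assert counts == {"train": 101, "val": 14, "test": 29}

    def test_deterministic_and_complete(self):
        pots = [f"p{i}" for i in range(20)]
        a = partition_by_pot(pots, seed=9)
        b = partition_by_pot(pots, seed=9)
        assert a == b
        assert set(a) == set(pots)

    def test_fewer_than_three_pots_rejected(self):
        with pytest.raises(ValueError):
            partition_by_pot(["a", "b"])

    def test_timepoints_of_one_pot_share_split(self, tmp_path, tiny_layout):
        from seedling3d.synthetic import make_experiment
        index = make_experiment(tiny_layout, (24.0, 120.0), seed=0,
                                root=tmp_path)
        assignment = partition_by_pot(index.pot_ids() + ["x", "y"], seed=0)
        splits = split_scenes(index, assignment)
        for name, entries in splits.items():
            for entry in entries:
                assert assignment[entry.pot_id] == name


class TestConvert:
    def test_purified_variant_shrinks_by_background(self, tmp_path):
        cloud = labeled([0, 0, 0, 1, 2])
        save_scene_array(cloud, "1", "s", tmp_path / "src", pot_id="p")
        index = load_dataset(tmp_path / "src")
        out = convert_dataset(index, tmp_path / "dst", purified=True)
        assert load_scene(out.scenes[0]).n_points == 2

    def test_conversion_idempotent(self, tmp_path):
        cloud = labeled([0, 1, 2])
        save_scene_array(cloud, "1", "s", tmp_path / "src", pot_id="p")
        index = load_dataset(tmp_path / "src")
        once = convert_dataset(index, tmp_path / "dst")
        twice = convert_dataset(once, tmp_path / "dst")
        np.testing.assert_array_equal(
            load_scene(once.scenes[0]).to_array(),
            load_scene(twice.scenes[0]).to_array(),
        )
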