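import numpy as np
import pytest

from seedling3d.phenotype import (
    cotyledon_angle,
    fit_leaf_plane,
    measure_plant,
    phenotype_report,
    plant_height,
    restore_physical_scale,
    stem_diameter,
    surface_area,
)
from seedling3d.preprocess import augment_sample, scale_factor
from seedling3d.synthetic import PhenotypeParams, make_seedling

from conftest import random_cloud


def cylinder(radius=0.05, height=1.0, density=400.0, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    n = int(2 * np.pi * radius * height * density)
    phi = rng.uniform(0, 2 * np.pi, n)
    z = rng.uniform(0, height, n)
    pts = np.column_stack([radius * np.cos(phi), radius * np.sin(phi), z])
    if noise:
        nrm = np.column_stack([np.cos(phi), np.sin(phi), np.zeros(n)])
        pts = pts + nrm * rng.normal(0, noise, n)[:, None]
    return pts


class TestRestoreScale:
    def test_identity(self):
        cloud = random_cloud(20, seed=0)
        out = restore_physical_scale(cloud, 1.0)
        np.testing.assert_array_equal(out.coords, cloud.coords)

    def test_augmentation_scale_round_trip(self):
        cloud = random_cloud(50, seed=1)
        aug, record = augment_sample(cloud, spec=("scaling",), seed=2,
                                     sample_id="s")
        restored = restore_physical_scale(aug, 1.0, record=record,
                                          sample_id="s")
        np.testing.assert_allclose(restored.coords, cloud.coords, atol=1e-9)

    def test_tray_calibration_doubles_distances(self):
        cloud = random_cloud(10, seed=2)
        cal = scale_factor(25.0, 12.5)
        out = restore_physical_scale(cloud, cal)
        np.testing.assert_allclose(out.coords, 2.0 * cloud.coords)

    def test_mismatched_sample_id_rejected(self):
        cloud = random_cloud(20, seed=3)
        _, record = augment_sample(cloud, spec=("scaling",), seed=0,
                                   sample_id="a")
        with pytest.raises(ValueError, match="ledger"):
            restore_physical_scale(cloud, 1.0, record=record, sample_id="b")


class TestPlantHeight:
    def test_max_minus_min(self):
        pts = np.zeros((3, 3))
        pts[:, 2] = [0.2, 1.0, 2.3]
        h, flag = plant_height(pts)
        assert h == pytest.approx(2.1)
        assert flag == ""

    def test_single_point_is_zero(self):
        h, _ = plant_height(np.array([[1.0, 2.0, 3.0]]))
        assert h == 0.0

    def test_empty_cloud_flagged(self):
        h, flag = plant_height(np.zeros((0, 3)))
        assert h is None and flag

    def test_invariant_under_xy_motion(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(50, 3))
        from seedling3d.geometry import rot_axis
        moved = pts @ rot_axis("z", 77.0).T + [5.0, -3.0, 0.0]
        assert plant_height(moved)[0] == pytest.approx(plant_height(pts)[0])


class TestStemDiameter:
    def test_noise_free_cylinder_within_two_percent(self):
        fit = stem_diameter(cylinder(radius=0.05, noise=0.0), seed=0)
        assert fit.flag == ""
        assert fit.diameter == pytest.approx(0.100, abs=0.002)

    def test_cocircular_slab_is_exact(self):
        phi = np.linspace(0, 2 * np.pi, 40, endpoint=False)
        pts = np.column_stack([0.07 * np.cos(phi), 0.07 * np.sin(phi),
                               np.full(40, 0.5)])
        fit = stem_diameter(pts, subsample=1.0, seed=0, z_ref=0.0)
        assert np.allclose(fit.radii, 0.07, atol=1e-9)
        assert fit.diameter == pytest.approx(0.14, abs=1e-9)

    def test_full_subsample_is_deterministic(self):
        pts = cylinder(seed=1)
        fit = stem_diameter(pts, subsample=1.0, seed=3)
        assert len(set(np.round(fit.radii, 12))) == 1

    def test_empty_slab_flagged_not_raised(self):
        pts = cylinder(height=0.3)   # stem shorter than the slab position
        fit = stem_diameter(pts, slab_center=0.5, slab_halfwidth=0.05)
        assert fit.flag == "empty slab"
        assert np.isnan(fit.diameter)

    def test_literal_slab_range(self):
        pts = cylinder(height=6.0)
        fit = stem_diameter(pts, literal_slab=True, seed=0)
        assert fit.z_lo == pytest.approx(4.5, abs=0.01)
        assert fit.z_hi == pytest.approx(5.5, abs=0.01)
        assert fit.flag == ""


class TestLeafPlane:
    def test_horizontal_plane(self):
        rng = np.random.default_rng(5)
        pts = np.column_stack([rng.uniform(-1, 1, 100),
                               rng.uniform(-1, 1, 100), np.ones(100)])
        fit = fit_leaf_plane(pts, seed=0)
        np.testing.assert_allclose(fit.normal, [0, 0, 1], atol=1e-9)
        assert fit.theta_deg == pytest.approx(0.0, abs=1e-6)

    def test_thirty_degree_tilt(self):
        rng = np.random.default_rng(6)
        n_true = np.array([0.5, 0.0, np.sqrt(3) / 2])
        basis = np.linalg.svd(n_true[None])[2][1:]
        pts = rng.uniform(-1, 1, (200, 2)) @ basis
        fit = fit_leaf_plane(pts, seed=0)
        assert fit.theta_deg == pytest.approx(30.0, abs=1e-6)
        assert fit.complement_deg == pytest.approx(60.0, abs=1e-6)

    def test_seeded_repeatability(self):
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(100, 3))
        pts[:, 2] *= 0.01
        a = fit_leaf_plane(pts, seed=5)
        b = fit_leaf_plane(pts, seed=5)
        np.testing.assert_array_equal(a.normal, b.normal)


class TestCotyledonAngle:
    def _patch(self, theta_deg, seed=0):
        rng = np.random.default_rng(seed)
        n_true = np.array([np.sin(np.deg2rad(theta_deg)), 0.0,
                           np.cos(np.deg2rad(theta_deg))])
        basis = np.linalg.svd(n_true[None])[2][1:]
        return rng.uniform(-0.5, 0.5, (150, 2)) @ basis

    def test_two_cotyledons_average(self):
        theta, compl, flag = cotyledon_angle(
            [self._patch(20.0), self._patch(40.0)], seed=0
        )
        assert flag == ""
        assert theta == pytest.approx(30.0, abs=0.01)
        assert compl == pytest.approx(60.0, abs=0.01)

    def test_horizontal_cotyledon_is_zero(self):
        theta, _, _ = cotyledon_angle([self._patch(0.0)], seed=0)
        assert theta == pytest.approx(0.0, abs=1e-6)

    def test_no_cotyledons_flagged(self):
        theta, compl, flag = cotyledon_angle([])
        assert theta is None and flag


class TestSurfaceArea:
    def test_mesh_failure_flagged(self):
        area, k, flag = surface_area(np.eye(3) * 100, ball_radius=0.1)
        assert area is None and flag == "mesh failure"

    def test_single_triangle(self):
        pts = np.array([[0.0, 0, 0], [3.0, 0, 0], [0.0, 4, 0]])
        area, k, flag = surface_area(pts, ball_radius=3.0)
        assert k == 1
        assert area == pytest.approx(6.0)


class TestMeasurePlant:
    def test_noise_free_recovery(self):
        params = PhenotypeParams(2.0, 0.10, (30.0, 30.0), (1.0, 1.0), 10.0)
        # dense sampling: the mesh boundary bite scales with point spacing
        cloud, _ = make_seedling(params, density=800, noise_sd=0.0, seed=8)
        rec = measure_plant(cloud.coords, cloud.sem_label, cloud.normals,
                            plant_id=1, timepoint_h=72.0, seed=0,
                            mesh_max_points=1200)
        assert rec.height_cm == pytest.approx(2.0, abs=0.02)
        assert rec.stem_diam_cm == pytest.approx(0.10, rel=0.02)
        assert rec.incl_deg == pytest.approx(30.0, abs=0.5)
        assert rec.area_cm2 == pytest.approx(2.0, rel=0.05)
        assert rec.incl_complement_deg == pytest.approx(60.0, abs=0.5)

    def test_report_sorted_and_complete(self):
        params = PhenotypeParams(2.0, 0.10, (30.0, 30.0), (1.0, 1.0), 0.0)
        plants = []
        for pid in (3, 1):
            cloud, _ = make_seedling(params, noise_sd=0.0, seed=pid)
            plants.append({
                "plant_id": pid, "coords": cloud.coords,
                "sem": cloud.sem_label, "normals": cloud.normals,
            })
        frame = phenotype_report(plants, timepoint_h=72.0)
        assert frame["plant_id"].tolist() == [1, 3]
        assert {"height_cm", "stem_diam_cm", "incl_deg",
                "area_cm2"} <= set(frame.columns)
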