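"""Physical-scale restoration and the four trait estimators.

Per plant and timepoint the pipeline measures, on the size-restored cloud:

* plant height ``H = z_max - z_min``;
* stem diameter ``D = 2 r_bar`` from minimum-enclosing-circle fits of the
  XY-projected stem slab just above the ground (denoised, 5 seeded
  subsample repeats averaged);
* cotyledon inclination ``theta = arccos|n . z|`` in degrees from a RANSAC
  plane fit per cotyledon (3 seeded repeats averaged, then averaged over
  the two cotyledons); the complement ``90 - theta`` — the angle between
  the leaf plane and the vertical plane — is reported alongside, without
  choosing between the two conventions;
* cotyledon area from a ball-pivoting mesh (0.2 cm ball) summed with
  Heron's formula.

The printed slab for the stem diameter is configurable: the default is
[z_min + 0.45, z_min + 0.55] cm (physically consistent with seedlings a
few cm tall); a literal mode reproduces a [z_min + 4.5, z_min + 5.5] cm
slab for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bpa import MeshFailure, ball_pivot_mesh
from .cloud import LEAF, STEM, LabeledPointCloud
from .geometry import (
    fit_plane_ransac,
    min_enclosing_circle,
    statistical_outlier_mask,
    triangle_areas,
)
from .preprocess import AugmentationRecord, ScaleCalibration


# ----------------------------------------------------------------------
# size restoration
# ----------------------------------------------------------------------

def restore_physical_scale(
    cloud: LabeledPointCloud,
    calibration: ScaleCalibration | float = 1.0,
    record: AugmentationRecord | None = None,
    sample_id: str | None = None,
) -> LabeledPointCloud:
    """Undo the augmentation scaling (traced by sample id) and apply ``k``.

    The augmentation ledger provides the per-sample scaling factor; the
    tray-based calibration ``k`` then converts reconstruction units to cm.
    """
    out = cloud.copy()
    if record is not None:
        if sample_id is not None and record.sample_id != sample_id:
            raise ValueError(
                f"ledger record is for '{record.sample_id}', not '{sample_id}'"
            )
        scaling = record.get("scaling")
        if scaling is not None:
            out.coords = out.coords / scaling["scale"]
    k = calibration.k if isinstance(calibration, ScaleCalibration) else float(calibration)
    if k <= 0:
        raise ValueError("scale factor must be positive")
    out.coords = out.coords * k
    return out


# ----------------------------------------------------------------------
# trait estimators
# ----------------------------------------------------------------------

def plant_height(coords: np.ndarray):
    """``H = z_max - z_min``; None with a flag for an empty cloud."""
    coords = np.asarray(coords, dtype=np.float64).reshape(-1, 3)
    if coords.shape[0] == 0:
        return None, "empty cloud"
    return float(coords[:, 2].max() - coords[:, 2].min()), ""


@dataclass
class StemSlabFit:
    """Minimum-enclosing-circle slab fit of the stem."""

    z_lo: float
    z_hi: float
    radii: list
    flag: str = ""

    @property
    def mean_radius(self) -> float:
        return float(np.mean(self.radii)) if self.radii else float("nan")

    @property
    def diameter(self) -> float:
        return 2.0 * self.mean_radius


def stem_diameter(
    stem_coords: np.ndarray,
    slab_center: float = 0.5,
    slab_halfwidth: float = 0.05,
    repeats: int = 5,
    subsample: float = 0.8,
    seed: int = 0,
    literal_slab: bool = False,
    z_ref: float | None = None,
) -> StemSlabFit:
    """Stem diameter from repeated MEC fits of the XY-projected slab.

    The slab sits ``slab_center`` above the lowest stem point (cm);
    ``literal_slab`` instead selects [z_min + 4.5, z_min + 5.5] cm.  The
    slab is denoised by statistical outlier removal (k=8, 2 sigma), then
    each repeat fits a seeded random ``subsample`` fraction; the diameter
    is twice the mean radius.  An empty slab yields a flagged result, not
    an exception.
    """
    coords = np.asarray(stem_coords, dtype=np.float64).reshape(-1, 3)
    if coords.shape[0] == 0:
        return StemSlabFit(0.0, 0.0, [], "empty slab")
    z0 = float(coords[:, 2].min()) if z_ref is None else float(z_ref)
    if literal_slab:
        lo, hi = z0 + 4.5, z0 + 5.5
    else:
        lo, hi = z0 + slab_center - slab_halfwidth, z0 + slab_center + slab_halfwidth
    slab = coords[(coords[:, 2] >= lo) & (coords[:, 2] <= hi)]
    if slab.shape[0] >= 3:
        slab = slab[statistical_outlier_mask(slab, k=8, std_ratio=2.0)]
    if slab.shape[0] < 3:
        return StemSlabFit(lo, hi, [], "empty slab")
    xy = slab[:, :2]
    rng = np.random.default_rng(seed)
    radii = []
    for rep in range(repeats):
        m = max(3, int(round(subsample * xy.shape[0])))
        m = min(m, xy.shape[0])
        idx = (rng.choice(xy.shape[0], m, replace=False)
               if m < xy.shape[0] else np.arange(xy.shape[0]))
        _, r = min_enclosing_circle(xy[idx], seed=rep)
        radii.append(r)
    return StemSlabFit(lo, hi, radii)


@dataclass
class LeafPlaneFit:
    """RANSAC cotyledon plane with both angle conventions."""

    normal: np.ndarray
    inlier_fraction: float
    theta_deg: float          # angle between the plane normal and +Z
    complement_deg: float     # angle between the leaf plane and the vertical


def fit_leaf_plane(leaf_coords: np.ndarray, iters: int = 200,
                   dist_threshold: float = 0.05, seed: int = 0) -> LeafPlaneFit:
    """RANSAC plane fit; the normal is oriented with a non-negative z."""
    plane = fit_plane_ransac(leaf_coords, iters=iters,
                             dist_threshold=dist_threshold, seed=seed)
    c = abs(float(plane.normal[2]))
    theta = float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))
    return LeafPlaneFit(plane.normal, plane.inlier_fraction, theta, 90.0 - theta)


def cotyledon_angle(leaf_clouds, repeats: int = 3, seed: int = 0):
    """Mean inclination over cotyledons, each averaged over seeded refits.

    Returns ``(theta, 90 - theta, flag)`` in degrees; a plant with no
    fittable cotyledon yields a flagged missing value.
    """
    if not leaf_clouds:
        return None, None, "no cotyledon"
    per_leaf = []
    for i, coords in enumerate(leaf_clouds):
        coords = np.asarray(coords, dtype=np.float64).reshape(-1, 3)
        if coords.shape[0] < 3:
            continue
        thetas = []
        for rep in range(repeats):
            try:
                fit = fit_leaf_plane(coords, seed=seed + 31 * i + rep)
            except ValueError:
                continue
            thetas.append(fit.theta_deg)
        if thetas:
            per_leaf.append(float(np.mean(thetas)))
    if not per_leaf:
        return None, None, "plane fit failed"
    theta = float(np.mean(per_leaf))
    return theta, 90.0 - theta, ""


def surface_area(coords: np.ndarray, normals: np.ndarray | None = None,
                 ball_radius: float = 0.2, max_points: int = 350,
                 retry_larger: bool = False, seed: int = 0):
    """Ball-pivoting mesh area: ``A`` (cm2), triangle count, flag.

    Sums each unique triangle's Heron area once.  On mesh failure an
    optional second pass retries with a 1.5x larger ball.
    """
    coords = np.asarray(coords, dtype=np.float64).reshape(-1, 3)
    if coords.shape[0] < 3:
        return None, 0, "mesh failure"
    try:
        faces = ball_pivot_mesh(coords, normals, radius=ball_radius,
                                max_points=max_points, seed=seed)
    except MeshFailure:
        if not retry_larger:
            return None, 0, "mesh failure"
        try:
            faces = ball_pivot_mesh(coords, normals, radius=1.5 * ball_radius,
                                    max_points=max_points, seed=seed)
        except MeshFailure:
            return None, 0, "mesh failure"
    areas = triangle_areas(coords, faces)
    return float(areas.sum()), int(len(faces)), ""


# ----------------------------------------------------------------------
# per-plant record assembly
# ----------------------------------------------------------------------

@dataclass
class PhenotypeRecord:
    """The four traits of one plant at one timepoint, with quality flags."""

    plant_id: int
    timepoint_h: float
    height_cm: float | None
    stem_diam_cm: float | None
    incl_deg: float | None
    incl_complement_deg: float | None
    area_cm2: float | None
    area_leaf1_cm2: float | None
    area_leaf2_cm2: float | None
    flags: str = ""

    def as_row(self) -> dict:
        return {
            "plant_id": self.plant_id,
            "t_h": self.timepoint_h,
            "height_cm": self.height_cm,
            "stem_diam_cm": self.stem_diam_cm,
            "incl_deg": self.incl_deg,
            "incl_complement_deg": self.incl_complement_deg,
            "area_cm2": self.area_cm2,
            "area_leaf1_cm2": self.area_leaf1_cm2,
            "area_leaf2_cm2": self.area_leaf2_cm2,
            "flags": self.flags,
        }


def measure_plant(
    coords: np.ndarray,
    sem: np.ndarray,
    normals: np.ndarray | None = None,
    leaf_clusters=None,
    plant_id: int = 0,
    timepoint_h: float = float("nan"),
    seed: int = 0,
    literal_slab: bool = False,
    ball_radius: float = 0.2,
    mesh_max_points: int = 350,
) -> PhenotypeRecord:
    """All four traits for one assembled plant.

    ``leaf_clusters`` optionally lists per-cotyledon index arrays (from
    instance segmentation); otherwise leaves are split into the two
    cotyledons by the sign of their first principal XY axis.  The two
    largest leaf clusters are treated as the cotyledons; extra clusters
    are flagged.
    """
    coords = np.asarray(coords, dtype=np.float64).reshape(-1, 3)
    sem = np.asarray(sem).reshape(-1)
    flags = []
    height, flag = plant_height(coords)
    if flag:
        flags.append(flag)

    stem = coords[sem == STEM]
    fit = stem_diameter(stem, seed=seed, literal_slab=literal_slab)
    diam = None if fit.flag else fit.diameter
    if fit.flag:
        flags.append(fit.flag)

    if leaf_clusters is None:
        leaf_clusters = _split_cotyledons(coords, sem)
    else:
        leaf_clusters = [np.asarray(c) for c in leaf_clusters]
    leaf_clusters = sorted(leaf_clusters, key=len, reverse=True)
    if len(leaf_clusters) > 2:
        flags.append(f"{len(leaf_clusters) - 2} extra leaf clusters")
        leaf_clusters = leaf_clusters[:2]

    theta, compl, flag = cotyledon_angle(
        [coords[c] for c in leaf_clusters], seed=seed
    )
    if flag:
        flags.append(flag)

    leaf_areas = []
    for i, cluster in enumerate(leaf_clusters):
        nrm = None if normals is None else np.asarray(normals)[cluster]
        a, _, aflag = surface_area(coords[cluster], nrm, ball_radius=ball_radius,
                                   max_points=mesh_max_points, seed=seed + i)
        leaf_areas.append(a)
        if aflag:
            flags.append(f"leaf{i + 1} {aflag}")
    known = [a for a in leaf_areas if a is not None]
    total = float(sum(known)) if known else None
    leaf_areas += [None] * (2 - len(leaf_areas))

    return PhenotypeRecord(
        plant_id=plant_id,
        timepoint_h=timepoint_h,
        height_cm=height,
        stem_diam_cm=diam,
        incl_deg=theta,
        incl_complement_deg=compl,
        area_cm2=total,
        area_leaf1_cm2=leaf_areas[0],
        area_leaf2_cm2=leaf_areas[1],
        flags=";".join(flags),
    )


def _split_cotyledons(coords, sem):
    """Fallback cotyledon split by the sign of the first principal XY axis."""
    idx = np.flatnonzero(sem == LEAF)
    if idx.size == 0:
        return []
    xy = coords[idx, :2] - coords[idx, :2].mean(axis=0)
    if idx.size < 2:
        return [idx]
    _, _, vt = np.linalg.svd(xy, full_matrices=False)
    side = xy @ vt[0] >= 0
    return [idx[side], idx[~side]]


def phenotype_report(plants, timepoint_h: float = float("nan"),
                     seed: int = 0, **kwargs) -> pd.DataFrame:
    """Trait table for a list of measured plants.

    ``plants`` yields dicts with keys ``plant_id``, ``coords``, ``sem``
    and optionally ``normals``, ``leaf_clusters``, ``timepoint_h``.  The
    table is sorted by (plant id, timepoint).
    """
    rows = []
    for spec in plants:
        record = measure_plant(
            spec["coords"], spec["sem"],
            normals=spec.get("normals"),
            leaf_clusters=spec.get("leaf_clusters"),
            plant_id=spec["plant_id"],
            timepoint_h=spec.get("timepoint_h", timepoint_h),
            seed=seed + int(spec["plant_id"]),
            **kwargs,
        )
        rows.append(record.as_row())
    frame = pd.DataFrame(rows)
    if len(frame):
        frame = frame.sort_values(["plant_id", "t_h"]).reset_index(drop=True)
    return frame
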