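"""Synthetic labeled tray scenes with known ground-truth phenotypes.

The generator emulates the study system: 25 cm x 25 cm cultivation trays,
each carrying a 6 x 6 grid of eggplant seedlings at 41 mm pitch, imaged at
24 h intervals between 24 h and 120 h after sowing.  A seedling is a thin
cylindrical hypocotyl (semantic label 1) topped by two planar elliptical
cotyledons (label 2) on opposite azimuths; the tray plate and its four low
walls are dense background (label 0).  Background sampling density is chosen
so that tray points exceed 75 % of each scene, matching the extreme
foreground/background imbalance of real tray reconstructions.

Growth trajectories are monotone interpolations anchored at the five
observation times; defaults span the reported ranges (height below 1.5 cm
and stem diameter 0.06-0.08 cm at 24 h, mean diameter 0.102 cm at 72 h,
inclination rising to 50-90 degrees, cotyledon area below 0.8 cm2 at 24 h).
Ground truth is recorded before surface noise is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .cloud import CLASS_PALETTE, LEAF, STEM, TRAY, LabeledPointCloud, concatenate
from . import io as pcio

T_MIN, T_MAX = 24.0, 120.0

#: anchor times (h) and default trait trajectories
_ANCHOR_T = np.array([24.0, 48.0, 72.0, 96.0, 120.0])
_ANCHOR_HEIGHT = np.array([1.20, 1.55, 2.00, 2.50, 2.90])     # cm
_ANCHOR_DIAM = np.array([0.070, 0.085, 0.102, 0.115, 0.125])  # cm
_ANCHOR_INCL = np.array([15.0, 27.0, 40.0, 58.0, 72.0])       # deg, normal vs +Z
_ANCHOR_AREA = np.array([0.50, 0.75, 1.00, 1.20, 1.35])       # cm2 per cotyledon

#: radial gap between the stem axis and the inner edge of each cotyledon (cm)
COTYLEDON_GAP = 0.15
#: cotyledon ellipse aspect ratio (semi-minor / semi-major)
LEAF_ASPECT = 0.45


@dataclass
class PhenotypeParams:
    """True morphometry of one synthetic seedling."""

    height: float                      # cm, max z of the noise-free plant
    stem_diameter: float               # cm
    cotyledon_incl: tuple              # deg per cotyledon, leaf normal vs +Z
    cotyledon_area: tuple              # cm2 per cotyledon
    azimuth: float = 0.0               # deg, first cotyledon direction

    def validate(self) -> "PhenotypeParams":
        if not self.height > 0:
            raise ValueError("height must be positive")
        if not 0 < self.stem_diameter < self.height:
            raise ValueError("stem diameter must lie in (0, height)")
        if any(a <= 0 for a in self.cotyledon_area):
            raise ValueError("cotyledon areas must be positive")
        if any(not 0 <= t <= 90 for t in self.cotyledon_incl):
            raise ValueError("inclinations must lie in [0, 90] degrees")
        return self


@dataclass
class GroundTruthPhenotype:
    """Recovery target for the trait estimators."""

    plant_id: int
    tray_id: int
    timepoint_h: float
    params: PhenotypeParams

    def as_row(self) -> dict:
        p = self.params
        return {
            "plant_id": self.plant_id,
            "tray": self.tray_id,
            "t_h": self.timepoint_h,
            "height_cm": p.height,
            "stem_diam_cm": p.stem_diameter,
            "incl1_deg": p.cotyledon_incl[0],
            "incl2_deg": p.cotyledon_incl[1],
            "area1_cm2": p.cotyledon_area[0],
            "area2_cm2": p.cotyledon_area[1],
            "azimuth_deg": p.azimuth,
        }


@dataclass
class LayoutConfig:
    """Tray geometry and sampling densities."""

    trays: int = 4
    rows: int = 6
    cols: int = 6
    pitch: float = 4.1                 # cm between seedlings
    tray_side: float = 25.0            # cm
    wall_height: float = 1.5           # cm
    tray_density: float = 250.0        # points / cm2 on tray surfaces
    plant_density: float = 400.0       # points / cm2 on plant surfaces
    noise_sd: float = 0.01             # cm, Gaussian displacement along normals
    bend_radius: float = 0.0           # cm; 0 keeps cotyledons exactly planar

    def validate(self) -> "LayoutConfig":
        if self.pitch * (self.cols - 1) >= self.tray_side:
            raise ValueError("grid does not fit on the tray")
        if self.tray_density <= 0 or self.plant_density <= 0:
            raise ValueError("densities must be positive")
        return self


# ----------------------------------------------------------------------
# growth model
# ----------------------------------------------------------------------

def growth_params(t: float, seed: int = 0, jitter: float = 0.06) -> PhenotypeParams:
    """Trait values at growth time ``t`` hours with per-plant jitter.

    All four traits are monotone non-decreasing in ``t``; the jitter is a
    fixed multiplicative factor per plant (drawn once from ``seed``), so
    monotonicity also holds across timepoints of the same plant.
    """
    if not T_MIN <= t <= T_MAX:
        raise ValueError(f"growth time {t} h outside [{T_MIN}, {T_MAX}]")
    rng = np.random.default_rng(seed)
    factors = np.exp(rng.normal(0.0, jitter, size=6)) if jitter > 0 else np.ones(6)
    azimuth = float(rng.uniform(0.0, 360.0))
    height = float(np.interp(t, _ANCHOR_T, _ANCHOR_HEIGHT) * factors[0])
    diam = float(np.interp(t, _ANCHOR_T, _ANCHOR_DIAM) * factors[1])
    incl = np.interp(t, _ANCHOR_T, _ANCHOR_INCL) * factors[2:4]
    incl = np.clip(incl, 0.0, 88.0)
    area = np.interp(t, _ANCHOR_T, _ANCHOR_AREA) * factors[4:6]
    return PhenotypeParams(
        height=height,
        stem_diameter=diam,
        cotyledon_incl=(float(incl[0]), float(incl[1])),
        cotyledon_area=(float(area[0]), float(area[1])),
        azimuth=azimuth,
    ).validate()


# ----------------------------------------------------------------------
# single seedling
# ----------------------------------------------------------------------

def _leaf_rise(area: float, incl_deg: float) -> float:
    """Height gained by a cotyledon tip above its attachment."""
    a = np.sqrt(area / (np.pi * LEAF_ASPECT))
    return float(np.sin(np.deg2rad(incl_deg)) * 2.0 * a)


def _sample_leaf(area, incl_deg, azimuth_deg, z_att, density, bend_radius, rng):
    """Sample one planar (optionally bent) elliptical cotyledon."""
    a = np.sqrt(area / (np.pi * LEAF_ASPECT))
    b = LEAF_ASPECT * a
    n = max(12, int(round(area * density)))
    r = np.sqrt(rng.uniform(0.0, 1.0, n))
    phi = rng.uniform(0.0, 2.0 * np.pi, n)
    r[0], phi[0] = 1.0, 0.0          # anchor the tip so extent is exact
    # local frame: attachment axis at x=0, leaf extends over x in [0, 2a]
    x = a + a * r * np.cos(phi)
    y = b * r * np.sin(phi)
    z = np.zeros(n)
    normals = np.tile([0.0, 0.0, 1.0], (n, 1))
    if bend_radius > 0:
        # gentle fold about the major axis
        ang = y / bend_radius
        z = bend_radius * (1.0 - np.cos(ang))
        normals = np.column_stack([np.zeros(n), np.sin(ang), np.cos(ang)])
    pts = np.column_stack([x, y, z])
    # tilt upward about the attachment axis (y), by the inclination
    th = np.deg2rad(incl_deg)
    tilt = np.array(
        [[np.cos(th), 0.0, -np.sin(th)],
         [0.0, 1.0, 0.0],
         [np.sin(th), 0.0, np.cos(th)]]
    )
    pts = pts @ tilt.T
    normals = normals @ tilt.T
    # swing to the azimuth and push out of the stem by the petiole gap
    ps = np.deg2rad(azimuth_deg)
    swing = np.array(
        [[np.cos(ps), -np.sin(ps), 0.0],
         [np.sin(ps), np.cos(ps), 0.0],
         [0.0, 0.0, 1.0]]
    )
    pts[:, 0] += COTYLEDON_GAP
    pts = pts @ swing.T
    normals = normals @ swing.T
    pts[:, 2] += z_att
    return pts, normals


def make_seedling(
    params: PhenotypeParams,
    density: float = 400.0,
    noise_sd: float = 0.01,
    seed: int = 0,
    origin=(0.0, 0.0),
    instance_id: int = 1,
    bend_radius: float = 0.0,
):
    """Sample one labeled seedling; returns ``(cloud, noise_free_cloud)``.

    The hypocotyl is a cylinder from z=0 up to the cotyledon attachment,
    placed so that the noise-free maximum z equals ``params.height`` exactly.
    """
    params.validate()
    rng = np.random.default_rng(seed)
    rise = max(
        _leaf_rise(a, t)
        for a, t in zip(params.cotyledon_area, params.cotyledon_incl)
    )
    z_att = params.height - rise
    if z_att <= 0.1 * params.height:
        raise ValueError(
            "cotyledon rise leaves no room for the hypocotyl; "
            "inclination/area too large for this height"
        )

    radius = params.stem_diameter / 2.0
    lateral = 2.0 * np.pi * radius * z_att
    n_stem = int(round(lateral * density))
    if n_stem < 10:
        raise ValueError(
            f"density {density}/cm2 places only {n_stem} stem points (<10)"
        )
    phi = rng.uniform(0.0, 2.0 * np.pi, n_stem)
    z = rng.uniform(0.0, z_att, n_stem)
    z[0], z[1] = 0.0, z_att          # anchor base and attachment
    stem_pts = np.column_stack([radius * np.cos(phi), radius * np.sin(phi), z])
    stem_normals = np.column_stack([np.cos(phi), np.sin(phi), np.zeros(n_stem)])

    leaf_pts, leaf_normals = [], []
    for i, (area, incl) in enumerate(
        zip(params.cotyledon_area, params.cotyledon_incl)
    ):
        az = params.azimuth + 180.0 * i
        p, nrm = _sample_leaf(area, incl, az, z_att, density, bend_radius, rng)
        leaf_pts.append(p)
        leaf_normals.append(nrm)
    leaf_pts = np.concatenate(leaf_pts)
    leaf_normals = np.concatenate(leaf_normals)

    pts = np.concatenate([stem_pts, leaf_pts])
    normals = np.concatenate([stem_normals, leaf_normals])
    sem = np.concatenate(
        [np.full(n_stem, STEM, np.int64), np.full(len(leaf_pts), LEAF, np.int64)]
    )
    pts[:, 0] += origin[0]
    pts[:, 1] += origin[1]

    colors = np.array([CLASS_PALETTE[s] for s in (STEM, LEAF)])
    col = np.where(sem[:, None] == STEM, colors[0], colors[1])
    inst = np.full(pts.shape[0], instance_id, np.int64)
    clean = LabeledPointCloud(pts.copy(), col, normals.copy(), sem, inst)
    noisy_pts = pts + normals * rng.normal(0.0, noise_sd, pts.shape[0])[:, None] \
        if noise_sd > 0 else pts
    cloud = LabeledPointCloud(noisy_pts, col, normals, sem, inst)
    return cloud, clean


# ----------------------------------------------------------------------
# tray scenes and experiments
# ----------------------------------------------------------------------

def _sample_rect(rng, density, extent_u, extent_v):
    n = max(1, int(round(density * extent_u * extent_v)))
    u = rng.uniform(0.0, extent_u, n)
    v = rng.uniform(0.0, extent_v, n)
    return u, v


def _make_tray(layout: LayoutConfig, rng) -> LabeledPointCloud:
    side, wall = layout.tray_side, layout.wall_height
    parts, normals = [], []
    # plate
    u, v = _sample_rect(rng, layout.tray_density, side, side)
    parts.append(np.column_stack([u, v, np.zeros_like(u)]))
    normals.append(np.tile([0.0, 0.0, 1.0], (len(u), 1)))
    # four walls (inward normals)
    for axis, pos, nrm in (
        (0, 0.0, (1.0, 0.0, 0.0)),
        (0, side, (-1.0, 0.0, 0.0)),
        (1, 0.0, (0.0, 1.0, 0.0)),
        (1, side, (0.0, -1.0, 0.0)),
    ):
        u, v = _sample_rect(rng, layout.tray_density, side, wall)
        pts = np.zeros((len(u), 3))
        pts[:, 1 - axis] = u
        pts[:, axis] = pos
        pts[:, 2] = v
        parts.append(pts)
        normals.append(np.tile(nrm, (len(u), 1)))
    pts = np.concatenate(parts)
    nrm = np.concatenate(normals)
    if layout.noise_sd > 0:
        pts = pts + nrm * rng.normal(0.0, layout.noise_sd, len(pts))[:, None]
    n = len(pts)
    col = np.tile(CLASS_PALETTE[TRAY], (n, 1))
    return LabeledPointCloud(
        pts, col, nrm, np.zeros(n, np.int64), np.zeros(n, np.int64)
    )


def make_tray_scene(
    layout: LayoutConfig | None = None,
    t: float = 72.0,
    seed: int = 0,
    tray_id: int = 0,
    n_plants: int | None = None,
):
    """One tray scene at growth time ``t``; returns ``(cloud, truths)``.

    Seedlings occupy a ``rows x cols`` grid at ``pitch`` spacing, instance
    ids 1..rows*cols assigned row-major; the tray plate and walls are
    background.  With default densities, background exceeds 75 % of points.
    """
    layout = (layout or LayoutConfig()).validate()
    rng = np.random.default_rng([seed, tray_id, 1000003])
    tray = _make_tray(layout, rng)

    total = layout.rows * layout.cols
    if n_plants is None:
        n_plants = total
    grid_w = layout.pitch * (layout.cols - 1)
    grid_h = layout.pitch * (layout.rows - 1)
    x0 = (layout.tray_side - grid_w) / 2.0
    y0 = (layout.tray_side - grid_h) / 2.0

    clouds, truths = [tray], []
    for cell in range(n_plants):
        r, c = divmod(cell, layout.cols)
        plant_id = tray_id * total + cell + 1
        params = growth_params(t, seed=_plant_seed(seed, tray_id, cell))
        # guard against cotyledon overlap at this pitch
        reach = 2.0 * max(
            COTYLEDON_GAP
            + 2.0 * np.sqrt(a / (np.pi * LEAF_ASPECT)) * np.cos(np.deg2rad(th))
            for a, th in zip(params.cotyledon_area, params.cotyledon_incl)
        )
        if reach > layout.pitch:
            warnings.warn(
                f"plant {plant_id}: cotyledon span {reach:.2f} cm exceeds "
                f"pitch {layout.pitch} cm (occlusion mode)",
                stacklevel=2,
            )
        cloud, _ = make_seedling(
            params,
            density=layout.plant_density,
            noise_sd=layout.noise_sd,
            seed=_plant_seed(seed, tray_id, cell) + 1,
            origin=(x0 + c * layout.pitch, y0 + r * layout.pitch),
            instance_id=cell + 1,
            bend_radius=layout.bend_radius,
        )
        clouds.append(cloud)
        truths.append(
            GroundTruthPhenotype(
                plant_id=plant_id, tray_id=tray_id, timepoint_h=t, params=params
            )
        )
    return concatenate(clouds), truths


def _plant_seed(seed: int, tray_id: int, cell: int) -> int:
    """Stable per-plant seed, below 2**31, independent of timepoint."""
    return int((seed * 977 + tray_id * 131 + cell * 2) % (2**31 - 1))


def make_experiment(
    layout: LayoutConfig | None = None,
    timepoints=(24.0, 48.0, 72.0, 96.0, 120.0),
    seed: int = 0,
    root=None,
) -> "pcio.DatasetIndex":
    """Full study: one scene per (tray, timepoint), saved Area-organised.

    Pot ids (= tray ids) are stable across timepoints so pot-level
    partitioning keeps all timepoints of a tray in one split.  The
    ground-truth phenotype table is saved alongside as ``ground_truth.csv``.
    """
    layout = (layout or LayoutConfig()).validate()
    if root is None:
        raise ValueError("make_experiment needs an output root")
    if len(tuple(timepoints)) == 0:
        raise ValueError("need at least one timepoint")
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    rows = []
    for tray in range(layout.trays):
        for t in timepoints:
            cloud, truths = make_tray_scene(layout, t=t, seed=seed, tray_id=tray)
            pcio.save_scene_array(
                cloud,
                area_id=str(tray + 1),
                scene_id=f"t{int(t)}h",
                root=root,
                pot_id=f"tray{tray}",
                timepoint_h=float(t),
                k=1.0,
                units="cm",
                overwrite=True,
            )
            rows.extend(g.as_row() for g in truths)
    pd.DataFrame(rows).to_csv(root / "ground_truth.csv", index=False)
    return pcio.load_dataset(root)
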