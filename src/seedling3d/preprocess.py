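"""Preprocessing: background purification, ground alignment, scale
calibration, augmentation with a provenance ledger, and pot-level splits.

Background purification removes every tray point (semantic label 0) while
leaving the source cloud untouched; it is the first stage of the
"purification - semantic segmentation - instance segmentation" pipeline and
typically discards more than 75 % of a tray scene.

Augmentation follows a fixed operation order (dropout -> rotation ->
scaling -> translation -> jitter -> shuffle) and records every sampled
parameter, so the geometric operations can be inverted exactly when traits
are extracted at physical scale (dropout and jitter are irreversible and
flagged as such).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cloud import TRAY, LabeledPointCloud
from .geometry import PlaneModel, fit_plane_ransac, rot_axis, rotation_aligning
from . import io as pcio

AUG_ORDER = ("dropout", "rotation", "scaling", "translation", "jitter", "shuffle")

#: sampled-parameter ranges for each augmentation
DROPOUT_RANGE = (0.10, 0.20)
ROTATION_RANGE_DEG = 10.0
SCALE_RANGE = (0.7, 1.3)
TRANSLATION_RANGE = 0.1          # cm per axis
JITTER_SIGMA = 0.01              # cm
JITTER_CLIP = 0.05               # cm per coordinate


# ----------------------------------------------------------------------
# background purification
# ----------------------------------------------------------------------

def purify_background(cloud: LabeledPointCloud) -> LabeledPointCloud:
    """Return a new cloud with every tray (label 0) point removed.

    Point order is preserved and the input is left untouched; an
    all-background input yields an empty cloud with a warning.
    """
    mask = cloud.sem_label != TRAY
    out = cloud.select(mask)
    if out.n_points == 0 and cloud.n_points > 0:
        warnings.warn("purification removed every point (all-background scene)",
                      stacklevel=2)
    return out


# ----------------------------------------------------------------------
# ground alignment and scale calibration
# ----------------------------------------------------------------------

def detect_ground_plane(
    cloud: LabeledPointCloud,
    iters: int = 1000,
    dist_threshold: float = 0.05,
    seed: int = 0,
) -> PlaneModel:
    """RANSAC ground-plane detection on the scene coordinates."""
    return fit_plane_ransac(
        cloud.coords, iters=iters, dist_threshold=dist_threshold, seed=seed
    )


def align_to_z(cloud: LabeledPointCloud, plane: PlaneModel):
    """Rotate the scene so the ground normal maps onto +Z.

    Returns ``(aligned cloud, rotation matrix R)`` with ``R`` orthonormal,
    det +1, applied to both coordinates and normals.
    """
    R = rotation_aligning(plane.normal, np.array([0.0, 0.0, 1.0]))
    out = cloud.copy()
    out.coords = cloud.coords @ R.T
    out.normals = cloud.normals @ R.T
    return out, R


@dataclass
class ScaleCalibration:
    """Scale factor k = L_real / L_virtual from the known tray side length."""

    k: float
    L_real: float
    L_virtual: float


def scale_factor(L_real: float, L_virtual: float) -> ScaleCalibration:
    if L_real <= 0 or L_virtual <= 0:
        raise ValueError("tray side lengths must be positive")
    return ScaleCalibration(k=L_real / L_virtual, L_real=L_real, L_virtual=L_virtual)


def apply_scale(cloud: LabeledPointCloud, k: float) -> LabeledPointCloud:
    """Multiply coordinates by ``k`` (labels and unit normals unchanged)."""
    if k <= 0:
        raise ValueError("scale factor must be positive")
    out = cloud.copy()
    out.coords = cloud.coords * float(k)
    return out


# ----------------------------------------------------------------------
# augmentation with provenance ledger
# ----------------------------------------------------------------------

@dataclass
class AugmentationRecord:
    """Ordered ledger of the operations applied to one sample."""

    sample_id: str
    ops: list = field(default_factory=list)   # (name, {param: value})

    def add(self, name: str, **params) -> None:
        self.ops.append((name, dict(params)))

    def get(self, name: str):
        for op, params in self.ops:
            if op == name:
                return params
        return None

    def rows(self):
        for op, params in self.ops:
            for key, value in params.items():
                yield {"sample_id": self.sample_id, "op": op,
                       "param_name": key, "param_value": value}


def augment_sample(
    cloud: LabeledPointCloud,
    spec=AUG_ORDER,
    seed: int = 0,
    sample_id: str = "sample",
):
    """Apply the selected augmentations in the canonical order.

    Rotations are applied to normals as well; jitter perturbs coordinates
    only and clips each perturbation to +-0.05 cm.  Every sampled parameter
    is recorded in the returned :class:`AugmentationRecord`.
    """
    if cloud.n_points == 0:
        raise ValueError("cannot augment an empty cloud")
    chosen = set(spec)
    unknown = chosen - set(AUG_ORDER)
    if unknown:
        raise ValueError(f"unknown augmentation ops: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    record = AugmentationRecord(sample_id=sample_id)
    out = cloud.copy()

    if "dropout" in chosen:
        rate = float(rng.uniform(*DROPOUT_RANGE))
        keep = rng.random(out.n_points) >= rate
        if int(keep.sum()) < 10:
            raise ValueError("dropout would leave fewer than 10 points")
        out = out.select(keep)
        record.add("dropout", rate=rate)

    if "rotation" in chosen:
        angles = rng.uniform(-ROTATION_RANGE_DEG, ROTATION_RANGE_DEG, 3)
        R = rot_axis("z", angles[2]) @ rot_axis("y", angles[1]) @ rot_axis("x", angles[0])
        out.coords = out.coords @ R.T
        out.normals = out.normals @ R.T
        record.add("rotation", angle_x_deg=float(angles[0]),
                   angle_y_deg=float(angles[1]), angle_z_deg=float(angles[2]))

    if "scaling" in chosen:
        s = float(rng.uniform(*SCALE_RANGE))
        out.coords = out.coords * s
        record.add("scaling", scale=s)

    if "translation" in chosen:
        shift = rng.uniform(-TRANSLATION_RANGE, TRANSLATION_RANGE, 3)
        out.coords = out.coords + shift
        record.add("translation", shift_x=float(shift[0]),
                   shift_y=float(shift[1]), shift_z=float(shift[2]))

    if "jitter" in chosen:
        noise = np.clip(rng.normal(0.0, JITTER_SIGMA, out.coords.shape),
                        -JITTER_CLIP, JITTER_CLIP)
        out.coords = out.coords + noise
        record.add("jitter", sigma=JITTER_SIGMA, clip=JITTER_CLIP)

    if "shuffle" in chosen:
        perm_seed = int(rng.integers(0, 2**31 - 1))
        perm = np.random.default_rng(perm_seed).permutation(out.n_points)
        out = out.select(perm)
        record.add("shuffle", perm_seed=perm_seed, n_points=out.n_points)

    return out, record


def invert_augmentation(cloud: LabeledPointCloud, record: AugmentationRecord):
    """Undo the geometric augmentations of ``record`` (reverse order).

    Dropout and jitter have no inverse; their presence is reported in the
    returned list of irreversible op names.  Surviving points are restored
    to their pre-augmentation coordinates up to the jitter clip.
    """
    out = cloud.copy()
    irreversible = []
    for op, params in reversed(record.ops):
        if op == "shuffle":
            perm = np.random.default_rng(params["perm_seed"]).permutation(
                params["n_points"]
            )
            out = out.select(np.argsort(perm))
        elif op == "jitter":
            irreversible.append(op)
        elif op == "translation":
            out.coords = out.coords - np.array(
                [params["shift_x"], params["shift_y"], params["shift_z"]]
            )
        elif op == "scaling":
            out.coords = out.coords / params["scale"]
        elif op == "rotation":
            R = (
                rot_axis("z", params["angle_z_deg"])
                @ rot_axis("y", params["angle_y_deg"])
                @ rot_axis("x", params["angle_x_deg"])
            )
            out.coords = out.coords @ R
            out.normals = out.normals @ R
        elif op == "dropout":
            irreversible.append(op)
    return out, irreversible


def write_augmentation_ledger(records, path) -> None:
    """Delimited ledger: one row per sampled parameter value."""
    rows = [row for record in records for row in record.rows()]
    pd.DataFrame(rows, columns=["sample_id", "op", "param_name", "param_value"]).to_csv(
        path, sep="\t", index=False
    )


def read_augmentation_ledger(path) -> dict:
    """Ledger file -> {sample_id: AugmentationRecord} (op order preserved)."""
    df = pd.read_csv(path, sep="\t")
    records: dict = {}
    for sample_id, group in df.groupby("sample_id", sort=False):
        rec = AugmentationRecord(sample_id=str(sample_id))
        for op, op_group in group.groupby("op", sort=False):
            params = {}
            for _, row in op_group.iterrows():
                value = row["param_value"]
                name = str(row["param_name"])
                if name in ("perm_seed", "n_points"):
                    value = int(value)
                else:
                    value = float(value)
                params[name] = value
            rec.add(str(op), **params)
        records[str(sample_id)] = rec
    return records


# ----------------------------------------------------------------------
# pot-level partitioning
# ----------------------------------------------------------------------

def partition_by_pot(pot_ids, ratios=(7, 1, 2), seed: int = 0) -> dict:
    """Random pot -> {train, val, test} assignment (largest remainder).

    Each pot appears in exactly one split, every split receives at least
    one pot, and all timepoint samples of a pot inherit its assignment.
    """
    pots = list(dict.fromkeys(pot_ids))
    n = len(pots)
    if n < 3:
        raise ValueError("need at least 3 pots to populate all three splits")
    ratios = np.asarray(ratios, dtype=np.float64)
    shares = ratios / ratios.sum() * n
    counts = np.floor(shares).astype(int)
    counts = np.maximum(counts, 1)
    remainders = shares - np.floor(shares)
    # distribute leftovers by largest remainder; ties favour train, val, test
    while counts.sum() < n:
        order = np.lexsort((np.arange(3), -remainders))
        counts[order[0]] += 1
        remainders[order[0]] = -1.0
    while counts.sum() > n:
        order = np.lexsort((np.arange(3)[::-1], remainders))
        for j in order:
            if counts[j] > 1:
                counts[j] -= 1
                break
    rng = np.random.default_rng(seed)
    shuffled = [pots[i] for i in rng.permutation(n)]
    assignment = {}
    start = 0
    for split, count in zip(("train", "val", "test"), counts):
        for pot in shuffled[start:start + count]:
            assignment[pot] = split
        start += count
    return assignment


def split_scenes(index: "pcio.DatasetIndex", assignment: dict) -> dict:
    """Group the scenes of an index by their pot's split."""
    out = {"train": [], "val": [], "test": []}
    for scene in index.scenes:
        split = assignment.get(scene.pot_id)
        if split is None:
            raise KeyError(f"scene {scene.scene_id}: pot '{scene.pot_id}' unassigned")
        out[split].append(scene)
    return out


# ----------------------------------------------------------------------
# dataset conversion
# ----------------------------------------------------------------------

def convert_dataset(
    index: "pcio.DatasetIndex", destination, purified: bool = False
) -> "pcio.DatasetIndex":
    """Re-save every scene as a merged N x 11 array (optionally purified).

    Purified and unpurified variants can coexist under different
    destinations, supporting with/without-purification comparisons.
    """
    destination = Path(destination)
    for scene in index.scenes:
        cloud = pcio.load_scene(scene)
        if purified:
            cloud = purify_background(cloud)
        pcio.save_scene_array(
            cloud,
            area_id=scene.area.removeprefix(pcio.AREA_PREFIX),
            scene_id=scene.scene_id,
            root=destination,
            pot_id=scene.pot_id,
            timepoint_h=scene.timepoint_h,
            k=scene.k,
            units=scene.units,
            ledger=scene.ledger,
            overwrite=True,
        )
    return pcio.load_dataset(destination)
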