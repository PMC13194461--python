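"""Labeled point-cloud container shared by every pipeline stage.

A scene is an unordered set of 3D points, each carrying RGB color, a unit
surface normal, a semantic label (0 tray background, 1 stem, 2 leaf) and an
instance label (0 background, >=1 individual plant id).  Coordinates are
centimetres once a scene has been aligned and scale-calibrated; freshly
reconstructed scenes may still be in arbitrary reconstruction units (tracked
by the sidecar ``units`` flag, see :mod:`seedling3d.io`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

TRAY, STEM, LEAF = 0, 1, 2
SEMANTIC_CLASSES = (TRAY, STEM, LEAF)
CLASS_NAMES = {TRAY: "tray", STEM: "stem", LEAF: "leaf"}

#: fixed per-class RGB palette used by the synthetic generator
CLASS_PALETTE = {TRAY: (120, 100, 80), STEM: (170, 200, 120), LEAF: (60, 160, 60)}

_NORMAL_TOL = 1e-3


@dataclass
class LabeledPointCloud:
    """Point cloud with per-point color, normal, semantic and instance labels.

    Invariants (checked by :meth:`validate`):

    * all arrays share the first dimension ``N``;
    * normals are unit length to ``1e-3`` (or all-zero, for points flagged
      normal-free);
    * background points and only background points carry instance id 0.
    """

    coords: np.ndarray
    colors: np.ndarray
    normals: np.ndarray
    sem_label: np.ndarray
    inst_label: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64).reshape(-1, 3)
        self.colors = np.asarray(self.colors, dtype=np.int64).reshape(-1, 3)
        self.normals = np.asarray(self.normals, dtype=np.float64).reshape(-1, 3)
        self.sem_label = np.asarray(self.sem_label, dtype=np.int64).reshape(-1)
        self.inst_label = np.asarray(self.inst_label, dtype=np.int64).reshape(-1)

    # ------------------------------------------------------------------
    @property
    def n_points(self) -> int:
        return self.coords.shape[0]

    def __len__(self) -> int:  # pragma: no cover - convenience
        return self.n_points

    def validate(self) -> "LabeledPointCloud":
        n = self.n_points
        for name in ("colors", "normals", "sem_label", "inst_label"):
            arr = getattr(self, name)
            if arr.shape[0] != n:
                raise ValueError(f"{name} has length {arr.shape[0]}, expected {n}")
        if n == 0:
            return self
        if not np.all(np.isin(self.sem_label, SEMANTIC_CLASSES)):
            bad = np.setdiff1d(np.unique(self.sem_label), SEMANTIC_CLASSES)
            raise ValueError(f"semantic labels outside {{0,1,2}}: {bad.tolist()}")
        if np.any(self.inst_label < 0):
            raise ValueError("instance labels must be non-negative")
        bg = self.sem_label == TRAY
        if np.any(self.inst_label[bg] != 0) or np.any(self.inst_label[~bg] == 0):
            raise ValueError("sem_label == 0 must coincide with inst_label == 0")
        norms = np.linalg.norm(self.normals, axis=1)
        ok = (np.abs(norms - 1.0) <= _NORMAL_TOL) | (norms == 0.0)
        if not np.all(ok):
            raise ValueError(
                f"{int(np.sum(~ok))} normals are neither unit length nor zero"
            )
        return self

    # ------------------------------------------------------------------
    def select(self, mask_or_idx) -> "LabeledPointCloud":
        """Row subset (order preserved for boolean masks)."""
        return LabeledPointCloud(
            self.coords[mask_or_idx],
            self.colors[mask_or_idx],
            self.normals[mask_or_idx],
            self.sem_label[mask_or_idx],
            self.inst_label[mask_or_idx],
        )

    def copy(self) -> "LabeledPointCloud":
        return LabeledPointCloud(
            self.coords.copy(),
            self.colors.copy(),
            self.normals.copy(),
            self.sem_label.copy(),
            self.inst_label.copy(),
        )

    def to_array(self) -> np.ndarray:
        """N x 11 array in the canonical column order (x y z r g b nx ny nz l1 l2)."""
        return np.column_stack(
            [
                self.coords,
                self.colors.astype(np.float64),
                self.normals,
                self.sem_label.astype(np.float64),
                self.inst_label.astype(np.float64),
            ]
        )

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "LabeledPointCloud":
        arr = np.asarray(arr, dtype=np.float64)
        if arr.ndim != 2 or arr.shape[1] != 11:
            raise ValueError(f"expected an N x 11 array, got shape {arr.shape}")
        return cls(
            arr[:, 0:3],
            np.rint(arr[:, 3:6]).astype(np.int64),
            arr[:, 6:9],
            np.rint(arr[:, 9]).astype(np.int64),
            np.rint(arr[:, 10]).astype(np.int64),
        )

    @classmethod
    def empty(cls) -> "LabeledPointCloud":
        z = np.zeros((0, 3))
        return cls(z, z.astype(np.int64), z, np.zeros(0, np.int64), np.zeros(0, np.int64))

    def concat(self, other: "LabeledPointCloud") -> "LabeledPointCloud":
        return concatenate([self, other])


def concatenate(clouds) -> LabeledPointCloud:
    clouds = list(clouds)
    if not clouds:
        return LabeledPointCloud.empty()
    return LabeledPointCloud(
        np.concatenate([c.coords for c in clouds]),
        np.concatenate([c.colors for c in clouds]),
        np.concatenate([c.normals for c in clouds]),
        np.concatenate([c.sem_label for c in clouds]),
        np.concatenate([c.inst_label for c in clouds]),
    )
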