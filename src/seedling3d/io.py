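"""Reading and writing the annotated point-cloud formats.

Two on-disk representations are supported:

* an 11-column whitespace text format, one point per line
  (``x y z r g b nx ny nz label1 label2``), with ``#`` comment lines; and
* a per-scene ``.npy`` binary layout organised as ``Area_<id>/<scene>.npy``
  with a small key-value sidecar per scene (pot id, timepoint, scale factor,
  units, augmentation-ledger reference) so that physical scale restoration
  stays traceable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .cloud import SEMANTIC_CLASSES, LabeledPointCloud

AREA_PREFIX = "Area_"
SIDECAR_SUFFIX = ".meta.txt"


class PointCloudParseError(ValueError):
    """Malformed line in an annotated point-cloud text file."""


@dataclass
class SceneEntry:
    """One scene (one tray at one timepoint) of a dataset."""

    area: str
    scene_id: str
    path: Path
    pot_id: str = ""
    timepoint_h: float = float("nan")
    k: float = 1.0
    units: str = "cm"
    ledger: str = ""

    @property
    def key(self) -> tuple:
        return (self.area, self.scene_id)


@dataclass
class DatasetIndex:
    """Enumeration of all scenes of an Area-organised dataset."""

    root: Path
    scenes: list = field(default_factory=list)

    @property
    def areas(self) -> list:
        return sorted({s.area for s in self.scenes})

    def __len__(self) -> int:
        return len(self.scenes)

    def by_area(self, area: str) -> list:
        return [s for s in self.scenes if s.area == area]

    def pot_ids(self) -> list:
        return sorted({s.pot_id for s in self.scenes if s.pot_id})


# ----------------------------------------------------------------------
# 11-column text format
# ----------------------------------------------------------------------

def read_labeled_points(path) -> LabeledPointCloud:
    """Read an annotated text file into a :class:`LabeledPointCloud`.

    Every non-comment, non-blank line must carry exactly 11 whitespace
    separated numeric fields; row order is preserved.
    """
    path = Path(path)
    rows = []
    with path.open("r") as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            fields = stripped.split()
            if len(fields) != 11:
                raise PointCloudParseError(
                    f"{path}:{lineno}: expected 11 fields, got {len(fields)}"
                )
            try:
                rows.append([float(x) for x in fields])
            except ValueError as exc:
                raise PointCloudParseError(f"{path}:{lineno}: {exc}") from exc
    if not rows:
        return LabeledPointCloud.empty()
    arr = np.asarray(rows, dtype=np.float64)
    sem = np.rint(arr[:, 9]).astype(np.int64)
    bad = ~np.isin(sem, SEMANTIC_CLASSES)
    if np.any(bad):
        first = int(np.flatnonzero(bad)[0])
        raise ValueError(
            f"{path}: semantic label {sem[first]} outside {{0,1,2}} "
            f"(data row {first + 1})"
        )
    return LabeledPointCloud.from_array(arr)


def write_labeled_points(cloud: LabeledPointCloud, path) -> None:
    """Write the 11-column text format (floats with 6 decimals)."""
    path = Path(path)
    arr = cloud.to_array()
    with path.open("w") as fh:
        for row in arr:
            fh.write(
                "%.6f %.6f %.6f %d %d %d %.6f %.6f %.6f %d %d\n"
                % (
                    row[0], row[1], row[2],
                    int(row[3]), int(row[4]), int(row[5]),
                    row[6], row[7], row[8],
                    int(row[9]), int(row[10]),
                )
            )


# ----------------------------------------------------------------------
# sidecar metadata
# ----------------------------------------------------------------------

def _write_sidecar(entry: SceneEntry) -> None:
    side = Path(str(entry.path)[: -len(".npy")] + SIDECAR_SUFFIX)
    with side.open("w") as fh:
        fh.write(f"pot_id\t{entry.pot_id}\n")
        fh.write(f"timepoint_h\t{entry.timepoint_h}\n")
        fh.write(f"k\t{entry.k}\n")
        fh.write(f"units\t{entry.units}\n")
        fh.write(f"ledger\t{entry.ledger}\n")


def _read_sidecar(npy_path: Path) -> dict:
    side = Path(str(npy_path)[: -len(".npy")] + SIDECAR_SUFFIX)
    if not side.exists():
        warnings.warn(
            f"missing sidecar for {npy_path.name}; assuming k=1, no ledger",
            stacklevel=3,
        )
        return {}
    out = {}
    for line in side.read_text().splitlines():
        if "\t" in line:
            key, _, value = line.partition("\t")
            out[key] = value
    return out


# ----------------------------------------------------------------------
# Area-organised binary layout
# ----------------------------------------------------------------------

def save_scene_array(
    cloud: LabeledPointCloud,
    area_id: str,
    scene_id: str,
    root,
    *,
    pot_id: str = "",
    timepoint_h: float = float("nan"),
    k: float = 1.0,
    units: str = "cm",
    ledger: str = "",
    overwrite: bool = False,
) -> Path:
    """Save one scene as an ``N x 11`` array under ``Area_<id>/<scene_id>.npy``.

    The column order matches the text schema exactly, so text and binary
    round trips are interchangeable.
    """
    root = Path(root)
    area_dir = root / f"{AREA_PREFIX}{area_id}"
    area_dir.mkdir(parents=True, exist_ok=True)
    path = area_dir / f"{scene_id}.npy"
    if path.exists() and not overwrite:
        raise FileExistsError(f"scene '{scene_id}' already exists in Area_{area_id}")
    np.save(path, cloud.to_array())
    entry = SceneEntry(
        area=f"{AREA_PREFIX}{area_id}", scene_id=scene_id, path=path,
        pot_id=pot_id, timepoint_h=timepoint_h, k=k, units=units, ledger=ledger,
    )
    _write_sidecar(entry)
    return path


def load_scene(entry: SceneEntry) -> LabeledPointCloud:
    return LabeledPointCloud.from_array(np.load(entry.path))


def load_dataset(root) -> DatasetIndex:
    """Enumerate every scene array under an Area-organised root."""
    root = Path(root)
    area_dirs = sorted(p for p in root.glob(f"{AREA_PREFIX}*") if p.is_dir())
    if not area_dirs:
        raise FileNotFoundError(f"no {AREA_PREFIX}* directories under {root}")
    index = DatasetIndex(root=root)
    for area_dir in area_dirs:
        for npy in sorted(area_dir.glob("*.npy")):
            meta = _read_sidecar(npy)
            index.scenes.append(
                SceneEntry(
                    area=area_dir.name,
                    scene_id=npy.stem,
                    path=npy,
                    pot_id=meta.get("pot_id", ""),
                    timepoint_h=float(meta.get("timepoint_h", "nan") or "nan"),
                    k=float(meta.get("k", 1.0)),
                    units=meta.get("units", "cm"),
                    ledger=meta.get("ledger", ""),
                )
            )
    return index


# ----------------------------------------------------------------------
# convenience exports
# ----------------------------------------------------------------------

def export_ply(cloud: LabeledPointCloud, path) -> None:
    """Binary little-endian PLY export (coords, colors, normals)."""
    path = Path(path)
    n = cloud.n_points
    header = (
        "ply\nformat binary_little_endian 1.0\n"
        f"element vertex {n}\n"
        "property float x\nproperty float y\nproperty float z\n"
        "property uchar red\nproperty uchar green\nproperty uchar blue\n"
        "property float nx\nproperty float ny\nproperty float nz\n"
        "end_header\n"
    )
    rec = np.zeros(
        n,
        dtype=[
            ("xyz", "<f4", 3),
            ("rgb", "u1", 3),
            ("n", "<f4", 3),
        ],
    )
    rec["xyz"] = cloud.coords
    rec["rgb"] = np.clip(cloud.colors, 0, 255)
    rec["n"] = cloud.normals
    with path.open("wb") as fh:
        fh.write(header.encode("ascii"))
        fh.write(rec.tobytes())
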