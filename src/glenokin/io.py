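"""File formats: region surfaces (PLY/STL/CSV), study manifests, transforms.

All coordinates are millimetres in the world frame of the reference scan;
nothing here deals in voxels.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

from .exceptions import MeshIOError
from .kinematics import LabelledFrame

__all__ = ["read_region_mesh", "write_region_mesh", "StudyManifest", "load_manifest"]


def read_region_mesh(path):
    """Read a region surface from PLY/STL (ASCII or binary) or an x,y,z CSV.

    Returns a :class:`trimesh.Trimesh` for triangulated input, otherwise an
    (n, 3) float array of points.  Triangles are validated: out-of-range
    vertex indices raise :class:`MeshIOError`; (near-)zero-area faces only
    trigger a warning.
    """
    path = Path(path)
    if not path.exists():
        raise MeshIOError(f"no such file: {path}")
    if path.stat().st_size == 0:
        raise MeshIOError(f"empty file: {path}")
    if path.suffix.lower() in (".csv", ".xyz"):
        try:
            df = pd.read_csv(path)
        except Exception as exc:
            raise MeshIOError(f"cannot parse point CSV {path}: {exc}") from exc
        cols = [c for c in ("x", "y", "z") if c in df.columns]
        if len(cols) != 3:
            raise MeshIOError(f"{path} must have x,y,z columns")
        return df[["x", "y", "z"]].to_numpy(float)
    try:
        obj = trimesh.load(path, process=False, force=None)
    except Exception as exc:
        raise MeshIOError(f"cannot read mesh {path}: {exc}") from exc
    if isinstance(obj, trimesh.Scene):
        geoms = list(obj.geometry.values())
        if len(geoms) != 1:
            raise MeshIOError(f"{path} holds {len(geoms)} geometries, expected 1")
        obj = geoms[0]
    if isinstance(obj, trimesh.PointCloud):
        pts = np.asarray(obj.vertices, dtype=float)
        if len(pts) == 0:
            raise MeshIOError(f"{path} contains no vertices")
        return pts
    if not isinstance(obj, trimesh.Trimesh):
        raise MeshIOError(f"unsupported geometry in {path}: {type(obj).__name__}")
    verts = np.asarray(obj.vertices, dtype=float)
    faces = np.asarray(obj.faces)
    if len(verts) == 0:
        raise MeshIOError(f"{path} contains no vertices")
    if len(faces) == 0:
        return verts
    if faces.min() < 0 or faces.max() >= len(verts):
        raise MeshIOError(f"{path}: face references vertex outside 0..{len(verts) - 1}")
    areas = trimesh.triangles.area(verts[faces])
    if np.any(areas < 1e-10):
        warnings.warn(
            f"{path.name}: {int(np.sum(areas < 1e-10))} (near-)zero-area faces",
            stacklevel=2,
        )
    return trimesh.Trimesh(vertices=verts, faces=faces, process=False)


def write_region_mesh(obj, path) -> Path:
    """Write a mesh or point set to PLY/STL (by extension)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(obj, trimesh.Trimesh):
        obj.export(path)
    else:
        trimesh.PointCloud(np.asarray(obj, dtype=float)).export(path)
    return path


@dataclass
class StudyManifest:
    """Per-shoulder description of a dynamic acquisition on disk.

    ``frames`` maps frame indices to ``{"time_s": float, "regions":
    {name: path}}`` with paths relative to ``root``.
    """

    shoulder_id: str
    group: str
    side: str
    reference_index: int
    frames: dict[int, dict]
    root: Path
    superior_hint: np.ndarray | None = None
    anterior_hint: np.ndarray | None = None
    config: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.reference_index not in self.frames:
            raise ValueError(
                f"reference_index {self.reference_index} not among frames"
            )
        for idx, entry in self.frames.items():
            for name, rel in entry["regions"].items():
                p = self.root / rel
                if not p.exists():
                    raise FileNotFoundError(
                        f"frame {idx} region {name!r}: missing file {p}"
                    )

    def load_frames(self) -> list[LabelledFrame]:
        """Read every referenced surface file into labelled frames, ordered
        by frame index."""
        self.validate()
        frames = []
        for idx in sorted(self.frames):
            entry = self.frames[idx]
            regions = {
                name: read_region_mesh(self.root / rel)
                for name, rel in entry["regions"].items()
            }
            frames.append(
                LabelledFrame(
                    frame_index=idx,
                    time_s=float(entry["time_s"]),
                    regions=regions,
                    side=self.side,
                )
            )
        return frames


def load_manifest(path) -> StudyManifest:
    """Load a ``manifest.json`` written by the cohort generator (or by
    hand, same schema)."""
    path = Path(path)
    try:
        data = json.loads(path.read_text())
    except Exception as exc:
        raise MeshIOError(f"cannot parse manifest {path}: {exc}") from exc
    frames = {
        int(e["index"]): {"time_s": e["time_s"], "regions": e["regions"]}
        for e in data["frames"]
    }
    return StudyManifest(
        shoulder_id=data["shoulder_id"],
        group=data.get("group", "NA"),
        side=data.get("side", "right"),
        reference_index=int(data.get("reference_index", 0)),
        frames=frames,
        root=path.parent,
        superior_hint=np.array(data["superior_hint"]) if "superior_hint" in data else None,
        anterior_hint=np.array(data["anterior_hint"]) if "anterior_hint" in data else None,
        config=data.get("config", {}),
    )
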