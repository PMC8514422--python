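"""Reading and writing meshes, landmarks, scenes, configs, and results.

Meshes are STL/OBJ/PLY (mm units); landmarks are CSV (``name,x,y,z``) or
JSON keyed by the ten closed schema names — explicit names, never positional
order, so left/right swaps cannot pass silently.  A scene is one JSON file
per motion segment with mesh paths relative to the scene file; bending
configurations are JSON or YAML; result tables are CSV.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh
import yaml

from .bending_engine import BendingConfig, LABEL_PRIORITY
from .rigid_geometry import JointFrame
from .segment_model import LandmarkSet, MotionSegment, build_segment

__all__ = [
    "read_mesh", "write_mesh", "read_landmarks", "write_landmarks",
    "SceneDescription", "load_scene", "save_scene", "load_segment",
    "read_config", "write_config", "write_results", "read_results",
    "RESULT_COLUMNS",
]

_MESH_SUFFIXES = {".stl", ".obj", ".ply"}

RESULT_COLUMNS = ["segment_id", "direction", "stop_angle", "constraint_label",
                  "run_variant", "all_labels", "translation_used"]

_VALID_LABELS = set(LABEL_PRIORITY)


def read_mesh(path, units_scale: float = 1.0) -> trimesh.Trimesh:
    """Load a triangle mesh, scaling vertex coordinates by ``units_scale``.

    The watertightness flag is available as ``mesh.is_watertight``; meshes
    are not repaired here beyond trimesh's parsing.
    """
    if not (units_scale > 0 and np.isfinite(units_scale)):
        raise ValueError("degenerate scale")
    path = Path(path)
    if path.suffix.lower() not in _MESH_SUFFIXES:
        raise ValueError(f"unsupported mesh format {path.suffix!r} "
                         f"(expected one of {sorted(_MESH_SUFFIXES)})")
    # process=True merges the duplicated vertices of STL triangle soup so
    # connected components (and their convexity) are detected correctly
    mesh = trimesh.load(path, force="mesh", process=True)
    if not isinstance(mesh, trimesh.Trimesh) or len(mesh.faces) == 0:
        raise ValueError(f"{path}: no triangles found")
    if not np.all(np.isfinite(mesh.vertices)):
        raise ValueError(f"{path}: non-finite vertex coordinates")
    if units_scale != 1.0:
        mesh.apply_scale(units_scale)
    return mesh


def write_mesh(mesh: trimesh.Trimesh, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    mesh.export(path)


def read_landmarks(path) -> LandmarkSet:
    """Read the ten named joint landmarks from CSV (name,x,y,z) or JSON."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        coords = json.loads(path.read_text())
    else:
        df = pd.read_csv(path)
        required = {"name", "x", "y", "z"}
        if not required.issubset(df.columns):
            raise ValueError(f"{path}: landmark CSV needs columns "
                             f"{sorted(required)}")
        dup = df["name"][df["name"].duplicated()].tolist()
        if dup:
            raise ValueError(f"{path}: duplicate landmark name(s): {dup}")
        coords = {r["name"]: [r["x"], r["y"], r["z"]]
                  for _, r in df.iterrows()}
    return LandmarkSet(coords)  # closed schema validated there


def write_landmarks(landmarks: LandmarkSet, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(landmarks.to_dict(), indent=1))
    else:
        rows = [{"name": n, "x": v[0], "y": v[1], "z": v[2]}
                for n, v in landmarks.to_dict().items()]
        pd.DataFrame(rows).to_csv(path, index=False)


@dataclass(frozen=True)
class SceneDescription:
    """One articulated motion-segment scene (paths relative to the file)."""

    segment_id: str
    anterior_mesh_path: Path
    posterior_mesh_path: Path
    frame: JointFrame
    landmarks: LandmarkSet
    species: str = ""
    joint: str = ""
    anterior_id: str = "anterior"
    posterior_id: str = "posterior"


def load_scene(path) -> SceneDescription:
    path = Path(path)
    d = json.loads(path.read_text())
    base = path.parent
    ant = base / d["anterior_mesh"]
    post = base / d["posterior_mesh"]
    for p in (ant, post):
        if not p.exists():
            raise FileNotFoundError(f"scene mesh path does not resolve: {p}")
    lm = d["landmarks"]
    landmarks = (LandmarkSet(lm) if isinstance(lm, dict)
                 else read_landmarks(base / lm))
    return SceneDescription(
        segment_id=d.get("segment_id", path.stem),
        anterior_mesh_path=ant, posterior_mesh_path=post,
        frame=JointFrame.from_dict(d["frame"]), landmarks=landmarks,
        species=d.get("species", ""), joint=d.get("joint", ""),
        anterior_id=d.get("anterior_id", "anterior"),
        posterior_id=d.get("posterior_id", "posterior"))


def save_scene(scene: SceneDescription, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    d = {
        "segment_id": scene.segment_id,
        "anterior_mesh": str(Path(scene.anterior_mesh_path).name
                             if Path(scene.anterior_mesh_path).parent
                             == path.parent else scene.anterior_mesh_path),
        "posterior_mesh": str(Path(scene.posterior_mesh_path).name
                              if Path(scene.posterior_mesh_path).parent
                              == path.parent else scene.posterior_mesh_path),
        "frame": scene.frame.to_dict(),
        "landmarks": scene.landmarks.to_dict(),
        "species": scene.species, "joint": scene.joint,
        "anterior_id": scene.anterior_id, "posterior_id": scene.posterior_id,
    }
    path.write_text(json.dumps(d, indent=1))


def load_segment(scene: SceneDescription, units_scale: float = 1.0
                 ) -> MotionSegment:
    """Read the scene's meshes and assemble the motion segment."""
    anterior = read_mesh(scene.anterior_mesh_path, units_scale)
    posterior = read_mesh(scene.posterior_mesh_path, units_scale)
    return build_segment(anterior, posterior, scene.frame, scene.landmarks,
                         segment_id=scene.segment_id,
                         anterior_id=scene.anterior_id,
                         posterior_id=scene.posterior_id)


def read_config(path) -> BendingConfig:
    path = Path(path)
    text = path.read_text()
    d = (json.loads(text) if path.suffix.lower() == ".json"
         else yaml.safe_load(text))
    return BendingConfig.from_dict(d or {})


def write_config(config: BendingConfig, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    d = config.to_dict()
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(d, indent=1))
    else:
        path.write_text(yaml.safe_dump(d))


def _validate_results(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in RESULT_COLUMNS if c not in table.columns]
    if missing and len(table) > 0:
        raise ValueError(f"result table missing column(s): {missing}")
    if len(table) == 0:
        return pd.DataFrame(columns=RESULT_COLUMNS)
    bad = set(table["constraint_label"]) - _VALID_LABELS
    if bad:
        raise ValueError(f"invalid constraint label(s): {sorted(bad)}")
    if (table["stop_angle"] < 0).any():
        raise ValueError("negative stop angle")
    return table[RESULT_COLUMNS + [c for c in table.columns
                                   if c not in RESULT_COLUMNS]]


def write_results(table: pd.DataFrame, path) -> None:
    """Write a result table as CSV with a fixed header (lossless round trip)."""
    out = _validate_results(table)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, index=False)


def read_results(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    return _validate_results(df)
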