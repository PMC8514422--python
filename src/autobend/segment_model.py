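"""Motion-segment assembly: landmarks, strain references, spacing, chaining.

A motion segment is two adjacent vertebrae plus the joint between them.  The
anterior vertebra is fixed; all posterior-body motion is expressed relative
to it.  Strain constraints are referenced to the neutral pose: the
craniocaudal (frame-x) separation of the two zygapophyseal landmarks and the
Euclidean distances of the four matched centrum endplate landmark pairs.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import trimesh

from .rigid_geometry import (JointFrame, RigidShape, intersect_shapes,
                             surface_area, translate_along_frame)

__all__ = [
    "LANDMARK_NAMES", "ANTERIOR_LANDMARKS", "POSTERIOR_LANDMARKS",
    "LandmarkSet", "StrainReference", "MotionSegment", "ColumnChain",
    "build_segment", "adjust_spacing", "chain_segments",
]

# Closed landmark schema: one zygapophyseal pair (left side) and four centrum
# endplate pairs (dorsal, ventral, left, right).
ANTERIOR_LANDMARKS = ("zyg_post_caudal", "ant_dorsal", "ant_ventral",
                      "ant_left", "ant_right")
POSTERIOR_LANDMARKS = ("zyg_pre_cranial", "post_dorsal", "post_ventral",
                       "post_left", "post_right")
LANDMARK_NAMES = ANTERIOR_LANDMARKS + POSTERIOR_LANDMARKS

CENTRUM_PAIRS = (("ant_dorsal", "post_dorsal"), ("ant_ventral", "post_ventral"),
                 ("ant_left", "post_left"), ("ant_right", "post_right"))
CENTRUM_PAIR_NAMES = ("dorsal", "ventral", "left", "right")


class LandmarkSet(Mapping):
    """The ten named joint landmarks, keyed by name.

    Anterior-group landmarks ride the (fixed) anterior vertebra; the
    posterior group rides the posterior rigid body.
    """

    def __init__(self, coords: Mapping[str, Sequence[float]]):
        keys = set(coords)
        missing = set(LANDMARK_NAMES) - keys
        extra = keys - set(LANDMARK_NAMES)
        if missing:
            raise ValueError(f"missing landmark(s): {sorted(missing)}")
        if extra:
            raise ValueError(f"unknown landmark(s): {sorted(extra)}")
        self._coords = {}
        for name in LANDMARK_NAMES:
            v = np.asarray(coords[name], dtype=float).reshape(3)
            if not np.all(np.isfinite(v)):
                raise ValueError(f"non-finite coordinate for landmark {name!r}")
            self._coords[name] = v

    def __getitem__(self, name):
        return self._coords[name]

    def __iter__(self):
        return iter(self._coords)

    def __len__(self):
        return len(self._coords)

    def posterior_array(self) -> np.ndarray:
        return np.stack([self._coords[n] for n in POSTERIOR_LANDMARKS])

    def anterior_array(self) -> np.ndarray:
        return np.stack([self._coords[n] for n in ANTERIOR_LANDMARKS])

    def with_posterior_transformed(self, matrix: np.ndarray) -> "LandmarkSet":
        coords = dict(self._coords)
        for name in POSTERIOR_LANDMARKS:
            coords[name] = coords[name] @ matrix[:3, :3].T + matrix[:3, 3]
        return LandmarkSet(coords)

    def to_dict(self) -> dict:
        return {k: v.tolist() for k, v in self._coords.items()}


@dataclass(frozen=True)
class StrainReference:
    """Neutral-pose reference lengths for the strain constraints (mm)."""

    zyg_d0: float                 # |frame-x component| of the zyg pair
    centrum_d0: np.ndarray        # (dorsal, ventral, left, right) distances
    mean_spacing: float           # mean of centrum_d0
    zyg_usable: bool = True


@dataclass(frozen=True)
class MotionSegment:
    """Two vertebrae, their joint frame, landmarks, and cached references."""

    anterior: trimesh.Trimesh
    posterior: trimesh.Trimesh
    frame: JointFrame
    landmarks: LandmarkSet
    reference: StrainReference
    mean_area: float
    sqrt_area: float
    segment_id: str = "segment"
    anterior_id: str = "anterior"
    posterior_id: str = "posterior"
    neutral_overlap_warning: bool = False
    _shapes: dict = field(default_factory=dict, repr=False, compare=False)

    @property
    def anterior_shape(self) -> RigidShape:
        if "anterior" not in self._shapes:
            self._shapes["anterior"] = RigidShape(self.anterior)
        return self._shapes["anterior"]

    @property
    def posterior_shape(self) -> RigidShape:
        if "posterior" not in self._shapes:
            self._shapes["posterior"] = RigidShape(self.posterior)
        return self._shapes["posterior"]


def _compute_reference(frame: JointFrame, landmarks: LandmarkSet) -> StrainReference:
    sep = landmarks["zyg_pre_cranial"] - landmarks["zyg_post_caudal"]
    # absolute x-component so landmark ordering cannot flip the sign
    zyg_d0 = float(abs(sep @ frame.x_axis))
    zyg_usable = zyg_d0 > 1e-12
    d0 = np.array([np.linalg.norm(landmarks[b] - landmarks[a])
                   for a, b in CENTRUM_PAIRS])
    if np.any(d0 <= 1e-12):
        bad = [CENTRUM_PAIR_NAMES[i] for i in np.flatnonzero(d0 <= 1e-12)]
        raise ValueError(f"zero centrum reference length for pair(s): {bad}")
    return StrainReference(zyg_d0=zyg_d0, centrum_d0=d0,
                           mean_spacing=float(d0.mean()), zyg_usable=zyg_usable)


def build_segment(anterior: trimesh.Trimesh, posterior: trimesh.Trimesh,
                  frame: JointFrame, landmarks: LandmarkSet,
                  segment_id: str = "segment", anterior_id: str = "anterior",
                  posterior_id: str = "posterior") -> MotionSegment:
    """Assemble a motion segment and cache its neutral references.

    Caches the zygapophyseal reference length (absolute frame-x component),
    the four centrum pair distances, and the mean vertebral surface area.  A
    zero zygapophyseal reference leaves the segment usable with the zyg
    constraint flagged off; a zero centrum reference is an error.
    """
    reference = _compute_reference(frame, landmarks)
    if not reference.zyg_usable:
        warnings.warn("zygapophyseal reference length is zero; "
                      "zyg strain constraint disabled for this segment")
    mean_area = 0.5 * (surface_area(anterior) + surface_area(posterior))
    return MotionSegment(anterior=anterior, posterior=posterior, frame=frame,
                         landmarks=landmarks, reference=reference,
                         mean_area=mean_area, sqrt_area=float(np.sqrt(mean_area)),
                         segment_id=segment_id, anterior_id=anterior_id,
                         posterior_id=posterior_id)


def adjust_spacing(segment: MotionSegment, fraction: float) -> MotionSegment:
    """Widen (+) or narrow (-) the joint by ``fraction`` of the mean spacing.

    The posterior rigid body (mesh and its landmarks) is translated along
    frame x by ``fraction * mean_spacing`` and all references are recomputed:
    the shifted pose becomes the new neutral.  For landmark pairs parallel to
    the x-axis this scales the mean spacing by exactly ``1 + fraction``.
    """
    if not abs(fraction) < 1:
        raise ValueError("|fraction| must be < 1")
    if fraction == 0:
        return segment
    dist = fraction * segment.reference.mean_spacing
    posterior = translate_along_frame(segment.posterior, segment.frame,
                                      segment.frame.x_axis, dist)
    m = np.eye(4)
    m[:3, 3] = segment.frame.x_axis * dist
    landmarks = segment.landmarks.with_posterior_transformed(m)
    out = build_segment(segment.anterior, posterior, segment.frame, landmarks,
                        segment_id=segment.segment_id,
                        anterior_id=segment.anterior_id,
                        posterior_id=segment.posterior_id)
    overlap = intersect_shapes(out.anterior_shape, out.posterior_shape)
    if overlap.area > 0:
        warnings.warn(f"adjust_spacing({fraction:+g}) produced neutral-pose "
                      f"overlap (area {overlap.area:.3g} mm^2)")
        out = replace(out, neutral_overlap_warning=True)
    return out


# ---------------------------------------------------------------------------
# Craniocaudal chaining
# ---------------------------------------------------------------------------

class ColumnChain:
    """Hierarchically linked motion segments, cranial to caudal.

    World transforms compose down the column, so vertebra ``k`` carries the
    product of all upstream joint poses.  Per-joint ROM is nevertheless
    evaluated segment-by-segment from each joint's own neutral pose: chained
    rotations do not alter a single joint's admissible angles.
    """

    def __init__(self, segments: Sequence[MotionSegment]):
        segments = list(segments)
        for prev, nxt in zip(segments, segments[1:]):
            if prev.posterior_id != nxt.anterior_id:
                raise ValueError(
                    f"segment chain mismatch: {prev.segment_id!r} posterior "
                    f"{prev.posterior_id!r} != {nxt.segment_id!r} anterior "
                    f"{nxt.anterior_id!r}")
        self.segments = segments

    def __len__(self):
        return len(self.segments)

    def world_poses(self, joint_poses: Sequence[np.ndarray] | None = None):
        """4x4 world transforms for each vertebra (n_segments + 1 entries).

        ``joint_poses[i]`` is the pose of segment i's posterior body relative
        to its own anterior (identity when None).
        """
        n = len(self.segments)
        if joint_poses is None:
            joint_poses = [np.eye(4)] * n
        if len(joint_poses) != n:
            raise ValueError("one joint pose per segment required")
        poses = [np.eye(4)]
        for jp in joint_poses:
            poses.append(poses[-1] @ np.asarray(jp, float))
        return poses

    def to_json(self, joint_poses=None) -> str:
        poses = self.world_poses(joint_poses)
        ids = [self.segments[0].anterior_id] + [s.posterior_id
                                                for s in self.segments]
        return json.dumps({"vertebrae": ids,
                           "poses": [p.tolist() for p in poses]}, indent=1)

    @staticmethod
    def poses_from_json(text: str):
        d = json.loads(text)
        return d["vertebrae"], [np.asarray(p, float) for p in d["poses"]]


def chain_segments(segments: Sequence[MotionSegment]) -> ColumnChain:
    """Chain segments cranial to caudal, validating shared-vertebra ids."""
    return ColumnChain(segments)
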