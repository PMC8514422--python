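"""The incremental digital-bending loop with constraint evaluation.

The posterior vertebra is rotated about the joint COR in fixed increments
(default half a degree) until a constraint on motion is reached: boolean
mesh intersection above a threshold fraction of mean vertebral surface area,
zygapophyseal strain outside its bounds, or centrum strain outside its
bounds.  If no constraint is reached, bending stops at the configured cap
(default 45 degrees).  The reported stop angle is the last non-violating
probe — the pose actually attainable.

Direction sign convention (configuration-documented, not an anatomical
assumption): positive z-rotation is dorsiflexion, negative ventroflexion;
positive y-rotation is labelled left lateroflexion; positive x-rotation left
axial rotation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .rigid_geometry import intersect_shapes
from .segment_model import (CENTRUM_PAIRS, CENTRUM_PAIR_NAMES, MotionSegment)

__all__ = [
    "DIRECTIONS", "LABEL_PRIORITY", "primary_label", "BendingConfig",
    "ConstraintStatus", "DirectionResult", "BendingResult",
    "eval_intersection", "eval_zyg_strain", "eval_centrum_strain",
    "bend_direction", "run_all_directions",
]

# direction -> (frame axis, rotation sign)
DIRECTIONS: Mapping[str, tuple] = {
    "dorsiflexion": ("z", +1.0),
    "ventroflexion": ("z", -1.0),
    "left-lateral": ("y", +1.0),
    "right-lateral": ("y", -1.0),
    "left-axial": ("x", +1.0),
    "right-axial": ("x", -1.0),
}

# Relief translation: a perpendicular shift toward the side the posterior
# body swings during bending.  Dorsi/ventroflexion shift dorsally/ventrally
# along frame y; lateral and axial rotations shift mediolaterally along
# frame z toward the swing side (+y rotation swings the posterior body,
# which sits at +x, toward -z).
_RELIEF = {
    "dorsiflexion": ("y", +1.0),
    "ventroflexion": ("y", -1.0),
    "left-lateral": ("z", -1.0),
    "right-lateral": ("z", +1.0),
    "left-axial": ("z", +1.0),
    "right-axial": ("z", -1.0),
}

LABEL_PRIORITY = ("intersection", "zyg-disarticulation", "zyg-overlap",
                  "centrum-tension", "centrum-compression", "max-angle")


def primary_label(labels) -> str:
    """Resolve a set of simultaneous constraint labels by fixed priority
    (intersection > zygapophyseal > centrum)."""
    for lab in LABEL_PRIORITY:
        if lab in labels:
            return lab
    raise ValueError(f"no known label in {labels!r}")


@dataclass(frozen=True)
class BendingConfig:
    """Parameters of one digital bending experiment.

    ``intersection_threshold`` is a fraction of mean vertebral surface area;
    strain bounds are signed fractions of the neutral reference lengths;
    ``translation_fraction`` is the total relief-translation budget as a
    fraction of sqrt(mean area) (0 disables translation), consumed in steps
    of ``translation_step_fraction`` (defaults to the whole budget).
    """

    increment: float = 0.5
    max_angle: float = 45.0
    intersection_threshold: float = 0.0025
    zyg_bounds: tuple = (-0.5, 0.5)
    centrum_bounds: tuple = (-0.5, 0.5)
    translation_fraction: float = 0.0
    translation_step_fraction: float | None = None
    enabled: tuple = ("intersection", "zyg", "centrum")
    intersection_measure: str = "surface_area"
    voxel_pitch: float | None = None

    def __post_init__(self):
        if not (self.increment > 0 and np.isfinite(self.increment)):
            raise ValueError("increment must be positive")
        k = self.max_angle / self.increment
        if abs(k - round(k)) > 1e-9:
            raise ValueError("max_angle must be a multiple of increment")
        for name, bounds in (("zyg", self.zyg_bounds),
                             ("centrum", self.centrum_bounds)):
            if name in self.enabled:
                lo, hi = bounds
                if not (lo < 0 < hi):
                    raise ValueError(f"{name}_bounds must straddle 0")
        unknown = set(self.enabled) - {"intersection", "zyg", "centrum"}
        if unknown:
            raise ValueError(f"unknown constraints enabled: {sorted(unknown)}")
        if self.translation_fraction < 0:
            raise ValueError("translation_fraction must be >= 0")
        if self.intersection_measure not in ("surface_area", "volume"):
            raise ValueError("intersection_measure must be "
                             "'surface_area' or 'volume'")

    @property
    def n_steps(self) -> int:
        return int(round(self.max_angle / self.increment))

    def to_dict(self) -> dict:
        return {
            "increment": self.increment, "max_angle": self.max_angle,
            "intersection_threshold": self.intersection_threshold,
            "zyg_bounds": list(self.zyg_bounds),
            "centrum_bounds": list(self.centrum_bounds),
            "translation_fraction": self.translation_fraction,
            "translation_step_fraction": self.translation_step_fraction,
            "enabled": list(self.enabled),
            "intersection_measure": self.intersection_measure,
            "voxel_pitch": self.voxel_pitch,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BendingConfig":
        kw = dict(d)
        for key in ("zyg_bounds", "centrum_bounds", "enabled"):
            if key in kw and kw[key] is not None:
                kw[key] = tuple(kw[key])
        return cls(**kw)


@dataclass(frozen=True)
class ConstraintStatus:
    violated: bool
    labels: frozenset
    measures: dict = field(default_factory=dict)
    flagged: bool = False

    def __post_init__(self):
        if self.violated != bool(self.labels):
            raise ValueError("labels must be non-empty iff violated")


def _merge(*statuses: ConstraintStatus) -> ConstraintStatus:
    labels = frozenset(itertools.chain.from_iterable(s.labels for s in statuses))
    measures = {}
    for s in statuses:
        measures.update(s.measures)
    return ConstraintStatus(violated=bool(labels), labels=labels,
                            measures=measures,
                            flagged=any(s.flagged for s in statuses))


# ---------------------------------------------------------------------------
# Constraint evaluators (pose = 4x4 rigid transform of the posterior body)
# ---------------------------------------------------------------------------

def eval_intersection(segment: MotionSegment, pose: np.ndarray,
                      threshold: float, measure_mode: str = "surface_area",
                      pitch: float | None = None) -> ConstraintStatus:
    """Bony-contact constraint: intersection measure above ``threshold`` x
    mean vertebral surface area."""
    posed = segment.posterior_shape.transformed(np.asarray(pose, float))
    res = intersect_shapes(segment.anterior_shape, posed, pitch=pitch)
    value = res.measure(measure_mode)
    violated = value > threshold * segment.mean_area
    return ConstraintStatus(
        violated=violated,
        labels=frozenset({"intersection"}) if violated else frozenset(),
        measures={"intersection_area": res.area,
                  "intersection_volume": res.volume},
        flagged=res.flagged)


def eval_zyg_strain(segment: MotionSegment, pose: np.ndarray,
                    bounds: tuple) -> ConstraintStatus:
    """Zygapophyseal strain: fractional change of the craniocaudal (frame-x)
    landmark separation.  Below the lower bound is disarticulation
    (ventroflexion-type failure), above the upper bound is overlap."""
    ref = segment.reference
    if not ref.zyg_usable:
        return ConstraintStatus(False, frozenset(),
                                {"zyg_strain": np.nan}, flagged=True)
    pose = np.asarray(pose, float)
    pre = segment.landmarks["zyg_pre_cranial"] @ pose[:3, :3].T + pose[:3, 3]
    sep = pre - segment.landmarks["zyg_post_caudal"]
    d = abs(float(sep @ segment.frame.x_axis))
    s = (d - ref.zyg_d0) / ref.zyg_d0
    lo, hi = bounds
    labels = set()
    if s < lo:
        labels.add("zyg-disarticulation")
    elif s > hi:
        labels.add("zyg-overlap")
    return ConstraintStatus(bool(labels), frozenset(labels), {"zyg_strain": s})


def eval_centrum_strain(segment: MotionSegment, pose: np.ndarray,
                        bounds: tuple) -> ConstraintStatus:
    """Centrum strain: fractional change of each of the four endplate
    landmark-pair distances (dorsal, ventral, left, right)."""
    pose = np.asarray(pose, float)
    lo, hi = bounds
    labels = set()
    strains = {}
    for (a, b), name in zip(CENTRUM_PAIRS, CENTRUM_PAIR_NAMES):
        pb = segment.landmarks[b] @ pose[:3, :3].T + pose[:3, 3]
        d = float(np.linalg.norm(pb - segment.landmarks[a]))
        i = CENTRUM_PAIR_NAMES.index(name)
        d0 = segment.reference.centrum_d0[i]
        s = (d - d0) / d0
        strains[f"centrum_strain_{name}"] = s
        if s > hi:
            labels.add("centrum-tension")
        elif s < lo:
            labels.add("centrum-compression")
    return ConstraintStatus(bool(labels), frozenset(labels), strains)


def _evaluate(segment: MotionSegment, pose: np.ndarray,
              config: BendingConfig) -> ConstraintStatus:
    parts = []
    if "intersection" in config.enabled:
        parts.append(eval_intersection(segment, pose,
                                       config.intersection_threshold,
                                       config.intersection_measure,
                                       config.voxel_pitch))
    if "zyg" in config.enabled:
        parts.append(eval_zyg_strain(segment, pose, config.zyg_bounds))
    if "centrum" in config.enabled:
        parts.append(eval_centrum_strain(segment, pose, config.centrum_bounds))
    if not parts:
        return ConstraintStatus(False, frozenset())
    return _merge(*parts)


# ---------------------------------------------------------------------------
# The bending loop
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DirectionResult:
    direction: str
    stop_angle: float
    constraint_labels: frozenset
    translation_used: float = 0.0
    flagged: bool = False

    @property
    def primary_label(self) -> str:
        return primary_label(self.constraint_labels)


@dataclass(frozen=True)
class BendingResult:
    """Six per-direction results for one motion segment."""
    directions: dict   # direction name -> DirectionResult

    def __getitem__(self, key) -> DirectionResult:
        return self.directions[key]

    def stop_angles(self) -> dict:
        return {k: v.stop_angle for k, v in self.directions.items()}

    def to_rows(self, segment_id: str = None, run_variant: str = "base"):
        rows = []
        for name in DIRECTIONS:
            r = self.directions[name]
            rows.append({
                "segment_id": segment_id,
                "direction": name,
                "stop_angle": r.stop_angle,
                "constraint_label": r.primary_label,
                "run_variant": run_variant,
                "all_labels": "+".join(sorted(r.constraint_labels)),
                "translation_used": r.translation_used,
            })
        return rows


def _pose(segment: MotionSegment, axis: str, signed_angle: float,
          relief_vec: np.ndarray) -> np.ndarray:
    """Rotation composed fresh from neutral, then world translation."""
    m = segment.frame.rotation_matrix(axis, signed_angle)
    m = m.copy()
    m[:3, 3] += relief_vec
    return m


def bend_direction(segment: MotionSegment, direction: str,
                   config: BendingConfig) -> DirectionResult:
    """Rotate the posterior vertebra in one direction until a constraint is
    reached.

    Probes theta = k * increment.  On a violation where intersection is the
    only violated constraint and translation budget remains, one relief
    translation is applied (perpendicular shift toward the bending side) and
    the same angle re-tested once; otherwise the loop stops and reports the
    last non-violating angle with the violating labels.  An unviolated sweep
    reports (max_angle, {max-angle}).
    """
    if direction not in DIRECTIONS:
        raise ValueError(f"invalid direction {direction!r}; expected one of "
                         f"{sorted(DIRECTIONS)}")
    axis, sign = DIRECTIONS[direction]
    relief_axis, relief_sign = _RELIEF[direction]
    relief_dir = relief_sign * segment.frame.axis(relief_axis)

    budget = config.translation_fraction * segment.sqrt_area
    step_frac = (config.translation_step_fraction
                 if config.translation_step_fraction is not None
                 else config.translation_fraction)
    step = step_frac * segment.sqrt_area
    used = 0.0
    relief_vec = np.zeros(3)
    flagged = False

    status = _evaluate(segment, _pose(segment, axis, 0.0, relief_vec), config)
    flagged |= status.flagged
    if status.violated:
        return DirectionResult(direction, 0.0, status.labels, 0.0, flagged)

    last_ok = 0.0
    for k in range(1, config.n_steps + 1):
        theta = k * config.increment
        status = _evaluate(segment, _pose(segment, axis, sign * theta,
                                          relief_vec), config)
        flagged |= status.flagged
        if status.violated and status.labels == {"intersection"} \
                and step > 0 and used + step <= budget + 1e-12:
            # one relief attempt per probe angle; translation persists
            relief_vec = relief_vec + relief_dir * step
            used += step
            status = _evaluate(segment, _pose(segment, axis, sign * theta,
                                              relief_vec), config)
            flagged |= status.flagged
        if status.violated:
            return DirectionResult(direction, last_ok, status.labels,
                                   used, flagged)
        last_ok = theta
    return DirectionResult(direction, config.max_angle,
                           frozenset({"max-angle"}), used, flagged)


def run_all_directions(segment: MotionSegment,
                       config: BendingConfig) -> BendingResult:
    """Run the bending loop in all six directions.  Deterministic."""
    return BendingResult({name: bend_direction(segment, name, config)
                          for name in DIRECTIONS})
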