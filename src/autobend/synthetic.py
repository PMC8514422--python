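"""Procedural motion segments with analytically known geometry.

The block segment stands in for a CT-derived vertebra pair: two cuboid
"centra" separated by a parameterized inter-endplate gap along the frame-x
axis, plus overlapping dorsal zygapophyseal tabs carrying the zygapophyseal
landmark pair.  Every connected component is a convex box, so the exact
intersection backend applies and first bone-contact angles have closed-form
2D solutions, which makes the bending engine testable end to end without any
external data.

Default dimensions approximate a mid-lumbar joint of a mid-sized quadruped
(centrum 10 mm wide x 8 mm high x 15 mm long, 2 mm joint gap, 3 mm arch
height) — the same scale as the worked stiffness example.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass
from typing import Optional

import numpy as np
import trimesh
from shapely import affinity
from shapely.geometry import Polygon

from .rigid_geometry import JointFrame
from .segment_model import LandmarkSet, build_segment, MotionSegment

__all__ = ["SegmentParams", "GroundTruth", "make_block_segment",
           "make_vertebra_segment", "analytic_contact_angle",
           "segment_from_scene"]


@dataclass(frozen=True)
class SegmentParams:
    """Parameters of a synthetic two-vertebra motion segment (mm).

    ``zyg_tab_offset`` is the dorsoventral clearance of the facet joint (the
    gap between the overlapped tabs); ``zyg_tab_overlap`` is the craniocaudal
    extent by which the two tabs overlap, and equals the zygapophyseal
    reference length.  ``jitter_sd`` adds seeded vertex noise (each jittered
    component is re-hulled so it stays convex); 0 keeps the analytic ground
    truth exact.
    """

    centrum_width: float = 10.0
    centrum_height: float = 8.0
    centrum_length: float = 15.0
    gap: float = 2.0
    arch_height: float = 3.0
    zyg_tab_length: float = 4.0
    zyg_tab_overlap: float = 2.0
    zyg_tab_offset: float = 0.4
    bilateral_symmetry: bool = True
    random_seed: int = 0
    jitter_sd: float = 0.0

    def __post_init__(self):
        if self.gap <= 0:
            raise ValueError("gap must be > 0")
        if self.zyg_tab_overlap > self.zyg_tab_length:
            raise ValueError("zyg_tab_overlap must be <= zyg_tab_length")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")
        if self.zyg_tab_offset <= 0:
            raise ValueError("zyg_tab_offset must be > 0 "
                             "(tabs would overlap at neutral)")
        for name in ("centrum_width", "centrum_height", "centrum_length",
                     "zyg_tab_length", "zyg_tab_overlap"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    # internal derived dimensions of the tab construction
    @property
    def tab_thickness(self) -> float:
        return 0.15 * self.centrum_height

    @property
    def tab_width(self) -> float:
        return 0.2 * self.centrum_width

    @property
    def tab_clearance_above_centrum(self) -> float:
        return 0.05 * self.centrum_height


@dataclass(frozen=True)
class GroundTruth:
    """Analytic reference quantities for a generated segment."""

    landmarks: dict                    # name -> [x, y, z]
    surface_area_anterior: float
    surface_area_posterior: float
    contact_angles: dict               # direction -> degrees (or None)
    zyg_d0: float
    centrum_d0: float                  # common value of the four pairs
    mean_spacing: float


def _box(xlim, ylim, zlim) -> trimesh.Trimesh:
    extents = [xlim[1] - xlim[0], ylim[1] - ylim[0], zlim[1] - zlim[0]]
    center = [(xlim[0] + xlim[1]) / 2, (ylim[0] + ylim[1]) / 2,
              (zlim[0] + zlim[1]) / 2]
    m = trimesh.creation.box(extents=extents)
    m.apply_translation(center)
    return m


def _block_boxes(p: SegmentParams):
    """Axis-aligned boxes (as limit triples) for each rigid body."""
    w, h, L, g = p.centrum_width, p.centrum_height, p.centrum_length, p.gap
    ov, tl = p.zyg_tab_overlap, p.zyg_tab_length
    th, tw, cl = p.tab_thickness, p.tab_width, p.zyg_tab_offset
    s = p.tab_clearance_above_centrum
    # anterior (post-zyg) tab sits dorsal to the posterior (pre-zyg) tab
    ya = h / 2 + s + th + cl          # bottom of the anterior tab
    ant = [((-g / 2 - L, -g / 2), (-h / 2, h / 2), (-w / 2, w / 2)),
           ((ov / 2 - tl, ov / 2), (ya, ya + th), (w / 2 - tw, w / 2))]
    post = [((g / 2, g / 2 + L), (-h / 2, h / 2), (-w / 2, w / 2)),
            ((-ov / 2, -ov / 2 + tl), (ya - cl - th, ya - cl),
             (w / 2 - tw, w / 2))]
    if p.bilateral_symmetry:
        ant.append(((ov / 2 - tl, ov / 2), (ya, ya + th),
                    (-w / 2, -w / 2 + tw)))
        post.append(((-ov / 2, -ov / 2 + tl), (ya - cl - th, ya - cl),
                     (-w / 2, -w / 2 + tw)))
    return ant, post


def _assemble(boxes, jitter_sd: float, rng) -> trimesh.Trimesh:
    parts = []
    for lims in boxes:
        m = _box(*lims)
        if jitter_sd > 0:
            m.vertices = m.vertices + rng.normal(0.0, jitter_sd,
                                                 m.vertices.shape)
            m = m.convex_hull
        parts.append(m)
    return trimesh.util.concatenate(parts)


def _box_area(lims) -> float:
    dx = lims[0][1] - lims[0][0]
    dy = lims[1][1] - lims[1][0]
    dz = lims[2][1] - lims[2][0]
    return 2.0 * (dx * dy + dy * dz + dx * dz)


def make_block_segment(params: SegmentParams = SegmentParams()
                       ) -> tuple[MotionSegment, GroundTruth]:
    """Generate a cuboid-centrum motion segment with analytic ground truth.

    COR at mid-gap on the centrum long axis; frame axes aligned with the
    cuboids (x craniocaudal, y dorsoventral, z mediolateral, left = +z).
    The eight centrum landmarks sit at the endplate extremes, so the four
    neutral pair distances all equal the gap; the two zygapophyseal
    landmarks sit on the facing faces of the overlapping dorsal tabs, so the
    zygapophyseal reference length equals the tab overlap.
    """
    p = params
    ant_boxes, post_boxes = _block_boxes(p)
    rng = np.random.default_rng(p.random_seed)
    anterior = _assemble(ant_boxes, p.jitter_sd, rng)
    posterior = _assemble(post_boxes, p.jitter_sd, rng)

    w, h, g, ov = p.centrum_width, p.centrum_height, p.gap, p.zyg_tab_overlap
    th, tw, cl = p.tab_thickness, p.tab_width, p.zyg_tab_offset
    ya = h / 2 + p.tab_clearance_above_centrum + th + cl
    zc = w / 2 - tw / 2
    landmarks = LandmarkSet({
        "ant_dorsal": (-g / 2, h / 2, 0.0),
        "ant_ventral": (-g / 2, -h / 2, 0.0),
        "ant_left": (-g / 2, 0.0, w / 2),
        "ant_right": (-g / 2, 0.0, -w / 2),
        "post_dorsal": (g / 2, h / 2, 0.0),
        "post_ventral": (g / 2, -h / 2, 0.0),
        "post_left": (g / 2, 0.0, w / 2),
        "post_right": (g / 2, 0.0, -w / 2),
        # caudal face of the anterior tab / cranial face of the posterior tab
        "zyg_post_caudal": (ov / 2, ya + th / 2, zc),
        "zyg_pre_cranial": (-ov / 2, ya - cl - th / 2, zc),
    })
    frame = JointFrame.standard()
    segment = build_segment(anterior, posterior, frame, landmarks,
                            segment_id="synthetic-block")

    directions = ("dorsiflexion", "ventroflexion", "left-lateral",
                  "right-lateral", "left-axial", "right-axial")
    # closed-form contact angles exist only for the unjittered boxes
    contact = ({d: analytic_contact_angle(p, d) for d in directions}
               if p.jitter_sd == 0 else {d: None for d in directions})
    truth = GroundTruth(
        landmarks=landmarks.to_dict(),
        surface_area_anterior=sum(_box_area(b) for b in ant_boxes),
        surface_area_posterior=sum(_box_area(b) for b in post_boxes),
        contact_angles=contact, zyg_d0=ov, centrum_d0=g, mean_spacing=g)
    return segment, truth


def make_vertebra_segment(params: SegmentParams = SegmentParams()
                          ) -> tuple[MotionSegment, GroundTruth]:
    """Vertebra-like composite: cylindrical centrum + arch block + tabs.

    Used for realistic-shape smoke tests.  Each primitive is a closed convex
    component (assembled without fusing, so the pair stays usable by the
    exact intersection backend); contact angles have no closed form here and
    are supplied by fine-angle sampling in the caller when needed.
    """
    p = params
    r = p.centrum_height / 2
    g, L = p.gap, p.centrum_length
    sections = 32  # multiple of 4 so rim vertices land on +-y and +-z

    def centrum(x0):
        # cylinder along x with rim vertices at the dorsal/ventral/lateral poles
        m = trimesh.creation.cylinder(radius=r, height=L, sections=sections)
        rot = np.array([[0.0, 0, 1, 0], [1, 0, 0, 0], [0, 1, 0, 0],
                        [0, 0, 0, 1.0]])  # local z -> global x, x -> y, y -> z
        m.apply_transform(rot)
        m.apply_translation([x0 + L / 2, 0, 0])
        return m

    ant_parts = [centrum(-g / 2 - L)]
    post_parts = [centrum(g / 2)]
    # arch block floating dorsal to each centrum
    s = p.tab_clearance_above_centrum
    for parts, xlim in ((ant_parts, (-g / 2 - L, -g / 2)),
                        (post_parts, (g / 2, g / 2 + L))):
        parts.append(_box(xlim, (r + s, r + s + p.arch_height),
                          (-p.tab_width, p.tab_width)))
    # zygapophyseal tabs as in the block segment, raised above the arch
    bp = SegmentParams(**{**asdict(p), "centrum_height":
                          2 * (r + s + p.arch_height), "jitter_sd": 0.0})
    ant_boxes, post_boxes = _block_boxes(bp)
    rng = np.random.default_rng(p.random_seed)
    for lims in ant_boxes[1:]:
        ant_parts.append(_box(*lims))
    for lims in post_boxes[1:]:
        post_parts.append(_box(*lims))

    anterior = trimesh.util.concatenate(ant_parts)
    posterior = trimesh.util.concatenate(post_parts)
    for m, name in ((anterior, "anterior"), (posterior, "posterior")):
        if not m.is_watertight:
            raise RuntimeError(f"synthetic {name} vertebra is not watertight")
        if m.volume <= 0:
            raise RuntimeError(f"synthetic {name} vertebra has no volume")

    ya = bp.centrum_height / 2 + bp.tab_clearance_above_centrum \
        + bp.tab_thickness + bp.zyg_tab_offset
    ov, zc = p.zyg_tab_overlap, p.centrum_width / 2 - bp.tab_width / 2
    landmarks = LandmarkSet({
        "ant_dorsal": (-g / 2, r, 0.0),
        "ant_ventral": (-g / 2, -r, 0.0),
        "ant_left": (-g / 2, 0.0, r),
        "ant_right": (-g / 2, 0.0, -r),
        "post_dorsal": (g / 2, r, 0.0),
        "post_ventral": (g / 2, -r, 0.0),
        "post_left": (g / 2, 0.0, r),
        "post_right": (g / 2, 0.0, -r),
        "zyg_post_caudal": (ov / 2, ya + bp.tab_thickness / 2, zc),
        "zyg_pre_cranial": (-ov / 2, ya - bp.zyg_tab_offset
                            - bp.tab_thickness / 2, zc),
    })
    segment = build_segment(anterior, posterior, JointFrame.standard(),
                            landmarks, segment_id="synthetic-vertebra")
    truth = GroundTruth(
        landmarks=landmarks.to_dict(),
        surface_area_anterior=float(anterior.area),
        surface_area_posterior=float(posterior.area),
        contact_angles={}, zyg_d0=ov, centrum_d0=g, mean_spacing=g)
    return segment, truth


# ---------------------------------------------------------------------------
# Closed-form first-contact angles (2D corner-trajectory solution)
# ---------------------------------------------------------------------------

def _rect(xlim, ylim) -> Polygon:
    return Polygon([(xlim[0], ylim[0]), (xlim[1], ylim[0]),
                    (xlim[1], ylim[1]), (xlim[0], ylim[1])])


def _vertex_edge_candidates(moving: Polygon, fixed: Polygon, sign: float,
                            max_rad: float):
    """Angles where a rotating vertex of ``moving`` crosses an edge line of
    ``fixed``: solve n.R(s*theta)v = d per vertex/edge pair."""
    out = []
    mv = np.asarray(moving.exterior.coords)[:-1]
    fv = np.asarray(fixed.exterior.coords)[:-1]
    for i in range(len(fv)):
        p, q = fv[i], fv[(i + 1) % len(fv)]
        e = q - p
        n = np.array([e[1], -e[0]])
        n = n / np.linalg.norm(n)
        d = n @ p
        for v in mv:
            A = n @ v
            B = sign * (n @ np.array([-v[1], v[0]]))
            r = math.hypot(A, B)
            if r < abs(d):
                continue
            base = math.atan2(B, A)
            for t in (base + math.acos(d / r), base - math.acos(d / r)):
                t = t % (2 * math.pi)
                if 1e-12 < t <= max_rad:
                    out.append(t)
    return out


def first_contact_angle_2d(moving: Polygon, fixed: Polygon, sign: float = 1.0,
                           max_angle_deg: float = 90.0) -> Optional[float]:
    """Smallest rotation of ``moving`` about the origin (by ``sign``*theta)
    at which it first penetrates ``fixed``, from the closed-form
    corner-trajectory events (vertex-of-one crossing edge-line-of-other).

    Returns degrees, or None if no contact occurs within ``max_angle_deg``.
    """
    if moving.intersection(fixed).area > 1e-12:
        return 0.0
    max_rad = math.radians(max_angle_deg)
    cands = _vertex_edge_candidates(moving, fixed, sign, max_rad)
    # vertices of the fixed polygon crossing edges of the moving one:
    # equivalent to rotating `fixed` backwards about the origin
    cands += _vertex_edge_candidates(fixed, moving, -sign, max_rad)
    # Penetration area grows quadratically past a contact event, so probe a
    # short step beyond each candidate; the step bounds the angular error and
    # stays far below the solver's stated 0.02-degree agreement.
    eps = 2e-4
    for t in sorted(set(cands)):
        probe = affinity.rotate(moving, math.degrees(sign * (t + eps)),
                                origin=(0, 0), use_radians=False)
        if probe.intersection(fixed).area > 1e-10:
            return math.degrees(t)
    return None


def _pairs_2d(p: SegmentParams, direction: str):
    """(moving, fixed, sign) rectangle pairs whose prism axes are preserved
    by the rotation — the planes where 2D analysis is exact."""
    ant_boxes, post_boxes = _block_boxes(p)
    from .bending_engine import DIRECTIONS
    axis, sign = DIRECTIONS[direction]
    # project onto the plane perpendicular to the rotation axis; a pair is
    # relevant only when the prisms overlap along the preserved axis
    keep = {"x": (1, 2, 0), "y": (2, 0, 1), "z": (0, 1, 2)}[axis]
    u, v, w_ax = keep
    pairs = []
    for pb in post_boxes:
        for ab in ant_boxes:
            if pb[w_ax][0] < ab[w_ax][1] and ab[w_ax][0] < pb[w_ax][1]:
                # orientation consistent with a right-handed rotation about
                # the preserved axis: (u, v) is a right-handed 2D basis
                pairs.append((_rect(pb[u], pb[v]), _rect(ab[u], ab[v]), sign))
    return pairs


def analytic_contact_angle(params: SegmentParams, direction: str,
                           max_angle_deg: float = 90.0) -> Optional[float]:
    """First bone-contact angle of a block segment in one bending direction.

    Exact for block geometry, where every rigid piece is an axis-aligned box
    and the rotation preserves one coordinate, reducing contact to 2D
    rotating-rectangle problems with closed-form corner-trajectory events.
    Jittered geometry has no closed form and raises.
    """
    if params.jitter_sd > 0:
        raise ValueError("no closed form for jittered geometry; "
                         "use the fine-sampling oracle")
    angles = [a for moving, fixed, sign in _pairs_2d(params, direction)
              for a in [first_contact_angle_2d(moving, fixed, sign,
                                               max_angle_deg)]
              if a is not None]
    return min(angles) if angles else None


def segment_from_scene(scene) -> MotionSegment:
    """Build a MotionSegment from a loaded SceneDescription (convenience)."""
    from .scene_io import load_segment
    return load_segment(scene)
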