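"""Independent oracles used by the test suite.

These deliberately avoid the package's geometry backends: box overlap is
decided by the separating-axis theorem on oriented boxes, and sequential
sums of squares are computed by nested least-squares projections.
"""

from __future__ import annotations

import numpy as np

from autobend.bending_engine import DIRECTIONS
from autobend.synthetic import SegmentParams, _block_boxes


# ---------------------------------------------------------------------------
# Oriented-box separating-axis overlap, vectorized over rotation angles
# ---------------------------------------------------------------------------

def _box_params(lims):
    lo = np.array([lims[0][0], lims[1][0], lims[2][0]], float)
    hi = np.array([lims[0][1], lims[1][1], lims[2][1]], float)
    return (lo + hi) / 2, (hi - lo) / 2


def _rotmats(axis: str, angles_rad: np.ndarray) -> np.ndarray:
    c, s = np.cos(angles_rad), np.sin(angles_rad)
    n = len(angles_rad)
    R = np.zeros((n, 3, 3))
    i = {"x": 0, "y": 1, "z": 2}[axis]
    j, k = (i + 1) % 3, (i + 2) % 3
    R[:, i, i] = 1
    R[:, j, j] = c
    R[:, k, k] = c
    R[:, j, k] = -s
    R[:, k, j] = s
    return R


def sat_overlap_angles(fixed_lims, moving_lims, axis: str,
                       angles_rad: np.ndarray, tol: float = 1e-9):
    """Boolean array: does the moving box, rotated about the origin by each
    angle, strictly (positive-volume) overlap the fixed axis-aligned box?"""
    ca, ha = _box_params(fixed_lims)      # fixed: axes = identity
    cb0, hb = _box_params(moving_lims)
    R = _rotmats(axis, angles_rad)        # (N, 3, 3)
    cb = np.einsum("nij,j->ni", R, cb0)
    d = cb - ca                           # (N, 3)
    eye = np.eye(3)
    overlap = np.ones(len(angles_rad), dtype=bool)

    def check(L):                          # L: (N, 3) axis per angle
        norm = np.linalg.norm(L, axis=1)
        ok = norm > 1e-12
        Ln = np.where(ok[:, None], L / np.where(ok, norm, 1)[:, None], 0)
        ra = np.abs(Ln) @ ha                              # fixed box radius
        rb = np.abs(np.einsum("ni,nij->nj", Ln, R)) @ hb  # moving box radius
        sep = np.abs(np.einsum("ni,ni->n", Ln, d)) - ra - rb
        overlap[ok & (sep >= -tol)] = False

    # 3 face axes of the fixed box
    for i in range(3):
        check(np.tile(eye[i], (len(R), 1)))
    # 3 face axes of the moving box
    for j in range(3):
        check(R[:, :, j])
    # 9 edge-cross axes
    for i in range(3):
        for j in range(3):
            check(np.cross(eye[i], R[:, :, j]))
    return overlap


def fine_sample_stop_angle(params: SegmentParams, direction: str,
                           fine_step: float = 0.01,
                           max_angle: float = 45.0) -> float:
    """Last non-penetrating angle on a fine grid, for intersection-only
    bending of a block segment (threshold 0 = any volumetric overlap)."""
    axis, sign = DIRECTIONS[direction]
    ant_boxes, post_boxes = _block_boxes(params)
    n = int(round(max_angle / fine_step))
    angles = np.radians(sign * fine_step * np.arange(1, n + 1))
    any_overlap = np.zeros(n, dtype=bool)
    for mb in post_boxes:
        for fb in ant_boxes:
            any_overlap |= sat_overlap_angles(fb, mb, axis, angles)
    hits = np.flatnonzero(any_overlap)
    if len(hits) == 0:
        return max_angle
    return hits[0] * fine_step  # last grid angle before the first overlap


# ---------------------------------------------------------------------------
# Sequential sums of squares by nested projection
# ---------------------------------------------------------------------------

def _term_matrix(df, cols):
    cells = df[list(cols)].astype(str).agg("|".join, axis=1)
    levels = sorted(cells.unique())
    X = np.zeros((len(df), len(levels)))
    for k, lev in enumerate(levels):
        X[:, k] = (cells == lev).to_numpy()
    return X


def projection_sequential_ss(df, response: str, terms):
    """Sequential SS: reduction in residual sum of squares as each term
    (a list of factor columns; interactions are crossed cells) is added."""
    y = df[response].to_numpy(float)
    X = np.ones((len(df), 1))
    rss_prev = float(((y - y.mean()) ** 2).sum())
    out = {}
    for term in terms:
        X = np.hstack([X, _term_matrix(df, term)])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        rss = float(((y - X @ beta) ** 2).sum())
        out[":".join(term)] = rss_prev - rss
        rss_prev = rss
    out["Residual"] = rss_prev
    return out
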