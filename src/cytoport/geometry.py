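"""Vectorized gate-membership predicates.

All predicates are boundary-inclusive ("on the line = in the gate") and
pure: identical inputs give identical outputs.  Points arrive already on
the transformed scale — coordinate preparation (compensation, transforms)
is the gating engine's job.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import cho_factor, cho_solve, LinAlgError

from .errors import InvalidGateError
from .model import (
    BooleanGate,
    EllipsoidGate,
    PolygonGate,
    QuadrantGate,
    RectangleGate,
)


def in_rectangle(points: np.ndarray, gate: RectangleGate) -> np.ndarray:
    """Boundary-inclusive box test; an unbounded side imposes no constraint."""
    points = np.asarray(points, dtype=float)
    n = points.shape[0]
    member = np.ones(n, dtype=bool)
    for j, (lo, hi) in enumerate(gate.bounds):
        col = points[:, j]
        if lo is not None:
            member &= col >= lo
        if hi is not None:
            member &= col <= hi
    return member


def _on_segment(px, py, x1, y1, x2, y2) -> np.ndarray:
    """True where point (px, py) lies exactly on segment (x1,y1)-(x2,y2)."""
    cross = (x2 - x1) * (py - y1) - (y2 - y1) * (px - x1)
    within = (np.minimum(x1, x2) <= px) & (px <= np.maximum(x1, x2)) & \
             (np.minimum(y1, y2) <= py) & (py <= np.maximum(y1, y2))
    return (cross == 0.0) & within


def in_polygon(points: np.ndarray, gate: PolygonGate) -> np.ndarray:
    """Even-odd (crossing-count) interior plus the boundary itself.

    A ray is cast toward +x from each point; an edge counts when it spans
    the point's y half-open ([y1, y2) after orientation) and the crossing
    lies strictly right of the point.  Vertices and edge points are then
    added explicitly so the result is boundary-inclusive even when the ray
    rule would exclude them.
    """
    points = np.asarray(points, dtype=float)
    verts = np.asarray(gate.vertices, dtype=float)
    if verts.shape[0] < 3:
        raise InvalidGateError("polygon gate requires at least 3 vertices")
    px, py = points[:, 0], points[:, 1]
    inside = np.zeros(points.shape[0], dtype=bool)
    boundary = np.zeros_like(inside)
    nv = verts.shape[0]
    for i in range(nv):
        x1, y1 = verts[i]
        x2, y2 = verts[(i + 1) % nv]
        crosses = (y1 > py) != (y2 > py)
        if np.any(crosses):
            with np.errstate(divide="ignore", invalid="ignore"):
                xint = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
            inside ^= crosses & (px < xint)
        boundary |= _on_segment(px, py, x1, y1, x2, y2)
    return inside | boundary


def in_ellipsoid(points: np.ndarray, gate: EllipsoidGate) -> np.ndarray:
    """(x - mean)' C^-1 (x - mean) <= D^2 via a Cholesky factorization."""
    C = np.asarray(gate.covariance, dtype=float)
    if C.shape[0] != C.shape[1] or not np.allclose(C, C.T, atol=1e-12 * max(1.0, np.abs(C).max())):
        raise InvalidGateError("ellipsoid shape matrix must be symmetric")
    try:
        factor = cho_factor(0.5 * (C + C.T), lower=True)
    except LinAlgError:
        raise InvalidGateError("ellipsoid shape matrix is not positive definite")
    diff = np.asarray(points, dtype=float) - np.asarray(gate.mean, dtype=float)
    d2 = np.einsum("ij,ij->i", diff, cho_solve(factor, diff.T).T)
    return d2 <= gate.distance_square


def in_quadrant(points: np.ndarray, gate: QuadrantGate) -> np.ndarray:
    """Quadrant membership; '+' is the closed side (>= divider)."""
    if len(gate.selector) != 2 or any(s not in "+-" for s in gate.selector):
        raise InvalidGateError(f"bad quadrant selector {gate.selector!r}")
    points = np.asarray(points, dtype=float)
    sx, sy = gate.selector
    mx = points[:, 0] >= gate.divider_x
    my = points[:, 1] >= gate.divider_y
    if sx == "-":
        mx = ~mx
    if sy == "-":
        my = ~my
    return mx & my


def eval_boolean(gate: BooleanGate,
                 operand_memberships: list[np.ndarray]) -> np.ndarray:
    """Elementwise AND/OR/NOT over operand membership vectors."""
    op = gate.operator.upper()
    if op == "NOT":
        if len(operand_memberships) != 1:
            raise InvalidGateError("NOT gate takes exactly one operand")
        return ~operand_memberships[0]
    if len(operand_memberships) < 1:
        raise InvalidGateError(f"{op} gate requires at least one operand")
    lengths = {len(m) for m in operand_memberships}
    if len(lengths) != 1:
        raise InvalidGateError("boolean operand vectors differ in length")
    out = operand_memberships[0].copy()
    for m in operand_memberships[1:]:
        if op == "AND":
            out &= m
        elif op == "OR":
            out |= m
        else:
            raise InvalidGateError(f"unknown boolean operator {gate.operator!r}")
    if op not in ("AND", "OR"):
        raise InvalidGateError(f"unknown boolean operator {gate.operator!r}")
    return out
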