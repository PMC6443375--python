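"""Hierarchical gating engine: resolve a tree against a sample.

Each population's membership is its parent's membership AND its own gate
predicate.  Before a geometric predicate is evaluated, each gate axis is
prepared in two steps, in Gating-ML processing order: (1) compensation
(matrix chosen by :func:`cytoport.compensation.select_compensation`),
(2) the per-dimension display transform.  Prepared columns are cached per
(compensation, transform, channel) within a resolve call; the cache is
purely observational.

Boolean gates may reference any already-defined path, so nodes are
evaluated in topological order with cycle detection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import geometry
from .compensation import compensate, select_compensation
from .errors import (
    GateCycleError,
    InvalidGateError,
    LabelLengthError,
    UnknownPopulationError,
)
from .model import (
    BooleanGate,
    ClusterAssignment,
    EllipsoidGate,
    FMeasureResult,
    GatingTree,
    IndexGate,
    PopulationNode,
    PolygonGate,
    QuadrantGate,
    RectangleGate,
    Sample,
    TransformDef,
    Workspace,
    GEOMETRIC_GATES,
    IDENTITY,
    ROOT_NAME,
    UNCOMPENSATED,
)
from .transforms import IDENTITY_TRANSFORM, make_transform


@dataclass
class _PrepCache:
    sample: Sample
    ws: Workspace
    compensated: dict[str, np.ndarray] = field(default_factory=dict)
    columns: dict[tuple[str, str, str], np.ndarray] = field(default_factory=dict)

    def _compensated_events(self, comp_ref: str) -> tuple[np.ndarray, str]:
        spill = select_compensation(self.sample, self.ws, comp_ref)
        key = spill.matrix_id if spill is not None else "<none>"
        if key not in self.compensated:
            if spill is None:
                self.compensated[key] = np.asarray(self.sample.events, dtype=float)
            else:
                self.compensated[key] = compensate(
                    self.sample.events, spill, self.sample.channel_names)
        return self.compensated[key], key

    def column(self, channel: str, transform_ref: str, comp_ref: str) -> np.ndarray:
        events, comp_key = self._compensated_events(comp_ref)
        key = (comp_key, transform_ref, channel)
        if key not in self.columns:
            if channel not in self.sample.channel_names:
                raise UnknownPopulationError(
                    f"channel {channel!r} not in sample {self.sample.sample_id!r}")
            col = events[:, self.sample.channel_index(channel)]
            if transform_ref == IDENTITY:
                tf = IDENTITY_TRANSFORM
            else:
                tdef: TransformDef = self.ws.transforms[transform_ref]
                tf = make_transform(tdef)
            self.columns[key] = np.asarray(tf.forward(col), dtype=float)
        return self.columns[key]


def _gate_points(gate, cache: _PrepCache) -> np.ndarray:
    cols = [cache.column(d.channel, d.transform_ref, d.compensation_ref)
            for d in gate.dims]
    return np.column_stack(cols)


def _eval_geometric(gate, cache: _PrepCache) -> np.ndarray:
    pts = _gate_points(gate, cache)
    if isinstance(gate, RectangleGate):
        return geometry.in_rectangle(pts, gate)
    if isinstance(gate, PolygonGate):
        return geometry.in_polygon(pts, gate)
    if isinstance(gate, EllipsoidGate):
        return geometry.in_ellipsoid(pts, gate)
    if isinstance(gate, QuadrantGate):
        return geometry.in_quadrant(pts, gate)
    raise InvalidGateError(f"unknown gate type {type(gate).__name__}")


def resolve(sample: Sample, tree: GatingTree, ws: Workspace) -> dict[str, np.ndarray]:
    """Compute per-event membership for every population in the tree.

    Returns a map population_path -> boolean vector of length n_events;
    "root" maps to all-true.  Boolean gates are evaluated after their
    operand paths; a reference cycle raises :class:`GateCycleError` listing
    the paths involved.
    """
    n = sample.n_events
    cache = _PrepCache(sample, ws)
    nodes = list(tree.walk())  # (path, parent_path, node), pre-order
    resolved: dict[str, np.ndarray] = {}
    pending = {path: (parent, node) for path, parent, node in nodes}
    order: list[str] = [p for p, _, _ in nodes]

    def deps(path: str) -> list[str]:
        parent, node = pending[path]
        d = [] if path == ROOT_NAME else [parent]
        if node.gate is not None and isinstance(node.gate, BooleanGate):
            d += [_canonical(tree, op) for op in node.gate.operands]
        return d

    canonical_cache: dict[str, str] = {}

    def _canonical(tree: GatingTree, path: str) -> str:
        # normalize operand spellings ("/a/b" vs "root/a/b") to walk paths
        if path in canonical_cache:
            return canonical_cache[path]
        node = tree.resolve_path(path)  # raises UnknownPopulationError
        for p, _, cand in nodes:
            if cand is node:
                canonical_cache[path] = p
                return p
        raise UnknownPopulationError(f"operand path {path!r} not in tree")

    # Kahn-style evaluation with cycle detection
    remaining = list(order)
    progress = True
    while remaining and progress:
        progress = False
        still = []
        for path in remaining:
            if any(d not in resolved for d in deps(path)):
                still.append(path)
                continue
            parent, node = pending[path]
            if path == ROOT_NAME:
                resolved[path] = np.ones(n, dtype=bool)
            else:
                parent_member = resolved[parent]
                gate = node.gate
                if gate is None:
                    member = parent_member.copy()
                elif isinstance(gate, BooleanGate):
                    ops = [resolved[_canonical(tree, op)] for op in gate.operands]
                    member = parent_member & geometry.eval_boolean(gate, ops)
                elif isinstance(gate, IndexGate):
                    pidx = np.flatnonzero(parent_member)
                    if gate.member.shape[0] != pidx.shape[0]:
                        raise LabelLengthError(
                            f"{path}: index gate has {gate.member.shape[0]} labels "
                            f"for {pidx.shape[0]} parent events")
                    member = np.zeros(n, dtype=bool)
                    member[pidx[gate.member]] = True
                elif isinstance(gate, GEOMETRIC_GATES):
                    member = parent_member & _eval_geometric(gate, cache)
                else:
                    raise InvalidGateError(f"unknown gate type {type(gate).__name__}")
                resolved[path] = member
            progress = True
        remaining = still
    if remaining:
        raise GateCycleError(f"boolean gate reference cycle among: {remaining}")
    return resolved


def get_indices(resolved: dict[str, np.ndarray], path: str) -> np.ndarray:
    """Boolean membership vector for one population (a copy)."""
    if path in resolved:
        return resolved[path].copy()
    alt = path if path.startswith("/") else "/" + path
    if alt in resolved:
        return resolved[alt].copy()
    raise UnknownPopulationError(f"unknown population path {path!r}")


def get_data(sample: Sample, resolved: dict[str, np.ndarray], path: str,
             ws: Workspace | None = None, prepared: bool = False) -> np.ndarray:
    """Event rows belonging to one population, in original column order.

    By default returns raw (untransformed, uncompensated) values; with
    ``prepared=True`` and a workspace, returns the compensated view used
    for gating (auto-selected matrix, no transform).
    """
    member = get_indices(resolved, path)
    events = sample.events
    if prepared:
        if ws is None:
            raise ValueError("prepared=True requires a workspace")
        spill = select_compensation(sample, ws, UNCOMPENSATED)
        if spill is not None:
            events = compensate(events, spill, sample.channel_names)
    return np.asarray(events, dtype=float)[member]


def compute_stats(resolved: dict[str, np.ndarray], tree: GatingTree,
                  n_events: int, sample_id: str = "") -> pd.DataFrame:
    """Population counts and frequencies, one row per node in pre-order.

    Columns: sample_id, population_path, parent_path, count, freq_of_parent,
    freq_of_total.  freq_of_parent is 0 when the parent is empty.
    """
    rows = []
    counts: dict[str, int] = {}
    for path, parent, _node in tree.walk():
        count = int(np.count_nonzero(resolved[path]))
        counts[path] = count
        if path == ROOT_NAME:
            fop = 1.0 if n_events else 0.0
        else:
            pc = counts[parent]
            fop = count / pc if pc else 0.0
        fot = count / n_events if n_events else 0.0
        rows.append((sample_id, path, parent, count, fop, fot))
    return pd.DataFrame(rows, columns=["sample_id", "population_path",
                                       "parent_path", "count",
                                       "freq_of_parent", "freq_of_total"])


def workspace_stats(ws: Workspace) -> pd.DataFrame:
    """compute_stats over every sample in a workspace, concatenated."""
    frames = []
    for s in ws.samples:
        tree = ws.tree_for(s.sample_id)
        frames.append(compute_stats(resolve(s, tree, ws), tree, s.n_events,
                                    sample_id=s.sample_id))
    return pd.concat(frames, ignore_index=True) if frames else compute_stats(
        {}, GatingTree(), 0)


def attach_clusters(tree: GatingTree, assignment: ClusterAssignment,
                    resolved: dict[str, np.ndarray] | None = None,
                    prefix: str = "cluster") -> GatingTree:
    """Attach cluster labels as index-defined child populations.

    One child per distinct nonzero label, named "<prefix>_<label>"; label 0
    means unassigned and produces no node.  The children partition the
    labeled events of the parent.  When a resolved membership map is given,
    the label-vector length is checked against the parent count up front;
    otherwise the check happens at resolve time.
    """
    labels = np.asarray(assignment.labels)
    parent = tree.resolve_path(assignment.parent_path)
    if resolved is not None:
        pc = int(np.count_nonzero(get_indices(resolved, assignment.parent_path)))
        if labels.shape[0] != pc:
            raise LabelLengthError(
                f"{assignment.parent_path}: {labels.shape[0]} labels for "
                f"{pc} parent events")
    for lab in np.unique(labels):
        if lab == 0:
            continue
        gate = IndexGate(member=(labels == lab))
        parent.add_child(PopulationNode(name=f"{prefix}_{lab}", gate=gate))
    return tree


def f_measure(a: np.ndarray, b: np.ndarray) -> FMeasureResult:
    """Precision/recall/F1 of candidate set b against reference set a.

    The reference is the manual gate, the candidate the cluster:
    P = |a AND b| / |b|, R = |a AND b| / |a|, F = 2PR/(P+R); empty sets
    give 0 for the affected component.
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    tp = int(np.count_nonzero(a & b))
    nb = int(np.count_nonzero(b))
    na = int(np.count_nonzero(a))
    P = tp / nb if nb else 0.0
    R = tp / na if na else 0.0
    F = 2 * P * R / (P + R) if (P + R) > 0 else 0.0
    return FMeasureResult(precision=P, recall=R, F=F)
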