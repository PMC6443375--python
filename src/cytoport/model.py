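"""Shared in-memory representation of a gated cytometry analysis.

A :class:`Workspace` is the interchange hub: it bundles samples (event
matrices read from FCS files), per-sample gating trees, a registry of axis
transforms and a registry of spillover (compensation) matrices, together
with the dialect it came from.  Every workspace reader produces this
structure and every writer consumes it, so that an analysis imported from
one platform can be re-exported to another without loss of meaning.

Gate coordinates are always stored on the *transformed* scale internally;
dialect readers that receive raw-scale coordinates convert them at parse
time.  This keeps a single evaluation path in the gating engine.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Iterator, Optional, Union

import numpy as np

from .errors import UnknownPopulationError

#: Sentinel transform reference meaning "evaluate on the linear scale as-is".
IDENTITY = "identity"

#: Sentinel compensation reference meaning "no explicit matrix — auto-select
#: per precedence (workspace per-sample matrix, then FCS $SPILLOVER, then none)".
UNCOMPENSATED = "uncompensated"

ROOT_NAME = "root"


@dataclass
class ChannelMeta:
    """Metadata for one measurement channel ($PnN/$PnS/$PnR)."""

    name: str
    marker: str = ""
    range: float = 262144.0


@dataclass
class Sample:
    """Per-event measurement matrix plus FCS keyword metadata.

    ``events`` is (n_events, n_channels) on the linearized scale; log-amplified
    integer channels are linearized by the FCS reader before they get here.
    """

    sample_id: str
    events: np.ndarray
    channels: list[ChannelMeta]
    keywords: dict[str, str] = field(default_factory=dict)

    @property
    def n_events(self) -> int:
        return int(self.events.shape[0])

    @property
    def channel_names(self) -> list[str]:
        return [c.name for c in self.channels]

    def channel_index(self, name: str) -> int:
        return self.channel_names.index(name)


@dataclass
class SpilloverMatrix:
    """Linear spillover model: observed = true @ S over the detector columns.

    Rows index the true signal, columns the detectors, diagonal 1.0 — the
    FCS $SPILLOVER convention.  Compensation right-multiplies by S^-1.
    """

    detectors: list[str]
    S: np.ndarray
    matrix_id: str = ""

    @property
    def k(self) -> int:
        return len(self.detectors)


@dataclass
class TransformDef:
    """Parametric axis transform declaration.

    T is the top-of-scale value, M the number of display decades, A the
    additional negative decades, and W (logicle only) the linearization
    width in decades.  The forward map sends [bottom-of-scale, T] into
    [0, 1] and is strictly increasing.
    """

    transform_id: str
    family: str  # linear | log | asinh | logicle
    T: float = 262144.0
    M: float = 4.5
    A: float = 0.0
    W: float = 0.5


@dataclass
class GateDimension:
    """Binds one gate axis to a channel and its evaluation context."""

    channel: str
    transform_ref: str = IDENTITY
    compensation_ref: str = UNCOMPENSATED


@dataclass
class RectangleGate:
    """Axis-aligned box; each dimension may leave either side unbounded."""

    dims: list[GateDimension]
    bounds: list[tuple[Optional[float], Optional[float]]]


@dataclass
class PolygonGate:
    """2-D polygon, even-odd interior, boundary-inclusive."""

    dims: list[GateDimension]
    vertices: np.ndarray  # (v, 2)


@dataclass
class EllipsoidGate:
    """Mahalanobis ball: (x - mean)' C^-1 (x - mean) <= distance_square."""

    dims: list[GateDimension]
    mean: np.ndarray
    covariance: np.ndarray
    distance_square: float


@dataclass
class QuadrantGate:
    """One quadrant of the plane split at (divider_x, divider_y).

    ``selector`` is two characters over {+, -}; '+' means >= the divider
    (ties land on the '+' side) so the four selectors partition the plane.
    """

    dims: list[GateDimension]
    divider_x: float
    divider_y: float
    selector: str  # "++", "+-", "-+", "--"


@dataclass
class BooleanGate:
    """AND/OR/NOT over previously defined population paths."""

    operator: str  # AND | OR | NOT
    operands: list[str]  # population paths


@dataclass
class IndexGate:
    """Membership by explicit event indices relative to the parent population.

    Produced by attaching cluster assignments; has no geometry.  ``member``
    is a boolean vector over the parent's member events in row order.
    """

    member: np.ndarray  # bool, length == parent population count


Gate = Union[RectangleGate, PolygonGate, EllipsoidGate, QuadrantGate,
             BooleanGate, IndexGate]

GEOMETRIC_GATES = (RectangleGate, PolygonGate, EllipsoidGate, QuadrantGate)


@dataclass
class PopulationNode:
    """A named population; membership = parent membership AND gate predicate."""

    name: str
    gate: Optional[Gate] = None
    children: list["PopulationNode"] = field(default_factory=list)

    def child(self, name: str) -> Optional["PopulationNode"]:
        for c in self.children:
            if c.name == name:
                return c
        return None

    def add_child(self, node: "PopulationNode") -> "PopulationNode":
        if self.child(node.name) is not None:
            raise ValueError(f"duplicate sibling name {node.name!r}")
        self.children.append(node)
        return node


class GatingTree:
    """Rooted hierarchy of populations addressed by '/'-separated paths.

    The root is the reserved node "root" (all events, no gate); the path of
    a node directly under root is "/<name>".  Names may contain spaces but
    never "/".
    """

    def __init__(self, root: Optional[PopulationNode] = None):
        self.root = root if root is not None else PopulationNode(ROOT_NAME)

    def copy(self) -> "GatingTree":
        return GatingTree(copy.deepcopy(self.root))

    def resolve_path(self, path: str) -> PopulationNode:
        if path in (ROOT_NAME, "", "/"):
            return self.root
        parts = path.strip("/").split("/")
        if parts and parts[0] == ROOT_NAME:
            parts = parts[1:]
        node = self.root
        for part in parts:
            nxt = node.child(part)
            if nxt is None:
                raise UnknownPopulationError(f"unknown population path {path!r}")
            node = nxt
        return node

    def add_population(self, parent_path: str, name: str, gate: Gate) -> PopulationNode:
        parent = self.resolve_path(parent_path)
        return parent.add_child(PopulationNode(name, gate))

    def walk(self) -> Iterator[tuple[str, str, PopulationNode]]:
        """Pre-order traversal yielding (path, parent_path, node)."""

        def _walk(node: PopulationNode, path: str, parent: str):
            yield path, parent, node
            for c in node.children:
                base = "" if path == ROOT_NAME else path
                yield from _walk(c, f"{base}/{c.name}", path)

        yield from _walk(self.root, ROOT_NAME, "")

    def paths(self) -> list[str]:
        return [p for p, _, _ in self.walk()]


@dataclass
class Workspace:
    """Samples + gating trees + transform/compensation registries + dialect."""

    samples: list[Sample] = field(default_factory=list)
    trees: dict[str, GatingTree] = field(default_factory=dict)
    template_tree: Optional[GatingTree] = None
    transforms: dict[str, TransformDef] = field(default_factory=dict)
    compensations: dict[str, SpilloverMatrix] = field(default_factory=dict)
    sample_compensation: dict[str, str] = field(default_factory=dict)
    dialect: str = "gatingml"
    name: str = ""

    def sample(self, sample_id: str) -> Sample:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)

    def tree_for(self, sample_id: str) -> GatingTree:
        """Per-sample tree; a shared template is copied on first resolve so
        per-sample edits never mutate the template."""
        if sample_id in self.trees:
            return self.trees[sample_id]
        if self.template_tree is not None:
            tree = self.template_tree.copy()
            self.trees[sample_id] = tree
            return tree
        raise UnknownPopulationError(f"no gating tree for sample {sample_id!r}")


@dataclass
class ClusterAssignment:
    """Per-event cluster labels over one parent population's events.

    Label 0 is reserved for "unassigned"; labels are 1-based cluster ids.
    """

    parent_path: str
    labels: np.ndarray


@dataclass
class FMeasureResult:
    precision: float
    recall: float
    F: float


def _gate_refs(gate: Gate) -> Iterator[GateDimension]:
    if isinstance(gate, GEOMETRIC_GATES):
        yield from gate.dims


def validate_workspace(ws: Workspace) -> list[str]:
    """Structural diagnostics; an empty list means all invariants hold.

    Returns human-readable violation strings, each naming the offending
    entity and the rule it breaks; never raises.
    """
    violations: list[str] = []

    seen_ids: set[str] = set()
    for s in ws.samples:
        if s.sample_id in seen_ids:
            violations.append(f"sample {s.sample_id!r}: duplicate sample_id")
        seen_ids.add(s.sample_id)
        names = s.channel_names
        if len(set(names)) != len(names):
            violations.append(f"sample {s.sample_id!r}: channel names not unique")
        if any(not n for n in names):
            violations.append(f"sample {s.sample_id!r}: empty channel name")
        if s.events.ndim != 2 or s.events.shape[1] != len(s.channels):
            violations.append(
                f"sample {s.sample_id!r}: event matrix shape {s.events.shape} "
                f"does not match {len(s.channels)} channels")
        elif s.events.size and not np.all(np.isfinite(s.events)):
            violations.append(f"sample {s.sample_id!r}: non-finite event values")

    for sid in ws.trees:
        if sid not in seen_ids:
            violations.append(f"tree keyed by unknown sample_id {sid!r}")

    trees = list(ws.trees.values())
    if ws.template_tree is not None:
        trees.append(ws.template_tree)
    for tree in trees:
        for path, _parent, node in tree.walk():
            names = [c.name for c in node.children]
            for n in set(names):
                if names.count(n) > 1:
                    violations.append(
                        f"population {path!r}: duplicate sibling name {n!r}")
            if node.gate is None:
                continue
            for dim in _gate_refs(node.gate):
                if dim.transform_ref != IDENTITY and dim.transform_ref not in ws.transforms:
                    violations.append(
                        f"population {path!r}: unresolved transform_ref "
                        f"{dim.transform_ref!r}")
                if (dim.compensation_ref != UNCOMPENSATED
                        and dim.compensation_ref not in ws.compensations):
                    violations.append(
                        f"population {path!r}: unresolved compensation_ref "
                        f"{dim.compensation_ref!r}")
            if isinstance(node.gate, BooleanGate):
                for op in node.gate.operands:
                    try:
                        tree.resolve_path(op)
                    except UnknownPopulationError:
                        violations.append(
                            f"population {path!r}: boolean operand {op!r} "
                            f"does not resolve")

    for tid, tdef in ws.transforms.items():
        if tdef.family not in ("linear", "log", "asinh", "logicle"):
            violations.append(f"transform {tid!r}: unknown family {tdef.family!r}")
        elif tdef.T <= 0 or tdef.M <= 0 or tdef.A < 0:
            violations.append(f"transform {tid!r}: parameter constraints violated")
        elif tdef.family == "logicle" and not (0 <= tdef.W <= tdef.M / 2):
            violations.append(f"transform {tid!r}: W outside [0, M/2]")

    for cid, comp in ws.compensations.items():
        k = comp.k
        if comp.S.shape != (k, k):
            violations.append(f"compensation {cid!r}: matrix not {k}x{k}")
            continue
        if not np.allclose(np.diag(comp.S), 1.0):
            violations.append(f"compensation {cid!r}: diagonal not 1.0")
        if k and np.linalg.cond(comp.S) > 1e12:
            violations.append(f"compensation {cid!r}: matrix near-singular")

    return violations
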