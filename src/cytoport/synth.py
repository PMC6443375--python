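"""Synthetic samples and reference workspaces with ground-truth labels.

Emulates stained control samples at desk scale: events are drawn from a
Gaussian mixture of cell populations on the linear fluorescence scale and
then mixed through a known spillover matrix (observed = true @ S), so the
compensation + gating pipeline can be verified against the component of
origin of every event.  The generator is seeded through numpy's PCG64
bit generator, a named, versioned algorithm, so fixtures are reproducible
across platforms and releases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2

from .compensation import spillover_to_keyword
from .errors import InvalidSpecError
from .model import (
    ChannelMeta,
    EllipsoidGate,
    GateDimension,
    GatingTree,
    PopulationNode,
    Sample,
    SpilloverMatrix,
    TransformDef,
    Workspace,
    IDENTITY,
)

log = logging.getLogger(__name__)


@dataclass
class Component:
    weight: float
    mean: np.ndarray
    covariance: np.ndarray
    name: str = ""


@dataclass
class SyntheticSpec:
    """Recipe for one synthetic sample: mixture + channels + spillover."""

    n_events: int
    components: list[Component]
    channel_names: list[str]
    markers: list[str] = field(default_factory=list)
    spillover: SpilloverMatrix | None = None
    seed: int = 0
    sample_id: str = "synthetic.fcs"

    def validate(self) -> None:
        w = sum(c.weight for c in self.components)
        if abs(w - 1.0) > 1e-12:
            raise InvalidSpecError(f"component weights sum to {w}, not 1")
        d = len(self.channel_names)
        for i, c in enumerate(self.components):
            if len(c.mean) != d or np.asarray(c.covariance).shape != (d, d):
                raise InvalidSpecError(
                    f"component {i}: dimension mismatch with {d} channels")
            evals = np.linalg.eigvalsh(np.asarray(c.covariance, dtype=float))
            if evals.min() <= 0:
                raise InvalidSpecError(f"component {i}: covariance not SPD")
        if not (0 < min(c.weight for c in self.components)):
            raise InvalidSpecError("component weights must be positive")


def simulate_sample(spec: SyntheticSpec) -> tuple[Sample, np.ndarray]:
    """Draw the mixture, apply spillover, return (Sample, 1-based labels).

    The observed event matrix is true @ S over the spillover's detector
    columns; the FCS $SPILLOVER keyword is set so the acquisition matrix
    travels with the sample.  Same seed, same output, bit for bit.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    d = len(spec.channel_names)
    weights = np.array([c.weight for c in spec.components])
    labels = rng.choice(len(spec.components), size=spec.n_events, p=weights) + 1
    events = np.empty((spec.n_events, d), dtype=float)
    for k, comp in enumerate(spec.components, start=1):
        idx = np.flatnonzero(labels == k)
        if idx.size:
            events[idx] = rng.multivariate_normal(
                np.asarray(comp.mean, dtype=float),
                np.asarray(comp.covariance, dtype=float), size=idx.size,
                method="cholesky")
    keywords: dict[str, str] = {}
    if spec.spillover is not None:
        cols = [spec.channel_names.index(det) for det in spec.spillover.detectors]
        events[:, cols] = events[:, cols] @ spec.spillover.S
        keywords["$SPILLOVER"] = spillover_to_keyword(spec.spillover)
    # events are float32-valued (promoted to double), matching FCS datatype F,
    # so writing and re-reading the sample never moves an event
    events = events.astype(np.float32).astype(np.float64)
    markers = spec.markers or [""] * d
    channels = [ChannelMeta(name=n, marker=m,
                            range=float(max(1.0, np.ceil(events[:, j].max()))
                                        if spec.n_events else 1.0))
                for j, (n, m) in enumerate(zip(spec.channel_names, markers))]
    sample = Sample(sample_id=spec.sample_id, events=events,
                    channels=channels, keywords=keywords)
    return sample, labels


def reference_workspace(spec: SyntheticSpec,
                        coverage_radius2: list[float] | float | None = None,
                        ) -> Workspace:
    """Workspace whose tree holds one ellipsoid gate per mixture component.

    Each gate is the component's own Mahalanobis ball: center and shape
    matrix are the generating parameters, threshold D^2 the given coverage
    radius (default: the 99.9% chi-square quantile in d dimensions).  Gates
    are evaluated on the compensated linear scale (identity transform), so
    membership equals the generating quadratic form exactly; per-channel
    asinh display transforms are declared in the registry for export and
    plotting.  Components closer than 2*sqrt(D^2) in Mahalanobis distance
    trigger an overlap warning (logged, not raised).
    """
    spec.validate()
    d = len(spec.channel_names)
    if coverage_radius2 is None:
        coverage_radius2 = float(chi2.ppf(0.999, df=d))
    if np.isscalar(coverage_radius2):
        radii = [float(coverage_radius2)] * len(spec.components)
    else:
        radii = [float(r) for r in coverage_radius2]

    for i, ci in enumerate(spec.components):
        for j, cj in enumerate(spec.components):
            if j <= i:
                continue
            delta = np.asarray(ci.mean, dtype=float) - np.asarray(cj.mean, dtype=float)
            for c, r2 in ((ci, radii[i]), (cj, radii[j])):
                m2 = float(delta @ np.linalg.solve(
                    np.asarray(c.covariance, dtype=float), delta))
                if np.sqrt(m2) <= 2.0 * np.sqrt(r2):
                    log.warning(
                        "components %d and %d overlap: Mahalanobis distance "
                        "%.2f <= 2*sqrt(D2)=%.2f", i, j, np.sqrt(m2),
                        2.0 * np.sqrt(r2))

    ws = Workspace(dialect="gatingml", name="synthetic-reference")
    for j, ch in enumerate(spec.channel_names):
        tid = f"asinh_{ch}"
        ws.transforms[tid] = TransformDef(transform_id=tid, family="asinh",
                                          T=262144.0, M=4.5, A=0.0)
    comp_ref_default = "uncompensated"
    if spec.spillover is not None:
        mid = spec.spillover.matrix_id or "acquisition"
        ws.compensations[mid] = SpilloverMatrix(
            detectors=list(spec.spillover.detectors),
            S=np.array(spec.spillover.S, dtype=float), matrix_id=mid)
        comp_ref_default = mid

    tree = GatingTree()
    for k, comp in enumerate(spec.components, start=1):
        name = comp.name or f"pop_{k}"
        dims = [GateDimension(channel=ch, transform_ref=IDENTITY,
                              compensation_ref=comp_ref_default)
                for ch in spec.channel_names]
        gate = EllipsoidGate(dims=dims,
                             mean=np.array(comp.mean, dtype=float),
                             covariance=np.array(comp.covariance, dtype=float),
                             distance_square=radii[k - 1])
        tree.root.add_child(PopulationNode(name=name, gate=gate))
    ws.template_tree = tree
    return ws


# --------------------------------------------------------------------------
# the standard fixture: 3 well-separated populations in 4 channels

STANDARD_CHANNELS = ["FL1-A", "FL2-A", "FL3-A", "FL4-A"]
STANDARD_MARKERS = ["CD3", "CD4", "CD8", "CD19"]


def standard_spec(n_events: int = 10_000, seed: int = 42,
                  spillover: bool = True) -> SyntheticSpec:
    """The standard fixture: 3 Gaussian components, weights (0.5, 0.3, 0.2),
    4 channels, means separated by ~12 component standard deviations,
    spillover off-diagonals <= 0.15, n = 10^4, seed 42."""
    sd = 150.0
    means = np.array([
        [2000.0, 2000.0, 9000.0, 2000.0],
        [9000.0, 2000.0, 2000.0, 5500.0],
        [5500.0, 9000.0, 5500.0, 9000.0],
    ])
    cov = (sd ** 2) * np.eye(4)
    comps = [Component(0.5, means[0], cov.copy(), name="T cells"),
             Component(0.3, means[1], cov.copy(), name="B cells"),
             Component(0.2, means[2], cov.copy(), name="NK cells")]
    spill = None
    if spillover:
        S = np.array([
            [1.00, 0.12, 0.05, 0.00],
            [0.08, 1.00, 0.10, 0.02],
            [0.00, 0.15, 1.00, 0.07],
            [0.03, 0.00, 0.09, 1.00],
        ])
        spill = SpilloverMatrix(detectors=list(STANDARD_CHANNELS), S=S,
                                matrix_id="acquisition")
    return SyntheticSpec(n_events=n_events,
                         components=comps,
                         channel_names=list(STANDARD_CHANNELS),
                         markers=list(STANDARD_MARKERS),
                         spillover=spill, seed=seed,
                         sample_id="standard_fixture.fcs")


def standard_fixture(n_events: int = 10_000, seed: int = 42,
                     spillover: bool = True,
                     coverage_radius2: float | list[float] | None = None,
                     ) -> tuple[Workspace, np.ndarray]:
    """Simulate the standard fixture and wire it into its reference workspace."""
    spec = standard_spec(n_events=n_events, seed=seed, spillover=spillover)
    sample, labels = simulate_sample(spec)
    ws = reference_workspace(spec, coverage_radius2=coverage_radius2)
    ws.samples.append(sample)
    return ws, labels


def realized_radii(spec: SyntheticSpec, sample: Sample,
                   labels: np.ndarray) -> list[float]:
    """Per-component max squared Mahalanobis distance actually realized.

    Computed on the true (pre-spillover) coordinates by undoing the known
    mixing; gates taken at these radii capture every own-labeled event.
    A 1e-9 relative margin keeps the radius-defining event inside the gate
    even when the engine's Cholesky route rounds its distance differently
    in the last ulp.
    """
    events = np.asarray(sample.events, dtype=float)
    if spec.spillover is not None:
        cols = [spec.channel_names.index(d) for d in spec.spillover.detectors]
        events = events.copy()
        events[:, cols] = np.linalg.solve(spec.spillover.S.T, events[:, cols].T).T
    radii = []
    for k, comp in enumerate(spec.components, start=1):
        diff = events[labels == k] - np.asarray(comp.mean, dtype=float)
        d2 = np.einsum("ij,ij->i", diff,
                       np.linalg.solve(np.asarray(comp.covariance, dtype=float),
                                       diff.T).T)
        radii.append(float(d2.max()) * (1.0 + 1e-9) if d2.size else 1.0)
    return radii


# --------------------------------------------------------------------------
# randomized workspaces for round-trip exercising

_FAMILIES = ("linear", "log", "asinh", "logicle")


def random_workspace(seed: int, n_events: int = 500,
                     include_ellipsoids: bool = True,
                     ) -> Workspace:
    """A randomized sample + gating tree exercising every gate family.

    Channels get a random display transform each (all four families);
    gates are drawn with coordinates on the transformed [0, 1] scale; a
    random diagonally dominant spillover matrix travels in the sample's
    $SPILLOVER keyword so the auto-selection precedence is exercised.
    Trees are up to 3 levels deep and include boolean gates referencing
    earlier paths.  2-D ellipsoid gates are included only on request:
    dialects without a native ellipse element polygonize them, which is
    deliberately (slightly) lossy.
    """
    rng = np.random.default_rng(seed)
    d = int(rng.integers(2, 5))
    channels = [f"FL{j + 1}-A" for j in range(d)]
    means = rng.uniform(2000.0, 30000.0, size=(2, d))
    comps = [Component(0.6, means[0], (rng.uniform(100, 400) ** 2) * np.eye(d)),
             Component(0.4, means[1], (rng.uniform(100, 400) ** 2) * np.eye(d))]
    S = np.eye(d) + rng.uniform(0.0, 0.08, size=(d, d)) * (1 - np.eye(d))
    spill = SpilloverMatrix(detectors=list(channels), S=S, matrix_id="acq")
    spec = SyntheticSpec(n_events=n_events, components=comps,
                         channel_names=channels, seed=int(rng.integers(2 ** 31)),
                         spillover=spill,
                         sample_id=f"random_{seed}.fcs")
    sample, _labels = simulate_sample(spec)

    ws = Workspace(dialect="gatingml", name=f"random-{seed}")
    channel_tref: dict[str, str] = {}
    for j, ch in enumerate(channels):
        fam = _FAMILIES[int(rng.integers(len(_FAMILIES)))]
        tid = f"t{j}_{fam}"
        ws.transforms[tid] = TransformDef(
            transform_id=tid, family=fam, T=262144.0,
            M=float(rng.uniform(4.0, 5.0)), A=0.0,
            W=float(rng.uniform(0.25, 1.5)))
        channel_tref[ch] = tid

    def dim(ch: str) -> GateDimension:
        return GateDimension(channel=ch, transform_ref=channel_tref[ch])

    def random_gate(allow_ellipse: bool):
        kinds = ["rect", "poly", "quad"]
        if allow_ellipse:
            kinds.append("ellipse")
        kind = kinds[int(rng.integers(len(kinds)))]
        if kind == "rect":
            k = int(rng.integers(1, min(d, 3) + 1))
            chs = list(rng.choice(channels, size=k, replace=False))
            bounds = []
            for _ in range(k):
                lo, hi = np.sort(rng.uniform(0.0, 1.0, size=2))
                which = rng.integers(3)
                bounds.append((None, float(hi)) if which == 0
                              else (float(lo), None) if which == 1
                              else (float(lo), float(hi)))
            from .model import RectangleGate
            return RectangleGate(dims=[dim(c) for c in chs], bounds=bounds)
        chs = list(rng.choice(channels, size=2, replace=False))
        if kind == "poly":
            from .model import PolygonGate
            nv = int(rng.integers(3, 8))
            verts = rng.uniform(0.0, 1.0, size=(nv, 2))
            return PolygonGate(dims=[dim(c) for c in chs], vertices=verts)
        if kind == "quad":
            from .model import QuadrantGate
            sel = "".join(rng.choice(["+", "-"], size=2))
            return QuadrantGate(dims=[dim(c) for c in chs],
                                divider_x=float(rng.uniform(0.2, 0.8)),
                                divider_y=float(rng.uniform(0.2, 0.8)),
                                selector=sel)
        from .model import EllipsoidGate
        A = rng.uniform(-1.0, 1.0, size=(2, 2))
        C = 0.01 * (A @ A.T + 2.0 * np.eye(2))
        return EllipsoidGate(dims=[dim(c) for c in chs],
                             mean=rng.uniform(0.3, 0.7, size=2),
                             covariance=C,
                             distance_square=float(rng.uniform(1.0, 4.0)))

    tree = GatingTree()
    paths: list[str] = []
    n_top = int(rng.integers(1, 4))
    for i in range(n_top):
        name = f"pop{i}"
        tree.root.add_child(PopulationNode(name, random_gate(include_ellipsoids)))
        paths.append(f"/{name}")
        for j in range(int(rng.integers(0, 3))):
            cname = f"pop{i}_{j}"
            tree.add_population(f"/{name}", cname,
                                random_gate(include_ellipsoids))
            paths.append(f"/{name}/{cname}")
    # one boolean node referencing existing populations
    if paths:
        op = ["NOT", "AND", "OR"][int(rng.integers(3))]
        k = 1 if op == "NOT" else int(rng.integers(1, min(3, len(paths)) + 1))
        operands = list(rng.choice(paths, size=min(k, len(paths)), replace=False))
        from .model import BooleanGate
        tree.root.add_child(
            PopulationNode("boolpop", BooleanGate(operator=op, operands=operands)))

    ws.samples.append(sample)
    ws.trees[sample.sample_id] = tree
    return ws
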