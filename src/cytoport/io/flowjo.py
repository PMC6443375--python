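"""FlowJo v10-style workspace (.wsp) reading and writing.

The wsp layout is SampleList/Sample, each holding Keywords, a
Transformations block binding one display transform to each channel, an
optional per-sample spillover matrix (FlowJo's analysis-time custom
matrix), and a SampleNode whose nested Subpopulations carry the gates as
embedded Gating-ML fragments.  Unlike plain Gating-ML, gate coordinates
are written on the *raw* scale (inverse-transformed from the internal
transformed-scale representation) to match FlowJo's rendering
expectations; the reader converts them back using the sample's declared
channel transforms.

Two dialect-specific representations:

* 2-D ellipsoid gates are polygonized to 100 vertices (the documented,
  slightly lossy mapping); ellipsoids in 3+ dimensions keep the native
  Gating-ML fragment with coordinates left on the transformed scale
  (marked ``scale="transformed"``), since no polygon can carry them.
* Index-defined cluster populations export as ``IndexGate`` elements
  enumerating parent-relative event indices — FlowJo is the one dialect
  where cluster results may travel.
"""

from __future__ import annotations

import os

import numpy as np
from lxml import etree

from ..errors import (
    MalformedFileError,
    MissingFileError,
    UnsupportedExportError,
    UnsupportedGateError,
)
from ..fcs import read_fcs, write_fcs
from ..model import (
    BooleanGate,
    EllipsoidGate,
    GateDimension,
    GatingTree,
    IndexGate,
    PolygonGate,
    PopulationNode,
    QuadrantGate,
    RectangleGate,
    Sample,
    SpilloverMatrix,
    TransformDef,
    Workspace,
    GEOMETRIC_GATES,
    IDENTITY,
    ROOT_NAME,
    UNCOMPENSATED,
)
from ..transforms import make_transform
from . import gatingml as gml
from .gatingml import D, G, T, NSMAP, num

ELLIPSE_POLY_VERTICES = 100


# --------------------------------------------------------------------------
# helpers

def _channel_transforms(tree: GatingTree, ws: Workspace) -> dict[str, str]:
    """channel -> transform_id map used by this tree's gates.

    FlowJo declares transforms per channel, not per gate, so a channel
    gated on two different scales cannot be represented.
    """
    mapping: dict[str, str] = {}
    for path, _parent, node in tree.walk():
        gate = node.gate
        if gate is None or not isinstance(gate, GEOMETRIC_GATES):
            continue
        for dim in gate.dims:
            prev = mapping.get(dim.channel)
            if prev is None:
                mapping[dim.channel] = dim.transform_ref
            elif prev != dim.transform_ref:
                raise UnsupportedExportError(
                    f"channel {dim.channel!r} gated on two transforms "
                    f"({prev!r} vs {dim.transform_ref!r}); the FlowJo dialect "
                    f"binds one transform per channel")
    return mapping


def _sample_spillover(tree: GatingTree, ws: Workspace,
                      sample: Sample) -> SpilloverMatrix | None:
    """The matrix to embed in the wsp for this sample, if any."""
    sid = sample.sample_id
    if sid in ws.sample_compensation:
        return ws.compensations[ws.sample_compensation[sid]]
    refs = set()
    for _p, _par, node in tree.walk():
        if node.gate is not None and isinstance(node.gate, GEOMETRIC_GATES):
            refs |= {d.compensation_ref for d in node.gate.dims}
    refs.discard(UNCOMPENSATED)
    if len(refs) > 1:
        raise UnsupportedExportError(
            f"sample {sid!r}: gates reference multiple compensation matrices "
            f"{sorted(refs)}; the FlowJo dialect stores one per sample")
    if refs:
        return ws.compensations[refs.pop()]
    return None  # acquisition $SPILLOVER travels inside the FCS file


def _polygonize_ellipse(gate: EllipsoidGate) -> PolygonGate:
    C = np.asarray(gate.covariance, dtype=float)
    L = np.linalg.cholesky(0.5 * (C + C.T))
    t = np.linspace(0.0, 2.0 * np.pi, ELLIPSE_POLY_VERTICES, endpoint=False)
    circle = np.vstack([np.cos(t), np.sin(t)])
    # scale vertices slightly outward so the polygon straddles the contour
    # (half the chord sagitta outside, half inside) instead of inscribing it
    balance = 2.0 / (1.0 + np.cos(np.pi / ELLIPSE_POLY_VERTICES))
    verts = (np.asarray(gate.mean, dtype=float)[:, None]
             + balance * np.sqrt(gate.distance_square) * (L @ circle)).T
    return PolygonGate(dims=[GateDimension(d.channel, d.transform_ref,
                                           d.compensation_ref)
                             for d in gate.dims],
                       vertices=verts)


def _raw_gate(gate, ws: Workspace):
    """Copy of a geometric gate with coordinates inverse-transformed to raw.

    Transform/compensation refs are stripped (channel binding carries them
    in the wsp).  Ellipsoids in 3+ dims are returned unchanged plus a flag.
    """
    def inv(dim: GateDimension):
        if dim.transform_ref == IDENTITY:
            return lambda v: v
        return make_transform(ws.transforms[dim.transform_ref]).inverse

    bare = [GateDimension(d.channel) for d in gate.dims]
    if isinstance(gate, RectangleGate):
        bounds = []
        for dim, (lo, hi) in zip(gate.dims, gate.bounds):
            f = inv(dim)
            bounds.append((float(f(lo)) if lo is not None else None,
                           float(f(hi)) if hi is not None else None))
        return RectangleGate(dims=bare, bounds=bounds), False
    if isinstance(gate, PolygonGate):
        verts = np.asarray(gate.vertices, dtype=float).copy()
        for j, dim in enumerate(gate.dims):
            verts[:, j] = inv(dim)(verts[:, j])
        return PolygonGate(dims=bare, vertices=verts), False
    if isinstance(gate, QuadrantGate):
        fx, fy = inv(gate.dims[0]), inv(gate.dims[1])
        return QuadrantGate(dims=bare, divider_x=float(fx(gate.divider_x)),
                            divider_y=float(fy(gate.divider_y)),
                            selector=gate.selector), False
    if isinstance(gate, EllipsoidGate):
        if len(gate.dims) == 2:
            return _raw_gate(_polygonize_ellipse(gate), ws)
        # no raw-scale ellipse exists under a nonlinear transform: keep
        # transformed-scale coordinates and mark the fragment
        return EllipsoidGate(dims=bare, mean=np.asarray(gate.mean, float),
                             covariance=np.asarray(gate.covariance, float),
                             distance_square=gate.distance_square), True
    raise UnsupportedGateError(f"cannot export {type(gate).__name__} to FlowJo")


# --------------------------------------------------------------------------
# writing

def _write_population(sub_el, node: PopulationNode, path: str, ws: Workspace):
    gate = node.gate
    if isinstance(gate, BooleanGate):
        tag = {"NOT": "NotNode", "AND": "AndNode", "OR": "OrNode"}[gate.operator.upper()]
        pop = etree.SubElement(sub_el, tag)
        pop.set("name", node.name)
        deps = etree.SubElement(pop, "Dependents")
        for op in gate.operands:
            dep = etree.SubElement(deps, "Dependent")
            dep.set("name", op)
    elif isinstance(gate, IndexGate):
        pop = etree.SubElement(sub_el, "Population")
        pop.set("name", node.name)
        g_el = etree.SubElement(pop, "Gate")
        ig = etree.SubElement(g_el, "IndexGate")
        ig.set("length", str(int(gate.member.shape[0])))
        ig.set("indices", " ".join(str(i) for i in np.flatnonzero(gate.member)))
    else:
        pop = etree.SubElement(sub_el, "Population")
        pop.set("name", node.name)
        g_el = etree.SubElement(pop, "Gate")
        raw, transformed_scale = _raw_gate(gate, ws)
        frag = gml._write_gate(g_el, raw, "g0", None, node.name, lambda p: p)
        if transformed_scale:
            frag.set("scale", "transformed")
    if node.children:
        subs = etree.SubElement(pop, "Subpopulations")
        for child in node.children:
            base = "" if path == ROOT_NAME else path
            _write_population(subs, child, f"{base}/{child.name}", ws)


def _write_transformations(sample_el, channel_map: dict[str, str],
                           ws: Workspace):
    tx = etree.SubElement(sample_el, "Transformations")
    for channel, tref in sorted(channel_map.items()):
        if tref == IDENTITY:
            continue
        tdef = ws.transforms[tref]
        fam_tag = {"linear": "linear", "log": "log", "asinh": "fasinh",
                   "logicle": "logicle"}[tdef.family]
        el = etree.SubElement(tx, f"{{{T}}}{fam_tag}")
        el.set(f"{{{T}}}T", num(tdef.T))
        if tdef.family != "linear":
            el.set(f"{{{T}}}M", num(tdef.M))
        if tdef.family in ("linear", "asinh", "logicle"):
            el.set(f"{{{T}}}A", num(tdef.A))
        if tdef.family == "logicle":
            el.set(f"{{{T}}}W", num(tdef.W))
        par = etree.SubElement(el, f"{{{D}}}parameter")
        par.set(f"{{{D}}}name", channel)


def _write_spillover_wsp(sample_el, spill: SpilloverMatrix):
    el = etree.SubElement(sample_el, f"{{{T}}}spilloverMatrix")
    el.set("name", spill.matrix_id or "custom")
    for det, row in zip(spill.detectors, np.asarray(spill.S, dtype=float)):
        sp = etree.SubElement(el, f"{{{T}}}spillover")
        sp.set(f"{{{D}}}parameter", det)
        for det2, v in zip(spill.detectors, row):
            co = etree.SubElement(sp, f"{{{T}}}coefficient")
            co.set(f"{{{D}}}parameter", det2)
            co.set(f"{{{T}}}value", num(v))


def write_flowjo(ws: Workspace, wsp_path: str, fcs_dir: str | None = None) -> None:
    """Write a FlowJo-dialect workspace (and the samples' FCS files).

    FCS files are written next to the wsp (or into ``fcs_dir``) so the
    workspace is self-contained.  Cluster (index-defined) populations are
    allowed — this is the one dialect that can carry them.
    """
    root = etree.Element("Workspace", nsmap=NSMAP)
    root.set("version", "20.0")
    root.set("flowJoVersion", "10.8.1")
    if ws.name:
        root.set("name", ws.name)
    sample_list = etree.SubElement(root, "SampleList")
    out_dir = fcs_dir or os.path.dirname(os.path.abspath(wsp_path))
    for i, sample in enumerate(ws.samples, start=1):
        tree = ws.tree_for(sample.sample_id)
        channel_map = _channel_transforms(tree, ws)
        sample_el = etree.SubElement(sample_list, "Sample")
        fname = sample.sample_id if sample.sample_id.lower().endswith(".fcs") \
            else sample.sample_id + ".fcs"
        ds = etree.SubElement(sample_el, "DataSet")
        ds.set("uri", f"file:{fname}")
        ds.set("sampleID", str(i))
        kw_el = etree.SubElement(sample_el, "Keywords")
        fil = etree.SubElement(kw_el, "Keyword")
        fil.set("name", "$FIL")
        fil.set("value", sample.sample_id)
        _write_transformations(sample_el, channel_map, ws)
        spill = _sample_spillover(tree, ws, sample)
        if spill is not None:
            _write_spillover_wsp(sample_el, spill)
        node_el = etree.SubElement(sample_el, "SampleNode")
        node_el.set("name", sample.sample_id)
        node_el.set("sampleID", str(i))
        subs = etree.SubElement(node_el, "Subpopulations")
        for child in tree.root.children:
            _write_population(subs, child, f"/{child.name}", ws)
        write_fcs(sample, os.path.join(out_dir, fname))
    etree.ElementTree(root).write(wsp_path, xml_declaration=True,
                                  encoding="UTF-8", pretty_print=True)


# --------------------------------------------------------------------------
# reading

def _transform_gate_coords(gate, channel_map: dict[str, str], ws: Workspace,
                           transformed_scale: bool):
    """Forward-transform raw wsp coordinates and bind per-channel refs."""
    def fwd(channel):
        tref = channel_map.get(channel, IDENTITY)
        if tref == IDENTITY:
            return lambda v: v
        return make_transform(ws.transforms[tref]).forward

    for dim in gate.dims:
        dim.transform_ref = channel_map.get(dim.channel, IDENTITY)
        dim.compensation_ref = UNCOMPENSATED
    if transformed_scale:
        return gate
    if isinstance(gate, RectangleGate):
        gate.bounds = [
            (float(fwd(d.channel)(lo)) if lo is not None else None,
             float(fwd(d.channel)(hi)) if hi is not None else None)
            for d, (lo, hi) in zip(gate.dims, gate.bounds)]
    elif isinstance(gate, PolygonGate):
        verts = np.asarray(gate.vertices, dtype=float)
        for j, d in enumerate(gate.dims):
            verts[:, j] = fwd(d.channel)(verts[:, j])
        gate.vertices = verts
    elif isinstance(gate, QuadrantGate):
        gate.divider_x = float(fwd(gate.dims[0].channel)(gate.divider_x))
        gate.divider_y = float(fwd(gate.dims[1].channel)(gate.divider_y))
    elif isinstance(gate, EllipsoidGate):
        raise MalformedFileError(
            "raw-scale ellipsoid fragment in wsp (expected scale=\"transformed\")")
    return gate


def _read_population(pop_el, parent_node: PopulationNode,
                     channel_map: dict[str, str], ws: Workspace):
    tag = etree.QName(pop_el).localname if isinstance(pop_el.tag, str) else ""
    name = pop_el.get("name")
    if tag in ("NotNode", "AndNode", "OrNode"):
        op = {"NotNode": "NOT", "AndNode": "AND", "OrNode": "OR"}[tag]
        operands = [d.get("name")
                    for d in pop_el.findall("Dependents/Dependent")]
        gate = BooleanGate(operator=op, operands=operands)
    elif tag == "Population":
        gate_el = pop_el.find("Gate")
        if gate_el is None or len(gate_el) == 0:
            raise MalformedFileError(f"population {name!r} has no gate")
        frag = gate_el[0]
        if etree.QName(frag).localname == "IndexGate":
            length = int(frag.get("length"))
            member = np.zeros(length, dtype=bool)
            idx_text = (frag.get("indices") or "").split()
            member[[int(i) for i in idx_text]] = True
            gate = IndexGate(member=member)
        else:
            gate = gml._parse_gate(frag, None)
            gate = _transform_gate_coords(
                gate, channel_map, ws,
                transformed_scale=frag.get("scale") == "transformed")
    else:
        return
    node = parent_node.add_child(PopulationNode(name=name, gate=gate))
    subs = pop_el.find("Subpopulations")
    if subs is not None:
        for child in subs:
            if isinstance(child.tag, str):
                _read_population(child, node, channel_map, ws)


def _locate_fcs(fcs_dir: str, fil: str | None, uri: str | None) -> str:
    candidates = []
    if fil:
        candidates.append(os.path.join(fcs_dir, fil))
        if not fil.lower().endswith(".fcs"):
            candidates.append(os.path.join(fcs_dir, fil + ".fcs"))
    if uri:
        base = os.path.basename(uri.replace("file:", ""))
        candidates.append(os.path.join(fcs_dir, base))
    for c in candidates:
        if os.path.exists(c):
            return c
    raise MissingFileError(
        f"FCS file not found; tried: {', '.join(candidates) or '(no name declared)'}")


def read_flowjo(wsp_path: str, fcs_dir: str | None = None) -> Workspace:
    """Read a FlowJo-dialect workspace plus its FCS files.

    Samples are located by the $FIL keyword, then by the DataSet uri.  A
    per-sample spillover matrix in the wsp is registered as that sample's
    custom matrix and auto-selected ahead of the FCS $SPILLOVER keyword.
    """
    fcs_dir = fcs_dir or os.path.dirname(os.path.abspath(wsp_path))
    try:
        doc = etree.parse(wsp_path)
    except etree.XMLSyntaxError as e:
        raise MalformedFileError(f"{wsp_path}: not well-formed XML: {e}")
    root = doc.getroot()
    if root.tag != "Workspace":
        raise MalformedFileError(f"{wsp_path}: root element is not Workspace")
    ws = Workspace(dialect="flowjo", name=root.get("name", ""))
    for sample_el in root.findall("SampleList/Sample"):
        kw = {k.get("name"): k.get("value")
              for k in sample_el.findall("Keywords/Keyword")}
        ds = sample_el.find("DataSet")
        path = _locate_fcs(fcs_dir, kw.get("$FIL"),
                           ds.get("uri") if ds is not None else None)
        sample = read_fcs(path)
        sid = sample.sample_id
        ws.samples.append(sample)

        channel_map: dict[str, str] = {}
        tx = sample_el.find("Transformations")
        if tx is not None:
            for el in tx:
                if not isinstance(el.tag, str) or etree.QName(el).namespace != T:
                    continue
                fam = {"linear": "linear", "log": "log", "fasinh": "asinh",
                       "logicle": "logicle"}.get(etree.QName(el).localname)
                if fam is None:
                    continue
                par = el.find(f"{{{D}}}parameter")
                channel = par.get(f"{{{D}}}name")
                tid = f"tr_{sid}_{channel}"

                def attr(name, default):
                    v = el.get(f"{{{T}}}{name}")
                    return float(v) if v is not None else default
                ws.transforms[tid] = TransformDef(
                    transform_id=tid, family=fam, T=attr("T", 262144.0),
                    M=attr("M", 4.5), A=attr("A", 0.0), W=attr("W", 0.5))
                channel_map[channel] = tid

        spill_el = sample_el.find(f"{{{T}}}spilloverMatrix")
        if spill_el is not None:
            detectors, rows = [], []
            for sp in spill_el.findall(f"{{{T}}}spillover"):
                detectors.append(sp.get(f"{{{D}}}parameter"))
                rows.append([float(c.get(f"{{{T}}}value"))
                             for c in sp.findall(f"{{{T}}}coefficient")])
            mid = f"comp_{sid}"
            ws.compensations[mid] = SpilloverMatrix(
                detectors=detectors, S=np.array(rows, dtype=float), matrix_id=mid)
            ws.sample_compensation[sid] = mid

        tree = GatingTree()
        node_el = sample_el.find("SampleNode")
        if node_el is not None:
            subs = node_el.find("Subpopulations")
            if subs is not None:
                for child in subs:
                    if isinstance(child.tag, str):
                        _read_population(child, tree.root, channel_map, ws)
        ws.trees[sid] = tree
    return ws
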