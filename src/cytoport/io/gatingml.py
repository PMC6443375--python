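"""Gating-ML 2.0 reading and writing.

A Gating-ML file declares transforms, spectrum (spillover) matrices and a
flat list of gates linked into a hierarchy by ``gating:parent_id``
attributes.  Population names are not part of the standard vocabulary, so
they travel in ``data-type:custom_info`` children; a file without them
still reads (gates are then named by their ids).  Gate coordinates are on
the transformed scale, exactly as this package stores them internally, so
the mapping is loss-free.

The Cytobank dialect shares all of this machinery (see
:mod:`cytoport.io.cytobank`); hooks let it add its extensions.
"""

from __future__ import annotations

import numpy as np
from lxml import etree

from ..errors import (
    DanglingReferenceError,
    MalformedFileError,
    UnsupportedExportError,
    UnsupportedGateError,
)
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
    SpilloverMatrix,
    TransformDef,
    Workspace,
    IDENTITY,
    ROOT_NAME,
    UNCOMPENSATED,
)

G = "http://www.isac-net.org/std/Gating-ML/v2.0/gating"
T = "http://www.isac-net.org/std/Gating-ML/v2.0/transformations"
D = "http://www.isac-net.org/std/Gating-ML/v2.0/datatypes"

NSMAP = {"gating": G, "transforms": T, "data-type": D}


def _g(tag):
    return f"{{{G}}}{tag}"


def _t(tag):
    return f"{{{T}}}{tag}"


def _d(tag):
    return f"{{{D}}}{tag}"


def num(x: float) -> str:
    """Decimal text that re-parses to the identical float."""
    return repr(float(x))


# --------------------------------------------------------------------------
# writing

def _write_dimension(gate_el, dim: GateDimension, lo=None, hi=None):
    el = etree.SubElement(gate_el, _g("dimension"))
    if dim.compensation_ref != UNCOMPENSATED:
        el.set(_g("compensation-ref"), dim.compensation_ref)
    else:
        el.set(_g("compensation-ref"), "uncompensated")
    if dim.transform_ref != IDENTITY:
        el.set(_g("transformation-ref"), dim.transform_ref)
    if lo is not None:
        el.set(_g("min"), num(lo))
    if hi is not None:
        el.set(_g("max"), num(hi))
    fcs = etree.SubElement(el, _d("fcs-dimension"))
    fcs.set(_d("name"), dim.channel)


def _write_coordinates(parent_el, tag: str, values):
    el = etree.SubElement(parent_el, _g(tag))
    for v in values:
        c = etree.SubElement(el, _g("coordinate"))
        c.set(_d("value"), num(v))
    return el


def _write_gate(root_el, gate, gate_id: str, parent_id: str | None,
                name: str, path_to_id) -> etree._Element:
    if isinstance(gate, RectangleGate):
        el = etree.SubElement(root_el, _g("RectangleGate"))
        for dim, (lo, hi) in zip(gate.dims, gate.bounds):
            _write_dimension(el, dim, lo, hi)
    elif isinstance(gate, PolygonGate):
        el = etree.SubElement(root_el, _g("PolygonGate"))
        for dim in gate.dims:
            _write_dimension(el, dim)
        for x, y in np.asarray(gate.vertices, dtype=float):
            _write_coordinates(el, "vertex", (x, y))
    elif isinstance(gate, EllipsoidGate):
        el = etree.SubElement(root_el, _g("EllipsoidGate"))
        for dim in gate.dims:
            _write_dimension(el, dim)
        _write_coordinates(el, "mean", np.asarray(gate.mean, dtype=float))
        cov = etree.SubElement(el, _g("covarianceMatrix"))
        for row in np.asarray(gate.covariance, dtype=float):
            r = etree.SubElement(cov, _g("row"))
            for v in row:
                e = etree.SubElement(r, _g("entry"))
                e.set(_d("value"), num(v))
        dsq = etree.SubElement(el, _g("distanceSquare"))
        dsq.set(_d("value"), num(gate.distance_square))
    elif isinstance(gate, QuadrantGate):
        el = etree.SubElement(root_el, _g("QuadrantGate"))
        for i, (dim, val) in enumerate(zip(gate.dims,
                                           (gate.divider_x, gate.divider_y))):
            div = etree.SubElement(el, _g("divider"))
            div.set(_g("id"), f"{gate_id}_d{i}")
            div.set(_g("compensation-ref"),
                    dim.compensation_ref if dim.compensation_ref != UNCOMPENSATED
                    else "uncompensated")
            if dim.transform_ref != IDENTITY:
                div.set(_g("transformation-ref"), dim.transform_ref)
            fcs = etree.SubElement(div, _d("fcs-dimension"))
            fcs.set(_d("name"), dim.channel)
            v = etree.SubElement(div, _g("value"))
            v.text = num(val)
        quad = etree.SubElement(el, _g("Quadrant"))
        quad.set(_g("id"), f"{gate_id}_q")
        for i, (sel, val) in enumerate(zip(gate.selector,
                                           (gate.divider_x, gate.divider_y))):
            pos = etree.SubElement(quad, _g("position"))
            pos.set(_g("divider_ref"), f"{gate_id}_d{i}")
            pos.set(_g("location"), num(val + 1.0 if sel == "+" else val - 1.0))
    elif isinstance(gate, BooleanGate):
        el = etree.SubElement(root_el, _g("BooleanGate"))
        opel = etree.SubElement(el, _g(gate.operator.lower()))
        for path in gate.operands:
            ref = etree.SubElement(opel, _g("gateReference"))
            ref.set(_g("ref"), path_to_id(path))
    elif isinstance(gate, IndexGate):
        raise UnsupportedExportError(
            "index-defined (cluster) populations cannot be exported to this "
            "dialect; export to the FlowJo dialect instead")
    else:
        raise UnsupportedGateError(f"cannot serialize gate {type(gate).__name__}")
    el.set(_g("id"), gate_id)
    if parent_id is not None:
        el.set(_g("parent_id"), parent_id)
    info = etree.SubElement(el, _d("custom_info"))
    nm = etree.SubElement(info, "name")
    nm.text = name
    return el


def _write_transform(root_el, tdef: TransformDef):
    el = etree.SubElement(root_el, _t("transformation"))
    el.set(_t("id"), tdef.transform_id)
    if tdef.family == "linear":
        f = etree.SubElement(el, _t("flin"))
        f.set(_t("T"), num(tdef.T))
        f.set(_t("A"), num(tdef.A))
    elif tdef.family == "log":
        f = etree.SubElement(el, _t("flog"))
        f.set(_t("T"), num(tdef.T))
        f.set(_t("M"), num(tdef.M))
    elif tdef.family == "asinh":
        f = etree.SubElement(el, _t("fasinh"))
        f.set(_t("T"), num(tdef.T))
        f.set(_t("M"), num(tdef.M))
        f.set(_t("A"), num(tdef.A))
    elif tdef.family == "logicle":
        f = etree.SubElement(el, _t("logicle"))
        f.set(_t("T"), num(tdef.T))
        f.set(_t("W"), num(tdef.W))
        f.set(_t("M"), num(tdef.M))
        f.set(_t("A"), num(tdef.A))
    else:
        raise UnsupportedGateError(f"unknown transform family {tdef.family!r}")


def _write_spillover(root_el, comp: SpilloverMatrix):
    el = etree.SubElement(root_el, _t("spectrumMatrix"))
    el.set(_t("id"), comp.matrix_id)
    fl = etree.SubElement(el, _t("fluorochromes"))
    dt = etree.SubElement(el, _t("detectors"))
    for group in (fl, dt):
        for det in comp.detectors:
            f = etree.SubElement(group, _d("fcs-dimension"))
            f.set(_d("name"), det)
    sp = etree.SubElement(el, _t("spectrum"))
    for row in np.asarray(comp.S, dtype=float):
        r = etree.SubElement(sp, _t("row"))
        for v in row:
            c = etree.SubElement(r, _t("coefficient"))
            c.set(_t("value"), num(v))


def _collect_tree_gates(tree: GatingTree):
    """(path, parent_path, node) for every non-root node, pre-order."""
    return [(p, par, n) for p, par, n in tree.walk() if p != ROOT_NAME]


def build_gatingml_document(ws: Workspace, tree: GatingTree,
                            gate_extras=None, root_extras=None) -> etree._ElementTree:
    """Serialize one tree + registries into a Gating-ML 2.0 element tree.

    ``gate_extras(path, node, gate_el)`` and ``root_extras(root_el)`` are
    dialect hooks (used by the Cytobank writer).
    """
    root = etree.Element(_g("Gating-ML"), nsmap=NSMAP)
    if root_extras is not None:
        root_extras(root)
    for tdef in ws.transforms.values():
        _write_transform(root, tdef)
    for comp in ws.compensations.values():
        _write_spillover(root, comp)

    entries = _collect_tree_gates(tree)
    path_ids = {ROOT_NAME: None}
    for i, (path, _parent, _node) in enumerate(entries):
        path_ids[path] = f"gate_{i}"

    def path_to_id(path: str) -> str:
        node = tree.resolve_path(path)
        for p, _, n in entries:
            if n is node:
                return path_ids[p]
        raise DanglingReferenceError(f"boolean operand {path!r} not in tree")

    for path, parent, node in entries:
        el = _write_gate(root, node.gate, path_ids[path], path_ids[parent],
                         node.name, path_to_id)
        if gate_extras is not None:
            gate_extras(path, node, el)
    return etree.ElementTree(root)


def write_gatingml(ws: Workspace, path: str) -> None:
    """Write the workspace's (template or single shared) tree as Gating-ML 2.0.

    Index-defined cluster populations are rejected: the standard has no
    vocabulary for them, so exporting would silently change the analysis.
    """
    tree = _export_tree(ws)
    doc = build_gatingml_document(ws, tree)
    doc.write(path, xml_declaration=True, encoding="UTF-8", pretty_print=True)


def _export_tree(ws: Workspace) -> GatingTree:
    # a resolved per-sample tree (possibly modified post-import) wins over
    # the pristine template it was copied from
    if len(ws.trees) == 1:
        return next(iter(ws.trees.values()))
    if ws.template_tree is not None and not ws.trees:
        return ws.template_tree
    if not ws.trees:
        return GatingTree()
    raise UnsupportedExportError(
        "this dialect stores one gating tree; workspace has per-sample trees "
        "(use the FlowJo or Cytobank dialect)")


# --------------------------------------------------------------------------
# reading

def _parse_dimension(el) -> tuple[GateDimension, float | None, float | None]:
    comp = el.get(_g("compensation-ref"), "uncompensated")
    if comp in ("uncompensated", "FCS"):
        comp = UNCOMPENSATED
    tref = el.get(_g("transformation-ref"), IDENTITY)
    fcs = el.find(_d("fcs-dimension"))
    if fcs is None:
        raise MalformedFileError("gate dimension lacks an fcs-dimension child")
    channel = fcs.get(_d("name"))
    lo = el.get(_g("min"))
    hi = el.get(_g("max"))
    return (GateDimension(channel=channel, transform_ref=tref,
                          compensation_ref=comp),
            float(lo) if lo is not None else None,
            float(hi) if hi is not None else None)


def _parse_coordinates(el) -> list[float]:
    return [float(c.get(_d("value"))) for c in el.findall(_g("coordinate"))]


def _parse_gate(el, id_to_path):
    tag = etree.QName(el).localname
    if tag == "RectangleGate":
        dims, bounds = [], []
        for del_ in el.findall(_g("dimension")):
            dim, lo, hi = _parse_dimension(del_)
            dims.append(dim)
            bounds.append((lo, hi))
        return RectangleGate(dims=dims, bounds=bounds)
    if tag == "PolygonGate":
        dims = [_parse_dimension(d)[0] for d in el.findall(_g("dimension"))]
        verts = np.array([_parse_coordinates(v)
                          for v in el.findall(_g("vertex"))], dtype=float)
        return PolygonGate(dims=dims, vertices=verts)
    if tag == "EllipsoidGate":
        dims = [_parse_dimension(d)[0] for d in el.findall(_g("dimension"))]
        mean = np.array(_parse_coordinates(el.find(_g("mean"))), dtype=float)
        cov = np.array(
            [[float(e.get(_d("value"))) for e in row.findall(_g("entry"))]
             for row in el.find(_g("covarianceMatrix")).findall(_g("row"))],
            dtype=float)
        d2 = float(el.find(_g("distanceSquare")).get(_d("value")))
        return EllipsoidGate(dims=dims, mean=mean, covariance=cov,
                             distance_square=d2)
    if tag == "QuadrantGate":
        dividers = el.findall(_g("divider"))
        if len(dividers) != 2:
            raise MalformedFileError("QuadrantGate needs exactly 2 dividers")
        dims, values, div_ids = [], [], []
        for div in dividers:
            comp = div.get(_g("compensation-ref"), "uncompensated")
            if comp in ("uncompensated", "FCS"):
                comp = UNCOMPENSATED
            tref = div.get(_g("transformation-ref"), IDENTITY)
            channel = div.find(_d("fcs-dimension")).get(_d("name"))
            dims.append(GateDimension(channel=channel, transform_ref=tref,
                                      compensation_ref=comp))
            values.append(float(div.find(_g("value")).text))
            div_ids.append(div.get(_g("id")))
        quad = el.find(_g("Quadrant"))
        selector = ""
        for i, div_id in enumerate(div_ids):
            loc = None
            for pos in quad.findall(_g("position")):
                if pos.get(_g("divider_ref")) == div_id:
                    loc = float(pos.get(_g("location")))
            if loc is None:
                raise MalformedFileError("Quadrant position missing a divider ref")
            selector += "+" if loc >= values[i] else "-"
        return QuadrantGate(dims=dims, divider_x=values[0], divider_y=values[1],
                            selector=selector)
    if tag == "BooleanGate":
        for opname in ("and", "or", "not"):
            opel = el.find(_g(opname))
            if opel is not None:
                refs = [r.get(_g("ref"))
                        for r in opel.findall(_g("gateReference"))]
                return BooleanGate(operator=opname.upper(),
                                   operands=refs)  # ids; re-pointed later
        raise MalformedFileError("BooleanGate without and/or/not child")
    raise UnsupportedGateError(f"unsupported gate element {tag!r}")


def _parse_transform(el) -> TransformDef:
    tid = el.get(_t("id"))
    for fam_tag, family in (("flin", "linear"), ("flog", "log"),
                            ("fasinh", "asinh"), ("logicle", "logicle")):
        f = el.find(_t(fam_tag))
        if f is not None:
            def attr(name, default):
                v = f.get(_t(name))
                return float(v) if v is not None else default
            return TransformDef(transform_id=tid, family=family,
                                T=attr("T", 262144.0), M=attr("M", 4.5),
                                A=attr("A", 0.0), W=attr("W", 0.5))
    raise UnsupportedGateError(f"transformation {tid!r} has no known family child")


def _parse_spillover(el) -> SpilloverMatrix:
    mid = el.get(_t("id"))
    det_el = el.find(_t("detectors"))
    detectors = [f.get(_d("name")) for f in det_el.findall(_d("fcs-dimension"))]
    S = np.array(
        [[float(c.get(_t("value"))) for c in row.findall(_t("coefficient"))]
         for row in el.find(_t("spectrum")).findall(_t("row"))], dtype=float)
    return SpilloverMatrix(detectors=detectors, S=S, matrix_id=mid)


GATE_TAGS = ("RectangleGate", "PolygonGate", "EllipsoidGate", "QuadrantGate",
             "BooleanGate")


def parse_registries(root, ws: Workspace) -> None:
    """Parse transform and spillover declarations into the registries."""
    for el in root.findall(_t("transformation")):
        tdef = _parse_transform(el)
        ws.transforms[tdef.transform_id] = tdef
    for el in root.findall(_t("spectrumMatrix")):
        comp = _parse_spillover(el)
        ws.compensations[comp.matrix_id] = comp


def collect_gate_records(root) -> list[tuple]:
    """Flat (gate_id, parent_id, name, gate, element) records, document order."""
    records = []
    for el in root:
        if not isinstance(el.tag, str):
            continue  # comments / processing instructions
        qn = etree.QName(el)
        if qn.namespace != G:
            continue
        if qn.localname not in GATE_TAGS:
            if qn.localname == "Gating-ML":
                continue
            raise UnsupportedGateError(
                f"unsupported gate element {qn.localname!r}")
        gate = _parse_gate(el, None)
        gid = el.get(_g("id"))
        pid = el.get(_g("parent_id"))
        info = el.find(_d("custom_info"))
        name = None
        if info is not None and info.find("name") is not None:
            name = info.find("name").text
        records.append((gid, pid, name or gid, gate, el))
    return records


def build_tree_from_records(records) -> tuple[GatingTree, dict, dict]:
    """Link flat gate records into a tree; returns (tree, paths, nodes).

    ``paths`` and ``nodes`` are keyed by gate id.  Boolean operand gate-ids
    are re-pointed at population paths.  Records with no parent id attach
    to root; a parent id naming no record raises.
    """
    known = {gid for gid, *_ in records}
    for gid, pid, _, _, _ in records:
        if pid is not None and pid not in known:
            raise DanglingReferenceError(
                f"gate {gid!r} references missing parent id {pid!r}")

    tree = GatingTree()
    nodes: dict[str, PopulationNode] = {}
    paths: dict[str | None, str] = {None: ROOT_NAME}
    placed_el: dict[str, etree._Element] = {}
    pending = list(records)
    while pending:
        progress = False
        still = []
        for rec in pending:
            gid, pid, name, gate, el = rec
            if pid is not None and pid not in nodes:
                still.append(rec)
                continue
            parent = tree.root if pid is None else nodes[pid]
            node = PopulationNode(name=name, gate=gate)
            parent.add_child(node)
            nodes[gid] = node
            base = "" if paths[pid] == ROOT_NAME else paths[pid]
            paths[gid] = f"{base}/{name}"
            placed_el[gid] = el
            progress = True
        if not progress:
            raise DanglingReferenceError(
                f"parent reference cycle among gates {[r[0] for r in still]}")
        pending = still

    # re-point boolean operand gate-ids at population paths
    for gid, node in nodes.items():
        if isinstance(node.gate, BooleanGate):
            ops = []
            for ref in node.gate.operands:
                if ref not in paths:
                    raise DanglingReferenceError(
                        f"boolean gate {gid!r} references unknown gate {ref!r}")
                ops.append(paths[ref])
            node.gate.operands = ops
    return tree, paths, nodes


def parse_gatingml_root(root, gate_hook=None) -> Workspace:
    """Parse a Gating-ML root element into a partial Workspace.

    ``gate_hook(el, path, node)`` lets the Cytobank reader pull extensions
    off each gate element once its tree position is known.
    """
    ws = Workspace(dialect="gatingml")
    parse_registries(root, ws)
    records = collect_gate_records(root)
    tree, paths, nodes = build_tree_from_records(records)
    if gate_hook is not None:
        by_id = {gid: el for gid, _pid, _name, _gate, el in records}
        for gid, el in by_id.items():
            gate_hook(el, paths[gid], nodes[gid])
    ws.template_tree = tree
    return ws


def read_gatingml(path: str) -> Workspace:
    """Read a Gating-ML 2.0 file: gates, transforms, compensations; no samples.

    Gates whose parent id is absent raise; gates with no parent id attach
    to root.
    """
    try:
        doc = etree.parse(path)
    except etree.XMLSyntaxError as e:
        raise MalformedFileError(f"{path}: not well-formed XML: {e}")
    root = doc.getroot()
    if etree.QName(root).namespace != G:
        raise MalformedFileError(
            f"{path}: root element not in the Gating-ML 2.0 namespace")
    ws = parse_gatingml_root(root)
    ws.dialect = "gatingml"
    return ws
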