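"""Cytobank-dialect Gating-ML reading/writing and ACS containers.

Cytobank stores a Gating-ML 2.0 document with platform extensions kept in
``data-type:custom_info`` blocks: an experiment name at the document root
and, per gate, a ``cytobank`` block carrying the population name and the
FCS filenames the gate is scoped to.  An ACS (Archival Cytometry
Standard) container is a zip bundling that XML with the experiment's FCS
files; handling is deliberately minimal — member discovery by extension,
the TOC manifest read when present but not required.

Cluster (index-defined) populations cannot be exported: the dialect has
no vocabulary for them.
"""

from __future__ import annotations

import io as _stdio
import os
import copy
import zipfile

import numpy as np
from lxml import etree

from ..errors import MalformedContainerError, MalformedFileError
from ..fcs import read_fcs, write_fcs
from ..model import GatingTree, Workspace, ROOT_NAME
from . import gatingml as gml
from .gatingml import D, G, _d, _g

_CYTOBANK_TAG = "cytobank"


# --------------------------------------------------------------------------
# writing

def _tree_scope_pairs(ws: Workspace):
    """(tree, scope filenames) pairs to serialize; None scope = unscoped."""
    if ws.trees:
        merged: list[tuple[GatingTree, list[str] | None]] = []
        for sid, tree in ws.trees.items():
            merged.append((tree, [sid]))
        return merged
    return [(gml._export_tree(ws), None)]


def write_cytobank(ws: Workspace, xml_path: str) -> None:
    """Write a Cytobank-dialect Gating-ML file.

    Per-sample trees become per-gate sample scoping; a shared template
    tree is written unscoped.  Cluster nodes are rejected.
    """
    pairs = _tree_scope_pairs(ws)

    root = etree.Element(_g("Gating-ML"), nsmap=gml.NSMAP)
    info = etree.SubElement(root, _d("custom_info"))
    cb = etree.SubElement(info, _CYTOBANK_TAG)
    name_el = etree.SubElement(cb, "experiment_title")
    name_el.text = ws.name or "cytoport export"

    for tdef in ws.transforms.values():
        gml._write_transform(root, tdef)
    for comp in ws.compensations.values():
        gml._write_spillover(root, comp)

    gate_counter = [0]
    for tree, scope in pairs:
        entries = gml._collect_tree_gates(tree)
        path_ids = {ROOT_NAME: None}
        for path, _parent, _node in entries:
            path_ids[path] = f"gate_{gate_counter[0]}"
            gate_counter[0] += 1

        def path_to_id(path, tree=tree, entries=entries, path_ids=path_ids):
            node = tree.resolve_path(path)
            for p, _, n in entries:
                if n is node:
                    return path_ids[p]
            raise MalformedFileError(f"boolean operand {path!r} not in tree")

        for path, parent, node in entries:
            el = gml._write_gate(root, node.gate, path_ids[path],
                                 path_ids[parent], node.name, path_to_id)
            info = el.find(_d("custom_info"))
            cb = etree.SubElement(info, _CYTOBANK_TAG)
            nm = etree.SubElement(cb, "name")
            nm.text = node.name
            if scope is not None:
                for sid in scope:
                    f = etree.SubElement(cb, "fcs_file_filename")
                    f.text = sid
    etree.ElementTree(root).write(xml_path, xml_declaration=True,
                                  encoding="UTF-8", pretty_print=True)


def write_acs(ws: Workspace, acs_path: str) -> None:
    """Pack the Cytobank XML together with the samples' FCS files into a zip."""
    with zipfile.ZipFile(acs_path, "w", zipfile.ZIP_DEFLATED) as zf:
        import tempfile
        with tempfile.TemporaryDirectory() as tmp:
            xml_p = os.path.join(tmp, "gating.xml")
            write_cytobank(ws, xml_p)
            zf.write(xml_p, "gating.xml")
            for sample in ws.samples:
                fname = sample.sample_id if sample.sample_id.lower().endswith(
                    ".fcs") else sample.sample_id + ".fcs"
                p = os.path.join(tmp, fname)
                write_fcs(sample, p)
                zf.write(p, fname)
        toc = "\n".join(["gating.xml"] + [s.sample_id for s in ws.samples])
        zf.writestr("TOC.txt", toc)


# --------------------------------------------------------------------------
# reading

def _record_scope(el) -> list[str] | None:
    info = el.find(_d("custom_info"))
    if info is None:
        return None
    cb = info.find(_CYTOBANK_TAG)
    if cb is None:
        return None
    files = [f.text for f in cb.findall("fcs_file_filename") if f.text]
    return files or None


def _read_cytobank_xml(xml_source) -> Workspace:
    try:
        doc = etree.parse(xml_source)
    except etree.XMLSyntaxError as e:
        raise MalformedFileError(f"not well-formed XML: {e}")
    root = doc.getroot()
    if etree.QName(root).namespace != G:
        raise MalformedFileError("root element not in the Gating-ML namespace")

    ws = Workspace(dialect="cytobank")
    gml.parse_registries(root, ws)
    top_info = root.find(_d("custom_info"))
    if top_info is not None:
        cb = top_info.find(_CYTOBANK_TAG)
        if cb is not None and cb.find("experiment_title") is not None:
            ws.name = cb.find("experiment_title").text or ""

    records = gml.collect_gate_records(root)
    scopes = {rec[0]: _record_scope(rec[4]) for rec in records}
    sample_ids = sorted({sid for files in scopes.values() if files
                         for sid in files})
    if not sample_ids:
        tree, _paths, _nodes = gml.build_tree_from_records(records)
        ws.template_tree = tree
        return ws
    # per-sample trees: each sample gets the records scoped to it (records
    # without scope apply to every sample); gates deep-copied per tree
    for sid in sample_ids:
        recs = [(gid, pid, name, copy.deepcopy(gate), el)
                for gid, pid, name, gate, el in records
                if scopes[gid] is None or sid in scopes[gid]]
        tree, _paths, _nodes = gml.build_tree_from_records(recs)
        ws.trees[sid] = tree
    return ws


def read_cytobank(path: str, fcs_source: str | None = None) -> Workspace:
    """Read a Cytobank workspace from XML or from an ACS zip container.

    For ACS, the contained XML is parsed and every FCS member becomes a
    sample; a zip without an XML member is malformed.  For bare XML,
    ``fcs_source`` may point at a directory of FCS files to attach.
    """
    if zipfile.is_zipfile(path):
        with zipfile.ZipFile(path) as zf:
            names = zf.namelist()
            xml_members = [n for n in names if n.lower().endswith(".xml")]
            if not xml_members:
                raise MalformedContainerError(
                    f"{path}: ACS container has no XML workspace member")
            ws = _read_cytobank_xml(_stdio.BytesIO(zf.read(xml_members[0])))
            import tempfile
            with tempfile.TemporaryDirectory() as tmp:
                for n in names:
                    if n.lower().endswith(".fcs"):
                        with open(os.path.join(tmp, os.path.basename(n)), "wb") as fh:
                            fh.write(zf.read(n))
                        ws.samples.append(
                            read_fcs(os.path.join(tmp, os.path.basename(n))))
    else:
        ws = _read_cytobank_xml(path)
        if fcs_source is not None and os.path.isdir(fcs_source):
            for fname in sorted(os.listdir(fcs_source)):
                if fname.lower().endswith(".fcs"):
                    ws.samples.append(read_fcs(os.path.join(fcs_source, fname)))
    _match_scoped_samples(ws)
    return ws


def _match_scoped_samples(ws: Workspace) -> None:
    """Re-key scoped trees by the sample ids of the attached samples.

    Scoping keys are FCS filenames; samples identify by $FIL.  Keys are
    matched exactly, then by basename without extension; ambiguity is an
    error, never a guess.
    """
    if not ws.trees or not ws.samples:
        return
    ids = [s.sample_id for s in ws.samples]
    rekeyed = {}
    for key, tree in ws.trees.items():
        if key in ids:
            rekeyed[key] = tree
            continue
        stem = os.path.splitext(os.path.basename(key))[0]
        matches = [sid for sid in ids
                   if os.path.splitext(os.path.basename(sid))[0] == stem]
        if len(matches) > 1:
            raise MalformedFileError(
                f"gate scope {key!r} matches multiple samples {matches}")
        rekeyed[matches[0] if matches else key] = tree
    ws.trees = rekeyed
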