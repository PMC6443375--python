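"""Dialect-to-dialect workspace conversion.

Reads with one dialect, writes with another; population statistics
computed before and after conversion must agree (counts exactly), which
is the package's master interchange contract.
"""

from __future__ import annotations

import os

from ..errors import UsageError
from ..fcs import read_fcs
from ..model import Workspace
from .cytobank import read_cytobank, write_acs, write_cytobank
from .flowjo import read_flowjo, write_flowjo
from .gatingml import read_gatingml, write_gatingml


def attach_fcs_dir(ws: Workspace, fcs_dir: str) -> Workspace:
    """Attach every FCS file in a directory to a workspace as samples."""
    for fname in sorted(os.listdir(fcs_dir)):
        if fname.lower().endswith(".fcs"):
            ws.samples.append(read_fcs(os.path.join(fcs_dir, fname)))
    return ws


def read_workspace(path: str, dialect: str,
                   fcs_source: str | None = None) -> Workspace:
    if dialect == "gatingml":
        ws = read_gatingml(path)
        if fcs_source:
            attach_fcs_dir(ws, fcs_source)
        return ws
    if dialect == "flowjo":
        return read_flowjo(path, fcs_source)
    if dialect == "cytobank":
        return read_cytobank(path, fcs_source)
    raise UsageError(f"unknown dialect {dialect!r}; supported: "
                     f"gatingml, flowjo, cytobank")


def write_workspace(ws: Workspace, path: str, dialect: str,
                    fcs_dir: str | None = None) -> None:
    if dialect == "gatingml":
        write_gatingml(ws, path)
    elif dialect == "flowjo":
        write_flowjo(ws, path, fcs_dir)
    elif dialect == "cytobank":
        if path.lower().endswith((".acs", ".zip")):
            write_acs(ws, path)
        else:
            write_cytobank(ws, path)
    else:
        raise UsageError(f"unknown dialect {dialect!r}; supported: "
                         f"gatingml, flowjo, cytobank")


def convert(in_path: str, dialect_in: str, dialect_out: str, out_path: str,
            fcs_source: str | None = None) -> str:
    """read with dialect_in, write with dialect_out; returns out_path."""
    ws = read_workspace(in_path, dialect_in, fcs_source)
    write_workspace(ws, out_path, dialect_out,
                    fcs_dir=os.path.dirname(os.path.abspath(out_path)))
    return out_path
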