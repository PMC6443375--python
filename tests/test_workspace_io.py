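import os
import zipfile

import numpy as np
import pytest
from lxml import etree

from cytoport.engine import attach_clusters, resolve, workspace_stats
from cytoport.errors import (
    DanglingReferenceError,
    MalformedContainerError,
    MissingFileError,
    UnsupportedExportError,
    UnsupportedGateError,
)
from cytoport.geometry import in_ellipsoid, in_polygon
from cytoport.io import (
    convert,
    read_cytobank,
    read_flowjo,
    read_gatingml,
    write_acs,
    write_cytobank,
    write_flowjo,
    write_gatingml,
)
from cytoport.io.convert import attach_fcs_dir, read_workspace
from cytoport.io.flowjo import _polygonize_ellipse
from cytoport.model import (
    ClusterAssignment,
    EllipsoidGate,
    GateDimension,
    PolygonGate,
    validate_workspace,
)
from cytoport.synth import random_workspace, standard_fixture

from conftest import make_sample


def _resolved(ws, sample=None):
    s = sample if sample is not None else ws.samples[0]
    return resolve(s, ws.tree_for(s.sample_id), ws)


def _assert_same_memberships(r1, r2):
    assert set(r1) == set(r2)
    for k in r1:
        np.testing.assert_array_equal(r1[k], r2[k], err_msg=k)


class TestGatingML:
    def test_structural_and_semantic_roundtrip(self, std_small, tmp_path):
        ws, _ = std_small
        p = str(tmp_path / "ws.xml")
        write_gatingml(ws, p)
        ws2 = read_gatingml(p)
        assert ws2.transforms.keys() == ws.transforms.keys()
        assert ws2.compensations.keys() == ws.compensations.keys()
        for cid in ws.compensations:
            np.testing.assert_array_equal(ws2.compensations[cid].S,
                                          ws.compensations[cid].S)
        assert not ws2.samples  # gates/transforms/compensations only
        s = ws.samples[0]
        ws2.samples.append(s)
        _assert_same_memberships(_resolved(ws), _resolved(ws2))
        assert validate_workspace(ws2) == []

    def test_dangling_parent_id_raises(self, tmp_path):
        xml = """<gating:Gating-ML
          xmlns:gating="http://www.isac-net.org/std/Gating-ML/v2.0/gating"
          xmlns:data-type="http://www.isac-net.org/std/Gating-ML/v2.0/datatypes">
          <gating:RectangleGate gating:id="g1" gating:parent_id="ghost">
            <gating:dimension gating:min="0" gating:max="1">
              <data-type:fcs-dimension data-type:name="FL1"/>
            </gating:dimension>
          </gating:RectangleGate>
        </gating:Gating-ML>"""
        p = tmp_path / "dangling.xml"
        p.write_text(xml)
        with pytest.raises(DanglingReferenceError, match="ghost"):
            read_gatingml(str(p))

    def test_minimal_polygon_attaches_to_root(self, tmp_path):
        xml = """<gating:Gating-ML
          xmlns:gating="http://www.isac-net.org/std/Gating-ML/v2.0/gating"
          xmlns:data-type="http://www.isac-net.org/std/Gating-ML/v2.0/datatypes">
          <gating:PolygonGate gating:id="poly1">
            <gating:dimension><data-type:fcs-dimension data-type:name="X"/></gating:dimension>
            <gating:dimension><data-type:fcs-dimension data-type:name="Y"/></gating:dimension>
            <gating:vertex><gating:coordinate data-type:value="0"/><gating:coordinate data-type:value="0"/></gating:vertex>
            <gating:vertex><gating:coordinate data-type:value="1"/><gating:coordinate data-type:value="0"/></gating:vertex>
            <gating:vertex><gating:coordinate data-type:value="0"/><gating:coordinate data-type:value="1"/></gating:vertex>
          </gating:PolygonGate>
        </gating:Gating-ML>"""
        p = tmp_path / "minimal.xml"
        p.write_text(xml)
        ws = read_gatingml(str(p))
        tree = ws.template_tree
        node = tree.root.children[0]
        assert isinstance(node.gate, PolygonGate)
        assert node.gate.dims[0].transform_ref == "identity"

    def test_unknown_gate_element_is_rejected(self, tmp_path):
        xml = """<gating:Gating-ML
          xmlns:gating="http://www.isac-net.org/std/Gating-ML/v2.0/gating">
          <gating:SpiderGate gating:id="s"/>
        </gating:Gating-ML>"""
        p = tmp_path / "unknown.xml"
        p.write_text(xml)
        with pytest.raises(UnsupportedGateError, match="SpiderGate"):
            read_gatingml(str(p))

    def test_cluster_nodes_are_rejected(self, tmp_path):
        ws, _ = standard_fixture(n_events=300)
        res = _resolved(ws)
        tree = ws.tree_for(ws.samples[0].sample_id)
        labels = np.ones(int(res["/T cells"].sum()), dtype=int)
        attach_clusters(tree, ClusterAssignment("/T cells", labels), resolved=res)
        with pytest.raises(UnsupportedExportError):
            write_gatingml(ws, str(tmp_path / "c.xml"))


class TestFlowJo:
    def test_roundtrip_stats_and_memberships(self, std_small, tmp_path):
        ws, _ = std_small
        p = str(tmp_path / "ws.wsp")
        write_flowjo(ws, p)
        ws2 = read_flowjo(p)
        _assert_same_memberships(_resolved(ws), _resolved(ws2))
        st1 = workspace_stats(ws).drop(columns="sample_id")
        st2 = workspace_stats(ws2).drop(columns="sample_id")
        assert st1.equals(st2)

    def test_missing_fcs_file_is_reported(self, tmp_path):
        ws, _ = standard_fixture(n_events=50)
        p = str(tmp_path / "ws.wsp")
        write_flowjo(ws, p)
        os.remove(tmp_path / "standard_fixture.fcs")
        with pytest.raises(MissingFileError, match="standard_fixture.fcs"):
            read_flowjo(p)

    def test_per_sample_matrix_beats_fcs_keyword(self, tmp_path):
        """A custom spillover in the wsp is auto-selected over $SPILLOVER."""
        ws, _ = standard_fixture(n_events=400)
        p = str(tmp_path / "ws.wsp")
        write_flowjo(ws, p)
        ws2 = read_flowjo(p)
        sid = ws2.samples[0].sample_id
        assert sid in ws2.sample_compensation
        chosen = ws2.compensations[ws2.sample_compensation[sid]]
        np.testing.assert_array_equal(
            chosen.S, ws.compensations["acquisition"].S)

    def test_cluster_nodes_roundtrip(self, tmp_path):
        ws, _ = standard_fixture(n_events=600)
        res = _resolved(ws)
        tree = ws.tree_for(ws.samples[0].sample_id)
        rng = np.random.default_rng(0)
        labels = rng.integers(0, 3, size=int(res["/T cells"].sum()))
        attach_clusters(tree, ClusterAssignment("/T cells", labels), resolved=res)
        p = str(tmp_path / "ws.wsp")
        write_flowjo(ws, p)
        ws2 = read_flowjo(p)
        _assert_same_memberships(_resolved(ws), _resolved(ws2))

    def test_2d_ellipsoid_polygonization_error_is_small(self):
        """The 100-vertex polygon disagrees with the exact ellipse on fewer
        than 0.5% of boundary-adjacent points."""
        rng = np.random.default_rng(8)
        gate = EllipsoidGate(
            dims=[GateDimension("X"), GateDimension("Y")],
            mean=np.array([0.5, 0.5]),
            covariance=np.array([[0.02, 0.005], [0.005, 0.01]]),
            distance_square=2.0)
        poly = _polygonize_ellipse(gate)
        # boundary-adjacent: radial perturbation of the exact contour
        t = rng.uniform(0, 2 * np.pi, 10_000)
        r = np.sqrt(gate.distance_square) * rng.uniform(0.97, 1.03, t.size)
        L = np.linalg.cholesky(gate.covariance)
        pts = (gate.mean[:, None] + L @ (r * np.vstack([np.cos(t), np.sin(t)]))).T
        exact = in_ellipsoid(pts, gate)
        approx = in_polygon(pts, poly)
        assert (exact != approx).mean() < 0.005


class TestCytobank:
    def test_xml_roundtrip_with_scoping(self, std_small, tmp_path):
        ws, _ = std_small
        ws.tree_for(ws.samples[0].sample_id)  # instantiate per-sample tree
        p = str(tmp_path / "cb.xml")
        write_cytobank(ws, p)
        ws2 = read_cytobank(p)
        ws2.samples.append(ws.samples[0])
        from cytoport.io.cytobank import _match_scoped_samples
        _match_scoped_samples(ws2)
        _assert_same_memberships(_resolved(ws), _resolved(ws2))

    def test_acs_roundtrip(self, std_small, tmp_path):
        ws, _ = std_small
        p = str(tmp_path / "exp.acs")
        write_acs(ws, p)
        ws2 = read_cytobank(p)
        assert len(ws2.samples) == 1
        _assert_same_memberships(_resolved(ws), _resolved(ws2))

    def test_acs_without_xml_is_malformed(self, tmp_path):
        p = tmp_path / "bad.acs"
        with zipfile.ZipFile(p, "w") as zf:
            zf.writestr("a.fcs", b"not really fcs")
        with pytest.raises(MalformedContainerError):
            read_cytobank(str(p))

    def test_two_sample_acs(self, tmp_path):
        ws1, _ = standard_fixture(n_events=100, seed=1)
        ws2, _ = standard_fixture(n_events=100, seed=2)
        ws2.samples[0].sample_id = "second.fcs"
        ws1.samples.append(ws2.samples[0])
        ws1.tree_for("standard_fixture.fcs")
        ws1.tree_for("second.fcs")
        p = str(tmp_path / "two.acs")
        write_acs(ws1, p)
        back = read_cytobank(p)
        assert len(back.samples) == 2
        assert set(back.trees) == {"standard_fixture.fcs", "second.fcs"}

    def test_cluster_nodes_are_rejected(self, tmp_path):
        ws, _ = standard_fixture(n_events=300)
        res = _resolved(ws)
        tree = ws.tree_for(ws.samples[0].sample_id)
        labels = np.ones(int(res["/T cells"].sum()), dtype=int)
        attach_clusters(tree, ClusterAssignment("/T cells", labels), resolved=res)
        with pytest.raises(UnsupportedExportError):
            write_cytobank(ws, str(tmp_path / "c.xml"))

    def test_logicle_parameters_roundtrip_bit_exact(self, tmp_path):
        ws = random_workspace(21)
        p = str(tmp_path / "t.xml")
        write_cytobank(ws, p)
        ws2 = read_cytobank(p)
        for tid, tdef in ws.transforms.items():
            back = ws2.transforms[tid]
            assert (back.T, back.M, back.A) == (tdef.T, tdef.M, tdef.A)
            if tdef.family == "logicle":
                assert back.W == tdef.W


class TestRandomizedRoundtrips:
    @pytest.mark.parametrize("seed", range(8))
    def test_all_dialects_preserve_memberships(self, seed, tmp_path):
        for dialect in ("gatingml", "flowjo", "cytobank"):
            ws = random_workspace(seed, n_events=300,
                                  include_ellipsoids=(dialect != "flowjo"))
            sample = ws.samples[0]
            r1 = _resolved(ws)
            if dialect == "gatingml":
                p = str(tmp_path / f"{seed}.xml")
                write_gatingml(ws, p)
                ws2 = read_gatingml(p)
                ws2.samples.append(sample)
                ws2.trees[sample.sample_id] = ws2.template_tree.copy()
            elif dialect == "flowjo":
                p = str(tmp_path / f"{seed}.wsp")
                write_flowjo(ws, p)
                ws2 = read_flowjo(p)
            else:
                p = str(tmp_path / f"{seed}_cb.acs")
                write_acs(ws, p)
                ws2 = read_cytobank(p)
            r2 = _resolved(ws2)
            _assert_same_memberships(r1, r2)


class TestConvert:
    def test_all_ordered_pairs_preserve_counts(self, tmp_path):
        ws, _ = standard_fixture(n_events=800)
        base_counts = workspace_stats(ws).set_index("population_path")["count"]
        src = {}
        for dialect, fname in (("gatingml", "src.xml"), ("flowjo", "src.wsp"),
                               ("cytobank", "src_cb.xml")):
            p = str(tmp_path / fname)
            if dialect == "gatingml":
                write_gatingml(ws, p)
            elif dialect == "flowjo":
                write_flowjo(ws, p)
            else:
                write_cytobank(ws, p)
            src[dialect] = p
        import itertools
        for din, dout in itertools.permutations(src, 2):
            out = str(tmp_path / f"out_{din}_{dout}"
                      ) + (".wsp" if dout == "flowjo" else ".xml")
            convert(src[din], din, dout, out, fcs_source=str(tmp_path))
            ws2 = read_workspace(out, dout, fcs_source=str(tmp_path))
            if not ws2.samples:
                attach_fcs_dir(ws2, str(tmp_path))
            counts = workspace_stats(ws2).set_index("population_path")["count"]
            assert base_counts.sort_index().equals(counts.sort_index()), \
                (din, dout)

    def test_clusters_to_cytobank_fails_loudly(self, tmp_path):
        ws, _ = standard_fixture(n_events=300)
        res = _resolved(ws)
        tree = ws.tree_for(ws.samples[0].sample_id)
        labels = np.ones(int(res["/T cells"].sum()), dtype=int)
        attach_clusters(tree, ClusterAssignment("/T cells", labels), resolved=res)
        wsp = str(tmp_path / "c.wsp")
        write_flowjo(ws, wsp)
        with pytest.raises(UnsupportedExportError):
            convert(wsp, "flowjo", "cytobank", str(tmp_path / "out.xml"),
                    fcs_source=str(tmp_path))

    def test_writers_output_revalidates(self, std_small, tmp_path):
        ws, _ = std_small
        p = str(tmp_path / "v.xml")
        write_gatingml(ws, p)
        ws2 = read_gatingml(p)
        assert validate_workspace(ws2) == []
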