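import numpy as np
import pytest

from cytoport.compensation import select_compensation
from cytoport.engine import (
    attach_clusters,
    compute_stats,
    f_measure,
    get_data,
    get_indices,
    resolve,
)
from cytoport.errors import (
    GateCycleError,
    LabelLengthError,
    UnknownPopulationError,
)
from cytoport.model import (
    BooleanGate,
    ClusterAssignment,
    EllipsoidGate,
    GateDimension,
    GatingTree,
    PolygonGate,
    PopulationNode,
    QuadrantGate,
    RectangleGate,
    Sample,
    Workspace,
    IDENTITY,
    ROOT_NAME,
    UNCOMPENSATED,
)
from cytoport.synth import (
    random_workspace,
    realized_radii,
    reference_workspace,
    simulate_sample,
    standard_spec,
)
from cytoport.transforms import make_transform

from conftest import make_sample, rect1d


# --------------------------------------------------------------------------
# independent per-event recursive oracle

def _prep_value(sample, ws, event_row, dim):
    spill = select_compensation(sample, ws, dim.compensation_ref)
    row = np.array(event_row, dtype=float)
    if spill is not None:
        idx = [sample.channel_names.index(d) for d in spill.detectors]
        row[idx] = np.linalg.solve(np.asarray(spill.S).T, row[idx])
    v = row[sample.channel_index(dim.channel)]
    if dim.transform_ref != IDENTITY:
        v = float(make_transform(ws.transforms[dim.transform_ref]).forward(v))
    return v


def _oracle_gate(sample, ws, tree, event_row, gate, member_of):
    if isinstance(gate, BooleanGate):
        vals = [member_of(op) for op in gate.operands]
        if gate.operator == "NOT":
            return not vals[0]
        if gate.operator == "AND":
            return all(vals)
        return any(vals)
    xs = [_prep_value(sample, ws, event_row, d) for d in gate.dims]
    if isinstance(gate, RectangleGate):
        for x, (lo, hi) in zip(xs, gate.bounds):
            if lo is not None and x < lo:
                return False
            if hi is not None and x > hi:
                return False
        return True
    if isinstance(gate, PolygonGate):
        from test_geometry import polygon_oracle
        return polygon_oracle(xs[0], xs[1], np.asarray(gate.vertices))
    if isinstance(gate, EllipsoidGate):
        diff = np.array(xs) - np.asarray(gate.mean, dtype=float)
        d2 = diff @ np.linalg.inv(np.asarray(gate.covariance, float)) @ diff
        return d2 <= gate.distance_square
    if isinstance(gate, QuadrantGate):
        ok_x = xs[0] >= gate.divider_x
        ok_y = xs[1] >= gate.divider_y
        if gate.selector[0] == "-":
            ok_x = not ok_x
        if gate.selector[1] == "-":
            ok_y = not ok_y
        return ok_x and ok_y
    raise AssertionError(type(gate))


def naive_resolve(sample, tree, ws):
    """Per-event recursive evaluator, independent of the vectorized engine."""
    paths = {p: node for p, _par, node in tree.walk()}
    parents = {p: par for p, par, _ in tree.walk()}
    out = {p: np.zeros(sample.n_events, dtype=bool) for p in paths}
    for i in range(sample.n_events):
        row = sample.events[i]
        memo: dict[str, bool] = {}

        def member(path: str) -> bool:
            if not path.startswith("/") and path != ROOT_NAME:
                path = "/" + path
            if path in memo:
                return memo[path]
            if path == ROOT_NAME:
                memo[path] = True
                return True
            node = paths[path]
            ok = member(parents[path]) and _oracle_gate(
                sample, ws, tree, row, node.gate, member)
            memo[path] = ok
            return ok

        for p in paths:
            out[p][i] = member(p)
    return out


# --------------------------------------------------------------------------

def _tiny_ws():
    """2-channel sample, rectangle parent with polygon child."""
    rng = np.random.default_rng(0)
    ev = rng.uniform(0, 10, size=(300, 2))
    ws = Workspace()
    sample = make_sample(ev, ["X", "Y"])
    ws.samples.append(sample)
    tree = GatingTree()
    tree.root.add_child(PopulationNode("box", RectangleGate(
        dims=[GateDimension("X")], bounds=[(2.0, 8.0)])))
    tree.add_population("/box", "tri", PolygonGate(
        dims=[GateDimension("X"), GateDimension("Y")],
        vertices=np.array([[2.0, 0.0], [8.0, 0.0], [5.0, 9.0]])))
    ws.trees[sample.sample_id] = tree
    return ws, sample, tree


class TestResolve:
    def test_root_only_tree(self):
        sample = make_sample(np.zeros((5, 1)), ["A"])
        res = resolve(sample, GatingTree(), Workspace())
        assert list(res) == ["root"]
        assert res["root"].all() and len(res["root"]) == 5

    def test_child_membership_subset_of_parent(self):
        ws, sample, tree = _tiny_ws()
        res = resolve(sample, tree, ws)
        assert not (res["/box/tri"] & ~res["/box"]).any()

    def test_ground_truth_recovery_exact(self):
        """Identity spillover + gates at generating parameters recover the
        component labels of every event."""
        spec = standard_spec(n_events=3000, spillover=False)
        sample, labels = simulate_sample(spec)
        ws = reference_workspace(spec, realized_radii(spec, sample, labels))
        ws.samples.append(sample)
        res = resolve(sample, ws.tree_for(sample.sample_id), ws)
        for k, name in enumerate(["T cells", "B cells", "NK cells"], start=1):
            assert f_measure(labels == k, res[f"/{name}"]).F == 1.0

    def test_determinism(self):
        ws, sample, tree = _tiny_ws()
        r1 = resolve(sample, tree, ws)
        r2 = resolve(sample, tree, ws)
        for k in r1:
            assert np.array_equal(r1[k], r2[k])

    @pytest.mark.parametrize("seed", range(12))
    def test_agrees_with_naive_recursive_oracle(self, seed):
        ws = random_workspace(seed, n_events=80)
        sample = ws.samples[0]
        tree = ws.tree_for(sample.sample_id)
        got = resolve(sample, tree, ws)
        want = naive_resolve(sample, tree, ws)
        assert set(got) == set(want)
        for path in got:
            np.testing.assert_array_equal(got[path], want[path], err_msg=path)

    def test_boolean_cycle_is_detected(self):
        sample = make_sample(np.zeros((3, 1)), ["A"])
        tree = GatingTree()
        tree.root.add_child(PopulationNode(
            "a", BooleanGate(operator="NOT", operands=["/b"])))
        tree.root.add_child(PopulationNode(
            "b", BooleanGate(operator="NOT", operands=["/a"])))
        with pytest.raises(GateCycleError):
            resolve(sample, tree, Workspace())

    def test_cross_branch_boolean_reference(self):
        ws, sample, tree = _tiny_ws()
        tree.add_population("/box", "not_tri",
                            BooleanGate(operator="NOT", operands=["/box/tri"]))
        res = resolve(sample, tree, ws)
        n_box = int(res["/box"].sum())
        assert int(res["/box/not_tri"].sum()) == n_box - int(res["/box/tri"].sum())


class TestAccess:
    def test_get_indices_root_and_unknown(self):
        ws, sample, tree = _tiny_ws()
        res = resolve(sample, tree, ws)
        assert get_indices(res, "root").all()
        with pytest.raises(UnknownPopulationError):
            get_indices(res, "/xyz")

    def test_get_data_row_count_matches_popcount(self):
        ws, sample, tree = _tiny_ws()
        res = resolve(sample, tree, ws)
        for path in res:
            assert get_data(sample, res, path).shape == (
                int(res[path].sum()), 2)

    def test_get_data_empty_population(self):
        sample = make_sample(np.full((10, 1), 5.0), ["A"])
        tree = GatingTree()
        tree.root.add_child(PopulationNode("none", rect1d("A", 100.0, 200.0)))
        res = resolve(sample, tree, Workspace())
        assert get_data(sample, res, "/none").shape == (0, 1)


class TestStats:
    def test_root_only(self):
        sample = make_sample(np.zeros((500, 1)), ["A"])
        res = resolve(sample, GatingTree(), Workspace())
        df = compute_stats(res, GatingTree(), 500)
        assert len(df) == 1
        row = df.iloc[0]
        assert row["count"] == 500
        assert row.freq_of_parent == 1.0 and row.freq_of_total == 1.0

    def test_freq_of_parent(self):
        ws, sample, tree = _tiny_ws()
        res = resolve(sample, tree, ws)
        df = compute_stats(res, tree, sample.n_events).set_index("population_path")
        assert df.loc["/box/tri", "freq_of_parent"] == pytest.approx(
            df.loc["/box/tri", "count"] / df.loc["/box", "count"])
        assert (df["count"] <= sample.n_events).all()


class TestClusters:
    def test_children_partition_labeled_events(self):
        ws, sample, tree = _tiny_ws()
        res = resolve(sample, tree, ws)
        n_box = int(res["/box"].sum())
        labels = np.random.default_rng(2).integers(0, 4, size=n_box)
        attach_clusters(tree, ClusterAssignment("/box", labels), resolved=res)
        res2 = resolve(sample, tree, ws)
        total = sum(int(res2[f"/box/cluster_{k}"].sum()) for k in (1, 2, 3))
        assert total == int((labels != 0).sum())

    def test_all_zero_labels_add_no_children(self):
        ws, sample, tree = _tiny_ws()
        res = resolve(sample, tree, ws)
        before = len(tree.resolve_path("/box").children)
        attach_clusters(tree, ClusterAssignment(
            "/box", np.zeros(int(res["/box"].sum()), dtype=int)), resolved=res)
        assert len(tree.resolve_path("/box").children) == before

    def test_length_mismatch_raises(self):
        ws, sample, tree = _tiny_ws()
        res = resolve(sample, tree, ws)
        with pytest.raises(LabelLengthError):
            attach_clusters(tree, ClusterAssignment("/box", np.ones(3, int)),
                            resolved=res)


class TestFMeasure:
    def test_identical_sets(self):
        a = np.array([True, False, True])
        assert f_measure(a, a).F == 1.0

    def test_disjoint_sets(self):
        assert f_measure(np.array([True, False]), np.array([False, True])).F == 0.0

    def test_hand_computed_example(self):
        a = np.zeros(1000, bool)
        b = np.zeros(1000, bool)
        a[:100] = True          # |a| = 100
        b[75:125] = True        # |b| = 50, overlap 25
        r = f_measure(a, b)
        assert r.precision == 0.5
        assert r.recall == 0.25
        assert r.F == pytest.approx(1 / 3)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            f_measure(np.ones(3, bool), np.ones(4, bool))
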