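"""Engine contract: params, registry/plugins, graph building, execution, persistence."""

from __future__ import annotations

import json

import numpy as np
import pytest

import saxsflow
from saxsflow.engine import (
    GraphValidationError,
    NodeRegistry,
    NodeType,
    ParamSpec,
    RegistrationError,
    ResultBundle,
    WorkflowBuilder,
    WorkflowRun,
    graph_from_dict,
    load_workflow,
    register_node_type,
    save_workflow,
)

from conftest import array_source_type, record_node_type, scalar_frames


# -- parameter specs ---------------------------------------------------------

class TestParamSpec:
    def test_enumeration_requires_choices(self):
        with pytest.raises(ValueError, match="choices"):
            ParamSpec("mode", "enumeration", "a")

    def test_enumeration_default_must_be_a_choice(self):
        with pytest.raises(ValueError, match="default"):
            ParamSpec("mode", "enumeration", "z", choices=("a", "b"))

    def test_unknown_ptype_rejected(self):
        with pytest.raises(ValueError, match="unknown type"):
            ParamSpec("x", "complex")

    @pytest.mark.parametrize("ptype,good,bad", [
        ("integer", 3, 3.5),
        ("float", 2.5, "2.5"),
        ("string", "s", 7),
        ("tuple", (1, 2), 5),
        ("boolean", True, 1),
        ("io", "path.h5", 3.0),
    ])
    def test_type_checking(self, ptype, good, bad):
        spec = ParamSpec("p", ptype, None)
        spec.check(good)
        with pytest.raises(TypeError):
            spec.check(bad)

    def test_boolean_not_accepted_as_integer(self):
        with pytest.raises(TypeError):
            ParamSpec("n", "integer", 0).check(True)


# -- registry and plugin discovery -------------------------------------------

DOUBLE_PLUGIN = '''
from saxsflow.engine import NodeType, ResultBundle
from saxsflow.sources import Frame

def _run(state, inputs, params):
    frame = inputs[0].data
    out = Frame(frame.image * 2.0, index=frame.index, coords=dict(frame.coords))
    return ResultBundle(data=out, data_kind="frame", context={"frame": out})

NODE_TYPES = [NodeType(function_text="Double", function_tip="doubles each frame",
                       run=_run)]
'''


class TestRegistry:
    def test_builtins_present(self, registry):
        for name in ("Data Source", "Azimuthal Integration", "Guinier Operation",
                     "Reconstruction", "Data Storage"):
            assert name in registry

    def test_duplicate_registration_names_both_origins(self, registry):
        clone = NodeType(function_text="Data Source", function_tip="dup")
        with pytest.raises(RegistrationError, match="builtin"):
            registry.register(clone, origin="elsewhere.py")

    def test_empty_plugins_dir_leaves_builtins_only(self, tmp_path):
        reg = register_node_type(tmp_path)
        assert reg.names() == saxsflow.builtin_registry().names()

    def test_plugin_node_runs_in_a_workflow(self, tmp_path):
        (tmp_path / "double.py").write_text(DOUBLE_PLUGIN)
        reg = register_node_type(tmp_path)
        assert "Double" in reg
        frames = scalar_frames([1.0, 2.0, 3.0])
        reg.register(array_source_type(frames))
        b = WorkflowBuilder(reg)
        b.add("Test Source")
        b.add("Double")
        graph = b.build()
        outputs = [r["Double_1"].data.image[0, 0] for r in WorkflowRun(graph, reg)]
        assert outputs == [2.0, 4.0, 6.0]

    def test_duplicate_plugin_names_are_hard_errors(self, tmp_path):
        (tmp_path / "a.py").write_text(DOUBLE_PLUGIN)
        (tmp_path / "b.py").write_text(DOUBLE_PLUGIN)
        with pytest.raises(RegistrationError, match=r"a\.py"):
            register_node_type(tmp_path)

    def test_malformed_plugin_skipped_with_warning(self, tmp_path, caplog):
        (tmp_path / "broken.py").write_text("this is not ( valid python")
        with caplog.at_level("WARNING"):
            reg = register_node_type(tmp_path)
        assert "broken.py" in caplog.text
        assert "Data Source" in reg  # registry still usable


# -- graph construction ------------------------------------------------------

def _toy_registry(n_frames=3):
    reg = NodeRegistry()
    log = []
    reg.register(array_source_type(scalar_frames(range(n_frames))))
    reg.register(record_node_type(log))
    return reg, log


class TestGraphBuilding:
    def test_list_structure_auto_wires_a_chain(self):
        reg, _ = _toy_registry()
        b = WorkflowBuilder(reg)
        b.add("Test Source")
        a = b.add("Record", node_id="A")
        b.add("Record", node_id="B")
        g = b.build()
        assert g.inputs_of("A") == ["Test Source_1"]
        assert g.inputs_of("B") == ["A"]

    def test_diamond_graph_is_valid(self):
        reg, _ = _toy_registry()
        b = WorkflowBuilder(reg)
        s = b.add("Test Source")
        b.add("Record", node_id="A", inputs=[s])
        b.add("Record", node_id="B", inputs=[s])
        b.add("Record", node_id="C", inputs=["A", "B"])
        g = b.build()
        assert g.inputs_of("C") == ["A", "B"]

    def test_cycle_rejected_naming_nodes(self):
        reg, _ = _toy_registry()
        b = WorkflowBuilder(reg)
        s = b.add("Test Source")
        b.add("Record", node_id="A", inputs=[s])
        b.add("Record", node_id="B", inputs=["A"])
        b.graph.edges.append(("B", "A", 1))
        with pytest.raises(GraphValidationError, match=r"cycle.*'A'.*'B'"):
            b.build()

    def test_unknown_node_type_rejected(self):
        reg, _ = _toy_registry()
        with pytest.raises(KeyError, match="Nonexistent"):
            WorkflowBuilder(reg).add("Nonexistent")

    def test_param_type_mismatch_names_node_and_param(self, registry):
        g = graph_from_dict({"nodes": [
            {"id": "src", "type": "Data Source", "params": {"port": "not-an-int"}}],
            "edges": []})
        with pytest.raises(GraphValidationError, match=r"'src'.*'port'"):
            g.validate(registry)

    def test_invariant_dependency_enforced_before_any_frame(self, registry):
        """A dependent analysis node without its required upstream operations
        must fail validation, not at run time."""
        spec = {"nodes": [
            {"id": "src", "type": "Data Source", "params": {}},
            {"id": "azi", "type": "Azimuthal Integration", "params": {}},
            {"id": "inv", "type": "Integral Invariant", "params": {}}],
            "edges": [["src", "azi", 0], ["azi", "inv", 0]]}
        g = graph_from_dict(spec)
        with pytest.raises(GraphValidationError,
                           match="Guinier Operation.*Porod Operation"):
            g.validate(registry)

    def test_exactly_one_source_required(self, registry):
        g = graph_from_dict({"nodes": [
            {"id": "a", "type": "Azimuthal Integration", "params": {}}],
            "edges": []})
        with pytest.raises(GraphValidationError, match="source"):
            g.validate(registry)


# -- streaming execution -----------------------------------------------------

class TestExecution:
    def test_diamond_counts_and_ordering(self):
        reg, log = _toy_registry(n_frames=3)
        b = WorkflowBuilder(reg)
        s = b.add("Test Source")
        b.add("Record", node_id="A", inputs=[s])
        b.add("Record", node_id="B", inputs=[s])
        b.add("Record", node_id="C", inputs=["A", "B"])
        run = WorkflowRun(b.build(), reg)
        results = list(run)
        assert len(results) == 3
        assert all(count == 3 for count in run.execution_counts.values())
        # C executes after both A and B within every frame
        for frame in range(3):
            events = [nid for nid, idx in log if idx == frame]
            assert events.index("C") > events.index("A")
            assert events.index("C") > events.index("B")

    def test_empty_stream_runs_init_and_finalizes_cleanly(self):
        reg, log = _toy_registry(n_frames=0)
        b = WorkflowBuilder(reg)
        b.add("Test Source", {"n": 0})
        b.add("Record", node_id="A")
        run = WorkflowRun(b.build(), reg)
        assert list(run) == []
        assert run.finalize() == {}
        assert log == []

    def test_halt_policy_raises_with_node_id(self):
        reg, _ = _toy_registry()
        def boom(state, inputs, params):
            raise RuntimeError("kaboom")
        reg.register(NodeType(function_text="Boom", run=boom))
        b = WorkflowBuilder(reg)
        b.add("Test Source")
        b.add("Boom")
        with pytest.raises(saxsflow.engine.NodeExecutionError, match="Boom_1"):
            list(WorkflowRun(b.build(), reg, on_error="halt"))

    def test_skip_policy_drops_failing_frames_only(self):
        reg, _ = _toy_registry()
        def sometimes(state, inputs, params):
            frame = inputs[0].context["frame"]
            if frame.index == 1:
                raise RuntimeError("bad frame")
            return ResultBundle(data=float(frame.index), data_kind="scalar")
        reg.register(NodeType(function_text="Flaky", run=sometimes))
        b = WorkflowBuilder(reg)
        b.add("Test Source")
        b.add("Flaky")
        results = list(WorkflowRun(b.build(), reg, on_error="skip"))
        assert [r["Flaky_1"].data for r in results] == [0.0, 2.0]


# -- persistence -------------------------------------------------------------

class TestPersistence:
    def _graph(self, registry, tmp_path):
        b = WorkflowBuilder(registry)
        b.add("Data Source", {"source_type": "hdf5", "path": "x.h5"})
        b.add("Azimuthal Integration", {"n_bins": 100, "q_range": (0.01, 0.1)})
        b.add("ROI Intensity", {"lo": 1.0, "hi": 2.0})
        return b.graph  # skip validation: the source file need not exist

    def test_save_load_round_trip_is_exact(self, registry, tmp_path):
        g = self._graph(registry, tmp_path)
        path = tmp_path / "wf.json"
        save_workflow(g, path)
        g2 = load_workflow(path, registry)
        assert g2.nodes == g.nodes
        assert sorted(g2.edges) == sorted(g.edges)

    def test_save_load_save_is_byte_identical(self, registry, tmp_path):
        g = self._graph(registry, tmp_path)
        p1, p2 = tmp_path / "a.json", tmp_path / "b.json"
        save_workflow(g, p1)
        save_workflow(load_workflow(p1, registry), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_hand_edited_param_is_honoured(self, registry, tmp_path):
        g = self._graph(registry, tmp_path)
        path = tmp_path / "wf.json"
        save_workflow(g, path)
        text = path.read_text().replace('"lo": 1.0', '"lo": 2.5')
        path.write_text(text)
        g2 = load_workflow(path, registry)
        assert g2.nodes["ROI Intensity_1"][1]["lo"] == 2.5

    def test_unknown_node_type_on_load_lists_missing(self, registry, tmp_path):
        path = tmp_path / "wf.json"
        path.write_text(json.dumps({"version": 1, "nodes": [
            {"id": "x", "type": "Nonexistent", "params": {}}], "edges": []}))
        with pytest.raises(GraphValidationError, match="Nonexistent"):
            load_workflow(path, registry)

    def test_invalid_json_reports_line(self, registry, tmp_path):
        path = tmp_path / "wf.json"
        path.write_text('{"version": 1,\n "nodes": [}')
        with pytest.raises(GraphValidationError, match="line 2"):
            load_workflow(path, registry)


# -- randomized DAG property (execution-count invariant) ----------------------

@pytest.mark.parametrize("seed", range(5))
def test_random_dags_execute_each_node_once_per_frame(seed):
    """On random DAGs (<=12 nodes) and streams (<=50 frames) every node runs
    exactly n_frames times, never before its inputs."""
    rng = np.random.default_rng(seed)
    n_nodes = int(rng.integers(2, 12))
    n_frames = int(rng.integers(0, 51))
    reg = NodeRegistry()
    log: list = []
    reg.register(array_source_type(scalar_frames(range(n_frames))))
    reg.register(record_node_type(log))
    b = WorkflowBuilder(reg)
    ids = [b.add("Test Source")]
    for k in range(n_nodes):
        n_in = int(rng.integers(1, min(4, len(ids)) + 1))
        parents = list(rng.choice(ids, size=n_in, replace=False))
        ids.append(b.add("Record", node_id=f"N{k}", inputs=parents))
    graph = b.build()
    run = WorkflowRun(graph, reg)
    results = list(run)
    assert len(results) == n_frames
    assert all(c == n_frames for c in run.execution_counts.values())
    for frame_idx in range(n_frames):
        order = [nid for nid, fi in log if fi == frame_idx]
        pos = {nid: i for i, nid in enumerate(order)}
        for src, dst, _ in graph.edges:
            if src in pos and dst in pos:
                assert pos[src] < pos[dst]


# -- chunked sink ------------------------------------------------------------

class TestChunkedSink:
    def _run_store(self, tmp_path, chunk_size, n_frames=25, fmt="hdf5"):
        from saxsflow.engine import run_workflow

        reg = NodeRegistry()
        log: list = []
        reg.register(array_source_type(scalar_frames(range(n_frames))))
        reg.register(record_node_type(log))
        b = WorkflowBuilder(reg)
        b.add("Test Source")
        b.add("Record", node_id="A")
        tmp_path.mkdir(parents=True, exist_ok=True)
        name = f"out_{chunk_size}" + (".h5" if fmt == "hdf5" else "")
        out = tmp_path / name
        run_workflow(b.build(), reg, output_path=out, output_format=fmt,
                     chunk_size=chunk_size)
        return out

    @pytest.mark.parametrize("fmt", ["hdf5", "txt"])
    def test_chunk_size_invisible_in_final_contents(self, tmp_path, fmt):
        from saxsflow.sources import read_results

        outs = [self._run_store(tmp_path, cs, fmt=fmt) for cs in (1, 7, 26)]
        ref = read_results(outs[0], fmt=fmt)
        assert set(ref) and all(v.shape[0] == 25 for v in ref.values())
        for other in outs[1:]:
            got = read_results(other, fmt=fmt)
            assert set(got) == set(ref)
            for k in ref:
                np.testing.assert_array_equal(got[k], ref[k])

    def test_zero_frames_still_persists_parameters(self, tmp_path):
        import h5py

        reg = NodeRegistry()
        reg.register(array_source_type([]))
        reg.register(record_node_type([]))
        b = WorkflowBuilder(reg)
        b.add("Test Source", {"n": 0})
        b.add("Record", node_id="A")
        out = tmp_path / "empty.h5"
        saxsflow.engine.run_workflow(b.build(), reg, output_path=out)
        with h5py.File(out) as h5:
            params = json.loads(h5["parameters"][()])
            assert "A" in params
            assert "results" not in h5 or len(h5["results"]) == 0

    def test_two_runs_produce_identical_outputs(self, tmp_path):
        """No hidden randomness: repeated runs persist identical bytes of data."""
        from saxsflow.sources import read_results

        a = self._run_store(tmp_path / "r1", 10)
        b = self._run_store(tmp_path / "r2", 10)
        ra, rb = read_results(a), read_results(b)
        assert set(ra) == set(rb)
        for k in ra:
            np.testing.assert_array_equal(ra[k], rb[k])
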