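"""Workflow engine: typed nodes, DAG construction/validation, streaming execution.

A workflow is a directed acyclic graph of typed processing nodes.  One node
is the designated *data source*; it turns a file stack or a live stream
into frames.  Every other node consumes the :class:`ResultBundle` outputs
of its input nodes and produces one bundle per frame.  Execution is a
single-threaded per-frame pipeline: node initialisation (calibration files,
masks, ...) happens exactly once before the first frame, then each frame
flows through the graph in topological order, so for a stream of n frames
every node runs exactly n times and never before its inputs.

Nodes that accumulate across frames (sinogram assembly, reconstruction,
storage) additionally implement a *finalize* step that runs once after the
stream ends, again in topological order.

Workflows persist as human-editable JSON with the fixed schema
``{"version": 1, "nodes": [{"id", "type", "params"}], "edges":
[[src, dst, slot]]}``; save -> load -> save is byte-identical.
"""

from __future__ import annotations

import importlib.util
import json
import logging
import sys
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Callable, Iterator, Optional

logger = logging.getLogger(__name__)

__all__ = [
    "ParamSpec",
    "NodeType",
    "ResultBundle",
    "WorkflowGraph",
    "WorkflowBuilder",
    "NodeRegistry",
    "GraphValidationError",
    "RegistrationError",
    "NodeExecutionError",
    "WorkflowRun",
    "execute_stream",
    "run_workflow",
    "save_workflow",
    "load_workflow",
    "graph_to_dict",
    "graph_from_dict",
]

PARAM_TYPES = ("integer", "float", "string", "tuple", "boolean", "enumeration", "io")
DATA_KINDS = ("frame", "curve", "cake", "scalar", "volume", "none")


class RegistrationError(RuntimeError):
    """Node-type registration conflict (duplicate display name)."""


class GraphValidationError(ValueError):
    """The workflow graph violates a structural or typing invariant."""


class NodeExecutionError(RuntimeError):
    def __init__(self, node_id: str, frame_index, cause: BaseException):
        super().__init__(f"node {node_id!r} failed on frame {frame_index}: {cause}")
        self.node_id = node_id
        self.frame_index = frame_index
        self.cause = cause


# -- parameter and node contracts -------------------------------------------

@dataclass(frozen=True)
class ParamSpec:
    """Declaration of one node parameter (name, type, default, tooltip)."""

    name: str
    ptype: str
    default: Any = None
    tip: str = ""
    choices: tuple = ()

    def __post_init__(self) -> None:
        if self.ptype not in PARAM_TYPES:
            raise ValueError(f"param {self.name!r}: unknown type {self.ptype!r}; "
                             f"expected one of {PARAM_TYPES}")
        if self.ptype == "enumeration":
            if not self.choices:
                raise ValueError(f"enumeration param {self.name!r} needs choices")
            if self.default not in self.choices:
                raise ValueError(f"enumeration param {self.name!r}: default "
                                 f"{self.default!r} not among choices {self.choices}")

    def check(self, value) -> Any:
        """Validate and coerce a value against this spec; returns the value."""
        p = self.ptype
        if value is None:
            return value
        if p == "integer":
            if isinstance(value, bool) or not isinstance(value, int):
                raise TypeError(f"param {self.name!r} expects an integer, "
                                f"got {value!r}")
        elif p == "float":
            if isinstance(value, bool) or not isinstance(value, (int, float)):
                raise TypeError(f"param {self.name!r} expects a float, got {value!r}")
            value = float(value)
        elif p == "string":
            if not isinstance(value, str):
                raise TypeError(f"param {self.name!r} expects a string, got {value!r}")
        elif p == "tuple":
            if not isinstance(value, (tuple, list)):
                raise TypeError(f"param {self.name!r} expects a tuple, got {value!r}")
            value = tuple(value)
        elif p == "boolean":
            if not isinstance(value, bool):
                raise TypeError(f"param {self.name!r} expects a boolean, got {value!r}")
        elif p == "enumeration":
            if value not in self.choices:
                raise TypeError(f"param {self.name!r}: {value!r} not among "
                                f"choices {self.choices}")
        elif p == "io":
            # an io parameter names a data source/sink binding
            if not isinstance(value, (str, dict)):
                raise TypeError(f"io param {self.name!r} expects a path string or "
                                f"binding mapping, got {value!r}")
        return value


@dataclass
class ResultBundle:
    """One node's per-frame output.

    ``data`` is the primary payload (array, Curve, scalar or None) and
    ``data_kind`` names its shape class.  ``plot_meta`` carries display
    metadata (legend, axis labels, title, line style) — the headless
    counterpart of a plot widget.  ``out_params`` holds named scalar/text
    values that are persisted and flow downstream.  ``context`` holds
    non-serializable objects shared along the graph (calibration, mask,
    fit results); the engine merges input contexts into each node's output.
    """

    data: Any = None
    data_kind: str = "none"
    plot_meta: dict = field(default_factory=dict)
    out_params: dict = field(default_factory=dict)
    context: dict = field(default_factory=dict)
    producer: str = ""

    def __post_init__(self) -> None:
        if self.data_kind not in DATA_KINDS:
            raise ValueError(f"unknown data_kind {self.data_kind!r}; "
                             f"expected one of {DATA_KINDS}")


@dataclass(frozen=True)
class NodeType:
    """The node contract: display name, tooltip, typed params, computation.

    ``run(state, inputs, params) -> ResultBundle`` executes once per frame;
    ``init(params, ctx) -> state`` once per run (ctx holds ``node_id`` and
    the full ``graph_params`` mapping); ``finalize(state, inputs, params)``
    once after the stream (inputs are the upstream finalize bundles, None
    where an input has no finalize output).  Source node types instead
    provide ``open_stream(params) -> iterator of Frame``.
    """

    function_text: str
    function_tip: str = ""
    params: tuple[ParamSpec, ...] = ()
    arity: tuple[int, int] = (1, 1)
    run: Optional[Callable] = None
    init: Optional[Callable] = None
    finalize: Optional[Callable] = None
    open_stream: Optional[Callable] = None
    requires_upstream: frozenset = frozenset()
    category: str = "general"

    def __post_init__(self) -> None:
        names = [p.name for p in self.params]
        if len(names) != len(set(names)):
            raise ValueError(f"node type {self.function_text!r}: duplicate "
                             "parameter names")

    @property
    def is_source(self) -> bool:
        return self.open_stream is not None

    def defaults(self) -> dict:
        return {p.name: p.default for p in self.params}

    def check_params(self, values: dict) -> dict:
        specs = {p.name: p for p in self.params}
        merged = self.defaults()
        for key, val in values.items():
            if key not in specs:
                raise TypeError(f"node type {self.function_text!r} has no "
                                f"parameter {key!r}")
            merged[key] = specs[key].check(val)
        return merged


# -- registry and plugin discovery -------------------------------------------

class NodeRegistry:
    """Mapping of ``function_text`` -> :class:`NodeType` with origin tracking."""

    def __init__(self) -> None:
        self._types: dict[str, NodeType] = {}
        self._origins: dict[str, str] = {}

    def register(self, node_type: NodeType, origin: str = "builtin") -> None:
        name = node_type.function_text
        if name in self._types:
            raise RegistrationError(
                f"duplicate node type {name!r}: already registered from "
                f"{self._origins[name]}, re-registered from {origin}")
        self._types[name] = node_type
        self._origins[name] = origin

    def get(self, name: str) -> NodeType:
        if name not in self._types:
            raise KeyError(f"unknown node type {name!r}; registered types: "
                           f"{sorted(self._types)}")
        return self._types[name]

    def __contains__(self, name) -> bool:
        return name in self._types

    def names(self) -> list[str]:
        return sorted(self._types)

    def __iter__(self):
        return iter(self._types.values())

    def discover_plugins(self, plugins_dir) -> list[str]:
        """Import ``*.py`` files from a directory and register the node
        types they expose (a module-level ``NODE_TYPES`` list, or any
        module attribute that is a :class:`NodeType`).

        Malformed plugin files are skipped with a logged warning; duplicate
        display names are hard errors naming both origins.  Returns the
        list of newly registered type names.
        """
        plugins_dir = Path(plugins_dir)
        if not plugins_dir.is_dir():
            raise FileNotFoundError(f"plugins directory {plugins_dir} does not exist")
        added = []
        for path in sorted(plugins_dir.glob("*.py")):
            modname = f"saxsflow_plugin_{path.stem}"
            try:
                spec = importlib.util.spec_from_file_location(modname, path)
                module = importlib.util.module_from_spec(spec)
                sys.modules[modname] = module
                spec.loader.exec_module(module)
            except Exception as exc:
                logger.warning("skipping malformed plugin %s: %s", path, exc)
                continue
            candidates = getattr(module, "NODE_TYPES", None)
            if candidates is None:
                candidates = [v for v in vars(module).values()
                              if isinstance(v, NodeType)]
            for nt in candidates:
                if not isinstance(nt, NodeType):
                    logger.warning("plugin %s: NODE_TYPES entry %r is not a "
                                   "NodeType; skipped", path, nt)
                    continue
                self.register(nt, origin=str(path))
                added.append(nt.function_text)
        return added


def register_node_type(plugins_dir=None) -> NodeRegistry:
    """Build a registry holding all built-in node types, plus any plugins
    discovered in ``plugins_dir``."""
    from .nodes import builtin_registry

    registry = builtin_registry()
    if plugins_dir is not None:
        registry.discover_plugins(plugins_dir)
    return registry


# -- workflow graph ----------------------------------------------------------

@dataclass
class WorkflowGraph:
    """Typed nodes plus directed data-flow edges; validated acyclic."""

    nodes: dict[str, tuple[str, dict]] = field(default_factory=dict)
    edges: list[tuple[str, str, int]] = field(default_factory=list)
    source_id: Optional[str] = None

    def inputs_of(self, node_id: str) -> list[str]:
        incoming = sorted((slot, src) for src, dst, slot in self.edges
                          if dst == node_id)
        return [src for _, src in incoming]

    def topological_order(self) -> list[str]:
        indeg = {nid: 0 for nid in self.nodes}
        for _, dst, _ in self.edges:
            indeg[dst] += 1
        ready = sorted(nid for nid, d in indeg.items() if d == 0)
        order = []
        while ready:
            nid = ready.pop(0)
            order.append(nid)
            for src, dst, _ in self.edges:
                if src == nid:
                    indeg[dst] -= 1
                    if indeg[dst] == 0:
                        ready.append(dst)
            ready.sort()
        if len(order) != len(self.nodes):
            cycle = sorted(set(self.nodes) - set(order))
            raise GraphValidationError(f"workflow contains a cycle through "
                                       f"nodes {cycle}")
        return order

    def ancestors(self, node_id: str) -> set[str]:
        parents: dict[str, set[str]] = {nid: set() for nid in self.nodes}
        for src, dst, _ in self.edges:
            parents[dst].add(src)
        seen: set[str] = set()
        stack = list(parents[node_id])
        while stack:
            cur = stack.pop()
            if cur not in seen:
                seen.add(cur)
                stack.extend(parents[cur])
        return seen

    def validate(self, registry: NodeRegistry) -> None:
        """Check every structural invariant; raises GraphValidationError."""
        if not self.nodes:
            raise GraphValidationError("workflow has no nodes")
        for src, dst, slot in self.edges:
            for nid in (src, dst):
                if nid not in self.nodes:
                    raise GraphValidationError(f"edge references unknown node "
                                               f"{nid!r}")
            if slot < 0:
                raise GraphValidationError("edge slot must be >= 0")
        missing = [tname for tname, _ in self.nodes.values()
                   if tname not in registry]
        if missing:
            raise GraphValidationError(f"unknown node types: {sorted(set(missing))}")
        self.topological_order()  # raises on cycles
        sources = [nid for nid, (tname, _) in self.nodes.items()
                   if registry.get(tname).is_source]
        if len(sources) != 1:
            raise GraphValidationError(
                f"workflow needs exactly one data-source node, found {sources}")
        if self.source_id is None:
            self.source_id = sources[0]
        elif self.source_id != sources[0]:
            raise GraphValidationError(
                f"source_id {self.source_id!r} is not the source node "
                f"{sources[0]!r}")
        for nid, (tname, params) in self.nodes.items():
            ntype = registry.get(tname)
            n_in = len(self.inputs_of(nid))
            if ntype.is_source:
                if n_in != 0:
                    raise GraphValidationError(f"source node {nid!r} must have "
                                               "no inputs")
            else:
                lo, hi = ntype.arity
                if n_in < max(lo, 1) or n_in > hi:
                    raise GraphValidationError(
                        f"node {nid!r} ({tname}) has {n_in} inputs; expected "
                        f"between {max(lo, 1)} and {hi}")
            try:
                ntype.check_params(params)
            except TypeError as exc:
                raise GraphValidationError(f"node {nid!r}: {exc}") from exc
            if ntype.requires_upstream:
                have = {self.nodes[a][0] for a in self.ancestors(nid)}
                absent = set(ntype.requires_upstream) - have
                if absent:
                    raise GraphValidationError(
                        f"node {nid!r} ({tname}) requires upstream node type(s) "
                        f"{sorted(absent)} which are missing from its input chain")


class WorkflowBuilder:
    """Incremental graph construction with list-style auto-wiring.

    ``add`` appends a node; without explicit ``inputs`` it is wired to the
    previously added node's output, so a plain sequence of ``add`` calls
    yields a chain.  Explicit ``inputs`` (a list of node ids) override the
    auto-wiring and create tree/diamond topologies.
    """

    def __init__(self, registry: NodeRegistry):
        self.registry = registry
        self.graph = WorkflowGraph()
        self._last: Optional[str] = None
        self._counter: dict[str, int] = {}

    def add(self, type_name: str, params: Optional[dict] = None,
            node_id: Optional[str] = None,
            inputs: Optional[list[str]] = None) -> str:
        ntype = self.registry.get(type_name)  # raises for unknown types
        if node_id is None:
            k = self._counter.get(type_name, 0) + 1
            self._counter[type_name] = k
            node_id = f"{type_name}_{k}"
        if node_id in self.graph.nodes:
            raise GraphValidationError(f"duplicate node id {node_id!r}")
        self.graph.nodes[node_id] = (type_name, ntype.check_params(params or {}))
        if ntype.is_source:
            if self.graph.source_id is not None:
                raise GraphValidationError("workflow already has a data source")
            self.graph.source_id = node_id
        else:
            if inputs is None:
                if self._last is None:
                    raise GraphValidationError(
                        f"cannot auto-wire node {node_id!r}: no previous node")
                inputs = [self._last]
            for slot, src in enumerate(inputs):
                if src not in self.graph.nodes:
                    raise GraphValidationError(f"unknown input node {src!r}")
                self.graph.edges.append((src, node_id, slot))
        self._last = node_id
        return node_id

    def build(self) -> WorkflowGraph:
        self.graph.validate(self.registry)
        return self.graph


def build_graph(spec: dict, registry: NodeRegistry) -> WorkflowGraph:
    """Construct and validate a graph from the JSON-schema dict."""
    graph = graph_from_dict(spec)
    graph.validate(registry)
    return graph


# -- persistence -------------------------------------------------------------

SCHEMA_VERSION = 1


def graph_to_dict(graph: WorkflowGraph) -> dict:
    return {
        "version": SCHEMA_VERSION,
        "nodes": [{"id": nid, "type": tname, "params": dict(sorted(params.items()))}
                  for nid, (tname, params) in sorted(graph.nodes.items())],
        "edges": sorted([list(e) for e in graph.edges]),
    }


def graph_from_dict(spec: dict) -> WorkflowGraph:
    if not isinstance(spec, dict) or "nodes" not in spec:
        raise GraphValidationError("workflow config must be a mapping with a "
                                   "'nodes' list")
    if spec.get("version", SCHEMA_VERSION) != SCHEMA_VERSION:
        raise GraphValidationError(f"unsupported workflow schema version "
                                   f"{spec.get('version')!r}")
    graph = WorkflowGraph()
    for i, node in enumerate(spec["nodes"]):
        for key in ("id", "type"):
            if key not in node:
                raise GraphValidationError(f"nodes[{i}]: missing key {key!r}")
        if node["id"] in graph.nodes:
            raise GraphValidationError(f"nodes[{i}]: duplicate id {node['id']!r}")
        params = node.get("params", {})
        params = {k: tuple(v) if isinstance(v, list) else v
                  for k, v in params.items()}
        graph.nodes[node["id"]] = (node["type"], params)
    for i, edge in enumerate(spec.get("edges", [])):
        if not (isinstance(edge, (list, tuple)) and len(edge) in (2, 3)):
            raise GraphValidationError(f"edges[{i}]: expected [src, dst, slot]")
        src, dst = edge[0], edge[1]
        slot = edge[2] if len(edge) == 3 else 0
        graph.edges.append((src, dst, int(slot)))
    return graph


def save_workflow(graph: WorkflowGraph, path) -> None:
    """Serialize a graph to editable JSON text (canonical key order)."""
    text = json.dumps(graph_to_dict(graph), indent=2, sort_keys=True)
    Path(path).write_text(text + "\n")


def load_workflow(path, registry: NodeRegistry) -> WorkflowGraph:
    """Parse and validate a workflow config file."""
    try:
        spec = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise GraphValidationError(
            f"workflow file {path}: invalid JSON at line {exc.lineno}, "
            f"column {exc.colno}: {exc.msg}") from exc
    missing = [n["type"] for n in spec.get("nodes", [])
               if isinstance(n, dict) and n.get("type") not in registry]
    if missing:
        raise GraphValidationError(
            f"workflow file {path}: unknown node types {sorted(set(missing))}")
    return build_graph(spec, registry)


# -- execution ---------------------------------------------------------------

class WorkflowRun:
    """Single streaming execution of a validated workflow.

    Iterating yields one ``{node_id: ResultBundle}`` mapping per frame.
    After exhaustion, :meth:`finalize` runs the end-of-stream phase and
    returns the final bundles.  ``on_error='halt'`` re-raises a node
    failure as :class:`NodeExecutionError`; ``'skip'`` logs it and drops
    the remainder of that frame.
    """

    def __init__(self, graph: WorkflowGraph, registry: NodeRegistry,
                 on_error: str = "halt"):
        if on_error not in ("halt", "skip"):
            raise ValueError("on_error must be 'halt' or 'skip'")
        graph.validate(registry)
        self.graph = graph
        self.registry = registry
        self.on_error = on_error
        self.execution_counts: dict[str, int] = {nid: 0 for nid in graph.nodes}
        self.n_frames = 0
        self._order = [nid for nid in graph.topological_order()
                       if nid != graph.source_id]
        self._states: dict[str, Any] = {}
        self._initialized = False
        self._final_bundles: Optional[dict] = None

    # initialization phase: runs exactly once, before the first frame
    def initialize(self) -> None:
        if self._initialized:
            return
        graph_params = {nid: {"type": tname, "params": dict(params)}
                        for nid, (tname, params) in self.graph.nodes.items()}
        for nid, (tname, params) in self.graph.nodes.items():
            ntype = self.registry.get(tname)
            full = ntype.check_params(params)
            if ntype.init is not None:
                ctx = {"node_id": nid, "graph_params": graph_params}
                logger.info("init node %s (%s)", nid, tname)
                self._states[nid] = ntype.init(full, ctx)
            else:
                self._states[nid] = {}
        self._initialized = True

    def __iter__(self) -> Iterator[dict]:
        self.initialize()
        src_type, src_params = self.graph.nodes[self.graph.source_id]
        ntype = self.registry.get(src_type)
        stream = ntype.open_stream(ntype.check_params(src_params))
        for frame in stream:
            self.n_frames += 1
            bundles: dict[str, ResultBundle] = {}
            bundles[self.graph.source_id] = ResultBundle(
                data=frame, data_kind="frame",
                out_params={"frame_index": frame.index,
                            **{f"coord_{k}": v for k, v in frame.coords.items()}},
                context={"frame": frame, "coords": dict(frame.coords)},
                producer=self.graph.source_id)
            self.execution_counts[self.graph.source_id] += 1
            ok = True
            for nid in self._order:
                tname, params = self.graph.nodes[nid]
                ntype = self.registry.get(tname)
                inputs = [bundles[src] for src in self.graph.inputs_of(nid)]
                merged_ctx = {}
                for b in inputs:
                    merged_ctx.update(b.context)
                try:
                    out = ntype.run(self._states[nid], inputs,
                                    ntype.check_params(params))
                except Exception as exc:
                    err = NodeExecutionError(nid, frame.index, exc)
                    if self.on_error == "halt":
                        raise err from exc
                    logger.warning("%s; skipping frame", err)
                    ok = False
                    break
                out.context = {**merged_ctx, **out.context}
                out.producer = nid
                bundles[nid] = out
                self.execution_counts[nid] += 1
            if ok:
                yield bundles

    def finalize(self) -> dict[str, ResultBundle]:
        """Run the end-of-stream phase; returns node_id -> final bundle."""
        if self._final_bundles is not None:
            return self._final_bundles
        self.initialize()   # an empty stream still initialises and finalises
        finals: dict[str, ResultBundle] = {}
        for nid in self.graph.topological_order():
            tname, params = self.graph.nodes[nid]
            ntype = self.registry.get(tname)
            if ntype.finalize is None:
                continue
            inputs = [finals.get(src) for src in self.graph.inputs_of(nid)]
            out = ntype.finalize(self._states[nid], inputs,
                                 ntype.check_params(params))
            if out is not None:
                out.producer = nid
                finals[nid] = out
        self._final_bundles = finals
        return finals


def execute_stream(graph: WorkflowGraph, registry: NodeRegistry,
                   on_error: str = "halt") -> WorkflowRun:
    """Create a :class:`WorkflowRun` (iterate it to process frames)."""
    return WorkflowRun(graph, registry, on_error=on_error)


def run_workflow(graph: WorkflowGraph, registry: NodeRegistry,
                 output_path=None, output_format: str = "hdf5",
                 chunk_size: int = 100, on_error: str = "halt",
                 store_nodes: Optional[list[str]] = None) -> dict:
    """Execute a workflow end to end with chunked result storage.

    Per-frame outputs of the selected nodes (default: every node that
    produces data) are buffered and flushed to ``output_path`` every
    ``chunk_size`` frames; node initialization parameters, per-frame
    out_params and end-of-stream outputs (sinograms, reconstructions) are
    stored alongside.  Returns a summary dict with ``n_frames``,
    ``execution_counts`` and the final bundles.
    """
    from .sources import ResultWriter

    run = WorkflowRun(graph, registry, on_error=on_error)
    writer = None
    if output_path is not None:
        writer = ResultWriter(output_path, fmt=output_format,
                              chunk_size=chunk_size)
        writer.write_params({nid: {"type": tname, "params": dict(params)}
                             for nid, (tname, params) in graph.nodes.items()})
    try:
        for bundles in run:
            if writer is not None:
                record = {}
                for nid, b in bundles.items():
                    if store_nodes is not None and nid not in store_nodes:
                        continue
                    value = b.data if b.data_kind in ("curve", "scalar", "cake") \
                        else None
                    if value is not None or b.out_params:
                        record[nid] = (value, b.out_params)
                if record:
                    writer.append(record)
        finals = run.finalize()
        if writer is not None:
            for nid, b in finals.items():
                if b.data is not None:
                    writer.write_final(nid, b.data)
    finally:
        if writer is not None:
            writer.close()
    return {"n_frames": run.n_frames,
            "execution_counts": dict(run.execution_counts),
            "finals": run.finalize()}
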