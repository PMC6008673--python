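"""Typed dataflow DAG: validation, dirty propagation, topological execution.

Nodes are instances of registered *node kinds* (see :mod:`voxelflow.nodes`).
Ports carry a datatype (``volume``, ``image2d``, ``scalar``, ``buffer``) and
only type-compatible out->in connections are allowed; attempts to close a
cycle are rejected at connect time, so the edge set is acyclic at all times.

Changing a parameter (or reconnecting an input) marks the node and everything
reachable downstream as *dirty*; :meth:`Graph.execute` then evaluates exactly
the dirty closure in a deterministic topological order, recording per-node
wall-clock timing.  A node failure is contained to its downstream cone: the
failed node and its descendants stay dirty, unrelated subgraphs still run.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Any, Callable

__all__ = [
    "PortSpec",
    "NodeKind",
    "Node",
    "Edge",
    "Graph",
    "GraphError",
    "TypeMismatchError",
    "CycleError",
    "ExecutionReport",
    "NodeResult",
    "NODE_DATATYPES",
]

NODE_DATATYPES = ("volume", "image2d", "scalar", "buffer")


class GraphError(ValueError):
    """Base class for graph construction/execution errors."""


class TypeMismatchError(GraphError):
    pass


class CycleError(GraphError):
    pass


@dataclass(frozen=True)
class PortSpec:
    """Declared port of a node kind; ``datatype`` is the connector "color"."""

    name: str
    datatype: str
    required: bool = True

    def __post_init__(self):
        if self.datatype not in NODE_DATATYPES:
            raise GraphError(f"unknown port datatype {self.datatype!r}")


@dataclass(frozen=True)
class NodeKind:
    """A registered node type: ports, parameter defaults and the compute function.

    ``fn(inputs, params)`` receives dicts keyed by port/param name and returns
    a dict keyed by out-port name.  ``radius`` declares the neighborhood
    radius for tiled execution (None = not tileable / pass-based).
    """

    name: str
    in_ports: tuple[PortSpec, ...]
    out_ports: tuple[PortSpec, ...]
    param_defaults: dict[str, Any]
    fn: Callable[[dict, dict], dict]
    radius: int | None = 0

    def in_port(self, name: str) -> PortSpec:
        for p in self.in_ports:
            if p.name == name:
                return p
        raise GraphError(f"node kind {self.name!r} has no in-port {name!r}")

    def out_port(self, name: str) -> PortSpec:
        for p in self.out_ports:
            if p.name == name:
                return p
        raise GraphError(f"node kind {self.name!r} has no out-port {name!r}")


@dataclass
class Node:
    id: str
    kind: NodeKind
    params: dict[str, Any]
    dirty: bool = True
    last_compute_ms: float | None = None
    outputs: dict[str, Any] = field(default_factory=dict)
    error: str | None = None


@dataclass(frozen=True)
class Edge:
    src: tuple[str, str]  # (node id, out-port name)
    dst: tuple[str, str]  # (node id, in-port name)


@dataclass
class NodeResult:
    node_id: str
    status: str  # "ok" | "error" | "skipped"
    duration_ms: float = 0.0
    message: str = ""


@dataclass
class ExecutionReport:
    order: list[str]                 # node ids evaluated, in execution order
    results: list[NodeResult]

    @property
    def errors(self) -> list[NodeResult]:
        return [r for r in self.results if r.status == "error"]


class Graph:
    """Mutable typed dataflow DAG."""

    def __init__(self) -> None:
        self.nodes: dict[str, Node] = {}
        self.edges: list[Edge] = []

    # -- construction -------------------------------------------------------

    def add_node(self, node_id: str, kind: NodeKind, **params) -> Node:
        if node_id in self.nodes:
            raise GraphError(f"duplicate node id {node_id!r}")
        merged = dict(kind.param_defaults)
        for k, v in params.items():
            if k not in merged:
                raise GraphError(
                    f"unknown parameter {k!r} for node kind {kind.name!r}; "
                    f"valid: {sorted(merged)}"
                )
            merged[k] = v
        node = Node(id=node_id, kind=kind, params=merged)
        self.nodes[node_id] = node
        return node

    def _node(self, node_id: str) -> Node:
        if node_id not in self.nodes:
            raise GraphError(f"unknown node {node_id!r}")
        return self.nodes[node_id]

    def connect(self, src: tuple[str, str], dst: tuple[str, str]) -> Edge:
        """Add an edge src=(node, out-port) -> dst=(node, in-port)."""
        src_node, dst_node = self._node(src[0]), self._node(dst[0])
        sp = src_node.kind.out_port(src[1])
        dp = dst_node.kind.in_port(dst[1])
        if sp.datatype != dp.datatype:
            raise TypeMismatchError(
                f"incompatible connector types: {src[0]}.{src[1]} is "
                f"{sp.datatype!r} but {dst[0]}.{dst[1]} is {dp.datatype!r}"
            )
        for e in self.edges:
            if e.dst == tuple(dst):
                raise GraphError(
                    f"input already connected: {dst[0]}.{dst[1]} "
                    f"(from {e.src[0]}.{e.src[1]})"
                )
        path = self._find_path(dst[0], src[0])
        if path is not None:
            raise CycleError(
                "cycle rejected: connecting "
                f"{src[0]} -> {dst[0]} would close the path "
                + " -> ".join(path + [src[0]])
            )
        edge = Edge(tuple(src), tuple(dst))
        self.edges.append(edge)
        self._mark_dirty(dst[0])
        return edge

    def disconnect(self, dst: tuple[str, str]) -> None:
        for e in self.edges:
            if e.dst == tuple(dst):
                self.edges.remove(e)
                self._mark_dirty(dst[0])
                return
        raise GraphError(f"no edge into {dst[0]}.{dst[1]}")

    # -- dirty propagation --------------------------------------------------

    def _successors(self, node_id: str) -> list[str]:
        return [e.dst[0] for e in self.edges if e.src[0] == node_id]

    def _find_path(self, start: str, goal: str) -> list[str] | None:
        """DFS path start -> goal along edges, or None."""
        stack = [(start, [start])]
        seen = set()
        while stack:
            cur, path = stack.pop()
            if cur == goal:
                return path
            if cur in seen:
                continue
            seen.add(cur)
            for nxt in self._successors(cur):
                stack.append((nxt, path + [nxt]))
        return None

    def downstream_closure(self, node_id: str) -> set[str]:
        """``node_id`` plus every node reachable from it."""
        closure = set()
        stack = [node_id]
        while stack:
            cur = stack.pop()
            if cur in closure:
                continue
            closure.add(cur)
            stack.extend(self._successors(cur))
        return closure

    def _mark_dirty(self, node_id: str) -> set[str]:
        closure = self.downstream_closure(node_id)
        for nid in closure:
            self.nodes[nid].dirty = True
        return closure

    def set_param(self, node_id: str, name: str, value) -> set[str]:
        """Set a parameter and mark the downstream closure dirty; returns it."""
        node = self._node(node_id)
        if name not in node.params:
            raise GraphError(
                f"unknown parameter {name!r} on node {node_id!r}; "
                f"valid: {sorted(node.params)}"
            )
        node.params[name] = value
        return self._mark_dirty(node_id)

    # -- execution ----------------------------------------------------------

    def topological_order(self) -> list[str]:
        """Kahn's algorithm; ties broken by node insertion order."""
        indeg = {nid: 0 for nid in self.nodes}
        for e in self.edges:
            indeg[e.dst[0]] += 1
        order_index = {nid: i for i, nid in enumerate(self.nodes)}
        ready = sorted([n for n, d in indeg.items() if d == 0],
                       key=order_index.__getitem__)
        out: list[str] = []
        while ready:
            cur = ready.pop(0)
            out.append(cur)
            newly = []
            for nxt in self._successors(cur):
                indeg[nxt] -= 1
                if indeg[nxt] == 0:
                    newly.append(nxt)
            ready = sorted(ready + newly, key=order_index.__getitem__)
        if len(out) != len(self.nodes):  # pragma: no cover - acyclic by construction
            raise CycleError("graph contains a cycle")
        return out

    def _gather_inputs(self, node: Node) -> tuple[dict, list[str]]:
        inputs: dict[str, Any] = {}
        missing: list[str] = []
        incoming = {e.dst[1]: e for e in self.edges if e.dst[0] == node.id}
        for spec in node.kind.in_ports:
            if spec.name in incoming:
                e = incoming[spec.name]
                inputs[spec.name] = self.nodes[e.src[0]].outputs.get(e.src[1])
            elif spec.required:
                missing.append(spec.name)
            else:
                inputs[spec.name] = None
        return inputs, missing

    def execute(self) -> ExecutionReport:
        """Evaluate every dirty node exactly once in topological order.

        Nodes downstream of a failed or unsatisfied node are skipped and left
        dirty; everything else runs.  Timing is wall clock, informational.
        """
        order = self.topological_order()
        failed: set[str] = set()
        evaluated: list[str] = []
        results: list[NodeResult] = []
        for nid in order:
            node = self.nodes[nid]
            if not node.dirty:
                continue
            upstream_failed = any(
                e.src[0] in failed for e in self.edges if e.dst[0] == nid
            )
            if upstream_failed:
                failed.add(nid)
                results.append(NodeResult(nid, "skipped",
                                          message="upstream node failed"))
                continue
            inputs, missing = self._gather_inputs(node)
            if missing:
                failed.add(nid)
                node.error = f"required input(s) not connected: {', '.join(missing)}"
                results.append(NodeResult(nid, "error", message=node.error))
                continue
            t0 = time.perf_counter()
            try:
                outputs = node.kind.fn(inputs, node.params)
            except Exception as exc:
                failed.add(nid)
                node.error = f"{type(exc).__name__}: {exc}"
                results.append(NodeResult(nid, "error", message=node.error))
                continue
            dt = (time.perf_counter() - t0) * 1000.0
            node.outputs = outputs or {}
            node.last_compute_ms = dt
            node.dirty = False
            node.error = None
            evaluated.append(nid)
            results.append(NodeResult(nid, "ok", duration_ms=dt))
        return ExecutionReport(order=evaluated, results=results)
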