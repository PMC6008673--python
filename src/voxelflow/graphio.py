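"""Load and validate graph description files (YAML).

Schema::

    nodes:
      - id: src            # unique identifier
        kind: head_phantom # registered node kind
        params:            # optional, merged over the kind's defaults
          dims: [64, 64, 64]
    edges:
      - src.out -> seg.in  # "<node>.<out-port> -> <node>.<in-port>"

Validation happens before any execution: unknown kinds, duplicate ids,
malformed edges, type-incompatible connections and cycles are all reported
with the offending node/edge identity.
"""

from __future__ import annotations

import re
from pathlib import Path

import yaml

from .graph import Graph, GraphError
from .nodes import get_kind

__all__ = ["load_graph", "parse_graph_dict", "GraphFileError"]


class GraphFileError(GraphError):
    pass


_EDGE_RE = re.compile(
    r"^\s*([\w-]+)\.([\w-]+)\s*->\s*([\w-]+)\.([\w-]+)\s*$"
)


def parse_graph_dict(doc: dict) -> Graph:
    if not isinstance(doc, dict) or "nodes" not in doc:
        raise GraphFileError("graph document must be a mapping with a 'nodes' list")
    g = Graph()
    for entry in doc.get("nodes") or []:
        if "id" not in entry or "kind" not in entry:
            raise GraphFileError(f"node entry {entry!r} needs 'id' and 'kind'")
        kind = get_kind(str(entry["kind"]))
        params = entry.get("params") or {}
        # yaml lists become tuples where the default is a tuple
        coerced = {}
        for k, v in params.items():
            default = kind.param_defaults.get(k)
            coerced[k] = tuple(v) if isinstance(default, tuple) and isinstance(v, list) else v
        try:
            g.add_node(str(entry["id"]), kind, **coerced)
        except GraphError as e:
            raise GraphFileError(f"node {entry['id']!r}: {e}") from None
    for spec in doc.get("edges") or []:
        m = _EDGE_RE.match(str(spec))
        if not m:
            raise GraphFileError(
                f"malformed edge {spec!r}; expected 'node.port -> node.port'"
            )
        try:
            g.connect((m.group(1), m.group(2)), (m.group(3), m.group(4)))
        except GraphError as e:
            raise GraphFileError(f"edge {spec!r}: {e}") from None
    return g


def load_graph(path) -> Graph:
    text = Path(path).read_text()
    doc = yaml.safe_load(text)
    return parse_graph_dict(doc)
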