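"""Shipped example graphs, as data files next to this module."""

from __future__ import annotations

from pathlib import Path

__all__ = ["graph_path", "available_graphs"]

_HERE = Path(__file__).parent


def graph_path(name: str) -> Path:
    """Absolute path of a shipped graph file, e.g. ``segmentation``."""
    p = _HERE / f"{name}.yaml"
    if not p.exists():
        raise FileNotFoundError(
            f"no shipped graph {name!r}; available: {available_graphs()}"
        )
    return p


def available_graphs() -> list[str]:
    return sorted(p.stem for p in _HERE.glob("*.yaml"))
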