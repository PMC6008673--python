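"""Registry of built-in node kinds.

Every kernel, the renderer, the live-code nodes, the phantom generators and
the file source/sink nodes are registered here as graph node kinds with
declared ports, parameter defaults and (where meaningful) a neighborhood
radius for tiled execution.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

from . import kernels, livecode, phantoms, render, vio
from .graph import GraphError, NodeKind, PortSpec
from .volume import Volume, convert_type

__all__ = ["REGISTRY", "get_kind", "register_kind", "kind_names"]

REGISTRY: dict[str, NodeKind] = {}


def register_kind(kind: NodeKind) -> None:
    if kind.name in REGISTRY:
        raise GraphError(f"node kind {kind.name!r} already registered")
    REGISTRY[kind.name] = kind


def get_kind(name: str) -> NodeKind:
    if name not in REGISTRY:
        raise GraphError(
            f"unknown node kind {name!r}; registered kinds: {sorted(REGISTRY)}"
        )
    return REGISTRY[name]


def kind_names() -> list[str]:
    return sorted(REGISTRY)


def _vin(name="in"):
    return PortSpec(name, "volume")


def _vout(name="out"):
    return PortSpec(name, "volume")


def _simple(name: str, fn: Callable, params: dict, radius: int | None = 0,
            out_datatype: str = "volume") -> None:
    """Register a one-volume-in / one-volume-out kernel node."""

    def node_fn(inputs, p):
        return {"out": fn(inputs["in"], **p)}

    register_kind(NodeKind(
        name=name,
        in_ports=(_vin(),),
        out_ports=(PortSpec("out", out_datatype),),
        param_defaults=dict(params),
        fn=node_fn,
        radius=radius,
    ))


# -- kernels ----------------------------------------------------------------

_simple("distance_transform", kernels.distance_transform_3d,
        {"t": 0.5}, radius=None)  # pass-based: not tileable along pass axes
_simple("median_filter", kernels.median_filter_3d, {}, radius=1)
_simple("rescale_intensity", kernels.rescale_intensity, {}, radius=None)  # global
_simple("threshold", kernels.threshold, {"t": 0.5}, radius=0)
_simple("gaussian_blur", kernels.gaussian_blur, {"sigma": 1.0}, radius=None)
_simple("derivative", kernels.derivative, {}, radius=1)
_simple("surface_normals", kernels.surface_normals, {}, radius=1)
_simple("curvature", kernels.curvature, {}, radius=2)
_simple("region_filter", kernels.region_filter, {"op": "avg", "radius": 1},
        radius=None)  # radius is a parameter; declared per-instance
_simple("convert_type", lambda v, dtype="f32": convert_type(v, dtype),
        {"dtype": "f32"}, radius=0)


def _elementwise_fn(inputs, p):
    b = inputs.get("b")
    if b is None:
        b = p["scalar"]
    return {"out": kernels.elementwise(inputs["a"], b, p["op"])}


register_kind(NodeKind(
    name="elementwise",
    in_ports=(PortSpec("a", "volume"), PortSpec("b", "volume", required=False)),
    out_ports=(_vout(),),
    param_defaults={"op": "add", "scalar": 0.0},
    fn=_elementwise_fn,
    radius=0,
))

register_kind(NodeKind(
    name="extract_slice",
    in_ports=(_vin(),),
    out_ports=(PortSpec("out", "image2d"),),
    param_defaults={"axis": 2, "index": 0},
    fn=lambda inputs, p: {"out": kernels.extract_slice(
        inputs["in"], int(p["axis"]), int(p["index"]))},
    radius=None,
))


# -- live code --------------------------------------------------------------

def _snippet_fn(inputs, p):
    k = livecode.compile_snippet(p["source"])
    overrides = {name: val for name, val in (p["params"] or {}).items()}
    return {"out": livecode.apply_pointwise(k, inputs["in"], **overrides)}


register_kind(NodeKind(
    name="compute_snippet",
    in_ports=(_vin(),),
    out_ports=(_vout(),),
    param_defaults={"source": "v", "params": {}},
    fn=_snippet_fn,
    radius=0,
))


def _image_snippet_fn(inputs, p):
    k = livecode.compile_image_snippet(p["source"])
    overrides = {name: val for name, val in (p["params"] or {}).items()}
    return {"out": livecode.generate_image(
        k, int(p["width"]), int(p["height"]), **overrides)}


register_kind(NodeKind(
    name="image_snippet",
    in_ports=(),
    out_ports=(PortSpec("out", "image2d"),),
    param_defaults={"source": "0", "width": 64, "height": 64, "params": {}},
    fn=_image_snippet_fn,
    radius=None,
))


# -- renderer ---------------------------------------------------------------

def _renderer_fn(inputs, p):
    v = inputs["in"]
    cam = render.Camera(
        eye=tuple(p["eye"]), target=tuple(p["target"]), up=tuple(p["up"]),
        fov_deg=float(p["fov_deg"]), width=int(p["width"]),
        height=int(p["height"]), eye_separation=float(p["eye_separation"]),
    )
    settings = render.RenderSettings(
        mode=p["mode"], threshold=float(p["threshold"]),
        opacity_scale=float(p["opacity_scale"]),
        step_size=float(p["step_size"]),
        background=tuple(p["background"]),
    )
    if p["stereo"]:
        return {"out": render.render_anaglyph(v, cam, settings)}
    return {"out": render.render_volume(v, cam, settings)}


register_kind(NodeKind(
    name="volume_renderer",
    in_ports=(_vin(),),
    out_ports=(PortSpec("out", "image2d"),),
    param_defaults={
        "eye": (96.0, 96.0, 48.0), "target": (32.0, 32.0, 32.0),
        "up": (0.0, 0.0, 1.0), "fov_deg": 45.0, "width": 64, "height": 64,
        "mode": "translucent", "threshold": 0.5, "opacity_scale": 1.0,
        "step_size": 0.5, "background": (0.0, 0.0, 0.0),
        "stereo": False, "eye_separation": 8.0,
    },
    fn=_renderer_fn,
    radius=None,
))


# -- sources and sinks ------------------------------------------------------

register_kind(NodeKind(
    name="load_volume",
    in_ports=(),
    out_ports=(_vout(),),
    param_defaults={"path": ""},
    fn=lambda inputs, p: {"out": vio.detect_and_read(p["path"])},
    radius=None,
))

register_kind(NodeKind(
    name="save_volume",
    in_ports=(_vin(),),
    out_ports=(),
    param_defaults={"path": ""},
    fn=lambda inputs, p: (vio.write_any(p["path"], inputs["in"]), {})[1],
    radius=None,
))

register_kind(NodeKind(
    name="save_image",
    in_ports=(PortSpec("in", "image2d"),),
    out_ports=(),
    param_defaults={"path": ""},
    fn=lambda inputs, p: (vio.write_any(p["path"], inputs["in"]), {})[1],
    radius=None,
))

register_kind(NodeKind(
    name="sphere_phantom",
    in_ports=(),
    out_ports=(_vout(),),
    param_defaults={"dims": (32, 32, 32), "radius": 10.0, "inside": 1.0,
                    "outside": 0.0, "noise_sd": 0.0, "seed": 0},
    fn=lambda inputs, p: {"out": phantoms.make_sphere_phantom(
        dims=tuple(p["dims"]), radius=float(p["radius"]),
        inside=float(p["inside"]), outside=float(p["outside"]),
        noise_sd=float(p["noise_sd"]), seed=int(p["seed"]))},
    radius=None,
))


def _head_phantom_fn(inputs, p):
    vol, labels = phantoms.make_head_phantom(
        dims=tuple(p["dims"]), noise_sd=float(p["noise_sd"]), seed=int(p["seed"]))
    return {"out": vol, "labels": labels}


register_kind(NodeKind(
    name="head_phantom",
    in_ports=(),
    out_ports=(_vout(), PortSpec("labels", "volume")),
    param_defaults={"dims": (64, 64, 64), "noise_sd": 0.0, "seed": 0},
    fn=_head_phantom_fn,
    radius=None,
))
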