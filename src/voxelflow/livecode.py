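"""Runtime-compiled per-voxel kernels ("live code" nodes).

A snippet is plain text in a small arithmetic expression dialect applied
independently to every element and channel of a volume.  The current element
is bound to ``v``; scalar parameters are declared inside the source with
``param`` directive lines and are discovered by introspection:

    param add = 0
    param exp = 1
    (v + add)^exp

``^`` is the power operator (matching shader-style notation); the usual
``+ - * /`` and unary minus are available, along with the math functions a
shader node set implies: ``min max abs clamp exp log sqrt pow floor ceil
sin cos step smoothstep``.

Compilation is pure and sandboxed: the source is parsed into a Python AST and
every node is checked against a whitelist.  Attribute access, subscripts,
imports, calls to anything but the whitelisted math functions — anything that
could reach I/O or host state — is rejected with a diagnostic that names the
offending position; a failed compilation never yields a partial kernel.
"""

from __future__ import annotations

import ast
import re
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .volume import Volume

__all__ = [
    "KernelSnippet",
    "ParamSpec",
    "compile_snippet",
    "apply_pointwise",
    "compile_image_snippet",
    "generate_image",
    "SnippetError",
    "SandboxViolation",
]


class SnippetError(ValueError):
    """Compilation diagnostic (syntax/semantic error with position info)."""


class SandboxViolation(SnippetError):
    """Disallowed construct (I/O, imports, attribute access, ...)."""


@dataclass(frozen=True)
class ParamSpec:
    name: str
    type: str        # always "float" in this dialect
    default: float


@dataclass(frozen=True)
class KernelSnippet:
    source: str
    params: tuple[ParamSpec, ...]
    fn: Callable[..., np.ndarray]  # fn(v, **params) -> array
    variables: tuple[str, ...] = ("v",)

    def param_names(self) -> list[str]:
        return [p.name for p in self.params]


def _step(edge, x):
    return (np.asarray(x, dtype=np.float64) >= edge).astype(np.float64)


def _smoothstep(e0, e1, x):
    t = np.clip((np.asarray(x, np.float64) - e0) / (e1 - e0), 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


_FUNCTIONS: dict[str, Callable] = {
    "min": np.minimum,
    "max": np.maximum,
    "abs": np.abs,
    "clamp": lambda x, lo, hi: np.clip(x, lo, hi),
    "exp": np.exp,
    "log": np.log,
    "sqrt": np.sqrt,
    "pow": np.power,
    "floor": np.floor,
    "ceil": np.ceil,
    "sin": np.sin,
    "cos": np.cos,
    "step": _step,
    "smoothstep": _smoothstep,
}

_ALLOWED_NODES = (
    ast.Expression, ast.BinOp, ast.UnaryOp, ast.Call, ast.Name, ast.Constant,
    ast.Load, ast.Add, ast.Sub, ast.Mult, ast.Div, ast.Pow, ast.Mod,
    ast.USub, ast.UAdd,
)

_PARAM_RE = re.compile(
    r"^\s*param\s+([A-Za-z_][A-Za-z_0-9]*)\s*(?::\s*float\s*)?=\s*([-+0-9.eE]+)\s*$"
)


def _parse_source(source: str, variables: tuple[str, ...]):
    """Split directive lines from the expression; parse and sandbox-check it."""
    params: list[ParamSpec] = []
    expr_lines: list[str] = []
    for line in source.splitlines():
        stripped = line.split("#", 1)[0]
        if not stripped.strip():
            continue
        m = _PARAM_RE.match(stripped)
        if m:
            name, default = m.group(1), m.group(2)
            # params may shadow math functions (e.g. a parameter named
            # "exp"); the shadowed function is then not callable
            if name in variables:
                raise SnippetError(
                    f"parameter name {name!r} collides with an input variable"
                )
            if any(p.name == name for p in params):
                raise SnippetError(f"duplicate parameter declaration {name!r}")
            try:
                params.append(ParamSpec(name, "float", float(default)))
            except ValueError:
                raise SnippetError(
                    f"invalid default {default!r} for parameter {name!r}"
                ) from None
        else:
            expr_lines.append(stripped.strip())
    if not expr_lines:
        raise SnippetError("snippet contains no expression")
    expr = " ".join(expr_lines)
    # '^' means power in this dialect
    expr_py = expr.replace("^", "**")
    try:
        tree = ast.parse(expr_py, mode="eval")
    except SyntaxError as e:
        raise SnippetError(
            f"syntax error at line {e.lineno}, column {e.offset}: {e.msg}"
        ) from None

    declared = {p.name for p in params}
    for node in ast.walk(tree):
        if not isinstance(node, _ALLOWED_NODES):
            pos = getattr(node, "col_offset", "?")
            raise SandboxViolation(
                f"disallowed construct {type(node).__name__} at column {pos}: "
                "snippets may only contain arithmetic, declared parameters and "
                f"the functions {', '.join(sorted(_FUNCTIONS))}"
            )
        if isinstance(node, ast.Constant) and not isinstance(node.value, (int, float)):
            raise SandboxViolation(
                f"only numeric literals are allowed, got {node.value!r}"
            )
        if isinstance(node, ast.Call):
            if isinstance(node.func, ast.Name) and node.func.id in declared:
                raise SnippetError(
                    f"{node.func.id!r} is declared as a parameter and cannot "
                    "be called as a function"
                )
            if not isinstance(node.func, ast.Name) or node.func.id not in _FUNCTIONS:
                name = getattr(node.func, "id", "<expression>")
                raise SandboxViolation(
                    f"call to {name!r} at column {node.col_offset} is not "
                    f"allowed; available functions: {', '.join(sorted(_FUNCTIONS))}"
                )
            if node.keywords:
                raise SandboxViolation("keyword arguments are not supported")
    # free-variable check: every Name must be a variable, param or function
    for node in ast.walk(tree):
        if isinstance(node, ast.Name):
            if node.id in variables or node.id in declared or node.id in _FUNCTIONS:
                continue
            raise SnippetError(
                f"undeclared name {node.id!r} at column {node.col_offset}; "
                f"declare it with 'param {node.id} = <default>' or use one of: "
                f"{', '.join(variables)}"
            )
    code = compile(tree, "<snippet>", "eval")
    return tuple(params), code


def _make_fn(code, variables: tuple[str, ...], params: tuple[ParamSpec, ...]):
    env_base = dict(_FUNCTIONS)

    def fn(*var_values, **param_values):
        env = dict(env_base)
        env.update(zip(variables, var_values))
        for p in params:
            env[p.name] = param_values.get(p.name, p.default)
        with np.errstate(all="ignore"):
            return eval(code, {"__builtins__": {}}, env)  # noqa: S307 - sandboxed AST

    return fn


def compile_snippet(source: str) -> KernelSnippet:
    """Compile a per-element snippet over ``v``; introspect its parameters."""
    variables = ("v",)
    params, code = _parse_source(source, variables)
    return KernelSnippet(source=source, params=params,
                         fn=_make_fn(code, variables, params),
                         variables=variables)


def apply_pointwise(k: KernelSnippet, v: Volume, **param_values) -> Volume:
    """Apply ``k`` to every element and channel of ``v``; shape preserved."""
    valid = set(k.param_names())
    unknown = sorted(set(param_values) - valid)
    if unknown:
        raise SnippetError(
            f"unknown parameter(s) {', '.join(unknown)}; "
            f"valid names: {sorted(valid) if valid else '(none)'}"
        )
    arr = v.astype_f32_normalized().astype(np.float64)
    out = k.fn(arr, **param_values)
    out = np.broadcast_to(np.asarray(out, dtype=np.float64), arr.shape)
    return Volume(v.dims, v.channels, "f32",
                  np.ascontiguousarray(out, np.float32))


def compile_image_snippet(source: str) -> KernelSnippet:
    """Compile a 2D generator snippet over pixel coordinates.

    The expression sees ``x, y`` (pixel indices) and ``width, height``,
    shader-toy style, and produces one grayscale value per pixel.
    """
    variables = ("x", "y", "width", "height")
    params, code = _parse_source(source, variables)
    return KernelSnippet(source=source, params=params,
                         fn=_make_fn(code, variables, params),
                         variables=variables)


def generate_image(k: KernelSnippet, width: int, height: int,
                   **param_values) -> Volume:
    """Evaluate a 2D generator snippet into a (width, height) f32 image."""
    if k.variables != ("x", "y", "width", "height"):
        raise SnippetError("not an image generator snippet; use compile_image_snippet")
    unknown = sorted(set(param_values) - set(k.param_names()))
    if unknown:
        raise SnippetError(f"unknown parameter(s) {', '.join(unknown)}")
    ys, xs = np.mgrid[0:height, 0:width].astype(np.float64)
    out = k.fn(xs, ys, float(width), float(height), **param_values)
    out = np.broadcast_to(np.asarray(out, np.float64), (height, width))
    return Volume((width, height), 1, "f32",
                  np.ascontiguousarray(out, np.float32)[..., None])
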