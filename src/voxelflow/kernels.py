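"""Built-in filter/algorithm library operating on :class:`~voxelflow.volume.Volume`.

All neighborhood operators use clamp-to-edge borders, consistent with the
sampling convention of the data model.  Every function here is pure: it
returns a new Volume and never mutates its input.

The 3D Euclidean distance transform is the separable squared-distance
algorithm of Felzenszwalb & Huttenlocher: an indicator preparation pass
followed by one 1D lower-envelope-of-parabolas pass per axis (four passes in
total for a 3D volume), then a square root.  It is exact, not an
approximation, and runs in O(n) per voxel line.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .volume import DTYPES, Volume, VolumeError, make_volume

__all__ = [
    "distance_transform_3d",
    "median_filter_3d",
    "rescale_intensity",
    "threshold",
    "convolve_separable",
    "gaussian_blur",
    "derivative",
    "surface_normals",
    "curvature",
    "region_filter",
    "elementwise",
    "extract_slice",
]


def _as_scalar_f32(v: Volume, op_name: str) -> np.ndarray:
    if v.channels != 1:
        raise VolumeError(
            f"{op_name} requires a single-channel volume (got {v.channels} "
            "channels); convert with a type/channel conversion node first"
        )
    return v.astype_f32_normalized()[..., 0]


def _wrap(v: Volume, arr: np.ndarray) -> Volume:
    return Volume(v.dims, 1, "f32", np.ascontiguousarray(arr, np.float32)[..., None])


# ---------------------------------------------------------------------------
# Euclidean distance transform
# ---------------------------------------------------------------------------

def _edt_1d_squared(f: np.ndarray) -> np.ndarray:
    """Lower envelope of parabolas: 1D squared distance transform of ``f``.

    ``f`` holds squared distances sampled on a grid; the result is
    ``min_q f[q] + (p-q)^2`` for every p.  Vectorized over the leading axes
    of ``f`` (the transform runs along the last axis).
    """
    n = f.shape[-1]
    lead = f.shape[:-1]
    f2 = f.reshape(-1, n)
    out = np.empty_like(f2)
    for row in range(f2.shape[0]):
        out[row] = _envelope_row(f2[row])
    return out.reshape(lead + (n,))


def _envelope_row(f: np.ndarray) -> np.ndarray:
    n = f.shape[0]
    d = np.empty(n, dtype=f.dtype)
    v = np.zeros(n, dtype=np.intp)      # parabola apex locations
    z = np.empty(n + 1, dtype=f.dtype)  # envelope breakpoints
    k = 0
    z[0] = -np.inf
    z[1] = np.inf
    for q in range(1, n):
        # intersection of parabola at q with parabola at v[k]
        s = ((f[q] + q * q) - (f[v[k]] + v[k] * v[k])) / (2 * q - 2 * v[k])
        while s <= z[k]:
            k -= 1
            s = ((f[q] + q * q) - (f[v[k]] + v[k] * v[k])) / (2 * q - 2 * v[k])
        k += 1
        v[k] = q
        z[k] = s
        z[k + 1] = np.inf
    k = 0
    for q in range(n):
        while z[k + 1] < q:
            k += 1
        d[q] = (q - v[k]) ** 2 + f[v[k]]
    return d


def distance_transform_3d(v: Volume, t: float = 0.5) -> Volume:
    """Exact Euclidean distance (voxel units) to the nearest solid voxel.

    A voxel is *solid* when its normalized intensity is >= ``t``.  The
    preparation pass writes squared distance 0 at solid voxels and a large
    finite sentinel elsewhere; one separable 1D pass per axis then computes
    the exact squared distance, and a final pass takes square roots.  When no
    voxel is solid every output equals the sentinel distance.
    """
    arr = _as_scalar_f32(v, "distance_transform_3d").astype(np.float64)
    # finite sentinel strictly above the squared diagonal keeps the all-empty
    # case well defined without inf arithmetic
    sentinel = float(sum((d - 1) ** 2 for d in v.dims) + 1) if v.n_voxels > 1 else 1.0
    f = np.where(arr >= t, 0.0, sentinel)
    for axis in range(f.ndim):
        f = np.moveaxis(_edt_1d_squared(np.moveaxis(f, axis, -1)), -1, axis)
    return _wrap(v, np.sqrt(f))


# ---------------------------------------------------------------------------
# Rank / region / smoothing filters
# ---------------------------------------------------------------------------

def median_filter_3d(v: Volume) -> Volume:
    """Median (14th order statistic) over the clamped 3x3x3 / 27-voxel box.

    For 1D/2D inputs the box degenerates to 3 / 9 elements accordingly.
    """
    arr = _as_scalar_f32(v, "median_filter_3d")
    out = ndimage.median_filter(arr, size=3, mode="nearest")
    return _wrap(v, out)


def rescale_intensity(v: Volume) -> Volume:
    """Affinely map intensities so output spans [0, 1]; constant input -> zeros."""
    arr = _as_scalar_f32(v, "rescale_intensity").astype(np.float64)
    lo, hi = float(arr.min()), float(arr.max())
    if hi == lo:
        return _wrap(v, np.zeros_like(arr))
    return _wrap(v, (arr - lo) / (hi - lo))


def threshold(v: Volume, t: float = 0.5) -> Volume:
    """Binary volume: 1 where intensity >= t else 0 (the solidity convention)."""
    arr = _as_scalar_f32(v, "threshold")
    return _wrap(v, (arr >= t).astype(np.float32))


def convolve_separable(v: Volume, kernels_1d) -> Volume:
    """Separable convolution with one odd-length 1D kernel per axis.

    ``kernels_1d`` is ordered x-first, matching ``dims``.  Borders clamp to
    the edge element.
    """
    arr = _as_scalar_f32(v, "convolve_separable").astype(np.float64)
    if len(kernels_1d) != v.ndim:
        raise VolumeError(
            f"need {v.ndim} kernels (one per axis), got {len(kernels_1d)}"
        )
    for axis_x_first, k in enumerate(kernels_1d):
        k = np.asarray(k, dtype=np.float64)
        if k.ndim != 1 or k.size % 2 == 0:
            raise VolumeError(
                f"kernel for axis {axis_x_first} must be 1D with odd length, "
                f"got shape {k.shape}"
            )
        np_axis = arr.ndim - 1 - axis_x_first  # x is the last numpy axis
        arr = ndimage.convolve1d(arr, k, axis=np_axis, mode="nearest")
    return _wrap(v, arr)


def gaussian_kernel_1d(sigma: float) -> np.ndarray:
    """Sampled Gaussian of radius ceil(3*sigma), renormalized to sum 1."""
    if sigma <= 0:
        return np.array([1.0])
    r = int(np.ceil(3.0 * sigma))
    x = np.arange(-r, r + 1, dtype=np.float64)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def gaussian_blur(v: Volume, sigma: float = 1.0) -> Volume:
    k = gaussian_kernel_1d(sigma)
    return convolve_separable(v, [k] * v.ndim)


def region_filter(v: Volume, op: str = "avg", radius: int = 1) -> Volume:
    """Per-voxel min/max/average over the clamped (2r+1)^ndim box."""
    if radius < 1:
        raise VolumeError(f"radius must be >= 1, got {radius}")
    arr = _as_scalar_f32(v, "region_filter")
    size = 2 * radius + 1
    if op == "min":
        out = ndimage.minimum_filter(arr, size=size, mode="nearest")
    elif op == "max":
        out = ndimage.maximum_filter(arr, size=size, mode="nearest")
    elif op == "avg":
        out = ndimage.uniform_filter(arr.astype(np.float64), size=size, mode="nearest")
    else:
        raise VolumeError(f"unknown region op {op!r} (must be min, max or avg)")
    return _wrap(v, out)


# ---------------------------------------------------------------------------
# Derivatives
# ---------------------------------------------------------------------------

_CD = np.array([-0.5, 0.0, 0.5])  # central difference, clamp borders


def _gradient(arr: np.ndarray) -> list[np.ndarray]:
    """Central-difference gradient components ordered x-first."""
    grads = []
    for axis_x_first in range(arr.ndim):
        np_axis = arr.ndim - 1 - axis_x_first
        grads.append(ndimage.correlate1d(arr, _CD, axis=np_axis, mode="nearest"))
    return grads


def derivative(v: Volume) -> Volume:
    """Gradient magnitude (edge detection)."""
    arr = _as_scalar_f32(v, "derivative").astype(np.float64)
    g = _gradient(arr)
    return _wrap(v, np.sqrt(np.sum([c * c for c in g], axis=0)))


def surface_normals(v: Volume) -> Volume:
    """Negated normalized gradient as an ndim-channel volume; zero where flat."""
    arr = _as_scalar_f32(v, "surface_normals").astype(np.float64)
    g = np.stack(_gradient(arr), axis=-1)
    mag = np.linalg.norm(g, axis=-1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        n = np.where(mag > 0, -g / mag, 0.0)
    return Volume(v.dims, g.shape[-1], "f32", np.ascontiguousarray(n, np.float32))


#: gradient magnitudes below this are treated as flat (curvature undefined -> 0)
CURVATURE_GRAD_TOL = 1e-8


def curvature(v: Volume) -> Volume:
    """Mean curvature of the implicit isosurfaces, H = div(grad v/|grad v|)/2.

    Computed with central differences on the normalized gradient field; a
    sphere of radius r (v = distance to center) yields H ~ 1/r.  Voxels where
    the gradient magnitude falls below ``CURVATURE_GRAD_TOL`` report 0.
    """
    arr = _as_scalar_f32(v, "curvature").astype(np.float64)
    g = _gradient(arr)
    mag = np.sqrt(np.sum([c * c for c in g], axis=0))
    flat = mag <= CURVATURE_GRAD_TOL
    safe = np.where(flat, 1.0, mag)
    div = np.zeros_like(arr)
    for axis_x_first, comp in enumerate(g):
        unit = np.where(flat, 0.0, comp / safe)
        np_axis = arr.ndim - 1 - axis_x_first
        div += ndimage.correlate1d(unit, _CD, axis=np_axis, mode="nearest")
    h = 0.5 * div
    h[flat] = 0.0
    return _wrap(v, h)


# ---------------------------------------------------------------------------
# Pointwise / structural
# ---------------------------------------------------------------------------

_ELEMENTWISE_OPS = {
    "add": np.add,
    "sub": np.subtract,
    "mul": np.multiply,
    "div": np.true_divide,
    "pow": np.power,
}


def elementwise(a: Volume, b, op: str) -> Volume:
    """Elementwise arithmetic with IEEE semantics (inf/NaN propagate, never trap)."""
    if op not in _ELEMENTWISE_OPS:
        raise VolumeError(f"unknown elementwise op {op!r} (must be one of "
                          f"{sorted(_ELEMENTWISE_OPS)})")
    arr_a = a.astype_f32_normalized()
    if isinstance(b, Volume):
        if b.dims != a.dims or b.channels != a.channels:
            raise VolumeError(
                f"shape mismatch: {a.dims} x {a.channels}ch vs "
                f"{b.dims} x {b.channels}ch"
            )
        arr_b = b.astype_f32_normalized()
    else:
        arr_b = np.float32(b)
    with np.errstate(all="ignore"):
        out = _ELEMENTWISE_OPS[op](arr_a, arr_b)
    return Volume(a.dims, a.channels, "f32",
                  np.ascontiguousarray(out, np.float32))


def extract_slice(v: Volume, axis: int, index: int) -> Volume:
    """2D cross-section of a 3D volume; ``axis`` is x-first (0=x, 1=y, 2=z)."""
    if v.ndim != 3:
        raise VolumeError(f"extract_slice needs a 3D volume, got {v.ndim}D")
    if not (0 <= axis <= 2):
        raise VolumeError(f"axis must be 0, 1 or 2, got {axis}")
    extent = v.dims[axis]
    if not (0 <= index < extent):
        raise VolumeError(
            f"slice index {index} out of range for axis {axis} "
            f"(valid range 0..{extent - 1})"
        )
    np_axis = v.data.ndim - 2 - axis  # data shape is (z, y, x, c)
    sl = np.take(v.data, index, axis=np_axis)
    out_dims = tuple(d for i, d in enumerate(v.dims) if i != axis)
    return Volume(out_dims, v.channels, v.dtype, np.ascontiguousarray(sl))
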