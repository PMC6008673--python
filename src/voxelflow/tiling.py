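"""Automatic tiled execution of volume kernels.

Large volumes are split into axis-aligned core blocks that partition the
volume exactly; each core is extended by a *halo* of border voxels so that a
neighborhood operator of radius <= halo produces, on the tile, exactly the
values the untiled run would produce.  Halos are filled from neighboring data
where available and clamp-to-edge at the volume borders — the same border
policy every kernel uses, which is what makes tiled == untiled an exact
identity rather than an approximation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volume import Volume

__all__ = ["Tile", "TilePlan", "plan_tiles", "run_tiled", "TilingError"]


class TilingError(ValueError):
    pass


@dataclass(frozen=True)
class Tile:
    origin: tuple[int, ...]   # core origin, x-first
    core: tuple[int, ...]     # core extent per axis
    halo: tuple[int, ...]     # requested halo per axis (clipped at borders)


@dataclass(frozen=True)
class TilePlan:
    dims: tuple[int, ...]
    tiles: tuple[Tile, ...]
    max_voxels_per_tile: int


def plan_tiles(dims, max_voxels_per_tile: int, halo_per_axis) -> TilePlan:
    """Deterministically split ``dims`` into cores in raster order.

    Every tile's core+halo (halo clipped at the volume border, so the worst
    case is core + 2*halo per axis) fits within ``max_voxels_per_tile``.
    """
    dims = tuple(int(d) for d in dims)
    if isinstance(halo_per_axis, int):
        halo = (halo_per_axis,) * len(dims)
    else:
        halo = tuple(int(h) for h in halo_per_axis)
    if len(halo) != len(dims):
        raise TilingError(f"halo {halo} does not match axis count of dims {dims}")
    if any(h < 0 for h in halo):
        raise TilingError(f"negative halo in {halo}")
    min_tile = int(np.prod([1 + 2 * h for h in halo]))
    if max_voxels_per_tile < min_tile:
        raise TilingError(
            f"voxel budget {max_voxels_per_tile} too small: the minimum legal "
            f"tile (core 1 voxel + halo {halo}) needs {min_tile} voxels"
        )

    # choose number of chunks per axis: greedily split the axis with the
    # largest core until the worst-case tile fits the budget
    nchunks = [1] * len(dims)

    def worst_tile(nc):
        return int(np.prod([
            min(-(-d // n) + 2 * h, d + 2 * h)
            for d, n, h in zip(dims, nc, halo)
        ]))

    while worst_tile(nchunks) > max_voxels_per_tile:
        cores = [-(-d // n) for d, n in zip(dims, nchunks)]
        # split the axis with the largest current core; ties -> lowest axis
        axis = max(range(len(dims)), key=lambda i: (cores[i], -i))
        if cores[axis] == 1:
            raise TilingError(
                f"voxel budget {max_voxels_per_tile} too small for dims {dims} "
                f"with halo {halo}: minimum achievable tile is {worst_tile(nchunks)}"
            )
        nchunks[axis] += 1

    # raster-order cartesian product of per-axis intervals
    per_axis = []
    for d, n in zip(dims, nchunks):
        size = -(-d // n)
        starts = list(range(0, d, size))
        per_axis.append([(s, min(size, d - s)) for s in starts])

    tiles = []
    # raster order: x fastest
    idx = [0] * len(dims)
    total = int(np.prod([len(p) for p in per_axis]))
    for _ in range(total):
        origin = tuple(per_axis[a][idx[a]][0] for a in range(len(dims)))
        core = tuple(per_axis[a][idx[a]][1] for a in range(len(dims)))
        tiles.append(Tile(origin=origin, core=core, halo=halo))
        for a in range(len(dims)):
            idx[a] += 1
            if idx[a] < len(per_axis[a]):
                break
            idx[a] = 0
    return TilePlan(dims=dims, tiles=tuple(tiles), max_voxels_per_tile=max_voxels_per_tile)


def _extract_clipped(v: Volume, tile: Tile):
    """Core + halo region with the halo clipped at the volume borders.

    Clipping (rather than edge-padding) keeps the kernel's own clamp-to-edge
    addressing acting at exactly the true volume border, so even nonlinear
    multi-stage kernels (e.g. curvature, where clamping the raw data does not
    commute with clamping intermediate fields) reproduce the untiled result.
    Returns the sub-volume plus the effective lower halo per axis (x-first).
    """
    ndim = v.ndim
    slices = []   # numpy order: slowest axis first; data is (..., channels)
    lower = [0] * ndim
    for axis in reversed(range(ndim)):
        o, c, h = tile.origin[axis], tile.core[axis], tile.halo[axis]
        d = v.dims[axis]
        lo, hi = max(o - h, 0), min(o + c + h, d)
        slices.append(slice(lo, hi))
        lower[axis] = o - lo
    sub = v.data[tuple(slices) + (slice(None),)]
    dims = tuple(sub.shape[ndim - 1 - i] for i in range(ndim))
    return Volume(dims, v.channels, v.dtype,
                  np.ascontiguousarray(sub)), tuple(lower)


def run_tiled(kernel, v: Volume, kernel_radius: int,
              max_voxels_per_tile: int, halo: int | None = None) -> Volume:
    """Run ``kernel`` (Volume -> Volume) piecewise; identical to the untiled run.

    ``kernel_radius`` is the kernel's declared neighborhood radius; the halo
    must be at least that wide or correctness cannot be guaranteed.
    """
    if halo is None:
        halo = kernel_radius
    if halo < kernel_radius:
        raise TilingError(
            f"halo {halo} is smaller than the kernel radius {kernel_radius}; "
            "tiled output would differ from the untiled run"
        )
    plan = plan_tiles(v.dims, max_voxels_per_tile, halo)
    out = None
    for tile in plan.tiles:
        sub, lower = _extract_clipped(v, tile)
        res = kernel(sub)
        if res.dims != sub.dims:
            raise TilingError(
                f"kernel changed tile dims {sub.dims} -> {res.dims}; "
                "only dims-preserving kernels can run tiled"
            )
        if out is None:
            out = np.empty(v.dims[::-1] + (res.channels,), dtype=res.data.dtype)
        # crop the core back out of the tile
        crop = []
        dst = []
        for axis in reversed(range(v.ndim)):
            o, c = tile.origin[axis], tile.core[axis]
            crop.append(slice(lower[axis], lower[axis] + c))
            dst.append(slice(o, o + c))
        crop.append(slice(None))
        dst.append(slice(None))
        out[tuple(dst)] = res.data[tuple(crop)]
    assert out is not None
    return Volume(v.dims, out.shape[-1],
                  _dtype_name_of(out.dtype), np.ascontiguousarray(out))


def _dtype_name_of(np_dtype) -> str:
    import numpy as _np
    return {_np.dtype(_np.uint8): "u8",
            _np.dtype(_np.uint16): "u16",
            _np.dtype(_np.float32): "f32"}[_np.dtype(np_dtype)]
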