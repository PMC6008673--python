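"""In-memory volume/image data model.

A :class:`Volume` is a dense 1- to 3-dimensional raster with 1-4 channels and
one of three element formats: ``u8`` (compact), ``u16`` (high detail) or
``f32`` (HDR).  Integer formats are interpreted as normalized intensities in
``[0, 1]`` when converted to float, mirroring how GPU texture units expose
``UNORM`` formats to shaders.

Conventions (fixed across the whole package):

* ``dims`` lists extents x-first (``(nx,)``, ``(nx, ny)`` or ``(nx, ny, nz)``)
  and x is the fastest-varying axis in memory.
* Out-of-range coordinates clamp to the nearest edge element everywhere
  (clamp-to-edge addressing, the default GPU sampling behaviour).
* Channel swizzle masks use the alphabet ``r g b a 0 1``; ``0`` yields zero,
  ``1`` yields full scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Volume",
    "make_volume",
    "sample",
    "convert_type",
    "DTYPES",
    "VolumeError",
]

#: supported element formats: name -> (numpy dtype, full-scale value or None)
DTYPES = {
    "u8": (np.uint8, 255),
    "u16": (np.uint16, 65535),
    "f32": (np.float32, None),
}

SWIZZLE_ALPHABET = "rgba01"
_CHANNEL_INDEX = {"r": 0, "g": 1, "b": 2, "a": 3}


class VolumeError(ValueError):
    """Raised for invalid volume construction or access."""


@dataclass
class Volume:
    """Dense 1-3D raster with 1-4 channels.

    ``data`` has shape ``dims[::-1] + (channels,)`` in C order, which makes x
    the fastest-varying axis as required.  Use :func:`sample` for swizzled /
    clamped access; ``data`` is the raw store.
    """

    dims: tuple[int, ...]
    channels: int
    dtype: str
    data: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        _validate_meta(self.dims, self.channels, self.dtype)
        expected = self.dims[::-1] + (self.channels,)
        if tuple(self.data.shape) != expected:
            raise VolumeError(
                f"data shape {self.data.shape} does not match dims {self.dims} "
                f"x {self.channels} channels (expected {expected})"
            )
        np_dtype = DTYPES[self.dtype][0]
        if self.data.dtype != np_dtype:
            raise VolumeError(
                f"data dtype {self.data.dtype} does not match declared '{self.dtype}'"
            )

    @property
    def ndim(self) -> int:
        return len(self.dims)

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.dims))

    def scalar(self) -> np.ndarray:
        """Single-channel view with the channel axis dropped."""
        if self.channels != 1:
            raise VolumeError(f"expected 1 channel, volume has {self.channels}")
        return self.data[..., 0]

    def astype_f32_normalized(self) -> np.ndarray:
        """Element array as float32 in normalized [0,1] space (u8/u16) or raw (f32)."""
        scale = DTYPES[self.dtype][1]
        arr = self.data.astype(np.float32)
        if scale is not None:
            arr /= scale
        return arr

    def copy(self) -> "Volume":
        return Volume(self.dims, self.channels, self.dtype, self.data.copy())

    @classmethod
    def from_array(cls, arr: np.ndarray, dims: tuple[int, ...], dtype: str) -> "Volume":
        """Wrap ``arr`` of shape dims[::-1] (+ optional channel axis)."""
        if arr.ndim == len(dims):
            arr = arr[..., np.newaxis]
        channels = arr.shape[-1]
        np_dtype = DTYPES[dtype][0]
        return cls(tuple(dims), channels, dtype, np.ascontiguousarray(arr, dtype=np_dtype))


def _validate_meta(dims, channels, dtype) -> None:
    if not (1 <= len(dims) <= 3):
        raise VolumeError(f"invalid axis count {len(dims)} (dims must have 1-3 axes)")
    for d in dims:
        if not (isinstance(d, (int, np.integer)) and d >= 1):
            raise VolumeError(f"invalid extent {d!r} in dims {tuple(dims)}")
    if channels not in (1, 2, 3, 4):
        raise VolumeError(f"invalid channels {channels!r} (must be 1-4)")
    if dtype not in DTYPES:
        raise VolumeError(f"invalid dtype {dtype!r} (must be one of {sorted(DTYPES)})")


def make_volume(dims, channels: int = 1, dtype: str = "f32", fill_value=0) -> Volume:
    """Create a volume with every element equal to ``fill_value``."""
    dims = tuple(int(d) for d in dims)
    _validate_meta(dims, channels, dtype)
    np_dtype = DTYPES[dtype][0]
    data = np.full(dims[::-1] + (channels,), fill_value, dtype=np_dtype)
    return Volume(dims, channels, dtype, data)


def _parse_swizzle(mask: str, channels: int):
    if not mask or not all(c in SWIZZLE_ALPHABET for c in mask):
        raise VolumeError(
            f"malformed swizzle mask {mask!r}: legal symbols are "
            f"{', '.join(SWIZZLE_ALPHABET)}"
        )
    out = []
    for c in mask:
        if c in _CHANNEL_INDEX:
            idx = _CHANNEL_INDEX[c]
            if idx >= channels:
                raise VolumeError(
                    f"swizzle component {c!r} addresses channel {idx} but the "
                    f"volume has only {channels} channel(s)"
                )
            out.append(idx)
        else:
            out.append(c)  # literal '0' or '1'
    return out


def sample(v: Volume, coord, swizzle: str | None = None) -> np.ndarray:
    """Fetch one element with clamp-to-edge addressing and optional swizzle.

    ``coord`` gives integer indices x-first.  Out-of-range indices clamp to the
    nearest edge.  A swizzle mask remaps output channels; the literal ``1``
    yields the full-scale value for the volume's dtype, ``0`` yields zero.
    """
    if len(coord) != v.ndim:
        raise VolumeError(f"coordinate {tuple(coord)} has wrong arity for dims {v.dims}")
    idx = tuple(
        int(np.clip(c, 0, d - 1)) for c, d in zip(reversed(coord), reversed(v.dims))
    )
    element = v.data[idx]
    if swizzle is None:
        return element.copy()
    plan = _parse_swizzle(swizzle, v.channels)
    scale = DTYPES[v.dtype][1]
    full = scale if scale is not None else 1.0
    out = np.empty(len(plan), dtype=v.data.dtype)
    for i, p in enumerate(plan):
        if p == "0":
            out[i] = 0
        elif p == "1":
            out[i] = full
        else:
            out[i] = element[p]
    return out


def convert_type(v: Volume, target_dtype: str) -> Volume:
    """Convert element format through normalized [0,1] space.

    u8 value x maps to x/255 as float; floats map back with round-half-up and
    clamping.  u8 <-> u16 rescales through the same normalized space.
    """
    if target_dtype not in DTYPES:
        raise VolumeError(f"invalid dtype {target_dtype!r} (must be one of {sorted(DTYPES)})")
    if target_dtype == v.dtype:
        return v.copy()
    norm = v.astype_f32_normalized().astype(np.float64)
    np_dtype, scale = DTYPES[target_dtype]
    if scale is None:
        out = norm.astype(np.float32)
    else:
        # round-half-up, then clamp to the integer range
        out = np.floor(norm * scale + 0.5)
        out = np.clip(out, 0, scale).astype(np_dtype)
    return Volume(v.dims, v.channels, target_dtype, out)
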