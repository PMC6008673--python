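"""Synthetic phantom volumes for pipelines, tests and examples.

Real clinical MRI/CT data cannot be redistributed, so every example pipeline
in this package runs on procedurally generated phantoms that emulate the
relevant structure: a noisy two-level sphere for distance-transform and
rendering demos, and a three-tissue "head" of nested ellipsoids — a bright
outer skull/skin shell, a thin intermediate cerebrospinal-fluid layer and a
darker textured brain core — paired with a ground-truth label volume so that
segmentation pipelines can be scored exactly.

All generators are deterministic given (parameters, seed).
"""

from __future__ import annotations

import numpy as np

from .volume import Volume

__all__ = [
    "make_sphere_phantom",
    "make_head_phantom",
    "HEAD_INTENSITIES",
    "HEAD_LABELS",
]

#: noise-free class intensities of the head phantom (normalized units)
HEAD_INTENSITIES = {
    "background": 0.0,
    "brain": 0.2,
    "csf": 0.45,
    "skull": 0.9,
}

#: label codes in the ground-truth volume
HEAD_LABELS = {"background": 0, "brain": 1, "csf": 2, "skull": 3}


def _grid(dims):
    """World coordinates of voxel centers, x-first, each shaped dims[::-1]."""
    axes = [np.arange(d, dtype=np.float64) for d in dims]
    mesh = np.meshgrid(*axes[::-1], indexing="ij")  # (z, y, x) order
    return mesh[::-1]  # x, y, z


def make_sphere_phantom(dims=(32, 32, 32), center=None, radius=10.0,
                        inside=1.0, outside=0.0, noise_sd=0.0,
                        seed=0) -> Volume:
    """Two-level sphere: ``inside`` where |p - center| <= radius else ``outside``.

    Gaussian noise of standard deviation ``noise_sd`` is added and the result
    is clamped to [0, 1].  ``radius=0`` yields a single-voxel sphere when the
    center lies on a voxel coordinate.
    """
    dims = tuple(int(d) for d in dims)
    if center is None:
        center = tuple((d - 1) / 2.0 for d in dims)
    coords = _grid(dims)
    r2 = sum((c - cc) ** 2 for c, cc in zip(coords, center))
    arr = np.where(r2 <= radius * radius, float(inside), float(outside))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        arr = arr + rng.normal(0.0, noise_sd, size=arr.shape)
    arr = np.clip(arr, 0.0, 1.0)
    return Volume(dims, 1, "f32", arr.astype(np.float32)[..., None])


def _ellipsoid_mask(coords, center, semi_axes):
    q = sum(((c - cc) / a) ** 2 for c, cc, a in zip(coords, center, semi_axes))
    return q <= 1.0


def make_head_phantom(dims=(64, 64, 64), noise_sd=0.0, seed=0):
    """Three-tissue head phantom plus its ground-truth label volume.

    Nested ellipsoids centered in the volume: the outermost shell is
    "skull/skin" at intensity 0.9, inside it a thin "CSF" layer at 0.45, and
    the core is "brain" at 0.2 with a mild smooth texture (+-0.03); the
    background is 0.  The class intensity ranges stay disjoint at
    ``noise_sd=0``.  Returns ``(volume, labels)`` where ``labels`` is a u8
    volume with codes from :data:`HEAD_LABELS`.
    """
    dims = tuple(int(d) for d in dims)
    center = tuple((d - 1) / 2.0 for d in dims)
    # semi-axes as fractions of the half-extent: slightly anisotropic
    half = [d / 2.0 for d in dims]
    outer = [0.90 * h for h in half]          # skull outer surface
    inner_skull = [0.74 * h for h in half]    # skull inner surface
    inner_csf = [0.66 * h for h in half]      # CSF inner surface

    coords = _grid(dims)
    m_outer = _ellipsoid_mask(coords, center, outer)
    m_inner_skull = _ellipsoid_mask(coords, center, inner_skull)
    m_inner_csf = _ellipsoid_mask(coords, center, inner_csf)

    labels = np.zeros(dims[::-1], dtype=np.uint8)
    labels[m_outer & ~m_inner_skull] = HEAD_LABELS["skull"]
    labels[m_inner_skull & ~m_inner_csf] = HEAD_LABELS["csf"]
    labels[m_inner_csf] = HEAD_LABELS["brain"]

    arr = np.zeros(dims[::-1], dtype=np.float64)
    arr[labels == HEAD_LABELS["skull"]] = HEAD_INTENSITIES["skull"]
    arr[labels == HEAD_LABELS["csf"]] = HEAD_INTENSITIES["csf"]
    # brain: base intensity plus a smooth low-amplitude texture
    texture = 0.03 * np.sin(coords[0] / 5.0) * np.cos(coords[1] / 7.0)
    brain = HEAD_INTENSITIES["brain"] + texture
    arr[labels == HEAD_LABELS["brain"]] = brain[labels == HEAD_LABELS["brain"]]

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        arr = arr + rng.normal(0.0, noise_sd, size=arr.shape)
    arr = np.clip(arr, 0.0, 1.0)
    vol = Volume(dims, 1, "f32", arr.astype(np.float32)[..., None])
    lab = Volume(dims, 1, "u8", labels[..., None])
    return vol, lab
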