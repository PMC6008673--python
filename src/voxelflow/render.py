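"""CPU volume ray-caster: a graph node turning a 3D volume into a 2D image.

A right-handed perspective camera shoots one ray through each pixel center;
samples are taken every ``step_size`` voxels by trilinear interpolation with
clamp-to-edge addressing.  Five render modes mirror the classic volume
renderer repertoire:

* ``translucent``  — front-to-back alpha compositing with early ray exit;
* ``solid``        — first-hit isosurface at the threshold, Lambert-shaded
  with a headlight, normals from the intensity gradient;
* ``solid_rescaled`` — as solid, after mapping intensities onto [0, 1];
* ``solid_curvature`` — first-hit surface colored by mean curvature through
  a diverging blue-white-red ramp;
* ``edge_step``    — binary occupancy (white where the ray crosses the
  threshold, background elsewhere).

Red/cyan anaglyph stereo renders the scene twice with the eye displaced
half the eye separation left and right along the camera's right axis and
packs the left eye's luminance into the red channel, the right eye's into
green and blue.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .kernels import curvature as _curvature_kernel
from .kernels import rescale_intensity, surface_normals
from .volume import Volume, VolumeError

__all__ = [
    "Camera",
    "RenderSettings",
    "render_volume",
    "render_anaglyph",
    "composite_front_to_back",
    "RENDER_MODES",
]

RENDER_MODES = ("solid", "solid_curvature", "edge_step", "solid_rescaled",
                "translucent")


@dataclass
class Camera:
    eye: tuple[float, float, float]
    target: tuple[float, float, float]
    up: tuple[float, float, float] = (0.0, 0.0, 1.0)
    fov_deg: float = 45.0
    width: int = 64
    height: int = 64
    eye_separation: float = 0.0  # voxel units, for stereo

    def __post_init__(self):
        if tuple(self.eye) == tuple(self.target):
            raise ValueError("camera eye must differ from target")
        if not (0.0 < self.fov_deg < 180.0):
            raise ValueError(f"fov {self.fov_deg} out of range (0, 180)")
        if self.width < 1 or self.height < 1:
            raise ValueError("image size must be at least 1x1")

    def basis(self):
        """Right-handed (forward, right, up) unit vectors."""
        eye = np.asarray(self.eye, np.float64)
        fwd = np.asarray(self.target, np.float64) - eye
        fwd /= np.linalg.norm(fwd)
        right = np.cross(fwd, np.asarray(self.up, np.float64))
        nr = np.linalg.norm(right)
        if nr == 0:
            raise ValueError("camera up vector is parallel to the view direction")
        right /= nr
        up = np.cross(right, fwd)
        return fwd, right, up


@dataclass
class RenderSettings:
    mode: str = "translucent"
    threshold: float = 0.5          # iso/step threshold, normalized
    opacity_scale: float = 1.0      # translucent transfer strength
    step_size: float = 0.5          # voxel units along the ray
    background: tuple[float, float, float] = (0.0, 0.0, 0.0)
    ambient: float = 0.15           # floor of the Lambert term
    curvature_scale: float = 5.0    # curvature mapped via tanh(k*scale)

    def __post_init__(self):
        if self.mode not in RENDER_MODES:
            raise ValueError(f"unknown render mode {self.mode!r}; "
                             f"choose from {RENDER_MODES}")
        if self.step_size <= 0:
            raise ValueError("step size must be positive")
        if not (0.0 <= self.threshold <= 1.0):
            raise ValueError("threshold must lie in [0, 1]")


def composite_front_to_back(colors: np.ndarray, alphas: np.ndarray):
    """Front-to-back alpha compositing of an ordered sample sequence.

    ``C <- C + (1-A)*a_i*c_i`` and ``A <- A + (1-A)*a_i``; equals the
    back-to-front closed form ``sum_i c_i a_i prod_{j<i} (1-a_j)``.
    Accepts ``colors`` of shape (k,) or (k, channels).
    """
    colors = np.asarray(colors, np.float64)
    alphas = np.asarray(alphas, np.float64)
    c_acc = np.zeros(colors.shape[1:] if colors.ndim > 1 else ())
    a_acc = 0.0
    for ci, ai in zip(colors, alphas):
        c_acc = c_acc + (1.0 - a_acc) * ai * ci
        a_acc = a_acc + (1.0 - a_acc) * ai
    return c_acc, a_acc


def _trilinear(arr3d: np.ndarray, pts_xyz: np.ndarray) -> np.ndarray:
    """Sample a (z,y,x) array at world points (N,3) x-first, clamp-to-edge."""
    # voxel i is centered at i + 0.5 in world units
    coords = np.stack([
        pts_xyz[:, 2] - 0.5,  # z index
        pts_xyz[:, 1] - 0.5,  # y index
        pts_xyz[:, 0] - 0.5,  # x index
    ])
    return ndimage.map_coordinates(arr3d, coords, order=1, mode="nearest")


def _ray_grid(cam: Camera, eye_offset: float = 0.0):
    fwd, right, up = cam.basis()
    eye = np.asarray(cam.eye, np.float64) + eye_offset * right
    tan_half = np.tan(np.deg2rad(cam.fov_deg) / 2.0)
    aspect = cam.width / cam.height
    i = (np.arange(cam.width) + 0.5) / cam.width * 2.0 - 1.0
    j = 1.0 - (np.arange(cam.height) + 0.5) / cam.height * 2.0
    px, py = np.meshgrid(i * tan_half * aspect, j * tan_half)
    dirs = (fwd[None, None, :]
            + px[..., None] * right[None, None, :]
            + py[..., None] * up[None, None, :])
    dirs /= np.linalg.norm(dirs, axis=-1, keepdims=True)
    return eye, dirs.reshape(-1, 3)


def _box_intersect(eye, dirs, dims):
    """Slab intersection with the box [0, dims] per ray; (t_near, t_far)."""
    lo = np.zeros(3)
    hi = np.asarray(dims, np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = 1.0 / dirs
        t0 = (lo[None, :] - eye[None, :]) * inv
        t1 = (hi[None, :] - eye[None, :]) * inv
    # rays parallel to a slab: inside -> (-inf, inf), outside -> miss
    parallel = dirs == 0.0
    inside = (eye[None, :] >= lo) & (eye[None, :] <= hi)
    t0 = np.where(parallel, np.where(inside, -np.inf, np.inf), t0)
    t1 = np.where(parallel, np.where(inside, np.inf, -np.inf), t1)
    tmin = np.minimum(t0, t1).max(axis=1)
    tmax = np.maximum(t0, t1).min(axis=1)
    tmin = np.maximum(tmin, 0.0)
    return tmin, tmax


_RAMP_NEG = np.array([0.23, 0.30, 0.75])   # blue end of the diverging ramp
_RAMP_MID = np.array([0.95, 0.95, 0.95])
_RAMP_POS = np.array([0.71, 0.02, 0.15])   # red end


def _diverging_ramp(t: np.ndarray) -> np.ndarray:
    """Map t in [-1,1] to blue-white-red colors, shape (N,3)."""
    t = np.clip(t, -1.0, 1.0)[:, None]
    neg = _RAMP_MID + (_RAMP_MID - _RAMP_NEG) * t      # t<0: towards blue
    pos = _RAMP_MID + (_RAMP_POS - _RAMP_MID) * t      # t>0: towards red
    return np.where(t < 0, neg, pos)


def render_volume(v: Volume, cam: Camera, s: RenderSettings,
                  _eye_offset: float = 0.0) -> Volume:
    """Render a single-channel 3D volume to a (width, height) RGBA f32 image."""
    if v.ndim != 3:
        raise VolumeError(f"renderer needs a 3D volume, got {v.ndim}D")
    if v.channels != 1:
        raise VolumeError("renderer needs a single-channel volume")
    if s.mode == "solid_rescaled":
        v = rescale_intensity(v)
        s = RenderSettings(**{**s.__dict__, "mode": "solid"})
    arr = v.astype_f32_normalized()[..., 0].astype(np.float64)

    eye, dirs = _ray_grid(cam, _eye_offset)
    n_rays = dirs.shape[0]
    tmin, tmax = _box_intersect(eye, dirs, v.dims)
    hit_box = tmax > tmin
    bg = np.asarray(s.background, np.float64)

    out = np.empty((n_rays, 4))
    out[:, :3] = bg
    out[:, 3] = 1.0
    if not hit_box.any():
        return _pack_image(out, cam)

    idx = np.nonzero(hit_box)[0]
    t0, t1 = tmin[idx], tmax[idx]
    d = dirs[idx]
    span = float((t1 - t0).max())
    n_steps = max(1, int(np.ceil(span / s.step_size)))

    if s.mode == "translucent":
        rgb, alpha = _march_translucent(arr, eye, d, t0, t1, n_steps, s)
        out[idx, :3] = rgb + (1.0 - alpha)[:, None] * bg[None, :]
    else:
        rgb = _march_solid(arr, v, eye, d, t0, t1, n_steps, s, bg)
        out[idx, :3] = rgb
    return _pack_image(out, cam)


def _march_translucent(arr, eye, dirs, t0, t1, n_steps, s):
    n = dirs.shape[0]
    c_acc = np.zeros((n, 3))
    a_acc = np.zeros(n)
    for k in range(n_steps):
        t = t0 + (k + 0.5) * s.step_size
        live = (t < t1) & (a_acc < 0.999)  # early exit at full opacity
        if not live.any():
            break
        pts = eye[None, :] + t[live, None] * dirs[live]
        intensity = _trilinear(arr, pts)
        a = np.clip(intensity * s.opacity_scale * s.step_size, 0.0, 1.0)
        contrib = (1.0 - a_acc[live]) * a
        c_acc[live] += (contrib * intensity)[:, None]  # grayscale emission
        a_acc[live] += contrib
    return c_acc, a_acc


def _march_solid(arr, v, eye, dirs, t0, t1, n_steps, s, bg):
    n = dirs.shape[0]
    hit_t = np.full(n, np.nan)
    undecided = np.ones(n, bool)
    prev_t = t0.copy()
    for k in range(n_steps):
        t = t0 + (k + 0.5) * s.step_size
        live = undecided & (t < t1)
        if not live.any():
            break
        pts = eye[None, :] + t[live, None] * dirs[live]
        val = _trilinear(arr, pts)
        crossed = val >= s.threshold
        live_idx = np.nonzero(live)[0]
        hit_idx = live_idx[crossed]
        hit_t[hit_idx] = t[hit_idx]
        undecided[hit_idx] = False
    hits = ~np.isnan(hit_t)
    rgb = np.tile(bg, (n, 1))
    if not hits.any():
        return rgb
    hp = eye[None, :] + hit_t[hits, None] * dirs[hits]
    if s.mode == "edge_step":
        rgb[hits] = 1.0
        return rgb
    normals = surface_normals(v)
    ncomp = np.stack([_trilinear(normals.data[..., c].astype(np.float64), hp)
                      for c in range(3)], axis=-1)
    norm = np.linalg.norm(ncomp, axis=-1, keepdims=True)
    ncomp = np.where(norm > 0, ncomp / np.maximum(norm, 1e-12), 0.0)
    lambert = np.maximum(np.sum(-dirs[hits] * ncomp, axis=-1), s.ambient)
    if s.mode == "solid":
        rgb[hits] = lambert[:, None]
    else:  # solid_curvature
        curv = _curvature_kernel(v).data[..., 0].astype(np.float64)
        kv = _trilinear(curv, hp)
        color = _diverging_ramp(np.tanh(kv * s.curvature_scale))
        rgb[hits] = lambert[:, None] * color
    return rgb


def _pack_image(flat_rgba: np.ndarray, cam: Camera) -> Volume:
    img = flat_rgba.reshape(cam.height, cam.width, 4)
    return Volume((cam.width, cam.height), 4, "f32",
                  np.ascontiguousarray(img, np.float32))


def luminance(img: Volume) -> np.ndarray:
    """Rec. 709 luminance of an RGB(A) image, shape (height, width)."""
    a = img.astype_f32_normalized()
    if img.channels == 1:
        return a[..., 0]
    return 0.2126 * a[..., 0] + 0.7152 * a[..., 1] + 0.0722 * a[..., 2]


def render_anaglyph(v: Volume, cam: Camera, s: RenderSettings) -> Volume:
    """Red/cyan stereo: left eye luminance -> red, right eye -> green+blue."""
    half = cam.eye_separation / 2.0
    left = render_volume(v, cam, s, _eye_offset=-half)
    right = render_volume(v, cam, s, _eye_offset=+half)
    lum_l = luminance(left)
    lum_r = luminance(right)
    rgb = np.stack([lum_l, lum_r, lum_r], axis=-1)
    return Volume((cam.width, cam.height), 3, "f32",
                  np.ascontiguousarray(rgb, np.float32))
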