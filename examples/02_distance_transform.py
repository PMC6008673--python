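"""Exact Euclidean distance transform on a synthetic sphere.

Computes the distance field of a ball (solid voxels: intensity >= 0.5) and
compares the measured distances against the analytic distance-to-ball
formula max(0, |p - c| - r).
"""

import numpy as np

from voxelflow import distance_transform_3d, make_sphere_phantom

v = make_sphere_phantom(dims=(48, 48, 48), radius=10.0)
d = distance_transform_3d(v, t=0.5)

arr = d.data[..., 0]
c = (np.array(v.dims) - 1) / 2.0
z, y, x = np.mgrid[0:48, 0:48, 0:48].astype(np.float64)
radial = np.sqrt((x - c[0]) ** 2 + (y - c[1]) ** 2 + (z - c[2]) ** 2)
analytic = np.maximum(0.0, radial - 10.0)

print("distance at the center voxel:", float(arr[24, 24, 24]), "(inside -> 0)")
print("distance at corner (0,0,0):  ", float(arr[0, 0, 0]))
print("analytic corner estimate:    ", float(analytic[0, 0, 0]))
err = np.abs(arr - analytic).max()
print(f"max |measured - analytic|: {err:.3f} voxels")
# The residual stays below one voxel: it stems from the discrete ball
# surface, not from the transform, which is exact on the voxel grid.
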