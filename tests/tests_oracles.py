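"""Independent brute-force oracles shared across test modules."""

import numpy as np
from scipy import ndimage


def brute_force_local_thickness(mask, voxel_size=1.0):
    """Direct inscribed-sphere oracle, O(N^2) on small masks.

    For every mask voxel v: thickness is the diameter of the largest
    maximal ball containing v, where the ball centered at c has EDT
    radius dt(c) and geometric diameter (2*dt(c) - 1) voxels.
    """
    mask = np.asarray(mask).astype(bool)
    dt = ndimage.distance_transform_edt(mask)
    pts = np.argwhere(mask)
    radii = dt[mask]
    out = np.zeros(mask.shape)
    for v in pts:
        d = np.linalg.norm(pts - v, axis=1)
        containing = radii[d <= radii + 1e-9]
        out[tuple(v)] = (2.0 * containing.max() - 1.0) * voxel_size
    return out
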