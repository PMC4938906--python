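"""Shared test utilities: sphere sampling and brute-force contact oracles."""
import numpy as np
from scipy.stats import special_ortho_group

from footkin.contact import point_surface_distance
from footkin.geometry import EllipsoidSurface


def fibonacci_sphere(n):
    k = np.arange(n, dtype=float)
    phi = np.arccos(1.0 - 2.0 * (k + 0.5) / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * k
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def random_ellipsoid(rng, center_range=0.5, semi_lo=0.3, semi_hi=1.2):
    return EllipsoidSurface(
        center=rng.uniform(-center_range, center_range, 3),
        semi_axes=rng.uniform(semi_lo, semi_hi, 3),
        orientation=special_ortho_group.rvs(3, random_state=int(rng.integers(1e9))),
    )


def _cone_directions(center, half_angle, n, rng_offset=0):
    """Quasi-uniform directions within a spherical cap around ``center``."""
    center = center / np.linalg.norm(center)
    # tangent basis
    helper = np.array([1.0, 0.0, 0.0])
    if abs(center[0]) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(center, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(center, e1)
    k = np.arange(n, dtype=float)
    r = half_angle * np.sqrt((k + 0.5) / n)
    th = np.pi * (1.0 + np.sqrt(5.0)) * (k + rng_offset)
    disk = r[:, None] * (np.cos(th)[:, None] * e1 + np.sin(th)[:, None] * e2)
    dirs = center + disk
    return dirs / np.linalg.norm(dirs, axis=1, keepdims=True)


def brute_force_separation(a, b, n=20000):
    """Dense-sampling oracle: min signed point-to-surface distance both ways.

    A coarse global scan over each surface is refined by two local
    resampling passes around the argmin (pure sampling, no gradient use).
    """
    best = np.inf
    for src, dst in ((a, b), (b, a)):
        dirs = fibonacci_sphere(n)
        local_best, local_dir = np.inf, None
        for stage, (dd, cap) in enumerate(
            [(dirs, None), (None, 0.08), (None, 0.004)]
        ):
            if dd is None:
                dd = _cone_directions(local_dir, cap, 4000)
            pts = src.center + (dd * src.semi_axes) @ src.orientation.T
            for u, p in zip(dd, pts):
                d, _ = point_surface_distance(p, dst)
                if d < local_best:
                    local_best, local_dir = d, u
        best = min(best, local_best)
    return best
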