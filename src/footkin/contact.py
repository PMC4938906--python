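"""Ellipsoid gliding contact for the inter-tarsal articulations.

The cuboid-navicular, cuneocuboid and the two intercuneiform articulations
carry no idealized joint; to keep the solver from driving those bones through
each other, each bone owns an ellipsoid surface and a non-penetration rule is
enforced between the articulating pairs.

Signed separation between two ellipsoids is defined as the minimum over both
surfaces of the signed distance of one surface's points to the other surface:
the gap (positive) when the bodies are disjoint, minus the deepest surface
penetration when they overlap. For two spheres this reduces to
``|c1 - c2| - r1 - r2``. It is symmetric and invariant under a common rigid
motion. The non-penetration rule enters the inverse-kinematics objective as a
smooth one-sided quadratic penalty ``weight * min(0, separation)^2``.
"""
from __future__ import annotations

import numpy as np
from scipy.optimize import brentq, minimize

from .errors import FitError, NumericError
from .geometry import EllipsoidSurface
from .skeleton import JointState, KinematicTemplate, fk_full, point_jacobian

__all__ = [
    "fit_ellipsoid",
    "penetration_depth",
    "separation_details",
    "point_surface_distance",
    "contact_penalty",
    "trial_separations",
]


def fit_ellipsoid(points: np.ndarray) -> EllipsoidSurface:
    """Least-squares algebraic ellipsoid fit to >= 9 points.

    Fits the general quadric ``x'Ax + b'x + j = 0`` by the singular vector of
    the design matrix and rejects non-ellipsoidal (indefinite) solutions.
    The RMS algebraic residual is attached as ``fit_residual``.
    """
    P = np.asarray(points, dtype=float)
    if P.ndim != 2 or P.shape[1] != 3:
        raise FitError(f"expected (n, 3) points, got shape {P.shape}")
    if P.shape[0] < 9:
        raise FitError(f"need at least 9 points to fit an ellipsoid, got {P.shape[0]}")
    # center & scale for conditioning
    mu = P.mean(axis=0)
    scale = max(P.std(), 1e-12)
    Q = (P - mu) / scale
    x, y, z = Q.T
    D = np.column_stack(
        [x * x, y * y, z * z, x * y, x * z, y * z, x, y, z, np.ones_like(x)]
    )
    U, s, Vt = np.linalg.svd(D, full_matrices=False)
    if s[-2] < 1e-10 * s[0]:
        raise FitError("degenerate point set (coplanar or otherwise rank-deficient)")
    c = Vt[-1]
    residual = s[-1] / np.sqrt(P.shape[0])
    A = np.array(
        [
            [c[0], c[3] / 2, c[4] / 2],
            [c[3] / 2, c[1], c[5] / 2],
            [c[4] / 2, c[5] / 2, c[2]],
        ]
    )
    bvec = c[6:9]
    j = c[9]
    try:
        center_q = np.linalg.solve(A, -bvec / 2.0)
    except np.linalg.LinAlgError as exc:
        raise FitError("singular quadric (not an ellipsoid)") from exc
    k = j + bvec @ center_q + center_q @ A @ center_q  # x'Ax = -k at the center
    lam, vec = np.linalg.eigh(A)
    ratios = -k / lam  # squared semi-axes if all positive
    if not np.all(ratios > 0):
        raise FitError("fitted quadric is not an ellipsoid (indefinite form)")
    semi = np.sqrt(ratios) * scale
    if np.linalg.det(vec) < 0:
        vec = vec.copy()
        vec[:, -1] *= -1.0
    ell = EllipsoidSurface(
        center=center_q * scale + mu, semi_axes=semi, orientation=vec
    )
    ell.fit_residual = float(residual)
    return ell


# ---------------------------------------------------------------------------
# point <-> ellipsoid
# ---------------------------------------------------------------------------


def _closest_in_frame(y: np.ndarray, a: np.ndarray) -> np.ndarray:
    """Closest point on the axis-aligned ellipsoid surface to ``y`` (its frame)."""
    # nudge off symmetry axes (relative to each semi-axis) so the root
    # bracket of phi stays valid for points on or near an axis
    eps = 1e-9 * a
    y = np.where(np.abs(y) < eps, np.copysign(eps, y + 1e-300), y)
    a2 = a * a

    def phi(t: float) -> float:
        return float(np.sum(a2 * y * y / (a2 + t) ** 2) - 1.0)

    inside = np.sum((y / a) ** 2) < 1.0
    if inside:
        lo = -np.min(a2) * (1.0 - 1e-12)
        hi = 0.0
        if phi(lo) < 0.0:  # pathological axis case after the nudge; fall back
            lo = -np.min(a2) * (1.0 - 1e-9)
    else:
        lo = 0.0
        hi = np.sqrt(np.sum(a2 * y * y))
        while phi(hi) > 0.0:
            hi = 2.0 * hi + np.max(a2)
    if phi(lo) < 0.0 <= phi(hi):
        lo, hi = hi, lo  # defensive; phi is decreasing so this never triggers
    t = brentq(phi, lo, hi, xtol=1e-30, rtol=1e-15, maxiter=200)
    return a2 * y / (a2 + t)


def point_surface_distance(
    point: np.ndarray, ell: EllipsoidSurface
) -> tuple[float, np.ndarray]:
    """Signed distance (negative inside) and closest surface point, lab frame."""
    p = np.asarray(point, dtype=float).reshape(3)
    y = ell.orientation.T @ (p - ell.center)
    s = _closest_in_frame(y, ell.semi_axes)
    closest = ell.orientation @ s + ell.center
    d = float(np.linalg.norm(p - closest))
    if np.sum((y / ell.semi_axes) ** 2) < 1.0:
        d = -d
    return d, closest


def _fibonacci_directions(n: int) -> np.ndarray:
    k = np.arange(n, dtype=float)
    phi = np.arccos(1.0 - 2.0 * (k + 0.5) / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * k
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


# fixed quasi-uniform direction sets for the cold-start scan; the dense set
# is used for overlapping pairs, whose deepest-point landscape is multimodal
_SCAN_DIRECTIONS = np.vstack([np.eye(3), -np.eye(3), _fibonacci_directions(246)])
_SCAN_DIRECTIONS_DENSE = np.vstack([np.eye(3), -np.eye(3), _fibonacci_directions(2042)])


def _homogeneous_form(e: EllipsoidSurface) -> np.ndarray:
    """4x4 quadric matrix of the ellipsoid (interior negative)."""
    M = e.orientation @ np.diag(1.0 / e.semi_axes**2) @ e.orientation.T
    A = np.zeros((4, 4))
    A[:3, :3] = M
    A[:3, 3] = -M @ e.center
    A[3, :3] = -M @ e.center
    A[3, 3] = e.center @ M @ e.center - 1.0
    return A


def ellipsoids_separated(
    a: EllipsoidSurface, b: EllipsoidSurface, tol: float = 1e-9
) -> bool:
    """Fast exact disjointness test via the characteristic equation.

    Two ellipsoids are disjoint iff ``det(lambda A + B) = 0`` has two
    distinct positive roots (algebraic separation condition for quadrics);
    borderline (touching) configurations report False, so a False return
    means "possibly in contact" and callers fall back to the distance
    computation.
    """
    lam = -np.linalg.eigvals(
        np.linalg.solve(_homogeneous_form(a), _homogeneous_form(b))
    )
    real = lam[np.abs(lam.imag) <= 1e-8 * np.maximum(1.0, np.abs(lam))]
    pos = np.sort(real.real[real.real > tol])
    return len(pos) == 2 and (pos[1] - pos[0]) > tol * pos[1]


def _min_signed_distance(
    src: EllipsoidSurface,
    dst: EllipsoidSurface,
    seeds: np.ndarray | None = None,
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """Minimize signed distance to ``dst`` over the surface of ``src``.

    By default a deterministic multi-start (a quasi-uniform scan over the
    direction sphere including the six axis-aligned directions, descending
    from the best candidates plus the center-line direction) avoids spurious
    local minima; warm-start directions can be supplied instead when the
    configuration changes slowly (consecutive IK frames). Returns
    (value, point on src, point on dst, optimal direction parameter).
    """

    def objective(p: np.ndarray) -> tuple[float, np.ndarray]:
        nrm = np.linalg.norm(p)
        u = p / nrm
        x = src.center + src.orientation @ (src.semi_axes * u)
        d, closest = point_surface_distance(x, dst)
        g = x - closest
        gn = np.linalg.norm(g)
        if gn < 1e-14:
            grad_x = np.zeros(3)
        else:
            grad_x = (g / gn) if d > 0 else (-g / gn)
        dx_dp = src.orientation @ (
            np.diag(src.semi_axes) @ ((np.eye(3) - np.outer(u, u)) / nrm)
        )
        return d, dx_dp.T @ grad_x

    center_seed = np.diag(1.0 / src.semi_axes) @ (
        src.orientation.T @ (dst.center - src.center)
    )
    nrm = np.linalg.norm(center_seed)
    center_seed = center_seed / nrm if nrm > 1e-12 else np.array([1.0, 0.0, 0.0])
    disjoint = ellipsoids_separated(src, dst)
    if seeds is None:
        # deterministic scan over the direction sphere, then descend from the
        # most promising candidates (plus the center-line direction)
        scan = _SCAN_DIRECTIONS if disjoint else _SCAN_DIRECTIONS_DENSE
        vals = [objective(p)[0] for p in scan]
        best_idx = np.argsort(vals)[:8]
        seed_list = np.vstack([scan[best_idx], center_seed])
    else:
        seed_list = np.vstack([np.atleast_2d(seeds), center_seed])
    best = None
    for seed in seed_list:
        res = minimize(
            objective,
            np.asarray(seed, dtype=float),
            jac=True,
            method="BFGS",
            options={"gtol": 1e-10, "maxiter": 150},
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.all(np.isfinite(best.x)):
        raise NumericError("ellipsoid separation minimization failed to converge")
    if not disjoint:
        # inside the other body the distance field is non-smooth along the
        # medial axis; a derivative-free polish escapes the kinked valleys
        # that stall the quasi-Newton steps
        res = minimize(
            lambda p: objective(p)[0],
            best.x / np.linalg.norm(best.x),
            method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 400},
        )
        if res.fun < best.fun and np.all(np.isfinite(res.x)):
            best = res
    u = best.x / np.linalg.norm(best.x)
    x = src.center + src.orientation @ (src.semi_axes * u)
    d, closest = point_surface_distance(x, dst)
    return d, x, closest, u


def separation_details(
    a: EllipsoidSurface,
    b: EllipsoidSurface,
    pose_a: tuple[np.ndarray, np.ndarray] | None = None,
    pose_b: tuple[np.ndarray, np.ndarray] | None = None,
    cache: dict | None = None,
    cache_key=None,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Signed separation and the realizing contact points (on a, on b).

    ``cache``/``cache_key`` enable warm-started minimization across nearby
    calls (e.g. consecutive frames of one trial); the cold path runs the
    full deterministic multi-start.
    """
    A = a.transformed(*pose_a) if pose_a is not None else a
    B = b.transformed(*pose_b) if pose_b is not None else b
    warm = cache.get(cache_key) if cache is not None else None
    d1, xa1, xb1, u1 = _min_signed_distance(A, B, None if warm is None else warm[0])
    d2, xb2, xa2, u2 = _min_signed_distance(B, A, None if warm is None else warm[1])
    if cache is not None:
        cache[cache_key] = (u1, u2)
    if d1 <= d2:
        return d1, xa1, xb1
    return d2, xa2, xb2


def penetration_depth(
    a: EllipsoidSurface,
    b: EllipsoidSurface,
    pose_a: tuple[np.ndarray, np.ndarray] | None = None,
    pose_b: tuple[np.ndarray, np.ndarray] | None = None,
    cache: dict | None = None,
    cache_key=None,
) -> float:
    """Signed separation: positive gap when disjoint, <= 0 when touching/overlapping."""
    return separation_details(a, b, pose_a, pose_b, cache, cache_key)[0]


# ---------------------------------------------------------------------------
# penalty over a posed template
# ---------------------------------------------------------------------------


def contact_penalty(
    state: JointState,
    template: KinematicTemplate,
    surfaces: dict[str, EllipsoidSurface] | None = None,
    pairs: list[tuple[str, str]] | None = None,
    weight: float = 1e6,
) -> tuple[float, np.ndarray]:
    """One-sided quadratic non-penetration penalty and its state gradient.

    ``penalty = weight * sum over pairs of min(0, separation)^2``; the gradient
    is with respect to the full generalized coordinates ``[root(6), q]`` and
    uses the envelope theorem (contact points held fixed in their body frames).
    """
    surfaces = surfaces if surfaces is not None else template.contact_surfaces
    pairs = pairs if pairs is not None else template.contact_pairs
    fk = fk_full(template, state)
    n = 6 + template.total_dof
    value = 0.0
    grad = np.zeros(n)
    for seg_a, seg_b in pairs:
        sep, xa, xb = separation_details(
            surfaces[seg_a], surfaces[seg_b], fk.poses[seg_a], fk.poses[seg_b]
        )
        if sep >= 0.0:
            continue
        gap = xa - xb
        nrm = np.linalg.norm(gap)
        if nrm < 1e-14:
            continue  # exactly touching; zero-measure, zero gradient
        normal = gap / nrm
        Ja = point_jacobian(template, fk, seg_a, xa)
        Jb = point_jacobian(template, fk, seg_b, xb)
        # sep = -|xa - xb| when overlapping
        dsep = -(normal @ (Ja - Jb))
        value += weight * sep * sep
        grad += 2.0 * weight * sep * dsep
    return value, grad


def trial_separations(
    template: KinematicTemplate,
    states: list[JointState],
    surfaces: dict[str, EllipsoidSurface] | None = None,
    pairs: list[tuple[str, str]] | None = None,
) -> np.ndarray:
    """Per-frame, per-pair signed separations (frames x pairs), NaN for bad frames."""
    surfaces = surfaces if surfaces is not None else template.contact_surfaces
    pairs = pairs if pairs is not None else template.contact_pairs
    out = np.full((len(states), len(pairs)), np.nan)
    cache: dict = {}
    for i, st in enumerate(states):
        if st is None:
            continue
        fk = fk_full(template, st)
        for k, (sa, sb) in enumerate(pairs):
            out[i, k] = penetration_depth(
                surfaces[sa],
                surfaces[sb],
                fk.poses[sa],
                fk.poses[sb],
                cache=cache,
                cache_key=k,
            )
    return out
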