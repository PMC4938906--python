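"""Subject-specific template scaling via a 3-D thin-plate-spline warp.

A set of 16 named surface landmarks is annotated on the template and on the
subject's foot scan; the radial-basis warp that carries the template
landmarks exactly onto the subject's is then applied to every model point
(joint centers, marker and landmark attachments, contact-ellipsoid centers).
Directions (joint axes, ellipsoid orientations) are transported by the local
warp Jacobian: axes by its polar rotation factor, ellipsoid shapes by its
full linear action.

The kernel is the 3-D biharmonic spline ``U(r) = r`` with a full affine
polynomial term, so any affine map of the landmarks (in particular uniform
scaling) is reproduced exactly; the familiar 2-D ``r^2 log r`` kernel is
available as ``kernel="r2logr"``.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import FitError, ScalingError
from .geometry import EllipsoidSurface, polar_rotation
from .skeleton import (
    LANDMARK_NAMES,
    JointState,
    KinematicTemplate,
    Segment,
    forward_kinematics,
    landmark_positions,
)

__all__ = [
    "LandmarkSet",
    "TpsWarp",
    "fit_tps",
    "warp_points",
    "warp_jacobian",
    "scale_template",
    "load_landmarks",
    "save_landmarks",
]


@dataclass
class LandmarkSet:
    """The 16 canonical scan landmarks as lab-frame points (meters)."""

    names: tuple[str, ...]
    positions: np.ndarray  # (16, 3)

    def __post_init__(self) -> None:
        self.names = tuple(self.names)
        self.positions = np.asarray(self.positions, dtype=float).reshape(
            len(self.names), 3
        )
        if set(self.names) != set(LANDMARK_NAMES):
            missing = set(LANDMARK_NAMES) - set(self.names)
            extra = set(self.names) - set(LANDMARK_NAMES)
            raise ValueError(
                f"landmark names must match the canonical 16: "
                f"missing {sorted(missing)}, unexpected {sorted(extra)}"
            )
        # canonical order
        order = [self.names.index(n) for n in LANDMARK_NAMES]
        self.names = LANDMARK_NAMES
        self.positions = self.positions[order]
        d = np.linalg.norm(
            self.positions[:, None, :] - self.positions[None, :, :], axis=-1
        )
        np.fill_diagonal(d, np.inf)
        if d.min() < 1e-12:
            raise ValueError("duplicate landmark positions")

    @classmethod
    def from_template(cls, template: KinematicTemplate) -> "LandmarkSet":
        pos = landmark_positions(template)
        return cls(tuple(pos), np.array([pos[n] for n in pos]))

    def to_dict(self) -> dict:
        return {n: p.tolist() for n, p in zip(self.names, self.positions)}


def load_landmarks(path: str | Path) -> LandmarkSet:
    """Read a landmark JSON sidecar: ``{"landmarks": {name: [x, y, z]}}`` (m)."""
    d = json.loads(Path(path).read_text())
    lm = d.get("landmarks", d)
    return LandmarkSet(tuple(lm), np.array(list(lm.values()), dtype=float))


def save_landmarks(path: str | Path, landmarks: LandmarkSet) -> None:
    Path(path).write_text(json.dumps({"landmarks": landmarks.to_dict()}, indent=1))


def _kernel(r: np.ndarray, kind: str) -> np.ndarray:
    if kind == "r":
        return r
    if kind == "r2logr":
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(r > 0, r * r * np.log(r, where=r > 0), 0.0)
        return out
    raise ValueError(f"unknown TPS kernel {kind!r}")


@dataclass
class TpsWarp:
    """A fitted thin-plate-spline warp ``x -> affine x + t + sum_i w_i U(|x-s_i|)``."""

    source: LandmarkSet
    rbf_weights: np.ndarray  # (16, 3)
    affine: np.ndarray  # (3, 3)
    translation: np.ndarray  # (3,)
    kernel: str = "r"
    target: LandmarkSet | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.rbf_weights = np.asarray(self.rbf_weights, dtype=float).reshape(
            len(self.source.names), 3
        )
        self.affine = np.asarray(self.affine, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        # side conditions: weights orthogonal to constants and coordinates
        s = self.source.positions
        if np.abs(self.rbf_weights.sum(axis=0)).max() > 1e-9:
            raise FitError("TPS side condition violated: sum of weights != 0")
        if np.abs(s.T @ self.rbf_weights).max() > 1e-9:
            raise FitError("TPS side condition violated: weights not moment-free")

    def __call__(self, points: np.ndarray) -> np.ndarray:
        return warp_points(self, points)


def fit_tps(
    source: LandmarkSet, target: LandmarkSet, kernel: str = "r"
) -> TpsWarp:
    """Fit the TPS carrying every source landmark exactly onto its target.

    Solves the standard bordered linear system; raises :class:`FitError` for
    coplanar or duplicate sources (singular system).
    """
    if source.names != target.names:
        raise ValueError("source and target must share the canonical landmark names")
    S = source.positions
    T = target.positions
    n = S.shape[0]
    r = np.linalg.norm(S[:, None, :] - S[None, :, :], axis=-1)
    K = _kernel(r, kernel)
    P = np.column_stack([np.ones(n), S])
    M = np.zeros((n + 4, n + 4))
    M[:n, :n] = K
    M[:n, n:] = P
    M[n:, :n] = P.T
    rhs = np.zeros((n + 4, 3))
    rhs[:n] = T
    cond = np.linalg.cond(M)
    if not np.isfinite(cond) or cond > 1e12:
        raise FitError(
            "singular TPS system (coplanar or duplicate source landmarks)"
        )
    sol = np.linalg.solve(M, rhs)
    W = sol[:n]
    translation = sol[n]
    A = sol[n + 1:].T  # rows of sol are per-coordinate; affine acts as A @ x
    warp = TpsWarp(
        source=source,
        rbf_weights=W,
        affine=A,
        translation=translation,
        kernel=kernel,
        target=target,
    )
    # interpolation condition
    err = np.abs(warp(S) - T).max()
    if err > 1e-9:
        raise FitError(f"TPS interpolation condition violated (max error {err:.2e})")
    return warp


def warp_points(warp: TpsWarp, points: np.ndarray) -> np.ndarray:
    """Apply the warp to one point or an (n, 3) array of points."""
    p = np.asarray(points, dtype=float)
    single = p.ndim == 1
    p = np.atleast_2d(p)
    r = np.linalg.norm(p[:, None, :] - warp.source.positions[None, :, :], axis=-1)
    out = (
        p @ warp.affine.T
        + warp.translation
        + _kernel(r, warp.kernel) @ warp.rbf_weights
    )
    return out[0] if single else out


def warp_jacobian(warp: TpsWarp, point: np.ndarray) -> np.ndarray:
    """Local 3x3 Jacobian of the warp (analytic; kernel U(r) = r)."""
    x = np.asarray(point, dtype=float).reshape(3)
    J = warp.affine.copy()
    diffs = x - warp.source.positions
    r = np.linalg.norm(diffs, axis=1)
    for i, (w, d, ri) in enumerate(zip(warp.rbf_weights, diffs, r)):
        if ri < 1e-12:
            continue  # kernel is non-smooth at a landmark; skip its term
        if warp.kernel == "r":
            J += np.outer(w, d / ri)
        else:  # r2logr: d/dx r^2 log r = (2 log r + 1) (x - s)
            J += np.outer(w, (2.0 * np.log(ri) + 1.0) * d)
    return J


def scale_template(
    template: KinematicTemplate, warp: TpsWarp
) -> KinematicTemplate:
    """Warp a template into a subject-specific model.

    All attachment points and joint centers are carried through the warp in
    the neutral-pose lab space; segment frames remain axis-aligned at
    neutral, so local coordinates are re-derived as differences of warped
    lab points. Joint axes rotate by the polar factor of the warp Jacobian
    at the joint center; contact ellipsoids transform by the full local
    linear action (SVD re-orthonormalization).
    """
    neutral = JointState.zeros(template)
    poses = forward_kinematics(template, neutral)
    origins = {name: t for name, (_, t) in poses.items()}
    new_origins = {name: warp(origins[name]) for name in origins}

    new_segments = []
    for name in template.topo_order:
        seg = template.segments[name]
        o_new = new_origins[name]
        if seg.parent is None:
            local_jc = np.zeros(3)
        else:
            local_jc = o_new - new_origins[seg.parent]
        markers = {
            m: warp(origins[name] + p) - o_new for m, p in seg.marker_points.items()
        }
        landmarks = {
            m: warp(origins[name] + p) - o_new
            for m, p in seg.landmark_points.items()
        }
        new_segments.append(
            Segment(
                name=name,
                parent=seg.parent,
                local_joint_center=local_jc,
                marker_points=markers,
                landmark_points=landmarks,
            )
        )

    new_joints = []
    for name in template.topo_order:
        if name not in template.joints:
            continue
        spec = template.joints[name]
        J = warp_jacobian(warp, origins[name])
        det = np.linalg.det(J)
        if not np.isfinite(det) or det <= 1e-12:
            raise ScalingError(
                f"warp Jacobian non-invertible at joint center of {name!r} "
                f"(det = {det:.3e})"
            )
        R = polar_rotation(J)
        axes = (R @ spec.axes.T).T
        axes /= np.linalg.norm(axes, axis=1, keepdims=True)
        new_joints.append(
            type(spec)(
                child_segment=spec.child_segment,
                joint_type=spec.joint_type,
                axes=axes,
                angle_names=spec.angle_names,
                sign_convention=spec.sign_convention,
                limits=spec.limits.copy(),
            )
        )

    new_surfaces = {}
    for seg_name, ell in template.contact_surfaces.items():
        center_lab = origins[seg_name] + ell.center  # frames are axis-aligned
        J = warp_jacobian(warp, center_lab)
        if np.linalg.det(J) <= 1e-12:
            raise ScalingError(
                f"warp Jacobian non-invertible at contact surface of {seg_name!r}"
            )
        M = J @ ell.orientation @ np.diag(ell.semi_axes)
        U, s, _ = np.linalg.svd(M)
        if np.linalg.det(U) < 0:
            U = U.copy()
            U[:, -1] *= -1.0
        new_surfaces[seg_name] = EllipsoidSurface(
            center=warp(center_lab) - new_origins[seg_name],
            semi_axes=s,
            orientation=U,
        )

    return KinematicTemplate(
        new_segments,
        new_joints,
        contact_surfaces=new_surfaces,
        contact_pairs=list(template.contact_pairs),
        rhythm_config=template.rhythm_config,
        name=f"{template.name}-scaled",
    )
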