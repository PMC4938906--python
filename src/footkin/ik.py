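"""Over-determinate inverse kinematics from labelled marker trajectories.

Each frame poses the model by weighted nonlinear least squares over the root
pose and the reduced (rhythm-constrained) joint coordinates:

    min over (root, q_reduced) of
        sum_i w_i |m_hat_i(root, C q_reduced + offset) - m_i|^2  +  contact penalty

solved with Levenberg-Marquardt using analytic geometric Jacobians chained
through the rhythm matrix C. Rhythms are hard constraints by construction
(the solve lives in the reduced coordinates); the inter-tarsal contact rule
is a soft one-sided penalty activated lazily — a frame is re-solved with the
penalty only when the penalty-free solution leaves two tarsal ellipsoids
interpenetrating. Occluded (NaN) markers are dropped from the sum that frame
and never interpolated inside the solver.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from . import contact as _contact
from .errors import DimensionError, InsufficientDataError, TrialError
from .rhythms import RhythmSet, reduced_to_full
from .skeleton import JointState, KinematicTemplate, fk_full, point_jacobian

__all__ = [
    "MarkerTrial",
    "IkOptions",
    "IkSolution",
    "solve_frame",
    "solve_trial",
    "full_joint_angles",
]


@dataclass
class MarkerTrial:
    """Labelled 3-D marker trajectories for one stance phase.

    ``positions`` is (n_frames, n_markers, 3) in meters with NaN rows for
    occluded samples; ``events`` holds heel-strike and toe-off times (s).
    """

    marker_names: list[str]
    times: np.ndarray
    positions: np.ndarray
    events: dict[str, float] | None = None

    def __post_init__(self) -> None:
        self.marker_names = list(self.marker_names)
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        n, m = self.times.shape[0], len(self.marker_names)
        if self.positions.shape != (n, m, 3):
            raise DimensionError(
                f"positions shape {self.positions.shape} != ({n}, {m}, 3)"
            )
        if n > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if self.events is not None:
            hs, to = self.events.get("heel_strike"), self.events.get("toe_off")
            if hs is None or to is None:
                raise ValueError("events must define heel_strike and toe_off")
            if not (hs < to):
                raise ValueError("heel_strike must precede toe_off")
            if hs < self.times[0] - 1e-9 or to > self.times[-1] + 1e-9:
                raise ValueError("events outside the recorded time range")

    @property
    def n_frames(self) -> int:
        return self.times.shape[0]

    def frame(self, i: int) -> dict[str, np.ndarray]:
        return {m: self.positions[i, k] for k, m in enumerate(self.marker_names)}


@dataclass
class IkOptions:
    """Solver configuration (all defaults overridable)."""

    weights: dict[str, float] = field(default_factory=dict)  # default 1.0 each
    contact: bool = True
    contact_weight: float = 1e6
    grad_tol: float = 1e-8  # first-order optimality threshold for the flag
    step_tol: float = 1e-10
    max_iterations: int = 100
    gap_fill: int = 0  # pre-filter: interpolate occlusion gaps <= this many frames


@dataclass
class FrameDiagnostics:
    converged: bool
    residual_rms: float
    n_markers: int
    grad_norm: float
    n_evaluations: int
    contact_active: bool = False
    message: str = ""


@dataclass
class IkSolution:
    """Per-frame solved states plus bookkeeping; failed frames carry NaN."""

    times: np.ndarray
    root: np.ndarray  # (n, 6)
    q_reduced: np.ndarray  # (n, n_reduced)
    residual_rms: np.ndarray
    n_markers: np.ndarray
    converged: np.ndarray
    dof_labels: list[str]
    diagnostics: list[FrameDiagnostics]
    events: dict[str, float] | None = None
    separations: np.ndarray | None = None  # (n, n_pairs) if contact surfaces exist

    def state(self, i: int, rhythms: RhythmSet) -> JointState | None:
        if not np.all(np.isfinite(self.root[i])):
            return None
        return JointState(self.root[i], reduced_to_full(rhythms, self.q_reduced[i]))

    def states(self, rhythms: RhythmSet) -> list[JointState | None]:
        return [self.state(i, rhythms) for i in range(self.times.shape[0])]


def _marker_arrays(template, markers, weights):
    names, obs, w = [], [], []
    for m, p in markers.items():
        if m not in template.marker_owner:
            continue
        p = np.asarray(p, dtype=float)
        if not np.all(np.isfinite(p)):
            continue
        names.append(m)
        obs.append(p)
        w.append(float(weights.get(m, 1.0)))
    return names, np.array(obs, dtype=float), np.array(w, dtype=float)


def solve_frame(
    template: KinematicTemplate,
    rhythms: RhythmSet,
    markers: dict[str, np.ndarray],
    options: IkOptions | None = None,
    x_init: np.ndarray | None = None,
    contact_cache: dict | None = None,
) -> tuple[np.ndarray, FrameDiagnostics]:
    """Solve one frame; returns ``x = [root(6), q_reduced]`` and diagnostics.

    ``x_init`` warm-starts the search (zeros = neutral pose by default).
    """
    options = options or IkOptions()
    names, obs, w = _marker_arrays(template, markers, options.weights)
    n_red = rhythms.reduced_dim
    n_par = 6 + n_red
    needed = math.ceil(n_par / 3)
    if len(names) < needed:
        raise InsufficientDataError(
            f"{len(names)} visible markers, need at least {needed} "
            f"for {n_par} coordinates"
        )
    if np.any(w <= 0):
        raise ValueError("marker weights must be positive")
    sw = np.sqrt(np.repeat(w, 3))
    C = rhythms.coupling_matrix
    x0 = np.zeros(n_par) if x_init is None else np.asarray(x_init, dtype=float).copy()
    if x0.shape != (n_par,):
        raise DimensionError(f"x_init shape {x0.shape} != ({n_par},)")

    n_mark = len(names)
    seg_of = [template.marker_owner[m] for m in names]
    local = np.array(
        [template.segments[s].marker_points[m] for m, s in zip(names, seg_of)]
    )
    chain_mask = np.zeros((n_mark, template.total_dof), dtype=bool)
    for k, s in enumerate(seg_of):
        chain_mask[k, template.chain_dofs[s]] = True

    fk_memo: dict[bytes, tuple] = {}

    def fk_at(x):
        key = x.tobytes()
        hit = fk_memo.get(key)
        if hit is None:
            state = JointState(x[:6], reduced_to_full(rhythms, x[6:]))
            hit = (state, fk_full(template, state))
            if len(fk_memo) > 4:
                fk_memo.clear()
            fk_memo[key] = hit
        return hit

    def predicted(fk):
        p = np.empty((n_mark, 3))
        for k, s in enumerate(seg_of):
            R, t = fk.poses[s]
            p[k] = R @ local[k] + t
        return p

    def residuals(x):
        _, fk = fk_at(x)
        return sw * (predicted(fk) - obs).ravel()

    def jacobian(x):
        # geometric Jacobian: each rotational column is axis x (marker - center)
        _, fk = fk_at(x)
        p = predicted(fk)
        J = np.zeros((n_mark, 3, n_par))
        J[:, :, :3] = np.eye(3)
        r_root = p - fk.root_origin
        J[:, :, 5] = np.cross(fk.root_axes[0], r_root)
        J[:, :, 4] = np.cross(fk.root_axes[1], r_root)
        J[:, :, 3] = np.cross(fk.root_axes[2], r_root)
        cols = np.cross(
            fk.dof_axes[None, :, :], p[:, None, :] - fk.dof_centers[None, :, :]
        )
        cols[~chain_mask] = 0.0
        J[:, :, 6:] = cols.transpose(0, 2, 1) @ C
        return sw[:, None] * J.reshape(3 * n_mark, n_par)

    def run(extra_res=None, extra_jac=None):
        fun = residuals if extra_res is None else (
            lambda x: np.concatenate([residuals(x), extra_res(x)])
        )
        jac = jacobian if extra_jac is None else (
            lambda x: np.vstack([jacobian(x), extra_jac(x)])
        )
        return least_squares(
            fun,
            x0,
            jac=jac,
            method="lm",
            xtol=options.step_tol,
            ftol=1e-14,
            gtol=1e-14,
            max_nfev=options.max_iterations * 3,
        )

    contact_on = (
        options.contact and template.contact_pairs and template.contact_surfaces
    )
    try:
        res = run()
        contact_active = False
        if contact_on:
            state, fk = fk_at(res.x)
            penetrating = False
            for j, (a, b) in enumerate(template.contact_pairs):
                A = template.contact_surfaces[a].transformed(*fk.poses[a])
                B = template.contact_surfaces[b].transformed(*fk.poses[b])
                if _contact.ellipsoids_separated(A, B):
                    continue
                s = _contact.penetration_depth(
                    A, B, cache=contact_cache, cache_key=j
                )
                if s < 0.0:
                    penetrating = True
                    break
            if penetrating:
                contact_active = True
                swc = np.sqrt(options.contact_weight)

                def pen_res(x):
                    _, fk = fk_at(x)
                    out = np.zeros(len(template.contact_pairs))
                    for j, (a, b) in enumerate(template.contact_pairs):
                        s = _contact.penetration_depth(
                            template.contact_surfaces[a],
                            template.contact_surfaces[b],
                            fk.poses[a],
                            fk.poses[b],
                            cache=contact_cache,
                            cache_key=j,
                        )
                        out[j] = swc * max(0.0, -s)
                    return out

                def pen_jac(x):
                    _, fk = fk_at(x)
                    out = np.zeros((len(template.contact_pairs), n_par))
                    for j, (a, b) in enumerate(template.contact_pairs):
                        s, xa, xb = _contact.separation_details(
                            template.contact_surfaces[a],
                            template.contact_surfaces[b],
                            fk.poses[a],
                            fk.poses[b],
                            cache=contact_cache,
                            cache_key=j,
                        )
                        if s >= 0.0:
                            continue
                        gap = xa - xb
                        nrm = np.linalg.norm(gap)
                        if nrm < 1e-14:
                            continue
                        normal = gap / nrm
                        Ja = point_jacobian(template, fk, a, xa)
                        Jb = point_jacobian(template, fk, b, xb)
                        dsep_full = -(normal @ (Ja - Jb))  # d(sep)/dx, sep < 0
                        row = np.concatenate(
                            [dsep_full[:6], dsep_full[6:] @ C]
                        )
                        out[j] = -swc * row  # residual is -sep
                    return out

                x0 = res.x
                res = run(pen_res, pen_jac)
    except (np.linalg.LinAlgError, FloatingPointError) as exc:
        diag = FrameDiagnostics(
            converged=False,
            residual_rms=np.nan,
            n_markers=len(names),
            grad_norm=np.nan,
            n_evaluations=0,
            message=f"diverged: {exc}",
        )
        return np.full(n_par, np.nan), diag

    if not np.all(np.isfinite(res.x)):
        diag = FrameDiagnostics(
            converged=False,
            residual_rms=np.nan,
            n_markers=len(names),
            grad_norm=np.nan,
            n_evaluations=res.nfev,
            message="diverged to non-finite coordinates",
        )
        return np.full(n_par, np.nan), diag

    r = residuals(res.x)
    grad = jacobian(res.x).T @ r
    grad_norm = float(np.linalg.norm(grad))
    rms = float(np.sqrt(np.mean((r / sw) ** 2)))
    diag = FrameDiagnostics(
        converged=bool(res.status > 0 and grad_norm < options.grad_tol),
        residual_rms=rms,
        n_markers=len(names),
        grad_norm=grad_norm,
        n_evaluations=res.nfev,
        contact_active=contact_active,
        message=res.message,
    )
    return res.x, diag


def _fill_gaps(trial: MarkerTrial, max_gap: int) -> MarkerTrial:
    """Linearly interpolate occlusion gaps of at most ``max_gap`` frames."""
    pos = trial.positions.copy()
    n = trial.n_frames
    for k in range(pos.shape[1]):
        good = np.all(np.isfinite(pos[:, k, :]), axis=1)
        if good.all() or not good.any():
            continue
        idx = np.flatnonzero(~good)
        # contiguous runs of missing frames
        runs = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
        for run in runs:
            a, b = run[0] - 1, run[-1] + 1
            if a < 0 or b >= n or len(run) > max_gap:
                continue
            for j in run:
                frac = (trial.times[j] - trial.times[a]) / (
                    trial.times[b] - trial.times[a]
                )
                pos[j, k, :] = (1 - frac) * pos[a, k, :] + frac * pos[b, k, :]
    return MarkerTrial(trial.marker_names, trial.times, pos, trial.events)


def solve_trial(
    template: KinematicTemplate,
    rhythms: RhythmSet,
    trial: MarkerTrial,
    options: IkOptions | None = None,
    compute_separations: bool = False,
) -> IkSolution:
    """Solve every frame in time order, warm-starting from the previous frame."""
    options = options or IkOptions()
    extras = set(trial.marker_names) - set(template.marker_owner)
    if extras:
        warnings.warn(
            f"ignoring markers with no template attachment: {sorted(extras)}",
            stacklevel=2,
        )
    if options.gap_fill > 0:
        trial = _fill_gaps(trial, options.gap_fill)

    n = trial.n_frames
    n_red = rhythms.reduced_dim
    root = np.full((n, 6), np.nan)
    q_red = np.full((n, n_red), np.nan)
    rms = np.full(n, np.nan)
    nmk = np.zeros(n, dtype=int)
    conv = np.zeros(n, dtype=bool)
    diags: list[FrameDiagnostics] = []
    x_prev: np.ndarray | None = None
    n_failed = 0
    contact_cache: dict = {}
    for i in range(n):
        try:
            x, diag = solve_frame(
                template,
                rhythms,
                trial.frame(i),
                options,
                x_init=x_prev,
                contact_cache=contact_cache,
            )
        except InsufficientDataError as exc:
            diag = FrameDiagnostics(
                converged=False,
                residual_rms=np.nan,
                n_markers=0,
                grad_norm=np.nan,
                n_evaluations=0,
                message=str(exc),
            )
            x = np.full(6 + n_red, np.nan)
        diags.append(diag)
        if np.all(np.isfinite(x)):
            root[i] = x[:6]
            q_red[i] = x[6:]
            x_prev = x
        else:
            n_failed += 1
        rms[i] = diag.residual_rms
        nmk[i] = diag.n_markers
        conv[i] = diag.converged
    if n_failed == n:
        raise TrialError(
            "every frame failed to solve:\n"
            + "\n".join(f"frame {i}: {d.message}" for i, d in enumerate(diags))
        )
    sol = IkSolution(
        times=trial.times.copy(),
        root=root,
        q_reduced=q_red,
        residual_rms=rms,
        n_markers=nmk,
        converged=conv,
        dof_labels=template.dof_labels(),
        diagnostics=diags,
        events=dict(trial.events) if trial.events else None,
    )
    if compute_separations and template.contact_pairs:
        sol.separations = _contact.trial_separations(
            template, sol.states(rhythms)
        )
    return sol


def full_joint_angles(solution: IkSolution, rhythms: RhythmSet) -> pd.DataFrame:
    """Expand the solved reduced coordinates to all joint angles, in degrees.

    Returns a time-indexed DataFrame whose columns are the per-DoF labels
    '(parent) to (child) - (plane)'.
    """
    q_full = reduced_to_full(rhythms, solution.q_reduced)
    return pd.DataFrame(
        np.rad2deg(q_full),
        index=pd.Index(solution.times, name="time_s"),
        columns=solution.dof_labels,
    )
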