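"""Synthetic stance-phase gait: joint-angle curves, marker trajectories, cohorts.

The generator is the test bed standing in for motion-capture recordings: it
draws smooth per-DoF joint-angle curves over 0-100% stance, runs forward
kinematics on a (subject-scaled) template, attaches the 43-marker protocol
and adds seeded Gaussian noise plus contiguous occlusion gaps. The true
curves are returned alongside, so the generator + IK solver form a closed
round-trip oracle.

Curves are sums of up to a few raised-cosine bumps (amplitude in degrees,
timing and width in % stance) — C1-smooth, zero-valued outside their
support, and anchored so that the 0%-stance sample equals the specified
heel-strike value exactly. Default amplitudes are set near the mean
stance-phase ranges of motion reported for healthy adult walking (ankle
~17 deg plantarflexion range, first MTP ~40 deg, midfoot joints a few
degrees); they are stand-ins with the right magnitude and phase, not
digitized recordings.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import GenerationError
from .ik import MarkerTrial
from .rhythms import RhythmSet, build_default_rhythms, reduced_to_full
from .scaling import LandmarkSet, fit_tps, scale_template
from .skeleton import JointState, KinematicTemplate, default_template, fk_full

__all__ = [
    "Bump",
    "GaitCurveSpec",
    "CohortVariability",
    "GroundTruth",
    "Subject",
    "default_gait_spec",
    "generate_subject",
    "generate_cohort",
    "true_joint_curves",
    "true_rom",
]

Dof = tuple[str, str]

#: (amplitude [deg or m], center [% stance], width [% stance])
Bump = tuple[float, float, float]


def _bumps_at(bumps: list[Bump], t: np.ndarray) -> np.ndarray:
    """Sum of raised-cosine bumps evaluated at t (% stance)."""
    out = np.zeros_like(t, dtype=float)
    for amp, center, width in bumps:
        lo = center - width / 2.0
        phase = (t - lo) / width
        mask = (phase >= 0.0) & (phase <= 1.0)
        out[mask] += amp * 0.5 * (1.0 - np.cos(2.0 * np.pi * phase[mask]))
    return out


@dataclass
class GaitCurveSpec:
    """Stance-phase curve family plus noise/occlusion model for one subject."""

    curves: dict[Dof, list[Bump]] = field(default_factory=dict)  # degrees
    heel_strike_values: dict[Dof, float] = field(default_factory=dict)  # degrees
    root_curves: dict[str, list[Bump]] = field(default_factory=dict)  # m / degrees
    stance_duration: float = 0.7  # seconds
    n_frames: int = 101
    amplitude_scale: float = 1.0
    subject_scale: float = 1.0  # anatomical scale relative to the template
    noise_sd_mm: float = 1.0
    occlusion_rate: float = 0.02
    seed: int = 0

    def percent_grid(self) -> np.ndarray:
        return np.linspace(0.0, 100.0, self.n_frames)

    def curve_deg(self, dof: Dof, t_pct: np.ndarray) -> np.ndarray:
        """One DoF's true curve (degrees); exact heel-strike anchoring."""
        bumps = self.curves.get(dof, [])
        vals = self.amplitude_scale * _bumps_at(bumps, np.asarray(t_pct, float))
        at0 = self.amplitude_scale * _bumps_at(bumps, np.zeros(1))[0]
        return self.heel_strike_values.get(dof, 0.0) + vals - at0

    def root_pose(self, t_pct: np.ndarray) -> np.ndarray:
        """(n, 6) root pose [tx, ty, tz, rx, ry, rz]; rotations given in degrees."""
        t_pct = np.asarray(t_pct, dtype=float)
        out = np.zeros((t_pct.shape[0], 6))
        order = ("tx", "ty", "tz", "rx", "ry", "rz")
        for i, key in enumerate(order):
            vals = _bumps_at(self.root_curves.get(key, []), t_pct)
            out[:, i] = np.deg2rad(vals) if i >= 3 else vals
        return out


def default_gait_spec(seed: int = 0) -> GaitCurveSpec:
    """Nominal healthy-adult stance curves for the default rhythm set.

    Curves are defined on the independent coordinates; slaved DoF follow
    through the rhythm map. Signs: plantarflexion / inversion / adduction
    positive.
    """
    pf, inv, add = "plantarflexion", "inversion", "adduction"
    curves: dict[Dof, list[Bump]] = {
        ("talus", pf): [(-12.0, 45.0, 70.0), (5.0, 90.0, 20.0)],
        ("calcaneus", inv): [(-4.0, 30.0, 40.0), (8.0, 85.0, 35.0)],
        ("navicular", pf): [(-3.0, 40.0, 60.0), (4.0, 90.0, 22.0)],
        ("navicular", inv): [(-9.0, 60.0, 70.0)],  # eversion only
        ("navicular", add): [(7.0, 30.0, 45.0), (-7.0, 85.0, 30.0)],
        ("cuboid", pf): [(-6.0, 50.0, 60.0), (3.0, 90.0, 20.0)],
        ("cuboid", inv): [(-5.0, 40.0, 55.0), (3.0, 88.0, 22.0)],
        ("cuboid", add): [(6.0, 35.0, 50.0), (-4.0, 85.0, 28.0)],
        ("central_cuneiform", add): [(1.8, 60.0, 60.0)],
        ("lateral_cuneiform", add): [(1.3, 55.0, 60.0)],
        ("metatarsal_2", add): [(1.6, 70.0, 55.0)],
        ("metatarsal_3", add): [(2.1, 70.0, 55.0)],
        ("metatarsal_4", add): [(-6.4, 70.0, 55.0)],
        ("metatarsal_5", add): [(-5.5, 70.0, 55.0)],
        ("proximal_phalanx_1", pf): [(-20.0, 50.0, 60.0), (20.0, 95.0, 14.0)],
        ("proximal_phalanx_1", add): [(6.0, 40.0, 50.0), (-5.5, 85.0, 30.0)],
        ("proximal_phalanx_2", add): [(-5.0, 45.0, 50.0), (5.0, 88.0, 24.0)],
        ("proximal_phalanx_3", add): [(-6.0, 45.0, 50.0), (7.0, 88.0, 24.0)],
        ("proximal_phalanx_4", add): [(-5.0, 45.0, 50.0), (5.0, 88.0, 24.0)],
        ("proximal_phalanx_5", add): [(-7.0, 45.0, 50.0), (6.0, 88.0, 24.0)],
        ("distal_phalanx_1", pf): [(-10.0, 55.0, 55.0), (8.0, 92.0, 16.0)],
        ("central_phalanx_2", pf): [(-9.0, 55.0, 55.0), (6.0, 92.0, 16.0)],
        ("central_phalanx_3", pf): [(-12.0, 55.0, 55.0), (8.0, 92.0, 16.0)],
        ("central_phalanx_4", pf): [(-14.0, 55.0, 55.0), (9.0, 92.0, 16.0)],
        ("central_phalanx_5", pf): [(-12.0, 55.0, 55.0), (8.0, 92.0, 16.0)],
    }
    root_curves = {
        "tx": [(0.04, 100.0, 200.0)],
        "tz": [(0.008, 50.0, 100.0)],
        "rx": [(2.0, 50.0, 90.0)],
        "ry": [(-15.0, 100.0, 200.0)],  # shank rolls forward over the foot
        "rz": [(3.0, 60.0, 120.0)],
    }
    return GaitCurveSpec(curves=curves, root_curves=root_curves, seed=seed)


@dataclass
class GroundTruth:
    """True generating motion of one trial."""

    times: np.ndarray
    percent_stance: np.ndarray
    root: np.ndarray  # (n, 6)
    q_full: np.ndarray  # (n, n_dof), radians
    dof_labels: list[str]
    clean_positions: np.ndarray  # (n, n_markers, 3), noise-free markers
    marker_names: list[str]

    def angles_deg(self) -> pd.DataFrame:
        return pd.DataFrame(
            np.rad2deg(self.q_full),
            index=pd.Index(self.times, name="time_s"),
            columns=self.dof_labels,
        )


def true_joint_curves(
    spec: GaitCurveSpec,
    template: KinematicTemplate,
    rhythms: RhythmSet,
    t_pct: np.ndarray | None = None,
) -> np.ndarray:
    """Full joint-angle curves (radians) implied by the spec, (n, n_dof)."""
    t_pct = spec.percent_grid() if t_pct is None else np.asarray(t_pct, float)
    independent = [tuple(name.split(":")) for name in rhythms.reduced_names]
    for dof in spec.curves:
        if dof not in independent:
            raise GenerationError(
                f"curve specified for non-independent DoF {dof!r} "
                "(slaved by the active rhythms)"
            )
    q_red = np.column_stack(
        [np.deg2rad(spec.curve_deg(dof, t_pct)) for dof in independent]
    )
    q_full = reduced_to_full(rhythms, q_red)
    for (seg, angle), idx in template.dof_index.items():
        lo, hi = template.joints[seg].limits[
            template.joints[seg].angle_names.index(angle)
        ]
        if q_full[:, idx].min() < lo or q_full[:, idx].max() > hi:
            raise GenerationError(
                f"generated curve for {seg}:{angle} exceeds joint limits "
                f"[{np.rad2deg(lo):.0f}, {np.rad2deg(hi):.0f}] deg"
            )
    return q_full


def true_rom(
    spec: GaitCurveSpec,
    template: KinematicTemplate,
    rhythms: RhythmSet,
    n_grid: int = 201,
) -> dict[str, float]:
    """Range of motion (deg) of each DoF's true heel-strike-zeroed curve."""
    t = np.linspace(0.0, 100.0, n_grid)
    q = np.rad2deg(true_joint_curves(spec, template, rhythms, t))
    q = q - q[0]
    labels = template.dof_labels()
    return {lab: float(q[:, i].max() - q[:, i].min()) for i, lab in enumerate(labels)}


def _occlude(rng: np.random.Generator, mask: np.ndarray, rate: float) -> None:
    """Mark contiguous occlusion gaps in-place until ~rate of samples are masked."""
    n_frames, n_markers = mask.shape
    if rate <= 0:
        return
    target = rate * n_frames * n_markers
    guard = 0
    while mask.sum() < target and guard < 10 * n_markers:
        guard += 1
        k = int(rng.integers(n_markers))
        if mask[:, k].mean() > 0.3:  # never blind one marker for long
            continue
        start = int(rng.integers(n_frames))
        length = int(rng.integers(1, 6))
        mask[start : start + length, k] = True


def generate_subject(
    spec: GaitCurveSpec,
    template: KinematicTemplate | None = None,
    rhythms: RhythmSet | None = None,
) -> tuple[GroundTruth, MarkerTrial]:
    """One stance-phase trial: true curves + noisy, occluded marker trajectories."""
    template = template if template is not None else default_template()
    rhythms = rhythms if rhythms is not None else build_default_rhythms(template)
    rng = np.random.default_rng(spec.seed)
    t_pct = spec.percent_grid()
    times = t_pct / 100.0 * spec.stance_duration
    q_full = true_joint_curves(spec, template, rhythms, t_pct)
    root = spec.root_pose(t_pct)
    marker_names = template.marker_names
    n, m = len(times), len(marker_names)
    clean = np.empty((n, m, 3))
    for i in range(n):
        fk = fk_full(template, JointState(root[i], q_full[i]))
        for k, name in enumerate(marker_names):
            seg = template.marker_owner[name]
            R, t = fk.poses[seg]
            clean[i, k] = R @ template.segments[seg].marker_points[name] + t
    noisy = clean + rng.normal(0.0, spec.noise_sd_mm * 1e-3, size=clean.shape)
    occluded = np.zeros((n, m), dtype=bool)
    _occlude(rng, occluded, spec.occlusion_rate)
    noisy[occluded] = np.nan
    truth = GroundTruth(
        times=times,
        percent_stance=t_pct,
        root=root,
        q_full=q_full,
        dof_labels=template.dof_labels(),
        clean_positions=clean,
        marker_names=marker_names,
    )
    trial = MarkerTrial(
        marker_names=marker_names,
        times=times,
        positions=noisy,
        events={"heel_strike": float(times[0]), "toe_off": float(times[-1])},
    )
    return truth, trial


@dataclass
class CohortVariability:
    """Inter-subject and anatomical variability of a synthetic cohort."""

    amplitude_sd: float = 0.10  # multiplicative, per subject per DoF
    timing_sd_pct: float = 2.0  # % stance shift, per subject per DoF
    scale_low: float = 0.92  # uniform anatomical scale range
    scale_high: float = 1.08
    anisotropy_sd: float = 0.02  # per-axis deviation from uniform scale
    n_trials: int = 3


@dataclass
class Subject:
    subject_id: str
    spec: GaitCurveSpec
    scale_factor: float
    target_landmarks: LandmarkSet
    scaled_template: KinematicTemplate
    trials: list[MarkerTrial]
    truths: list[GroundTruth]


def _jitter_spec(
    spec: GaitCurveSpec, rng: np.random.Generator, var: CohortVariability
) -> GaitCurveSpec:
    curves = {}
    for dof, bumps in spec.curves.items():
        amp_f = max(0.5, 1.0 + rng.normal(0.0, var.amplitude_sd))
        shift = rng.normal(0.0, var.timing_sd_pct)
        curves[dof] = [(a * amp_f, c + shift, w) for a, c, w in bumps]
    return replace(spec, curves=curves)


def generate_cohort(
    n_subjects: int,
    base_spec: GaitCurveSpec | None = None,
    variability: CohortVariability | None = None,
    seed: int = 0,
    template: KinematicTemplate | None = None,
    rhythms: RhythmSet | None = None,
) -> list[Subject]:
    """A cohort of subjects, each with an anatomically scaled model and trials.

    Each subject gets a drawn anatomical scale (applied through the TPS
    scaling pipeline via synthetic target landmarks), per-subject amplitude
    and timing jitter, and ``n_trials`` trials with independent noise and
    occlusion draws.
    """
    if n_subjects < 2:
        raise ValueError("a cohort needs at least 2 subjects")
    base_spec = base_spec if base_spec is not None else default_gait_spec()
    variability = variability if variability is not None else CohortVariability()
    template = template if template is not None else default_template()
    rhythms = rhythms if rhythms is not None else build_default_rhythms(template)
    rng = np.random.default_rng(seed)
    source = LandmarkSet.from_template(template)
    subjects = []
    for s in range(n_subjects):
        scale = float(rng.uniform(variability.scale_low, variability.scale_high))
        axis_scale = scale * (1.0 + rng.normal(0.0, variability.anisotropy_sd, 3))
        target = LandmarkSet(source.names, source.positions * axis_scale)
        warp = fit_tps(source, target)
        scaled = scale_template(template, warp)
        spec_s = _jitter_spec(base_spec, rng, variability)
        spec_s = replace(spec_s, subject_scale=scale)
        trials, truths = [], []
        for t in range(variability.n_trials):
            trial_seed = int(rng.integers(0, 2**31 - 1))
            truth, trial = generate_subject(
                replace(spec_s, seed=trial_seed), scaled, rhythms
            )
            trials.append(trial)
            truths.append(truth)
        subjects.append(
            Subject(
                subject_id=f"S{s + 1:02d}",
                spec=spec_s,
                scale_factor=scale,
                target_landmarks=target,
                scaled_template=scaled,
                trials=trials,
                truths=truths,
            )
        )
    return subjects
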