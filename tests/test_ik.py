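"""Inverse kinematics: round trips, occlusion handling, weights, toy oracles."""
import numpy as np
import pytest

from footkin.errors import InsufficientDataError
from footkin.ik import (
    IkOptions,
    MarkerTrial,
    full_joint_angles,
    solve_frame,
    solve_trial,
)
from footkin.rhythms import identity_rhythms, reduced_to_full
from footkin.skeleton import (
    JointSpec,
    JointState,
    KinematicTemplate,
    Segment,
    marker_positions,
)
from footkin.synthetic import default_gait_spec, generate_subject

OPTS = IkOptions(contact=False)


def random_feasible_x(rhythms, rng, q_scale=0.15):
    root = np.concatenate([rng.uniform(-0.05, 0.05, 3), rng.uniform(-0.2, 0.2, 3)])
    return np.concatenate([root, rng.uniform(-q_scale, q_scale, rhythms.reduced_dim)])


class TestSolveFrame:
    def test_neutral_fixed_point(self, template, rhythms):
        markers = marker_positions(template, JointState.zeros(template))
        x, diag = solve_frame(template, rhythms, markers, OPTS)
        assert np.abs(x).max() < 1e-10
        assert diag.residual_rms < 1e-10
        assert diag.converged

    def test_round_trip_from_perturbed_start(self, template, rhythms, rng):
        x_true = random_feasible_x(rhythms, rng)
        state = JointState(x_true[:6], reduced_to_full(rhythms, x_true[6:]))
        markers = marker_positions(template, state)
        x0 = x_true + rng.normal(0, 0.02, x_true.size)
        x, diag = solve_frame(template, rhythms, markers, OPTS, x_init=x0)
        assert np.abs(x - x_true).max() < 1e-3
        assert diag.residual_rms < 1e-9
        assert diag.grad_norm < 1e-8

    def test_round_trip_without_rhythms(self, template, free_rhythms, rng):
        """Disabling all rhythms still identifies the full 43-DoF model."""
        x_true = random_feasible_x(free_rhythms, rng, q_scale=0.1)
        state = JointState(x_true[:6], x_true[6:])
        markers = marker_positions(template, state)
        x, diag = solve_frame(
            template, free_rhythms, markers, OPTS, x_init=x_true + 0.01
        )
        assert np.abs(x - x_true).max() < 1e-3
        assert diag.residual_rms < 1e-9

    def test_rhythm_equivalence_on_noiseless_rhythmic_motion(
        self, template, rhythms, free_rhythms, rng
    ):
        """Rhythm-free IK agrees with rhythm-constrained IK when the true
        motion satisfies the rhythms."""
        x_true = random_feasible_x(rhythms, rng)
        q_full = reduced_to_full(rhythms, x_true[6:])
        markers = marker_positions(template, JointState(x_true[:6], q_full))
        x_r, _ = solve_frame(
            template, rhythms, markers, OPTS, x_init=x_true + 0.005
        )
        x_free_init = np.concatenate([x_true[:6], q_full]) + 0.005
        x_f, _ = solve_frame(
            template, free_rhythms, markers, OPTS, x_init=x_free_init
        )
        q_from_rhythms = reduced_to_full(rhythms, x_r[6:])
        assert np.abs(q_from_rhythms - x_f[6:]).max() < 1e-5

    def test_insufficient_markers_raises(self, template, rhythms):
        markers = marker_positions(template, JointState.zeros(template))
        few = dict(list(markers.items())[:5])
        with pytest.raises(InsufficientDataError):
            solve_frame(template, rhythms, few, OPTS)

    def test_occluded_markers_dropped(self, template, rhythms):
        markers = marker_positions(template, JointState.zeros(template))
        markers["TOE3_TIP"] = np.array([np.nan] * 3)
        x, diag = solve_frame(template, rhythms, markers, OPTS)
        assert diag.n_markers == 42
        assert np.abs(x).max() < 1e-8


def rotz_point(angle, local):
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]]) @ np.asarray(local, float)


class TestOneDofToy:
    """Single revolute joint; the base is pinned by heavily weighted anchors."""

    BASE_ANCHORS = {
        "R1": np.array([0.0, 0.0, 1.0]),
        "R2": np.array([0.0, -1.0, 0.0]),
        "R3": np.array([1.0, 0.0, 1.0]),
    }
    ARM_LOCALS = {"A": np.array([1.0, 0.0, 0.0]), "B": np.array([0.0, 1.0, 0.0])}

    def build(self):
        segments = [
            Segment("base", None, marker_points=self.BASE_ANCHORS),
            Segment("arm", "base", marker_points=self.ARM_LOCALS),
        ]
        joints = [JointSpec("arm", "revolute", [[0, 0, 1]], ("adduction",))]
        return KinematicTemplate(segments, joints)

    def observations(self, true, delta):
        # arm markers placed inconsistently at angles true+delta and true-delta
        obs = {n: p.copy() for n, p in self.BASE_ANCHORS.items()}
        obs["A"] = rotz_point(true + delta, self.ARM_LOCALS["A"])
        obs["B"] = rotz_point(true - delta, self.ARM_LOCALS["B"])
        return obs

    def solve(self, markers, weights, x_init):
        t = self.build()
        r = identity_rhythms(t)
        anchor_w = {n: 1e8 for n in self.BASE_ANCHORS}
        x, diag = solve_frame(
            t,
            r,
            markers,
            IkOptions(contact=False, weights={**anchor_w, **weights}),
            x_init=x_init,
        )
        return t, x, diag

    def test_inconsistent_markers_bisect_via_grid_search(self):
        """Equal weights: the LSQ angle matches a dense grid search (bisection)."""
        true, delta = 0.6, 0.1
        markers = self.observations(true, delta)

        def cost(angle):
            return sum(
                np.sum((rotz_point(angle, l) - markers[n]) ** 2)
                for n, l in self.ARM_LOCALS.items()
            )

        grid = np.linspace(0.0, 1.2, 24001)
        best_grid = grid[np.argmin([cost(a) for a in grid])]
        _, x, _ = self.solve(
            markers, {}, np.concatenate([np.zeros(6), [0.3]])
        )
        assert np.abs(x[:6]).max() < 1e-6  # base stays pinned
        assert x[6] == pytest.approx(best_grid, abs=1e-3)
        assert best_grid == pytest.approx(true, abs=1e-4)  # symmetric bisection

    def test_weight_monotonicity(self):
        """Raising one marker's weight cannot increase that marker's residual."""
        true, delta = 0.4, 0.12
        markers = self.observations(true, delta)
        prev = None
        for wa in [1.0, 4.0, 16.0, 64.0]:
            t, x, _ = self.solve(
                markers, {"A": wa}, np.concatenate([np.zeros(6), [true]])
            )
            state = JointState(x[:6], x[6:])
            res_a = np.linalg.norm(marker_positions(t, state)["A"] - markers["A"])
            if prev is not None:
                assert res_a <= prev + 1e-12
            prev = res_a


@pytest.fixture(scope="module")
def noiseless(template, rhythms):
    from dataclasses import replace

    spec = replace(default_gait_spec(seed=11), noise_sd_mm=0.0, occlusion_rate=0.0)
    truth, trial = generate_subject(spec, template, rhythms)
    return spec, truth, trial


class TestSolveTrial:
    def test_noiseless_trial_recovers_generating_curves(
        self, template, rhythms, noiseless
    ):
        _, truth, trial = noiseless
        sol = solve_trial(template, rhythms, trial, OPTS)
        ang = full_joint_angles(sol, rhythms).to_numpy()
        err = np.abs(ang - np.rad2deg(truth.q_full))
        assert np.nanmax(err) < 0.1
        assert sol.converged.all()

    def test_reversed_frame_order_gives_same_solutions(
        self, template, rhythms, noiseless
    ):
        """Warm-start independence on noiseless data."""
        _, _, trial = noiseless
        sol_fwd = solve_trial(template, rhythms, trial, OPTS)
        rev = MarkerTrial(
            trial.marker_names,
            trial.times,
            trial.positions[::-1].copy(),
            trial.events,
        )
        sol_rev = solve_trial(template, rhythms, rev, OPTS)
        assert (
            np.abs(sol_rev.q_reduced[::-1] - sol_fwd.q_reduced).max() < 1e-6
        )

    def test_occlusion_bookkeeping(self, template, rhythms, noiseless):
        _, _, trial = noiseless
        pos = trial.positions.copy()
        k = trial.marker_names.index("NAV_DORS")
        pos[:, k, :] = np.nan  # one marker fully occluded
        t2 = MarkerTrial(trial.marker_names, trial.times, pos, trial.events)
        sol = solve_trial(template, rhythms, t2, OPTS)
        assert (sol.n_markers == 42).all()
        assert np.isfinite(sol.q_reduced).all()

    def test_gap_fill_prefilter(self, template, rhythms, noiseless):
        _, _, trial = noiseless
        pos = trial.positions.copy()
        k = trial.marker_names.index("MT2_HEAD")
        pos[10:13, k, :] = np.nan  # 3-frame gap, fillable
        t2 = MarkerTrial(trial.marker_names, trial.times, pos, trial.events)
        sol = solve_trial(
            template, rhythms, t2, IkOptions(contact=False, gap_fill=5)
        )
        assert (sol.n_markers == 43).all()

    def test_extra_marker_warned_and_ignored(self, template, rhythms, noiseless):
        _, _, trial = noiseless
        pos = np.concatenate(
            [trial.positions, np.zeros((trial.n_frames, 1, 3))], axis=1
        )
        t2 = MarkerTrial(
            trial.marker_names + ["UNKNOWN"], trial.times, pos, trial.events
        )
        with pytest.warns(UserWarning, match="UNKNOWN"):
            sol = solve_trial(template, rhythms, t2, OPTS)
        assert (sol.n_markers == 43).all()

    def test_slaved_series_follow_masters_framewise(
        self, template, rhythms, noiseless
    ):
        _, _, trial = noiseless
        sol = solve_trial(template, rhythms, trial, OPTS)
        ang = full_joint_angles(sol, rhythms)
        dip = ang["Central Phalange 3 to Distal Phalange 3 - Plantarflexion"]
        pip = ang["Proximal Phalange 3 to Central Phalange 3 - Plantarflexion"]
        np.testing.assert_allclose(dip, 1.0 * pip, atol=1e-12)


class TestMarkerTrialValidation:
    def test_non_increasing_times_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            MarkerTrial(["A"], [0.0, 0.0], np.zeros((2, 1, 3)))

    def test_bad_events_rejected(self):
        with pytest.raises(ValueError, match="precede"):
            MarkerTrial(
                ["A"],
                [0.0, 1.0],
                np.zeros((2, 1, 3)),
                events={"heel_strike": 0.9, "toe_off": 0.2},
            )

    def test_events_outside_range_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            MarkerTrial(
                ["A"],
                [0.0, 1.0],
                np.zeros((2, 1, 3)),
                events={"heel_strike": 0.0, "toe_off": 2.0},
            )
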