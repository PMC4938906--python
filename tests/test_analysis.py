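"""Heel-strike zeroing, percent-stance resampling, RoM summaries and COV25."""
import numpy as np
import pandas as pd
import pytest

from footkin.analysis import (
    STANCE_GRID,
    CurveEnsemble,
    cov25,
    resample_stance,
    rom_summary,
    zero_at_heel_strike,
)
from footkin.errors import UndefinedStatisticError


def make_ensemble(curves_by_participant, dof="J - Plantarflexion"):
    ens = CurveEnsemble()
    for p, trials in curves_by_participant.items():
        for t, c in enumerate(trials):
            ens.add(p, f"T{t}", dof, np.asarray(c, float), already_on_grid=True)
    return ens


class TestZeroing:
    def test_constant_curve_becomes_zero(self):
        out = zero_at_heel_strike(np.full(201, 7.0))
        assert np.all(out == 0.0)

    def test_first_sample_exactly_zero(self):
        out = zero_at_heel_strike(np.linspace(5.0, 25.0, 201))
        assert out[0] == 0.0
        assert out[-1] == pytest.approx(20.0)

    def test_idempotent(self, rng):
        c = rng.normal(size=201)
        once = zero_at_heel_strike(c)
        np.testing.assert_array_equal(zero_at_heel_strike(once), once)

    def test_empty_curve_raises(self):
        with pytest.raises(ValueError):
            zero_at_heel_strike(np.array([]))


class TestResampling:
    def test_linear_ramp_is_exact(self):
        t = np.linspace(0.0, 1.0, 37)
        out = resample_stance(t, 3.0 * t, 0.0, 1.0)
        np.testing.assert_allclose(out, 3.0 * STANCE_GRID / 100.0, atol=1e-12)

    def test_already_on_grid_unchanged(self, rng):
        t = STANCE_GRID / 100.0
        v = rng.normal(size=201)
        np.testing.assert_allclose(resample_stance(t, v, 0.0, 1.0), v, atol=1e-12)

    def test_sine_matches_closed_form(self):
        t = np.linspace(0.0, 0.8, 801)  # 1 kHz sampling
        v = np.sin(2 * np.pi * 1.3 * t)
        out = resample_stance(t, v, 0.1, 0.7)
        grid_t = 0.1 + STANCE_GRID / 100.0 * 0.6
        np.testing.assert_allclose(out, np.sin(2 * np.pi * 1.3 * grid_t), atol=1e-5)

    def test_events_outside_span_raise(self):
        t = np.linspace(0.0, 1.0, 11)
        with pytest.raises(ValueError):
            resample_stance(t, t, -0.5, 0.9)
        with pytest.raises(ValueError):
            resample_stance(t, t, 0.5, 0.2)

    def test_gap_in_native_samples_stays_missing(self):
        t = np.linspace(0.0, 1.0, 101)
        v = np.sin(t)
        v[40:45] = np.nan
        out = resample_stance(t, v, 0.0, 1.0)
        # grid points strictly inside the gap's valid bracket are masked;
        # 45.0% coincides with the first valid sample again
        assert np.isnan(out[(STANCE_GRID > 39.5) & (STANCE_GRID < 44.6)]).all()
        assert np.isfinite(out[STANCE_GRID < 38]).all()
        assert np.isfinite(out[STANCE_GRID >= 45.0]).all()


class TestRomSummary:
    def test_single_triangle_curve(self):
        c = np.concatenate([np.linspace(0, 10, 101), np.linspace(10, 0, 100)])
        s = rom_summary(make_ensemble({"P1": [c]}))
        row = s.iloc[0]
        assert row.mean_rom == row.max_rom == row.min_rom == pytest.approx(10.0)
        assert row.max_angle == pytest.approx(10.0)
        assert row.min_angle == pytest.approx(0.0)

    def test_two_participants_rom_statistics(self):
        up = np.linspace(0, 1, 201)
        s = rom_summary(make_ensemble({"P1": [10 * up], "P2": [20 * up]}))
        row = s.iloc[0]
        assert row.mean_rom == pytest.approx(15.0)
        assert row.max_rom == pytest.approx(20.0)
        assert row.min_rom == pytest.approx(10.0)

    def test_trials_averaged_before_rom(self):
        up = np.linspace(0, 1, 201)
        # two trials 8 and 12 deg: participant mean curve has RoM 10
        s = rom_summary(make_ensemble({"P1": [8 * up, 12 * up]}))
        assert s.iloc[0].mean_rom == pytest.approx(10.0)

    def test_matches_brute_force_on_random_ensembles(self, rng):
        """Vector implementation equals an explicit loop-by-loop recomputation."""
        for _ in range(10):
            n_p, n_t = int(rng.integers(2, 5)), int(rng.integers(1, 4))
            data = {
                f"P{i}": [
                    zero_at_heel_strike(rng.normal(0, 5, 201)) for _ in range(n_t)
                ]
                for i in range(n_p)
            }
            ens = make_ensemble(data)
            s = rom_summary(ens).iloc[0]
            means = {p: sum(ts) / len(ts) for p, ts in data.items()}
            roms = [max(m) - min(m) for m in means.values()]
            assert s.mean_rom == pytest.approx(sum(roms) / len(roms))
            assert s.max_rom == pytest.approx(max(roms))
            assert s.min_rom == pytest.approx(min(roms))
            assert s.max_angle == pytest.approx(max(max(m) for m in means.values()))
            assert s.min_angle == pytest.approx(min(min(m) for m in means.values()))

    def test_rom_ordering_invariant(self, rng):
        for _ in range(5):
            data = {
                f"P{i}": [zero_at_heel_strike(rng.normal(0, 3, 201))]
                for i in range(4)
            }
            s = rom_summary(make_ensemble(data)).iloc[0]
            assert s.min_rom <= s.mean_rom <= s.max_rom
            assert s.min_angle <= 0.0 <= s.max_angle

    def test_empty_ensemble_raises(self):
        with pytest.raises(ValueError):
            rom_summary(CurveEnsemble())


class TestCov25:
    def test_identical_curves_give_100(self):
        c = zero_at_heel_strike(np.sin(STANCE_GRID / 10.0) * 5)
        ens = make_ensemble({"P1": [c], "P2": [c.copy()], "P3": [c.copy()]})
        assert cov25(ens, ens.dof_labels[0]) == 100.0

    def test_constant_offset_below_threshold_gives_100(self):
        """Two curves offset by 0.3*RoM: sd/RoM = 0.3/sqrt(2) ~ 0.212 < 0.25."""
        base = zero_at_heel_strike(np.sin(STANCE_GRID / 16.0) * 10)
        rom_single = base.max() - base.min()
        offset = 0.3 * rom_single
        ens = make_ensemble({"P1": [base], "P2": [base + offset]})
        # full RoM across participant means includes the offset
        full_rom = (base + offset).max() - base.min()
        expected_ratio = (offset / np.sqrt(2)) / full_rom
        assert expected_ratio < 0.25
        assert cov25(ens, ens.dof_labels[0]) == 100.0

    def test_toy_table_matches_hand_computation(self):
        # 3 participants x 4 steps; remaining grid points identical
        rows = np.zeros((3, 201))
        rows[0, :4] = [0.0, 1.0, 4.0, 0.0]
        rows[1, :4] = [0.0, 2.0, 8.0, 0.0]
        rows[2, :4] = [0.0, 3.0, 12.0, 0.0]
        ens = CurveEnsemble()
        for i, r in enumerate(rows):
            ens.add(f"P{i}", "T0", "J", r, already_on_grid=True)
        # full RoM = 12; sd at steps: 0, 1, 4, 0, then 0 at the rest
        # ratios: 0, 1/12, 4/12 (>0.25), 0, ... -> 200/201 below threshold
        expected = 100.0 * 200 / 201
        assert cov25(ens, "J") == pytest.approx(expected)

    def test_invariant_to_common_offset_and_relabeling(self, rng):
        base = {
            f"P{i}": [zero_at_heel_strike(rng.normal(0, 4, 201))] for i in range(4)
        }
        ens1 = make_ensemble(base)
        v1 = cov25(ens1, ens1.dof_labels[0])
        shifted = {
            f"Q{9 - i}": [c + 3.0 for c in cs]
            for i, (_, cs) in enumerate(base.items())
        }
        ens2 = make_ensemble(shifted)
        assert cov25(ens2, ens2.dof_labels[0]) == v1

    def test_single_participant_raises(self):
        ens = make_ensemble({"P1": [np.zeros(201)]})
        with pytest.raises(UndefinedStatisticError):
            cov25(ens, ens.dof_labels[0])

    def test_zero_rom_raises(self):
        ens = make_ensemble({"P1": [np.zeros(201)], "P2": [np.zeros(201)]})
        with pytest.raises(UndefinedStatisticError, match="RoM"):
            cov25(ens, ens.dof_labels[0])

    def test_per_trial_population_flag(self):
        """Trial-to-trial spread counts only under per_trial=True."""
        base = zero_at_heel_strike(np.sin(STANCE_GRID / 12.0) * 8)
        # amplitude disagreement between trials survives heel-strike zeroing
        ens = make_ensemble(
            {"P1": [0.1 * base, 1.9 * base], "P2": [0.1 * base, 1.9 * base]}
        )
        dof = ens.dof_labels[0]
        # participant means coincide -> zero spread across participants -> 100
        assert cov25(ens, dof) == 100.0
        # pooled trial curves: compare to a direct step-by-step computation
        M = np.vstack([0.1 * base, 1.9 * base, 0.1 * base, 1.9 * base])
        expected = 100.0 * np.mean(
            np.std(M, axis=0, ddof=1) / (M.max() - M.min()) < 0.25
        )
        got = cov25(ens, dof, per_trial=True)
        assert got == pytest.approx(expected)
        assert got < 100.0

    def test_steps_missing_any_participant_excluded(self):
        a = zero_at_heel_strike(np.sin(STANCE_GRID / 8.0) * 6)
        b = a + 10.0  # large offset: ratio above threshold where evaluated
        b = zero_at_heel_strike(b)  # re-zero; curves equal again
        c = a.copy()
        c[100:] = np.nan  # participant 3 missing half the stance
        d = a + 5.0 * (STANCE_GRID >= 50)  # diverges in the missing half
        ens = CurveEnsemble()
        ens.add("P1", "T0", "J", a, already_on_grid=True)
        ens.add("P2", "T0", "J", d, already_on_grid=True)
        ens.add("P3", "T0", "J", c, already_on_grid=True)
        # evaluated steps are only 0..99 where all three agree or differ mildly
        val = cov25(ens, "J")
        assert 0.0 <= val <= 100.0


class TestEnsembleFromTrialFrames:
    def test_add_trial_frame_resamples_and_zeroes(self):
        times = np.linspace(0.0, 0.7, 71)
        df = pd.DataFrame(
            {"A - Plantarflexion": 5.0 + 10.0 * times / 0.7},
            index=pd.Index(times, name="time_s"),
        )
        ens = CurveEnsemble()
        ens.add_trial_frame("P1", "T1", df, heel_strike=0.0, toe_off=0.7)
        curve = ens.curves[("P1", "T1", "A - Plantarflexion")]
        assert curve[0] == 0.0
        assert curve[-1] == pytest.approx(10.0)
        assert curve.shape == (201,)
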