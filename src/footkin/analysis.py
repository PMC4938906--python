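"""Stance-phase curve statistics: zeroing, resampling, RoM summaries, COV25.

All angle curves are expressed relative to their heel-strike value (so every
curve starts at 0 deg and ranges of motion are comparable across subjects
with different neutral postures), then resampled onto the canonical grid of
201 samples at 0.5% of stance phase.

Per DoF, trials are first averaged within each participant; the participant-
mean curves then yield the range of motion (max - min) per participant, the
mean/max/min RoM across participants, the extreme joint angles, and COV25.

COV25 is an adapted coefficient of variation for curves that oscillate
around zero: at every stance-phase step where all participants have data,
the inter-participant standard deviation is divided by the joint's full
range of motion (instead of the mean, which would blow up near zero); COV25
is the percentage of evaluated steps at which this ratio is below 0.25.
100 means low inter-subject variance, 0 high variance.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import UndefinedStatisticError

__all__ = [
    "STANCE_GRID",
    "CurveEnsemble",
    "zero_at_heel_strike",
    "resample_stance",
    "rom_summary",
    "cov25",
]

#: canonical percent-stance grid: 0 to 100% in steps of 0.5%
STANCE_GRID = np.linspace(0.0, 100.0, 201)
N_GRID = STANCE_GRID.shape[0]


def zero_at_heel_strike(curve: np.ndarray) -> np.ndarray:
    """Subtract the heel-strike (first) sample; output[0] is exactly 0."""
    c = np.asarray(curve, dtype=float)
    if c.size == 0:
        raise ValueError("empty curve")
    out = c - c[0]
    out[0] = 0.0
    return out


def resample_stance(
    times: np.ndarray,
    values: np.ndarray,
    heel_strike: float,
    toe_off: float,
) -> np.ndarray:
    """Linear interpolation onto the 201-point percent-stance grid."""
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.shape != values.shape:
        raise ValueError("times and values must have equal shape")
    if not heel_strike < toe_off:
        raise ValueError("heel_strike must precede toe_off")
    if heel_strike < times[0] - 1e-9 or toe_off > times[-1] + 1e-9:
        raise ValueError("gait events outside the recorded time span")
    grid_t = heel_strike + STANCE_GRID / 100.0 * (toe_off - heel_strike)
    finite = np.isfinite(values)
    if finite.sum() < 2:
        return np.full(N_GRID, np.nan)
    out = np.interp(grid_t, times[finite], values[finite])
    # do not invent data across interior gaps: mask grid points whose
    # bracketing native samples are missing
    if not finite.all():
        bad = ~finite
        for a in np.flatnonzero(bad):
            lo = times[a - 1] if a > 0 else -np.inf
            hi = times[a + 1] if a < times.shape[0] - 1 else np.inf
            out[(grid_t > lo) & (grid_t < hi)] = np.nan
    return out


@dataclass
class CurveEnsemble:
    """Angle curves on the canonical grid, keyed by (participant, trial, dof)."""

    curves: dict[tuple[str, str, str], np.ndarray] = field(default_factory=dict)

    def add(
        self,
        participant: str,
        trial: str,
        dof_label: str,
        curve: np.ndarray,
        already_on_grid: bool = False,
        times: np.ndarray | None = None,
        heel_strike: float | None = None,
        toe_off: float | None = None,
    ) -> None:
        """Add one curve; raw time series are resampled then zeroed."""
        c = np.asarray(curve, dtype=float)
        if not already_on_grid:
            c = resample_stance(times, c, heel_strike, toe_off)
        if c.shape != (N_GRID,):
            raise ValueError(f"curve must have {N_GRID} samples, got {c.shape}")
        self.curves[(participant, trial, dof_label)] = zero_at_heel_strike(c)

    def add_trial_frame(
        self,
        participant: str,
        trial: str,
        angles: pd.DataFrame,
        heel_strike: float,
        toe_off: float,
    ) -> None:
        """Add every DoF column of a time-indexed angle DataFrame (degrees)."""
        times = angles.index.to_numpy(dtype=float)
        for dof_label in angles.columns:
            self.add(
                participant,
                trial,
                dof_label,
                angles[dof_label].to_numpy(dtype=float),
                times=times,
                heel_strike=heel_strike,
                toe_off=toe_off,
            )

    @property
    def participants(self) -> list[str]:
        return sorted({p for p, _, _ in self.curves})

    @property
    def dof_labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for _, _, d in self.curves:
            seen.setdefault(d)
        return list(seen)

    def participant_mean(self, participant: str, dof_label: str) -> np.ndarray:
        """Across-trial mean curve (NaN-tolerant per step)."""
        stack = [
            c
            for (p, _, d), c in self.curves.items()
            if p == participant and d == dof_label
        ]
        if not stack:
            raise KeyError(f"no curves for ({participant!r}, {dof_label!r})")
        with warnings.catch_warnings():
            # steps missing in every trial stay NaN (explicit, not imputed)
            warnings.simplefilter("ignore", category=RuntimeWarning)
            return np.nanmean(np.vstack(stack), axis=0)


def cov25(
    ensemble: CurveEnsemble,
    dof_label: str,
    threshold: float = 0.25,
    per_trial: bool = False,
) -> float:
    """COV25 (percent in [0, 100]) for one DoF.

    Evaluated only at steps where every curve has data; the ratio uses the
    sample standard deviation (n-1) across participant-mean curves over the
    joint's full RoM; strict inequality at the threshold. ``per_trial=True``
    pools individual trial curves into the spread instead of averaging
    trials within participant first.
    """
    participants = ensemble.participants
    if len(participants) < 2:
        raise UndefinedStatisticError("COV25 needs at least 2 participants")
    if per_trial:
        M = np.vstack(
            [c for (_, _, d), c in ensemble.curves.items() if d == dof_label]
        )
    else:
        M = np.vstack(
            [ensemble.participant_mean(p, dof_label) for p in participants]
        )
    valid = np.all(np.isfinite(M), axis=0)
    if not valid.any():
        raise UndefinedStatisticError(
            f"no stance-phase step has data for all participants ({dof_label})"
        )
    rom = np.nanmax(M) - np.nanmin(M)
    if rom <= 0.0:
        raise UndefinedStatisticError(
            f"full RoM of {dof_label!r} is zero; COV25 undefined"
        )
    sd = np.std(M[:, valid], axis=0, ddof=1)
    return float(100.0 * np.mean(sd / rom < threshold))


def rom_summary(
    ensemble: CurveEnsemble, cov_threshold: float = 0.25
) -> pd.DataFrame:
    """Per-DoF summary: mean/max/min RoM, extreme angles, COV25 (degrees, %).

    RoM is computed on each participant's across-trial mean curve; extreme
    joint angles are taken over the participant-mean curves.
    """
    if not ensemble.curves:
        raise ValueError("empty ensemble")
    participants = ensemble.participants
    rows = {}
    for dof in ensemble.dof_labels:
        means = [ensemble.participant_mean(p, dof) for p in participants]
        roms = np.array([np.nanmax(m) - np.nanmin(m) for m in means])
        stacked = np.vstack(means)
        try:
            c25 = cov25(ensemble, dof, cov_threshold)
        except UndefinedStatisticError:
            c25 = np.nan
        rows[dof] = {
            "mean_rom": float(np.mean(roms)),
            "max_rom": float(np.max(roms)),
            "min_rom": float(np.min(roms)),
            "max_angle": float(np.nanmax(stacked)),
            "min_angle": float(np.nanmin(stacked)),
            "cov25": c25,
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "dof"
    return out
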