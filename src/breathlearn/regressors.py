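"""Stimulus-space transforms, valence splits and model-based event tables.

Fitted belief trajectories live in contingency space; here they are mapped
back to stimulus space (1 = maximal prediction of "no resistance"), split
by valence into prediction-certainty and prediction-error magnitudes, and
emitted as BIDS-style event tables (onset / duration / trial_type /
modulation) ready for external neuroimaging software. No convolution or
GLM estimation happens here.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .learning_models import BeliefTrajectory
from .task_sim import TaskSchedule

__all__ = [
    "StimulusSpaceTrajectory",
    "to_stimulus_space",
    "split_certainty",
    "split_prediction_error",
    "REGRESSOR_NAMES",
    "build_event_table",
    "write_three_column",
    "select_representative",
    "ValidationResult",
    "validate_unseen",
]


@dataclass(frozen=True)
class StimulusSpaceTrajectory:
    """Trajectory in stimulus space with valence-split magnitudes.

    The splits are exhaustive and exclusive:
    ``v_stim = 0.5 + v_pos - v_neg`` and
    ``delta_stim = delta_pos - delta_neg`` hold exactly on every trial.
    """

    v_stim: np.ndarray
    delta_stim: np.ndarray
    v_pos: np.ndarray
    v_neg: np.ndarray
    delta_pos: np.ndarray
    delta_neg: np.ndarray

    def __len__(self) -> int:
        return self.v_stim.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial": np.arange(1, len(self) + 1),
                "v_stim": self.v_stim,
                "delta_stim": self.delta_stim,
                "v_pos": self.v_pos,
                "v_neg": self.v_neg,
                "delta_pos": self.delta_pos,
                "delta_neg": self.delta_neg,
            }
        )


def split_certainty(v_stim: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split prediction certainty by valence around maximal uncertainty.

    ``v_pos = v_stim - 0.5`` where ``v_stim > 0.5`` (no-resistance
    predicted), ``v_neg = 0.5 - v_stim`` where ``v_stim < 0.5``; a trial at
    exactly 0.5 contributes zero to both streams (boundary rule, keeps the
    reconstruction identity exact).
    """
    v_stim = np.asarray(v_stim, dtype=float)
    v_pos = np.where(v_stim > 0.5, v_stim - 0.5, 0.0)
    v_neg = np.where(v_stim < 0.5, 0.5 - v_stim, 0.0)
    return v_pos, v_neg


def split_prediction_error(delta_stim: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split prediction errors by valence: magnitudes of the positive
    (no-resistance) and negative (resistance) deviations from zero."""
    delta_stim = np.asarray(delta_stim, dtype=float)
    delta_pos = np.where(delta_stim > 0, delta_stim, 0.0)
    delta_neg = np.where(delta_stim < 0, -delta_stim, 0.0)
    return delta_pos, delta_neg


def to_stimulus_space(
    trajectory: BeliefTrajectory, cues: np.ndarray
) -> StimulusSpaceTrajectory:
    """Back-transform a contingency-space trajectory given the cue sequence.

    ``v_stim = v`` on cue-1 trials and ``1 - v`` on cue-2 trials (and the
    prediction error flips sign on cue-2 trials), so the result is
    invariant to the contingency-coding convention.
    """
    cues = np.asarray(cues, dtype=int)
    if cues.size != len(trajectory):
        raise ValueError(
            f"cue sequence length {cues.size} does not match trajectory length {len(trajectory)}"
        )
    flip = cues == 2
    v_stim = np.where(flip, 1.0 - trajectory.v, trajectory.v)
    delta_stim = np.where(flip, -trajectory.delta, trajectory.delta)
    v_pos, v_neg = split_certainty(v_stim)
    delta_pos, delta_neg = split_prediction_error(delta_stim)
    return StimulusSpaceTrajectory(
        v_stim=v_stim,
        delta_stim=delta_stim,
        v_pos=v_pos,
        v_neg=v_neg,
        delta_pos=delta_pos,
        delta_neg=delta_neg,
    )


REGRESSOR_NAMES = (
    "cue",
    "positive_prediction",
    "negative_prediction",
    "no_resistance",
    "resistance",
    "positive_prediction_error",
    "negative_prediction_error",
    "rating",
)

PREDICTION_DURATION = 0.5
PREDICTION_ERROR_DURATION = 0.5


def build_event_table(
    schedule: TaskSchedule, stim_traj: StimulusSpaceTrajectory
) -> pd.DataFrame:
    """Emit the eight model-based regressors as one BIDS-style event table.

    1. ``cue``: every trial, cue onset, cue duration, magnitude 1.
    2./3. ``positive_prediction`` / ``negative_prediction``: cue onset,
       0.5 s, modulated by the certainty magnitudes; a trial predicting at
       exactly 0.5 belongs to neither.
    4./5. ``no_resistance`` / ``resistance``: stimulus onset, the stimulus
       window, magnitude 1, split by delivered outcome.
    6./7. ``positive_prediction_error`` / ``negative_prediction_error``:
       stimulus onset, 0.5 s, modulated by the prediction-error magnitudes
       (zero-magnitude trials are retained with modulation 0).
    8. ``rating``: every trial, rating onset and duration, magnitude 1.
    """
    n = len(schedule)
    if len(stim_traj) != n:
        raise ValueError("trajectory and schedule lengths differ")
    cfg = schedule.config
    no_resist = schedule.outcome == 0
    resist = ~no_resist
    pos_pred = stim_traj.v_stim > 0.5
    neg_pred = stim_traj.v_stim < 0.5

    def rows(mask, onset, duration, name, modulation):
        return pd.DataFrame(
            {
                "onset": onset[mask],
                "duration": duration if np.isscalar(duration) else duration[mask],
                "trial_type": name,
                "modulation": modulation if np.isscalar(modulation) else modulation[mask],
            }
        )

    every = np.ones(n, dtype=bool)
    parts = [
        rows(every, schedule.cue_onset, cfg.cue_duration, "cue", 1.0),
        rows(pos_pred, schedule.cue_onset, PREDICTION_DURATION, "positive_prediction", stim_traj.v_pos),
        rows(neg_pred, schedule.cue_onset, PREDICTION_DURATION, "negative_prediction", stim_traj.v_neg),
        rows(no_resist, schedule.stim_onset, cfg.stim_duration, "no_resistance", 1.0),
        rows(resist, schedule.stim_onset, cfg.stim_duration, "resistance", 1.0),
        rows(no_resist, schedule.stim_onset, PREDICTION_ERROR_DURATION, "positive_prediction_error", stim_traj.delta_pos),
        rows(resist, schedule.stim_onset, PREDICTION_ERROR_DURATION, "negative_prediction_error", stim_traj.delta_neg),
        rows(every, schedule.rating_onset, cfg.rating_duration, "rating", 1.0),
    ]
    table = pd.concat(parts, ignore_index=True)
    return table.sort_values(["onset", "trial_type"], kind="stable").reset_index(drop=True)


def write_three_column(events: pd.DataFrame, out_dir: str | Path) -> list[Path]:
    """Write per-regressor 3-column (onset, duration, modulation) text files."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, grp in events.groupby("trial_type", sort=False):
        path = out_dir / f"{name}.txt"
        np.savetxt(path, grp[["onset", "duration", "modulation"]].to_numpy(), fmt="%.6f")
        written.append(path)
    return written


def select_representative(alphas, subject_ids=None):
    """Pick the subject whose learning rate is closest to the cohort mean.

    Ties are broken by the lowest subject index. ``alphas`` may be a
    sequence of learning rates or of fit results exposing
    ``perceptual_param``.
    """
    vals = np.array(
        [a.perceptual_param if hasattr(a, "perceptual_param") else float(a) for a in alphas]
    )
    if vals.size == 0:
        raise ValueError("empty cohort: no included fits to select from")
    idx = int(np.argmin(np.abs(vals - vals.mean())))  # argmin takes the first tie
    return subject_ids[idx] if subject_ids is not None else idx


@dataclass(frozen=True)
class ValidationResult:
    slope: float
    intercept: float
    se_slope: float
    se_intercept: float
    z: float
    p: float
    separated: bool = False


def validate_unseen(representative_v: np.ndarray, unseen: list[np.ndarray]) -> ValidationResult:
    """Pooled logistic regression of unseen decisions on a fitted trajectory.

    All unseen binary series must be aligned to the same schedule as the
    representative prediction trajectory. On (quasi-)perfect separation, an
    L2-penalised fallback estimate is returned with ``separated=True``.
    """
    v = np.asarray(representative_v, dtype=float)
    series = [np.asarray(y, dtype=float) for y in unseen]
    if any(y.size != v.size for y in series):
        raise ValueError("all unseen series must match the trajectory length")
    y = np.concatenate(series)
    x = np.tile(v, len(series))
    X = sm.add_constant(x)
    separated = False
    try:
        with np.errstate(all="ignore"):
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        if not np.isfinite(res.bse).all() or np.abs(res.params).max() > 50:
            raise ValueError("separation suspected")
        params, bse = res.params, res.bse
    except Exception:
        separated = True
        params, bse = _penalized_logit(y, X, lam=1e-2)
    z = params[1] / bse[1]
    from scipy.stats import norm

    p = float(2.0 * norm.sf(abs(z)))
    return ValidationResult(
        slope=float(params[1]),
        intercept=float(params[0]),
        se_slope=float(bse[1]),
        se_intercept=float(bse[0]),
        z=float(z),
        p=p,
        separated=separated,
    )


def _penalized_logit(y, X, lam=1e-2, max_iter=100):
    """Newton-Raphson ridge-penalised logistic regression (fallback only)."""
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        W = mu * (1.0 - mu)
        H = X.T @ (W[:, None] * X) + lam * np.eye(X.shape[1])
        grad = X.T @ (y - mu) - lam * beta
        step = np.linalg.solve(H, grad)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            break
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    W = mu * (1.0 - mu)
    H = X.T @ (W[:, None] * X) + lam * np.eye(X.shape[1])
    cov = np.linalg.inv(H)
    return beta, np.sqrt(np.diag(cov))
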