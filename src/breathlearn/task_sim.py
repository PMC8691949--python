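"""Synthetic task generation: learning-task schedules, simulated agents,
staircase detection-task observers and multimodal cohort tables.

Everything downstream of this module runs on its output, so the whole
pipeline is testable without any external data. All randomness flows from
explicit per-call seeds; there is no global RNG state.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .learning_models import (
    ContingencyInput,
    BeliefTrajectory,
    encode_contingency_space,
    response_prob,
    trajectory_for,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ScheduleConfig",
    "TaskSchedule",
    "generate_blt_schedule",
    "AgentSpec",
    "simulate_agent",
    "FDTObserverSpec",
    "FDTSession",
    "simulate_fdt_observer",
    "CohortConfig",
    "MEASURE_NAMES",
    "AFFECTIVE_MEASURES",
    "INTEROCEPTIVE_MEASURES",
    "FDT_MEASURES",
    "BRAIN_MEASURES",
    "generate_multimodal_cohort",
]


# ---------------------------------------------------------------------------
# Breathing learning task schedule
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScheduleConfig:
    """Design constants of a learning-task session.

    The default block structure (30/10/10/10/20 trials) gives an initial
    stable period of 30 trials followed by four contingency reversals, with
    the 80/20 cue-outcome proportions exact within every block and
    resistance delivered on exactly half of all trials.
    """

    block_lengths: tuple[int, ...] = (30, 10, 10, 10, 20)
    p_high: float = 0.8
    first_block_high_cue: int = 1
    cue_duration: float = 2.5
    post_cue_pause: float = 2.5
    stim_duration: float = 5.0
    rating_duration: float = 7.0
    iti_range: tuple[float, float] = (7.0, 9.0)

    @property
    def n_trials(self) -> int:
        return int(sum(self.block_lengths))


@dataclass(frozen=True)
class TaskSchedule:
    """One session's cue/outcome sequence with per-trial timing (seconds)."""

    cue: np.ndarray
    outcome: np.ndarray
    p_resist_given_cue1: np.ndarray
    block_id: np.ndarray
    cue_onset: np.ndarray
    stim_onset: np.ndarray
    rating_onset: np.ndarray
    iti: np.ndarray
    config: ScheduleConfig = field(default_factory=ScheduleConfig)
    seed: int = 0

    def __len__(self) -> int:
        return self.cue.size

    @property
    def trial_index(self) -> np.ndarray:
        return np.arange(1, len(self) + 1)

    def reversal_trials(self) -> np.ndarray:
        """1-based indices of trials at which the contingency differs from
        the preceding trial."""
        p = self.p_resist_given_cue1
        return np.flatnonzero(p[1:] != p[:-1]) + 2

    def to_frame(self) -> pd.DataFrame:
        cfg = self.config
        return pd.DataFrame(
            {
                "trial_index": self.trial_index,
                "cue": self.cue,
                "outcome": self.outcome,
                "p_resist_given_cue1": self.p_resist_given_cue1,
                "block_id": self.block_id,
                "cue_onset": self.cue_onset,
                "cue_duration": np.full(len(self), cfg.cue_duration),
                "stim_onset": self.stim_onset,
                "stim_duration": np.full(len(self), cfg.stim_duration),
                "rating_onset": self.rating_onset,
                "rating_duration": np.full(len(self), cfg.rating_duration),
                "iti": self.iti,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, config: ScheduleConfig | None = None) -> "TaskSchedule":
        cfg = config or ScheduleConfig()
        return cls(
            cue=df["cue"].to_numpy(int),
            outcome=df["outcome"].to_numpy(int),
            p_resist_given_cue1=df["p_resist_given_cue1"].to_numpy(float),
            block_id=df["block_id"].to_numpy(int),
            cue_onset=df["cue_onset"].to_numpy(float),
            stim_onset=df["stim_onset"].to_numpy(float),
            rating_onset=df["rating_onset"].to_numpy(float),
            iti=df["iti"].to_numpy(float),
            config=cfg,
        )


def generate_blt_schedule(
    config: ScheduleConfig | None = None, seed: int = 0
) -> TaskSchedule:
    """Generate a schedule with exact within-block contingencies.

    Within each block both cues appear equally often and the outcome
    proportion of each cue matches the block contingency exactly; the
    high-contingency cue alternates between blocks (mirrored contingencies,
    so reversals occur exactly at block boundaries). Trial order within a
    block is pseudo-randomised by ``seed``.

    Raises
    ------
    ValueError
        If a block cannot realise the exact proportions (odd length, or
        ``p_high * block/2`` not an integer); the message names the block.
    """
    cfg = config or ScheduleConfig()
    rng = np.random.default_rng(seed)
    p_hi = cfg.p_high
    p_lo = round(1.0 - cfg.p_high, 12)  # keep the mirrored value tidy (0.2, not 0.19999...)

    cues, outcomes, pcue1, block_ids = [], [], [], []
    high_cue = cfg.first_block_high_cue
    for b, n_b in enumerate(cfg.block_lengths, start=1):
        if n_b % 2 != 0:
            raise ValueError(f"block {b} has odd length {n_b}; cues cannot balance")
        per_cue = n_b // 2
        n_hi = p_hi * per_cue
        if abs(n_hi - round(n_hi)) > 1e-9:
            raise ValueError(
                f"block {b} (length {n_b}) cannot realise exact contingency "
                f"{p_hi:g}: {p_hi:g} x {per_cue} is not an integer"
            )
        n_hi = round(n_hi)
        low_cue = 2 if high_cue == 1 else 1
        block = []
        # high-contingency cue: n_hi resisted of per_cue; low cue mirrored
        block += [(high_cue, 1)] * n_hi + [(high_cue, 0)] * (per_cue - n_hi)
        block += [(low_cue, 1)] * (per_cue - n_hi) + [(low_cue, 0)] * n_hi
        order = rng.permutation(n_b)
        for i in order:
            c, o = block[i]
            cues.append(c)
            outcomes.append(o)
            pcue1.append(p_hi if high_cue == 1 else p_lo)
            block_ids.append(b)
        high_cue = low_cue  # reversal at the next block boundary

    n = len(cues)
    iti = rng.uniform(*cfg.iti_range, size=n)
    cue_onset = np.empty(n)
    stim_onset = np.empty(n)
    rating_onset = np.empty(n)
    t = 0.0
    for k in range(n):
        cue_onset[k] = t
        stim_onset[k] = t + cfg.cue_duration + cfg.post_cue_pause
        rating_onset[k] = stim_onset[k] + cfg.stim_duration
        t = rating_onset[k] + cfg.rating_duration + iti[k]

    return TaskSchedule(
        cue=np.array(cues, dtype=int),
        outcome=np.array(outcomes, dtype=int),
        p_resist_given_cue1=np.array(pcue1, dtype=float),
        block_id=np.array(block_ids, dtype=int),
        cue_onset=cue_onset,
        stim_onset=stim_onset,
        rating_onset=rating_onset,
        iti=iti,
        config=cfg,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Simulated learning agents
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AgentSpec:
    """A simulated learner: perceptual model, its free parameter, and
    decision noise ``zeta`` of the unit-square sigmoid response model."""

    model: str
    perceptual_param: float
    zeta: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in ("RW", "HGF2", "HGF3"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.model == "RW" and not 0.0 <= self.perceptual_param <= 1.0:
            raise ValueError("RW learning rate must lie in [0, 1]")
        if self.zeta < 0:
            raise ValueError("zeta must be non-negative")


def simulate_agent(
    schedule: TaskSchedule, spec: AgentSpec
) -> tuple[np.ndarray, BeliefTrajectory, ContingencyInput]:
    """Simulate one agent on a schedule.

    Returns the binary decision series ``y(k)`` (contingency space), the
    latent belief trajectory used to generate it, and the contingency-space
    input — the latter two for parameter-recovery checks.
    """
    inp = encode_contingency_space(schedule)
    traj = trajectory_for(spec.model, inp, spec.perceptual_param)
    p1 = response_prob(traj.v, spec.zeta)
    rng = np.random.default_rng(spec.seed)
    y = (rng.random(p1.size) < p1).astype(int)
    return y, traj, inp


# ---------------------------------------------------------------------------
# Filter detection task observer under a staircase
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FDTObserverSpec:
    """A signal-detection observer for the filter detection task.

    Sensitivity grows linearly with filter load: ``d'(f) = slope * f``.
    On each trial evidence ``x ~ Normal(+-d'/2, 1)``; the observer answers
    yes iff ``x > criterion``. Confidence is a decile binning of the
    folded-normal CDF of ``|x - criterion|``, optionally jittered by
    Gaussian metacognitive noise before binning.
    """

    dprime_slope: float = 0.35
    criterion: float = 0.0
    confidence_noise_sd: float = 0.5
    seed: int = 0
    n_constant_trials: int = 60
    accuracy_band: tuple[float, float] = (0.60, 0.85)
    search_block: int = 5
    max_search_trials: int = 120
    max_filters: int = 12

    def __post_init__(self) -> None:
        if self.dprime_slope <= 0:
            raise ValueError("dprime_slope must be positive: observer can never reach the accuracy band")
        if self.confidence_noise_sd < 0:
            raise ValueError("confidence_noise_sd must be non-negative")


@dataclass(frozen=True)
class FDTSession:
    """Per-trial record of one simulated detection-task session."""

    trials: pd.DataFrame
    spec: FDTObserverSpec

    def constant_phase(self) -> pd.DataFrame:
        return self.trials[self.trials["phase"] == "constant"]

    def to_frame(self) -> pd.DataFrame:
        return self.trials.copy()


def _fdt_trial(rng, filters, spec):
    signal = int(rng.random() < 0.5)
    d = spec.dprime_slope * filters
    x = rng.normal(d / 2.0 if signal else -d / 2.0, 1.0)
    yes = int(x > spec.criterion)
    mag = abs(x - spec.criterion)
    if spec.confidence_noise_sd > 0:
        mag += rng.normal(0.0, spec.confidence_noise_sd)
    # decile binning of the folded-normal(0, 1) CDF of the magnitude
    q = 2.0 * norm.cdf(max(mag, 0.0)) - 1.0
    conf = int(min(10, max(1, int(np.ceil(q * 10.0)) if q > 0 else 1)))
    return signal, yes, conf, int(yes == signal)


def simulate_fdt_observer(spec: FDTObserverSpec | None = None) -> FDTSession:
    """Run one observer through the staircase and the constant phase.

    Search phase: mini-blocks at the current filter load; the load moves up
    when running accuracy is below the band and down (floor 1) when above,
    stopping once a mini-block lands inside the band or the trial cap is
    hit. Constant phase: the configured trial count at the settled load,
    with a +-1 adjustment (10-trial cooldown) when the trailing 10-trial
    accuracy leaves the band.
    """
    spec = spec or FDTObserverSpec()
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.accuracy_band
    rows = []
    filters = 1
    n_search = 0
    while n_search < spec.max_search_trials:
        correct_block = 0
        for _ in range(spec.search_block):
            signal, yes, conf, correct = _fdt_trial(rng, filters, spec)
            rows.append(("search", filters, signal, yes, conf, correct))
            correct_block += correct
            n_search += 1
        acc = correct_block / spec.search_block
        if acc < lo and filters < spec.max_filters:
            filters += 1
        elif acc > hi and filters > 1:
            filters -= 1
        else:
            break

    recent: list[int] = []
    cooldown = 0
    for _ in range(spec.n_constant_trials):
        signal, yes, conf, correct = _fdt_trial(rng, filters, spec)
        rows.append(("constant", filters, signal, yes, conf, correct))
        recent.append(correct)
        cooldown -= 1
        if len(recent) >= 10 and cooldown <= 0:
            acc10 = sum(recent[-10:]) / 10.0
            if acc10 < lo and filters < spec.max_filters:
                filters += 1
                cooldown = 10
            elif acc10 > hi and filters > 1:
                filters -= 1
                cooldown = 10

    trials = pd.DataFrame(
        rows,
        columns=["phase", "filter_count", "signal_present", "response_yes", "confidence", "correct"],
    )
    trials.insert(0, "trial", np.arange(1, len(trials) + 1))
    return FDTSession(trials=trials, spec=spec)


# ---------------------------------------------------------------------------
# Multimodal cohort tables
# ---------------------------------------------------------------------------

AFFECTIVE_MEASURES = ("stai_s", "gad7", "asi", "cesd")
INTEROCEPTIVE_MEASURES = ("maia", "bpq", "pcs_b", "pvq_b")
FDT_MEASURES = ("fdt_threshold", "fdt_decision_c", "fdt_metacog_bias", "fdt_mratio")
BRAIN_MEASURES = (
    "ains_pos_prediction",
    "ains_neg_prediction",
    "ains_pos_pe",
    "ains_neg_pe",
)
MEASURE_NAMES = AFFECTIVE_MEASURES + INTEROCEPTIVE_MEASURES + FDT_MEASURES + BRAIN_MEASURES


def _default_group_effects() -> dict[str, float]:
    # standardized shifts for the moderate group; pattern mirrors the kind of
    # cohort the downstream statistics are meant to detect (affective shifts
    # large, vigilance null, metacognitive bias reduced)
    return {
        "stai_s": 1.6,
        "gad7": 1.5,
        "asi": 1.7,
        "cesd": 1.5,
        "maia": -1.1,
        "bpq": 0.7,
        "pcs_b": 0.9,
        "pvq_b": 0.0,
        "fdt_threshold": 0.6,
        "fdt_decision_c": 0.0,
        "fdt_metacog_bias": -0.6,
        "fdt_mratio": 0.0,
    }


def _default_loadings() -> np.ndarray:
    # one latent "negative affect" factor loading on the 8 questionnaires
    load = np.zeros((len(MEASURE_NAMES), 1))
    for j, name in enumerate(MEASURE_NAMES):
        if name in AFFECTIVE_MEASURES:
            load[j, 0] = 0.9
        elif name in INTEROCEPTIVE_MEASURES:
            load[j, 0] = -0.9 if name == "maia" else 0.9
    return load


@dataclass
class CohortConfig:
    """Generative settings for a two-group, 16-measure cohort table."""

    n_low: int = 30
    n_moderate: int = 30
    group_effects: dict[str, float] = field(default_factory=_default_group_effects)
    loadings: np.ndarray | None = None
    noise_sd: float = 1.0
    seed: int = 0


def generate_multimodal_cohort(config: CohortConfig | None = None) -> pd.DataFrame:
    """Generate a subjects-by-measures table with planted structure.

    Each measure is ``group_effect * is_moderate + loadings @ latent_factors
    + Normal(0, noise_sd)``. Latent factors are standard normal per subject.
    """
    cfg = config or CohortConfig()
    rng = np.random.default_rng(cfg.seed)
    loadings = cfg.loadings if cfg.loadings is not None else _default_loadings()
    loadings = np.atleast_2d(np.asarray(loadings, dtype=float))
    if loadings.shape[0] != len(MEASURE_NAMES):
        raise ValueError(
            f"loadings must have {len(MEASURE_NAMES)} rows (one per measure), "
            f"got shape {loadings.shape}"
        )
    unknown = set(cfg.group_effects) - set(MEASURE_NAMES)
    if unknown:
        raise ValueError(f"unknown measures in group_effects: {sorted(unknown)}")

    n = cfg.n_low + cfg.n_moderate
    group = np.array(["low"] * cfg.n_low + ["moderate"] * cfg.n_moderate)
    is_mod = (group == "moderate").astype(float)
    factors = rng.standard_normal((n, loadings.shape[1]))
    noise = rng.standard_normal((n, len(MEASURE_NAMES))) * cfg.noise_sd
    effects = np.array([cfg.group_effects.get(m, 0.0) for m in MEASURE_NAMES])
    X = is_mod[:, None] * effects[None, :] + factors @ loadings.T + noise

    out = pd.DataFrame(X, columns=list(MEASURE_NAMES))
    out.insert(0, "group", group)
    out.insert(0, "subject_id", [f"s{i + 1:03d}" for i in range(n)])
    return out
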