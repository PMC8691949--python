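"""Perceptual learning models and the unit-square sigmoid response model.

All models operate on binary inputs coded in *contingency space*: a single
input sequence ``u(k)`` that collapses the two mirrored cues into one belief
trajectory. ``encode_contingency_space`` performs the coding;
``to_stimulus_space`` in :mod:`breathlearn.regressors` undoes it.

Three perceptual models are provided, each with one free parameter:

* Rescorla-Wagner delta rule (learning rate ``alpha``),
* two-level binary Hierarchical Gaussian Filter (evolution rate ``omega2``),
* three-level binary Hierarchical Gaussian Filter (coupling ``kappa2``).

The HGF updates follow the standard variational update equations of the
binary HGF as implemented in the open-source toolbox tradition (v5.3
semantics). Fixed-parameter defaults are reconstructions, overridable via
``HGFFixedParams``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import special

__all__ = [
    "ContingencyInput",
    "BeliefTrajectory",
    "HGFFixedParams",
    "TrajectoryInvalidError",
    "encode_contingency_space",
    "rw_trajectory",
    "rw_trajectory_grid",
    "hgf2_trajectory",
    "hgf3_trajectory",
    "response_prob",
    "response_loglik",
    "VCLAMP",
]

#: Probability clamp used inside the response model so the log-likelihood
#: stays finite for saturated beliefs.
VCLAMP = 1e-8


class TrajectoryInvalidError(ValueError):
    """Raised when an HGF update produces a non-positive posterior precision."""


@dataclass(frozen=True)
class ContingencyInput:
    """Binary input sequence in contingency space, with the cue carried along."""

    u: np.ndarray
    cue: np.ndarray

    def __post_init__(self) -> None:
        u = np.asarray(self.u, dtype=float)
        cue = np.asarray(self.cue, dtype=int)
        if u.shape != cue.shape or u.ndim != 1:
            raise ValueError("u and cue must be aligned 1-d sequences")
        if not np.isin(u, (0.0, 1.0)).all():
            raise ValueError("u must be binary")
        if not np.isin(cue, (1, 2)).all():
            raise ValueError("cue labels must be 1 or 2")
        object.__setattr__(self, "u", u)
        object.__setattr__(self, "cue", cue)

    def __len__(self) -> int:
        return self.u.size


@dataclass(frozen=True)
class BeliefTrajectory:
    """Trial-wise predictions ``v(k)`` and prediction errors ``delta(k)``.

    ``v`` holds the prediction *before* seeing trial ``k``'s outcome;
    ``v_final`` is the posterior belief after the last trial.
    """

    v: np.ndarray
    delta: np.ndarray
    model: str
    params: dict = field(default_factory=dict)
    v_final: float = float("nan")

    def __len__(self) -> int:
        return self.v.size

    def to_frame(self, input_: ContingencyInput | None = None) -> pd.DataFrame:
        data = {"trial": np.arange(1, len(self) + 1)}
        if input_ is not None:
            data["cue"] = input_.cue
            data["u"] = input_.u
        data["v"] = self.v
        data["delta"] = self.delta
        return pd.DataFrame(data)


def encode_contingency_space(schedule) -> ContingencyInput:
    """Code outcomes relative to the cue so one trajectory covers both cues.

    ``u(k) = 1`` iff (cue 1 and no resistance) or (cue 2 and resistance).
    The opposite coding yields identical stimulus-space trajectories after
    back-transformation, so the choice is a fixed convention.
    """
    cue = np.asarray(schedule.cue, dtype=int)
    outcome = np.asarray(schedule.outcome, dtype=int)
    u = np.where(cue == 1, 1 - outcome, outcome).astype(float)
    return ContingencyInput(u=u, cue=cue)


def rw_trajectory(
    u: ContingencyInput | np.ndarray, alpha: float, v0: float = 0.5
) -> BeliefTrajectory:
    """Rescorla-Wagner delta rule: ``v(k+1) = v(k) + alpha * (u(k) - v(k))``."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must lie in [0, 1], got {alpha}")
    if not 0.0 <= v0 <= 1.0:
        raise ValueError(f"v0 must lie in [0, 1], got {v0}")
    useq = u.u if isinstance(u, ContingencyInput) else np.asarray(u, dtype=float)
    n = useq.size
    v = np.empty(n)
    cur = float(v0)
    for k in range(n):
        v[k] = cur
        cur += alpha * (useq[k] - cur)
    delta = useq - v
    return BeliefTrajectory(
        v=v, delta=delta, model="RW", params={"alpha": alpha, "v0": v0}, v_final=cur
    )


def rw_trajectory_grid(useq: np.ndarray, alphas: np.ndarray, v0: float = 0.5) -> np.ndarray:
    """Vectorised RW recursion over a vector of learning rates.

    Returns an array of shape ``(len(alphas), len(useq))`` with the
    trial-wise predictions; used by grid-search oracles and batch scoring.
    """
    useq = np.asarray(useq, dtype=float)
    alphas = np.asarray(alphas, dtype=float)
    v = np.empty((alphas.size, useq.size))
    cur = np.full(alphas.size, float(v0))
    for k in range(useq.size):
        v[:, k] = cur
        cur = cur + alphas * (useq[k] - cur)
    return v


@dataclass(frozen=True)
class HGFFixedParams:
    """Fixed parameters of the binary HGF (reconstructed defaults).

    The free parameter of each variant (``omega2`` for the two-level model,
    ``kappa2`` for the three-level model) overrides the matching field at
    call time; everything else stays fixed during fitting.
    """

    mu2_0: float = 0.0
    sigma2_0: float = 0.1
    mu3_0: float = 1.0
    sigma3_0: float = 1.0
    kappa1: float = 1.0
    kappa2: float = 1.0
    omega2: float = -3.0
    omega3: float = -6.0
    rho2: float = 0.0


_DEFAULT_FIXED = HGFFixedParams()


def _hgf_binary(useq: np.ndarray, levels: int, p: HGFFixedParams) -> tuple[np.ndarray, float]:
    """Run the binary HGF update equations; returns (v, final posterior v)."""
    n = useq.size
    v = np.empty(n)
    mu2, sa2 = p.mu2_0, p.sigma2_0
    mu3, sa3 = p.mu3_0, p.sigma3_0
    ka1, ka2, om2, om3 = p.kappa1, p.kappa2, p.omega2, p.omega3
    for k in range(n):
        muhat2 = mu2 + p.rho2
        try:
            if levels == 3:
                step2 = math.exp(ka2 * mu3 + om2)
            else:
                step2 = math.exp(om2)
        except OverflowError:
            raise TrajectoryInvalidError(
                f"level-2 evolution variance overflowed at trial {k + 1}"
            ) from None
        if not math.isfinite(step2) or sa2 + step2 <= 0:
            raise TrajectoryInvalidError("level-2 prediction variance is invalid")
        pihat2 = 1.0 / (sa2 + step2)
        x = ka1 * muhat2
        muhat1 = 1.0 / (1.0 + math.exp(-x)) if abs(x) < 700 else (1.0 if x > 0 else 0.0)
        v[k] = muhat1
        da1 = useq[k] - muhat1
        pi2 = pihat2 + ka1 * ka1 * muhat1 * (1.0 - muhat1)
        mu2_new = muhat2 + ka1 / pi2 * da1
        if levels == 3:
            pihat3 = 1.0 / (sa3 + math.exp(om3))
            w2 = step2 * pihat2
            da2 = (1.0 / pi2 + (mu2_new - muhat2) ** 2) * pihat2 - 1.0
            pi3 = pihat3 + 0.5 * ka2 * ka2 * w2 * (w2 + (2.0 * w2 - 1.0) * da2)
            if pi3 <= 0 or not math.isfinite(pi3):
                raise TrajectoryInvalidError(
                    f"non-positive level-3 posterior precision at trial {k + 1}"
                )
            mu3 = mu3 + 0.5 * ka2 / pi3 * w2 * da2
            sa3 = 1.0 / pi3
        mu2, sa2 = mu2_new, 1.0 / pi2
        if not (math.isfinite(mu2) and math.isfinite(sa2)):
            raise TrajectoryInvalidError(f"level-2 state diverged at trial {k + 1}")
    xf = ka1 * (mu2 + p.rho2)
    v_final = 1.0 / (1.0 + math.exp(-xf)) if abs(xf) < 700 else (1.0 if xf > 0 else 0.0)
    return v, v_final


def hgf2_trajectory(
    u: ContingencyInput | np.ndarray,
    omega2: float,
    fixed: HGFFixedParams | None = None,
) -> BeliefTrajectory:
    """Two-level binary HGF with free evolution rate ``omega2``."""
    if not math.isfinite(omega2):
        raise ValueError("omega2 must be finite")
    useq = u.u if isinstance(u, ContingencyInput) else np.asarray(u, dtype=float)
    p = replace(fixed or _DEFAULT_FIXED, omega2=float(omega2))
    v, v_final = _hgf_binary(useq, levels=2, p=p)
    return BeliefTrajectory(
        v=v, delta=useq - v, model="HGF2", params={"omega2": float(omega2)}, v_final=v_final
    )


def hgf3_trajectory(
    u: ContingencyInput | np.ndarray,
    kappa2: float,
    fixed: HGFFixedParams | None = None,
) -> BeliefTrajectory:
    """Three-level binary HGF with free volatility coupling ``kappa2``."""
    if not math.isfinite(kappa2):
        raise ValueError("kappa2 must be finite")
    useq = u.u if isinstance(u, ContingencyInput) else np.asarray(u, dtype=float)
    p = replace(fixed or _DEFAULT_FIXED, kappa2=float(kappa2))
    v, v_final = _hgf_binary(useq, levels=3, p=p)
    return BeliefTrajectory(
        v=v, delta=useq - v, model="HGF3", params={"kappa2": float(kappa2)}, v_final=v_final
    )


def trajectory_for(
    model: str, u: ContingencyInput | np.ndarray, param: float,
    fixed: HGFFixedParams | None = None,
) -> BeliefTrajectory:
    """Dispatch on model name ('RW', 'HGF2' or 'HGF3')."""
    if model == "RW":
        return rw_trajectory(u, param)
    if model == "HGF2":
        return hgf2_trajectory(u, param, fixed)
    if model == "HGF3":
        return hgf3_trajectory(u, param, fixed)
    raise ValueError(f"unknown model {model!r}; expected RW, HGF2 or HGF3")


def response_prob(v: np.ndarray, zeta: float) -> np.ndarray:
    """Unit-square sigmoid: ``p(y=1) = v**zeta / (v**zeta + (1-v)**zeta)``.

    Computed in log space; ``zeta = 0`` degenerates to p = 0.5 everywhere.
    """
    if zeta < 0:
        raise ValueError("zeta must be non-negative")
    v = np.clip(np.asarray(v, dtype=float), VCLAMP, 1.0 - VCLAMP)
    # p(y=1) = expit(zeta * logit(v)); exact at v = 0.5 for any zeta.
    # zeta capped so inf * 0 never occurs at the v = 0.5 boundary.
    d = min(zeta, 1e12) * (np.log(v) - np.log1p(-v))
    return special.expit(d)


def response_loglik(v, y: np.ndarray, zeta: float) -> float:
    """Total log-likelihood of binary decisions ``y`` under the sigmoid model."""
    varr = v.v if isinstance(v, BeliefTrajectory) else np.asarray(v, dtype=float)
    y = np.asarray(y, dtype=float)
    if varr.shape != y.shape:
        raise ValueError(
            f"length mismatch: {varr.shape[0]} predictions vs {y.shape[0]} decisions"
        )
    if zeta < 0:
        raise ValueError("zeta must be non-negative")
    vc = np.clip(varr, VCLAMP, 1.0 - VCLAMP)
    d = min(zeta, 1e12) * (np.log(vc) - np.log1p(-vc))
    # log p(y=1) = -log(1 + exp(-d)); stable for any magnitude of d
    logp1 = -np.logaddexp(0.0, -d)
    logp0 = -np.logaddexp(0.0, d)
    return float(np.sum(y * logp1 + (1.0 - y) * logp0))
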