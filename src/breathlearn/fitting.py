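"""MAP / ML estimation of learning-model parameters with Laplace evidence.

Fitting happens in an unconstrained transformed space (logit for the RW
learning rate, log for the decision-noise parameter ``zeta``, identity for
the HGF evolution/coupling parameters) using quasi-Newton (BFGS) multi-start
optimisation. Log model evidence is approximated by the Laplace method at
the MAP estimate. A likelihood-ratio test against the chance ("null") model
flags subjects whose behaviour the model does not beat coin flipping on.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special, stats

from .learning_models import (
    ContingencyInput,
    HGFFixedParams,
    TrajectoryInvalidError,
    response_loglik,
    trajectory_for,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ParamPrior",
    "PriorSpec",
    "FitOptions",
    "FitResult",
    "default_priors",
    "fit_map",
    "fit_mle",
    "derive_priors",
    "laplace_lme",
    "null_loglik",
    "lr_test_vs_null",
    "MODEL_PARAM",
]

#: free perceptual parameter per model, with its transform to fitting space
MODEL_PARAM = {
    "RW": ("alpha", "logit"),
    "HGF2": ("omega2", "identity"),
    "HGF3": ("kappa2", "identity"),
}

_PENALTY = 1e10  # objective value for invalid trajectories


def _to_native(x: float, transform: str) -> float:
    if transform == "logit":
        return float(special.expit(x))
    if transform == "log":
        return float(np.exp(x))
    return float(x)


def _to_transformed(x: float, transform: str) -> float:
    if transform == "logit":
        x = min(max(x, 1e-12), 1 - 1e-12)
        return float(special.logit(x))
    if transform == "log":
        return float(np.log(x))
    return float(x)


@dataclass(frozen=True)
class ParamPrior:
    """Gaussian prior on one parameter in its transformed space."""

    transform: str  # {"logit", "log", "identity"}
    mean: float
    var: float

    def __post_init__(self) -> None:
        if self.transform not in ("logit", "log", "identity"):
            raise ValueError(f"unknown transform {self.transform!r}")
        if self.var <= 0:
            raise ValueError("prior variance must be positive")

    def logpdf(self, x: float) -> float:
        return -0.5 * ((x - self.mean) ** 2 / self.var + math.log(2 * math.pi * self.var))


@dataclass(frozen=True)
class PriorSpec:
    """Priors for one model's free parameters, keyed by parameter name."""

    params: dict[str, ParamPrior]

    def __getitem__(self, name: str) -> ParamPrior:
        return self.params[name]


def default_priors(model: str) -> PriorSpec:
    """Fallback priors when no holdout data are supplied (reconstructions).

    Standard-normal in transformed space around each model's fixed default
    (logit-alpha around 0, omega2 around -3, kappa2 around 1) and
    ``ln zeta ~ Normal(ln 2, 1)``. All overridable via an explicit
    :class:`PriorSpec` or :func:`derive_priors` on holdout fits.
    """
    name, transform = MODEL_PARAM[model]
    centre = {"RW": 0.0, "HGF2": -3.0, "HGF3": 1.0}[model]
    return PriorSpec(
        {
            name: ParamPrior(transform, centre, 1.0),
            "zeta": ParamPrior("log", math.log(2.0), 1.0),
        }
    )


@dataclass(frozen=True)
class FitOptions:
    n_restarts: int = 10
    seed: int = 0
    gtol: float = 1e-6
    fix_zeta: float | None = None
    hgf_fixed: HGFFixedParams | None = None


@dataclass
class FitResult:
    """One subject x model fit: estimates, likelihood and Laplace evidence."""

    model: str
    theta_map: dict[str, float]
    theta_transformed: np.ndarray
    loglik: float
    log_joint: float
    lme: float
    hessian_logdet: float
    converged: bool
    n_restarts_used: int
    flags: list[str] = field(default_factory=list)

    @property
    def perceptual_param(self) -> float:
        return self.theta_map[MODEL_PARAM[self.model][0]]


def _param_layout(model: str, opts: FitOptions):
    name, transform = MODEL_PARAM[model]
    names = [name]
    transforms = [transform]
    if opts.fix_zeta is None:
        names.append("zeta")
        transforms.append("log")
    return names, transforms


def _make_objective(y, u, model, priors, opts):
    names, transforms = _param_layout(model, opts)
    useq = u.u if isinstance(u, ContingencyInput) else np.asarray(u, float)
    y = np.asarray(y, float)

    def neg_log_joint(theta_t: np.ndarray) -> float:
        native = [_to_native(t, tr) for t, tr in zip(theta_t, transforms)]
        zeta = opts.fix_zeta if opts.fix_zeta is not None else native[-1]
        try:
            traj = trajectory_for(model, useq, native[0], opts.hgf_fixed)
        except (TrajectoryInvalidError, OverflowError):
            return _PENALTY
        ll = response_loglik(traj.v, y, zeta)
        lp = 0.0
        if priors is not None:
            lp = sum(priors[n].logpdf(t) for n, t in zip(names, theta_t))
        out = -(ll + lp)
        return out if math.isfinite(out) else _PENALTY

    return neg_log_joint, names, transforms


def _fd_hessian(f, x: np.ndarray, step: float = 1e-4) -> np.ndarray:
    """Central finite-difference Hessian of a scalar function."""
    d = x.size
    h = step * (1.0 + np.abs(x))
    H = np.empty((d, d))
    f0 = f(x)
    for i in range(d):
        ei = np.zeros(d)
        ei[i] = h[i]
        H[i, i] = (f(x + ei) - 2.0 * f0 + f(x - ei)) / h[i] ** 2
        for j in range(i + 1, d):
            ej = np.zeros(d)
            ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4.0 * h[i] * h[j])
    return H


def laplace_lme(
    log_joint: float,
    neg_log_joint_fn,
    theta: np.ndarray,
    hessian: np.ndarray | None = None,
) -> tuple[float, float, list[str]]:
    """Laplace approximation to the log model evidence.

    ``lme = log_joint(MAP) + d/2 * ln(2*pi) - 1/2 * ln det H`` with ``H``
    the (finite-difference) Hessian of the negative log-joint at the MAP.
    A non-positive-definite Hessian is ridge-regularised with a warning;
    ``d = 0`` returns the log-joint unchanged.

    Returns ``(lme, logdet_H, flags)``.
    """
    theta = np.atleast_1d(np.asarray(theta, float))
    d = theta.size
    if d == 0:
        return float(log_joint), 0.0, []
    flags: list[str] = []
    H = hessian if hessian is not None else _fd_hessian(neg_log_joint_fn, theta)
    H = 0.5 * (H + H.T)
    eigvals = np.linalg.eigvalsh(H)
    if eigvals.min() <= 0:
        ridge = abs(eigvals.min()) + 1e-6
        H = H + ridge * np.eye(d)
        eigvals = eigvals + ridge
        flags.append("hessian_regularized")
        warnings.warn("non-positive-definite Hessian; ridge-regularised for LME")
    logdet = float(np.sum(np.log(eigvals)))
    if not math.isfinite(logdet):
        flags.append("lme_undefined")
        return float("nan"), float("nan"), flags
    lme = float(log_joint) + 0.5 * d * math.log(2 * math.pi) - 0.5 * logdet
    return lme, logdet, flags


def _fit(y, u, model, priors, opts: FitOptions) -> FitResult:
    f, names, transforms = _make_objective(y, u, model, priors, opts)
    rng = np.random.default_rng(opts.seed)
    d = len(names)

    if priors is not None:
        centre = np.array([priors[n].mean for n in names])
        sd = np.array([math.sqrt(priors[n].var) for n in names])
    else:  # flat prior: start from the model's default-prior locations
        dflt = default_priors(model)
        centre = np.array([dflt[n].mean for n in names])
        sd = np.array([2.0 * math.sqrt(dflt[n].var) for n in names])

    best = None
    n_used = 0
    for r in range(max(1, opts.n_restarts)):
        x0 = centre if r == 0 else centre + sd * rng.standard_normal(d)
        if f(x0) >= _PENALTY:
            continue
        res = optimize.minimize(f, x0, method="BFGS", options={"gtol": opts.gtol})
        n_used += 1
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not math.isfinite(best.fun) or best.fun >= _PENALTY:
        return FitResult(
            model=model,
            theta_map={n: float("nan") for n in names},
            theta_transformed=np.full(d, np.nan),
            loglik=float("nan"),
            log_joint=float("nan"),
            lme=float("nan"),
            hessian_logdet=float("nan"),
            converged=False,
            n_restarts_used=n_used,
            flags=["all_restarts_failed"],
        )

    theta_t = np.asarray(best.x, float)
    native = {n: _to_native(t, tr) for n, t, tr in zip(names, theta_t, transforms)}
    if opts.fix_zeta is not None:
        native["zeta"] = float(opts.fix_zeta)
    zeta = native["zeta"]
    traj = trajectory_for(model, u, native[names[0]], opts.hgf_fixed)
    loglik = response_loglik(traj.v, np.asarray(y, float), zeta)
    log_joint = -float(best.fun)
    lme, logdet, flags = laplace_lme(log_joint, f, theta_t)
    converged = bool(best.success) or float(np.max(np.abs(best.jac))) < 1e-3
    if not converged:
        flags.append("optimizer_not_converged")
    if names[0] == "alpha" and abs(theta_t[0]) > 6.0:
        flags.append("boundary_alpha")
    return FitResult(
        model=model,
        theta_map=native,
        theta_transformed=theta_t,
        loglik=float(loglik),
        log_joint=log_joint,
        lme=lme,
        hessian_logdet=logdet,
        converged=converged,
        n_restarts_used=n_used,
        flags=flags,
    )


def fit_map(
    y,
    u,
    model: str,
    priors: PriorSpec | None = None,
    options: FitOptions | None = None,
) -> FitResult:
    """MAP fit of (perceptual parameter, zeta) by multi-start BFGS.

    ``priors`` defaults to :func:`default_priors`; pass a spec derived from
    holdout fits (:func:`derive_priors`) to mirror the intended workflow.
    """
    if model not in MODEL_PARAM:
        raise ValueError(f"unknown model {model!r}")
    opts = options or FitOptions()
    return _fit(y, u, model, priors or default_priors(model), opts)


def fit_mle(y, u, model: str, options: FitOptions | None = None) -> FitResult:
    """Maximum-likelihood fit (flat improper prior); for prior derivation.

    With a flat prior the log-joint equals the log-likelihood, so the
    "MAP" optimum is the MLE. Estimates at the edge of the (transformed)
    search space are flagged ``boundary_alpha``.
    """
    if model not in MODEL_PARAM:
        raise ValueError(f"unknown model {model!r}")
    opts = options or FitOptions()
    return _fit(y, u, model, None, opts)


def derive_priors(
    holdout_fits: list[FitResult], min_var: float = 0.1
) -> PriorSpec:
    """Turn transformed-space holdout MLEs into prior means and variances.

    Degenerate variances (all estimates identical) are floored at
    ``min_var``.
    """
    if len(holdout_fits) < 2:
        raise ValueError("need at least 2 holdout fits to derive priors")
    model = holdout_fits[0].model
    if any(f.model != model for f in holdout_fits):
        raise ValueError("holdout fits mix models")
    name, transform = MODEL_PARAM[model]
    names = [name, "zeta"]
    transforms = [transform, "log"]
    priors = {}
    for i, (n, tr) in enumerate(zip(names, transforms)):
        vals = np.array(
            [
                f.theta_transformed[i]
                if f.theta_transformed.size > i
                else _to_transformed(f.theta_map[n], tr)
                for f in holdout_fits
            ]
        )
        var = float(np.var(vals, ddof=1))
        if var < min_var:
            logger.warning("prior variance for %s floored at %g", n, min_var)
            var = min_var
        priors[n] = ParamPrior(tr, float(np.mean(vals)), var)
    return PriorSpec(priors)


def null_loglik(y) -> float:
    """Log-likelihood of the chance model: ``N * ln(0.5)``."""
    return len(np.asarray(y)) * math.log(0.5)


@dataclass(frozen=True)
class LRTestResult:
    statistic: float
    df: int
    p: float
    exclude: bool


def lr_test_vs_null(fit: FitResult, y, df: int = 2, alpha: float = 0.05) -> LRTestResult:
    """Likelihood-ratio test of a fitted model against the chance model.

    ``exclude`` is True when the fit does *not* beat chance (p > alpha),
    mirroring the exclusion of non-significant fits from further analysis.
    """
    ll0 = null_loglik(y)
    stat = 2.0 * (fit.loglik - ll0)
    if stat < 0:
        warnings.warn("fitted log-likelihood below the null; statistic floored at 0")
        stat = 0.0
    p = float(stats.chi2.sf(stat, df))
    return LRTestResult(statistic=float(stat), df=df, p=p, exclude=bool(p > alpha))
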