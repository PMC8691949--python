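"""Type-1 and type-2 signal-detection metrics for the filter detection task.

Computes the four session-level measures used for group comparisons:
perceptual threshold (modal constant-phase filter load), decision bias
``c`` (negative values = tendency to report the load present), metacognitive
bias (mean confidence) and metacognitive performance ``Mratio = meta-d'/d'``.

``meta-d'`` is fit per subject by maximum likelihood under the standard
type-2 signal-detection model (response-conditional confidence likelihood
with the type-1 criterion held at the subject's relative criterion). This
deliberately replaces hierarchical group-level estimation with per-subject
ML fits; group comparisons then use standard tests.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_BIN_EDGES",
    "SDTCounts",
    "sdt_indices",
    "MetaDFit",
    "fit_meta_d",
    "MetacogResult",
    "fdt_summary",
]

#: confidence 1-10 collapsed to 4 bins: {1-3, 4-5, 6-7, 8-10}
DEFAULT_BIN_EDGES = (4, 6, 8)


@dataclass(frozen=True)
class SDTCounts:
    """Joint counts per (stimulus, response, confidence bin).

    ``table[s, r, b]`` counts trials with stimulus ``s`` (0 = absent),
    response ``r`` (0 = no) and confidence bin ``b`` (ascending).
    """

    table: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.table, dtype=float)
        if t.shape[:2] != (2, 2) or t.ndim != 3 or t.shape[2] < 2:
            raise ValueError("table must have shape (2, 2, n_bins) with n_bins >= 2")
        if (t < 0).any():
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "table", t)

    @classmethod
    def from_trials(
        cls,
        signal_present,
        response_yes,
        confidence,
        bin_edges: tuple[int, ...] = DEFAULT_BIN_EDGES,
    ) -> "SDTCounts":
        s = np.asarray(signal_present, dtype=int)
        r = np.asarray(response_yes, dtype=int)
        b = np.digitize(np.asarray(confidence), bin_edges)
        nb = len(bin_edges) + 1
        table = np.zeros((2, 2, nb))
        np.add.at(table, (s, r, b), 1.0)
        return cls(table)

    @property
    def n_bins(self) -> int:
        return self.table.shape[2]

    @property
    def hits(self) -> float:
        return float(self.table[1, 1].sum())

    @property
    def misses(self) -> float:
        return float(self.table[1, 0].sum())

    @property
    def false_alarms(self) -> float:
        return float(self.table[0, 1].sum())

    @property
    def correct_rejections(self) -> float:
        return float(self.table[0, 0].sum())

    @property
    def n_trials(self) -> float:
        return float(self.table.sum())


def sdt_indices(counts: SDTCounts) -> tuple[float, float]:
    """Type-1 sensitivity and criterion: ``d' = z(HR) - z(FAR)``,
    ``c = -(z(HR) + z(FAR)) / 2``.

    Degenerate hit or false-alarm rates (0 or 1) trigger the log-linear
    correction ``(count + 0.5) / (n + 1)`` on both rates, with a warning.
    """
    n_sig = counts.hits + counts.misses
    n_noise = counts.false_alarms + counts.correct_rejections
    if n_sig == 0 or n_noise == 0:
        raise ValueError("need at least one signal and one noise trial")
    hr = counts.hits / n_sig
    far = counts.false_alarms / n_noise
    if hr in (0.0, 1.0) or far in (0.0, 1.0):
        warnings.warn("degenerate hit/false-alarm rate; applying log-linear correction")
        hr = (counts.hits + 0.5) / (n_sig + 1.0)
        far = (counts.false_alarms + 0.5) / (n_noise + 1.0)
    zh, zf = stats.norm.ppf(hr), stats.norm.ppf(far)
    return float(zh - zf), float(-(zh + zf) / 2.0)


@dataclass(frozen=True)
class MetaDFit:
    meta_d: float
    m_ratio: float
    d_prime: float
    criterion_c: float
    nll: float
    converged: bool
    flags: tuple[str, ...] = ()


def _type2_cell_probs(meta_d: float, criteria: np.ndarray) -> np.ndarray:
    """Response-conditional probabilities of the 2*n_bins confidence cells.

    ``criteria`` is the full ascending vector of 2*n_bins - 1 decision
    boundaries whose middle element is the (scaled) type-1 criterion.
    Returns an array of shape (2 stimuli, 2 responses, n_bins).
    """
    nb = (criteria.size + 1) // 2
    mc = criteria[nb - 1]
    bounds = np.concatenate(([-np.inf], criteria, [np.inf]))
    out = np.empty((2, 2, nb))
    for s, mu in enumerate((-meta_d / 2.0, meta_d / 2.0)):
        cdf = stats.norm.cdf(bounds - mu)
        region = np.diff(cdf)  # 2*nb regions, ascending in x
        p_no = max(stats.norm.cdf(mc - mu), 1e-12)
        p_yes = max(1.0 - stats.norm.cdf(mc - mu), 1e-12)
        # "no" regions run from high confidence (far left) to low; flip so
        # bins ascend in confidence
        out[s, 0] = region[:nb][::-1] / p_no
        out[s, 1] = region[nb:] / p_yes
    return np.clip(out, 1e-12, None)


def fit_meta_d(counts: SDTCounts, padding: float | None = None) -> MetaDFit:
    """Maximum-likelihood meta-d' with the type-1 criterion held at c'.

    The type-2 likelihood is the probability of each confidence bin
    conditional on (stimulus, response); each observed cell is padded by
    ``1 / (2 * n_bins)`` (default) before entering the likelihood. Confidence
    ratings collapsed into a single bin make meta-d' unidentifiable and
    return a flagged NaN fit.
    """
    nb = counts.n_bins
    pad = 1.0 / (2.0 * nb) if padding is None else padding
    d1, c1 = sdt_indices(counts)
    obs = counts.table + pad

    used_bins = (counts.table.sum(axis=(0, 1)) > 0).sum()
    if used_bins < 2:
        return MetaDFit(float("nan"), float("nan"), d1, c1, float("nan"), False,
                        ("degenerate_confidence",))
    if abs(d1) < 1e-8:
        return MetaDFit(float("nan"), float("nan"), d1, c1, float("nan"), False,
                        ("zero_d_prime",))

    rel_c = c1 / d1  # relative criterion, preserved at the meta level

    def unpack(theta):
        meta_d = theta[0]
        mc = rel_c * meta_d
        lo = mc - np.cumsum(np.exp(theta[1:nb]))[::-1]
        hi = mc + np.cumsum(np.exp(theta[nb:]))
        return meta_d, np.concatenate((lo, [mc], hi))

    def nll(theta):
        meta_d, crit = unpack(theta)
        probs = _type2_cell_probs(meta_d, crit)
        return -float(np.sum(obs * np.log(probs)))

    x0 = np.concatenate(([d1], np.full(2 * (nb - 1), np.log(0.5))))
    res = optimize.minimize(nll, x0, method="Nelder-Mead",
                            options={"maxiter": 4000, "xatol": 1e-6, "fatol": 1e-8})
    meta_d, _ = unpack(res.x)
    flags = () if res.success else ("optimizer_not_converged",)
    return MetaDFit(
        meta_d=float(meta_d),
        m_ratio=float(meta_d / d1),
        d_prime=d1,
        criterion_c=c1,
        nll=float(res.fun),
        converged=bool(res.success),
        flags=flags,
    )


@dataclass(frozen=True)
class MetacogResult:
    """Session-level measures from the constant phase of one session."""

    threshold_filters: int
    d_prime: float
    criterion_c: float
    mean_confidence: float
    meta_d: float
    m_ratio: float
    n_trials: int
    flags: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "threshold_filters": self.threshold_filters,
            "d_prime": self.d_prime,
            "criterion_c": self.criterion_c,
            "metacog_bias": self.mean_confidence,
            "meta_d": self.meta_d,
            "m_ratio": self.m_ratio,
            "n_trials": self.n_trials,
        }


def fdt_summary(session, bin_edges: tuple[int, ...] = DEFAULT_BIN_EDGES) -> MetacogResult:
    """Compute the four detection-task measures from constant-phase trials.

    Accepts an :class:`~breathlearn.task_sim.FDTSession` or a per-trial
    data frame with columns ``phase``, ``filter_count``, ``signal_present``,
    ``response_yes`` and ``confidence``. Trials with missing confidence are
    dropped (count logged).
    """
    trials = session.trials if hasattr(session, "trials") else session
    const = trials[trials["phase"] == "constant"]
    if len(const) == 0:
        raise ValueError("session has no constant-phase trials")
    n_before = len(const)
    const = const.dropna(subset=["confidence"])
    if len(const) < n_before:
        logger.info("dropped %d trials with missing confidence", n_before - len(const))

    filt = const["filter_count"].mode().iloc[0]
    counts = SDTCounts.from_trials(
        const["signal_present"], const["response_yes"], const["confidence"], bin_edges
    )
    d1, c1 = sdt_indices(counts)
    meta = fit_meta_d(counts)
    return MetacogResult(
        threshold_filters=int(filt),
        d_prime=d1,
        criterion_c=c1,
        mean_confidence=float(const["confidence"].mean()),
        meta_d=meta.meta_d,
        m_ratio=meta.m_ratio,
        n_trials=len(const),
        flags=meta.flags,
    )
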