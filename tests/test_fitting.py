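import math

import numpy as np
import pytest

from breathlearn import fitting
from breathlearn import learning_models as lm
from breathlearn import task_sim

FAST = fitting.FitOptions(n_restarts=3, seed=0)


# ---------------------------------------------------------------------------
# priors and transforms
# ---------------------------------------------------------------------------

def test_param_prior_validation():
    with pytest.raises(ValueError):
        fitting.ParamPrior("logit", 0.0, 0.0)
    with pytest.raises(ValueError):
        fitting.ParamPrior("weird", 0.0, 1.0)


def test_default_priors_cover_all_models():
    for model, (pname, _) in fitting.MODEL_PARAM.items():
        spec = fitting.default_priors(model)
        assert pname in spec.params and "zeta" in spec.params


def test_transform_roundtrip():
    for tr, val in [("logit", 0.37), ("log", 4.2), ("identity", -2.5)]:
        assert fitting._to_native(fitting._to_transformed(val, tr), tr) == pytest.approx(val)


# ---------------------------------------------------------------------------
# MAP fitting
# ---------------------------------------------------------------------------

def test_map_recovers_known_alpha(default_schedule, rw_cohort):
    recovered = []
    for y, _, inp in rw_cohort:
        fit = fitting.fit_map(y, inp, "RW", options=FAST)
        assert fit.converged
        recovered.append(fit.theta_map["alpha"])
    assert abs(np.mean(recovered) - 0.3) < 0.1


def test_map_coin_flips_give_chance_likelihood(contingency):
    rng = np.random.default_rng(0)
    y = rng.integers(0, 2, len(contingency))
    fit = fitting.fit_map(y, contingency, "RW", options=FAST)
    assert abs(fit.loglik - fitting.null_loglik(y)) < 4.0
    assert fit.theta_map["zeta"] < 2.0


def test_map_degenerates_to_prior_mode_with_tight_prior(contingency, rw_cohort):
    y = rw_cohort[0][0]
    tight = fitting.PriorSpec(
        {
            "alpha": fitting.ParamPrior("logit", fitting._to_transformed(0.7, "logit"), 1e-8),
            "zeta": fitting.ParamPrior("log", math.log(3.0), 1e-8),
        }
    )
    fit = fitting.fit_map(y, contingency, "RW", priors=tight, options=FAST)
    assert fit.theta_map["alpha"] == pytest.approx(0.7, abs=1e-3)
    assert fit.theta_map["zeta"] == pytest.approx(3.0, rel=1e-3)


def test_map_unknown_model():
    with pytest.raises(ValueError):
        fitting.fit_map(np.array([1, 0]), np.array([1.0, 0.0]), "nope")


def test_map_fix_zeta_option(contingency, rw_cohort):
    y = rw_cohort[0][0]
    opts = fitting.FitOptions(n_restarts=3, seed=0, fix_zeta=5.0)
    fit = fitting.fit_map(y, contingency, "RW", options=opts)
    assert fit.theta_map["zeta"] == 5.0
    assert fit.theta_transformed.size == 1


def test_map_matches_grid_search_oracle(contingency, rw_cohort):
    # coarse two-round grid oracle; the full dense version lives in the
    # acceptance suite
    for y, _, inp in rw_cohort[:3]:
        fit = fitting.fit_map(y, inp, "RW", options=fitting.FitOptions(n_restarts=5, seed=1))
        a_grid, z_grid = _grid_search_map(y, inp, rounds=3)
        assert fit.theta_map["alpha"] == pytest.approx(a_grid, abs=1e-2)
        assert fit.theta_map["zeta"] == pytest.approx(z_grid, rel=5e-2)


def _grid_search_map(y, inp, rounds=3, n=41):
    priors = fitting.default_priors("RW")
    y = np.asarray(y, float)
    a_lo, a_hi = -6.0, 6.0
    z_lo, z_hi = -3.0, 4.0
    best = None
    for _ in range(rounds):
        a_t = np.linspace(a_lo, a_hi, n)
        z_t = np.linspace(z_lo, z_hi, n)
        alphas = 1 / (1 + np.exp(-a_t))
        v = lm.rw_trajectory_grid(inp.u, alphas)
        vc = np.clip(v, 1e-8, 1 - 1e-8)
        lo = np.log(vc) - np.log1p(-vc)  # (na, N)
        zetas = np.exp(z_t)
        d = zetas[:, None, None] * lo[None, :, :]  # (nz, na, N)
        ll = -(np.logaddexp(0, -d) * y + np.logaddexp(0, d) * (1 - y)).sum(axis=2)
        lp = (
            -0.5 * (a_t - priors["alpha"].mean) ** 2 / priors["alpha"].var
            - 0.5 * np.log(2 * np.pi * priors["alpha"].var)
        )[None, :] + (
            -0.5 * (z_t - priors["zeta"].mean) ** 2 / priors["zeta"].var
            - 0.5 * np.log(2 * np.pi * priors["zeta"].var)
        )[:, None]
        obj = ll + lp
        zi, ai = np.unravel_index(np.argmax(obj), obj.shape)
        best = (alphas[ai], zetas[zi])
        da, dz = a_t[1] - a_t[0], z_t[1] - z_t[0]
        a_lo, a_hi = a_t[ai] - da, a_t[ai] + da
        z_lo, z_hi = z_t[zi] - dz, z_t[zi] + dz
    return best


# ---------------------------------------------------------------------------
# MLE fitting
# ---------------------------------------------------------------------------

def test_mle_close_to_map_under_wide_prior(contingency, rw_cohort):
    y = rw_cohort[1][0]
    wide = fitting.PriorSpec(
        {
            "alpha": fitting.ParamPrior("logit", 0.0, 1e6),
            "zeta": fitting.ParamPrior("log", 0.0, 1e6),
        }
    )
    opts = fitting.FitOptions(n_restarts=5, seed=0)
    mle = fitting.fit_mle(y, contingency, "RW", opts)
    map_wide = fitting.fit_map(y, contingency, "RW", priors=wide, options=opts)
    assert mle.theta_map["alpha"] == pytest.approx(map_wide.theta_map["alpha"], abs=2e-2)
    assert mle.loglik == pytest.approx(map_wide.loglik, abs=1e-3)


def test_mle_flat_likelihood_when_beliefs_stay_at_half(contingency):
    # zeta is unidentifiable when the generating beliefs never leave 0.5
    rng = np.random.default_rng(1)
    y = rng.integers(0, 2, len(contingency))
    fit = fitting.fit_mle(y, contingency, "RW", FAST)
    assert fit.loglik >= fitting.null_loglik(y) - 1e-6
    assert fit.loglik - fitting.null_loglik(y) < 6.0


def test_mle_bias_shrinks_with_long_series():
    cfg = task_sim.ScheduleConfig(block_lengths=(30, 10, 10, 10, 20) * 8)
    long_sched = task_sim.generate_blt_schedule(cfg, seed=0)
    short_sched = task_sim.generate_blt_schedule(seed=0)
    errs = {"short": [], "long": []}
    for seed in range(8):
        for name, sched in (("short", short_sched), ("long", long_sched)):
            y, _, inp = task_sim.simulate_agent(
                sched, task_sim.AgentSpec("RW", 0.3, 5.0, seed=seed)
            )
            fit = fitting.fit_mle(y, inp, "RW", FAST)
            errs[name].append(fit.theta_map["alpha"] - 0.3)
    assert abs(np.mean(errs["long"])) <= abs(np.mean(errs["short"])) + 0.02


# ---------------------------------------------------------------------------
# prior derivation
# ---------------------------------------------------------------------------

def test_derive_priors_from_holdout(default_schedule):
    rng = np.random.default_rng(5)
    true_logit_mean = fitting._to_transformed(0.35, "logit")
    fits = []
    for i in range(8):
        alpha = fitting._to_native(true_logit_mean + 0.5 * rng.standard_normal(), "logit")
        y, _, inp = task_sim.simulate_agent(
            default_schedule, task_sim.AgentSpec("RW", alpha, 5.0, seed=int(rng.integers(1 << 31)))
        )
        fits.append(fitting.fit_mle(y, inp, "RW", FAST))
    spec = fitting.derive_priors(fits)
    se = math.sqrt(spec["alpha"].var / 8)
    assert abs(spec["alpha"].mean - true_logit_mean) < 4 * se + 0.5
    assert spec["zeta"].transform == "log"


def test_derive_priors_floors_degenerate_variance(contingency, rw_cohort):
    y = rw_cohort[0][0]
    fit = fitting.fit_mle(y, contingency, "RW", FAST)
    spec = fitting.derive_priors([fit, fit, fit], min_var=0.25)
    assert spec["alpha"].var == 0.25
    assert spec["zeta"].var == 0.25


def test_derive_priors_rejects_too_few():
    with pytest.raises(ValueError):
        fitting.derive_priors([])


# ---------------------------------------------------------------------------
# Laplace evidence
# ---------------------------------------------------------------------------

def test_laplace_matches_gaussian_closed_form():
    # neg log joint 0.5 * a * (x - m)^2 + c  =>  evidence = -c + 0.5*ln(2*pi/a)
    a, m, c = 3.7, 0.4, 1.9
    f = lambda x: 0.5 * a * (x[0] - m) ** 2 + c
    lme, _, flags = fitting.laplace_lme(-c, f, np.array([m]))
    assert lme == pytest.approx(-c + 0.5 * math.log(2 * math.pi / a), abs=1e-6)
    assert not flags


def test_laplace_d0_returns_log_joint():
    lme, logdet, _ = fitting.laplace_lme(-12.3, None, np.array([]))
    assert lme == -12.3 and logdet == 0.0


def test_laplace_occam_penalty_widening_prior(contingency, rw_cohort):
    y = rw_cohort[2][0]
    lmes = []
    for scale in (1.0, 100.0):
        priors = fitting.PriorSpec(
            {
                "alpha": fitting.ParamPrior("logit", 0.0, 1.0 * scale),
                "zeta": fitting.ParamPrior("log", math.log(2.0), 1.0 * scale),
            }
        )
        fit = fitting.fit_map(y, contingency, "RW", priors=priors, options=FAST)
        lmes.append(fit.lme)
    assert lmes[1] < lmes[0]


def test_laplace_regularizes_flat_hessian():
    f = lambda x: 0.0 * x[0]
    with pytest.warns(UserWarning):
        lme, _, flags = fitting.laplace_lme(0.0, f, np.array([0.0]))
    assert "hessian_regularized" in flags


# ---------------------------------------------------------------------------
# null model and LR test
# ---------------------------------------------------------------------------

def test_null_loglik_closed_form():
    y = np.zeros(80)
    assert fitting.null_loglik(y) == pytest.approx(80 * math.log(0.5), abs=1e-12)
    assert fitting.null_loglik(y) == pytest.approx(-55.4518, abs=1e-4)


def test_lr_test_perfect_fit_not_excluded(contingency):
    traj = lm.rw_trajectory(contingency, 0.5)
    y = (traj.v > 0.5).astype(int)
    fit = fitting.fit_map(y, contingency, "RW", options=FAST)
    res = fitting.lr_test_vs_null(fit, y)
    assert res.p < 1e-6
    assert not res.exclude


def test_lr_test_floors_negative_statistic(contingency):
    fake = fitting.FitResult(
        model="RW", theta_map={}, theta_transformed=np.array([]),
        loglik=fitting.null_loglik(np.zeros(80)) - 5.0, log_joint=0.0, lme=0.0,
        hessian_logdet=0.0, converged=True, n_restarts_used=1,
    )
    with pytest.warns(UserWarning):
        res = fitting.lr_test_vs_null(fake, np.zeros(80))
    assert res.statistic == 0.0
    assert res.exclude


def test_lr_test_null_calibration_smoke(contingency):
    # full 1000-subject calibration lives in the acceptance suite
    rng = np.random.default_rng(11)
    excl = 0
    n = 60
    for _ in range(n):
        y = rng.integers(0, 2, len(contingency))
        fit = fitting.fit_mle(y, contingency, "RW", FAST)
        excl += fitting.lr_test_vs_null(fit, y).exclude
    assert excl / n > 0.85
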