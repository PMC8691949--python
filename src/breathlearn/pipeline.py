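"""End-to-end study orchestration on synthetic (or user-supplied) tables.

Stages mirror the analysis plan: simulate cohort -> fit all models ->
likelihood-ratio exclusion -> Bayesian model selection -> model-based event
tables (+ validation on an unseen cohort) -> detection-task summaries ->
multimodal group statistics, correlations and permutation PCA. Every output
table carries a header comment recording the package version and master
seed; reruns with the same config are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, fdt_metacognition, fitting, group_stats, regressors, selection_recovery, task_sim

logger = logging.getLogger(__name__)

__all__ = ["StudyConfig", "run_pipeline", "write_table"]


@dataclass
class StudyConfig:
    seed: int = 0
    n_subjects: int = 60
    n_validation: int = 15
    models: tuple[str, ...] = ("RW", "HGF2", "HGF3")
    sim_model: str = "RW"
    sim_zeta: float = 5.0
    n_restarts: int = 5
    schedule: task_sim.ScheduleConfig = field(default_factory=task_sim.ScheduleConfig)
    recovery_subjects: int = 60
    recovery_zeta_levels: tuple[float, ...] = (1.0, 5.0, 10.0)
    recovery_iterations: int = 10
    run_recovery: bool = False
    n_observers: int = 60
    pca_permutations: int = 1000
    out_dir: str = "study_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name in raw:
                val = raw[f.name]
                if f.name == "schedule":
                    val = task_sim.ScheduleConfig(**val)
                elif isinstance(val, list):
                    val = tuple(val)
                kwargs[f.name] = val
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**kwargs)


def write_table(df: pd.DataFrame, path: Path, seed: int, sep: str = ",") -> None:
    """Write a delimited table with a version/seed header comment."""
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# breathlearn {__version__} seed={seed}\n")
        df.to_csv(fh, index=False, sep=sep)


def _simulate_cohort(cfg: StudyConfig, schedule, rng):
    prior = fitting.default_priors(cfg.sim_model)
    pname = fitting.MODEL_PARAM[cfg.sim_model][0]
    rows = []
    subjects = []
    for s in range(cfg.n_subjects):
        param = selection_recovery._sample_perceptual(cfg.sim_model, prior, rng)
        spec = task_sim.AgentSpec(cfg.sim_model, param, cfg.sim_zeta, seed=int(rng.integers(2**63)))
        y, traj, inp = task_sim.simulate_agent(schedule, spec)
        subjects.append({"subject": f"s{s + 1:03d}", "y": y, "inp": inp, pname: param})
        for k in range(len(y)):
            rows.append(
                {
                    "subject": f"s{s + 1:03d}",
                    "trial": k + 1,
                    "cue": schedule.cue[k],
                    "outcome": schedule.outcome[k],
                    "u": inp.u[k],
                    "y": y[k],
                }
            )
    return subjects, pd.DataFrame(rows)


def run_pipeline(config: StudyConfig | None = None) -> dict:
    """Run the full synthetic study; returns a dict of result objects and
    writes one delimited table per stage under ``config.out_dir``."""
    cfg = config or StudyConfig()
    out = Path(cfg.out_dir)
    rng = np.random.default_rng(cfg.seed)
    results: dict = {"config": cfg}

    # --- simulate -----------------------------------------------------------
    schedule = task_sim.generate_blt_schedule(cfg.schedule, seed=cfg.seed)
    write_table(schedule.to_frame(), out / "schedule.csv", cfg.seed)
    subjects, trials = _simulate_cohort(cfg, schedule, rng)
    write_table(trials, out / "blt_trials.csv", cfg.seed)
    results["schedule"] = schedule

    # --- fit + LR exclusion -------------------------------------------------
    fit_rows = []
    fits_by_model: dict[str, list] = {m: [] for m in cfg.models}
    for subj in subjects:
        for model in cfg.models:
            opts = fitting.FitOptions(n_restarts=cfg.n_restarts, seed=int(rng.integers(2**63)))
            fit = fitting.fit_map(subj["y"], subj["inp"], model, options=opts)
            lr = fitting.lr_test_vs_null(fit, subj["y"])
            fits_by_model[model].append(fit)
            row = {
                "subject": subj["subject"],
                "model": model,
                "loglik": fit.loglik,
                "lme": fit.lme,
                "lr_statistic": lr.statistic,
                "lr_p": lr.p,
                "excluded": lr.exclude,
                "converged": fit.converged,
            }
            row.update({k: v for k, v in fit.theta_map.items()})
            fit_rows.append(row)
    fit_table = pd.DataFrame(fit_rows)
    write_table(fit_table, out / "fits.csv", cfg.seed)
    results["fits"] = fit_table

    # --- BMS ----------------------------------------------------------------
    lme = fit_table.pivot(index="subject", columns="model", values="lme")[list(cfg.models)]
    excluded = set(
        fit_table.loc[
            (fit_table["model"] == cfg.models[0]) & fit_table["excluded"], "subject"
        ]
    )
    included = [s for s in lme.index if s not in excluded]
    bms = selection_recovery.rfx_bms(lme.loc[included], models=cfg.models, seed=cfg.seed)
    write_table(bms.to_frame(), out / "bms.csv", cfg.seed)
    results["bms"] = bms
    logger.info("BMS winner: %s (excluded %d subjects)", bms.winner, len(excluded))

    # --- recovery study (optional; expensive) -------------------------------
    if cfg.run_recovery:
        rec = selection_recovery.run_recovery_study(
            selection_recovery.RecoveryConfig(
                models=cfg.models,
                n_subjects=cfg.recovery_subjects,
                zeta_levels=cfg.recovery_zeta_levels,
                n_iterations=cfg.recovery_iterations,
                seed=cfg.seed,
            )
        )
        write_table(rec.cells, out / "recovery_cells.csv", cfg.seed)
        write_table(rec.summary(), out / "recovery_summary.csv", cfg.seed)
        results["recovery"] = rec

    # --- representative-subject regressors + validation ---------------------
    rw_fits = fits_by_model[cfg.sim_model]
    incl_idx = [i for i, s in enumerate(subjects) if s["subject"] in included]
    rep_local = regressors.select_representative([rw_fits[i] for i in incl_idx])
    rep_idx = incl_idx[rep_local]
    rep_fit = rw_fits[rep_idx]
    from .learning_models import trajectory_for as _traj_for

    traj = _traj_for(cfg.sim_model, subjects[rep_idx]["inp"], rep_fit.perceptual_param)
    stim = regressors.to_stimulus_space(traj, schedule.cue)
    events = regressors.build_event_table(schedule, stim)
    write_table(events, out / "events.tsv", cfg.seed, sep="\t")
    regressors.write_three_column(events, out / "regressors_3col")
    results["events"] = events
    results["representative"] = subjects[rep_idx]["subject"]

    val_specs = [
        task_sim.AgentSpec(cfg.sim_model,
                           selection_recovery._sample_perceptual(
                               cfg.sim_model, fitting.default_priors(cfg.sim_model), rng),
                           cfg.sim_zeta, seed=int(rng.integers(2**63)))
        for _ in range(cfg.n_validation)
    ]
    unseen = [task_sim.simulate_agent(schedule, s)[0] for s in val_specs]
    val = regressors.validate_unseen(traj.v, unseen)
    write_table(pd.DataFrame([dataclasses.asdict(val)]), out / "validation.csv", cfg.seed)
    results["validation"] = val

    # --- FDT observer bank --------------------------------------------------
    fdt_rows = []
    for i in range(cfg.n_observers):
        spec = task_sim.FDTObserverSpec(
            dprime_slope=float(np.exp(rng.normal(np.log(0.35), 0.3))),
            criterion=float(rng.normal(0.0, 0.2)),
            confidence_noise_sd=float(abs(rng.normal(0.5, 0.2))),
            seed=int(rng.integers(2**63)),
        )
        session = task_sim.simulate_fdt_observer(spec)
        summary = fdt_metacognition.fdt_summary(session)
        row = {"subject": f"s{i + 1:03d}"}
        row.update(summary.to_dict())
        fdt_rows.append(row)
    fdt_table = pd.DataFrame(fdt_rows)
    write_table(fdt_table, out / "fdt_summaries.csv", cfg.seed)
    results["fdt"] = fdt_table

    # --- multimodal statistics ----------------------------------------------
    cohort = task_sim.generate_multimodal_cohort(
        task_sim.CohortConfig(n_low=cfg.n_subjects // 2,
                              n_moderate=cfg.n_subjects - cfg.n_subjects // 2,
                              seed=cfg.seed)
    )
    write_table(cohort, out / "multimodal_table.csv", cfg.seed)
    questionnaires = list(task_sim.AFFECTIVE_MEASURES + task_sim.INTEROCEPTIVE_MEASURES)
    comps = group_stats.compare_groups(cohort, questionnaires)
    comps += group_stats.compare_groups(cohort, list(task_sim.FDT_MEASURES))
    comp_table = pd.DataFrame([c.to_dict() for c in comps])
    write_table(comp_table, out / "group_comparisons.csv", cfg.seed)
    results["group_comparisons"] = comps

    corr = group_stats.correlation_matrix(cohort)
    write_table(corr.r.reset_index().rename(columns={"index": "measure"}),
                out / "correlation_matrix.csv", cfg.seed)
    results["correlations"] = corr

    pca = group_stats.pca_significance(cohort, n_perm=cfg.pca_permutations, seed=cfg.seed)
    pca_table = pd.DataFrame(
        pca.weights.T,
        index=list(pca.measures),
        columns=[f"PC{i + 1}" for i in range(pca.weights.shape[0])],
    )
    write_table(pca_table.reset_index().rename(columns={"index": "measure"}),
                out / "pca_weights.csv", cfg.seed)
    write_table(
        pd.DataFrame(
            {
                "component": [f"PC{i + 1}" for i in range(pca.variance_explained.size)],
                "variance_explained": pca.variance_explained,
                "null_95": pca.null_95,
                "significant": [i in pca.significant for i in range(pca.variance_explained.size)],
            }
        ),
        out / "pca_significance.csv",
        cfg.seed,
    )
    results["pca"] = pca
    if pca.significant:
        score_comps = group_stats.compare_component_scores(pca, cohort["group"].to_numpy())
        write_table(pd.DataFrame([c.to_dict() for c in score_comps]),
                    out / "pca_score_comparisons.csv", cfg.seed)
        results["pca_score_comparisons"] = score_comps

    with open(out / "summary.json", "w") as fh:
        json.dump(
            {
                "version": __version__,
                "seed": cfg.seed,
                "n_subjects": cfg.n_subjects,
                "n_excluded": len(excluded),
                "bms_winner": bms.winner,
                "pxp": bms.pxp.tolist(),
                "representative": results["representative"],
                "n_significant_components": pca.n_significant,
            },
            fh,
            indent=2,
        )
    return results
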