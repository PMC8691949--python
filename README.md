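# breathlearn

A self-contained analysis pipeline for interoceptive breathing-task studies:
associative-learning model fitting and selection on a binary prediction task,
model-based fMRI event-table construction, breathing-perception
metacognition metrics, and permutation-tested multimodal PCA — all runnable
end-to-end on synthetic cohorts generated by the package itself.

## What's inside

| module | contents |
| --- | --- |
| `breathlearn.task_sim` | 80-trial learning-task schedules with exact within-block contingencies and 4 reversals; simulated RW/HGF agents; staircase detection-task observers; 2-group × 16-measure multimodal cohort tables |
| `breathlearn.learning_models` | Rescorla-Wagner, 2- and 3-level binary Hierarchical Gaussian Filter trajectories; unit-square sigmoid response model; contingency-space coding |
| `breathlearn.fitting` | multi-start BFGS MAP/ML estimation in transformed space, Laplace log model evidence, holdout-based prior derivation, likelihood-ratio test against chance |
| `breathlearn.selection_recovery` | random-effects Bayesian model selection (expected frequencies, exceedance, BOR, protected exceedance probability); parameter-recovery / model-identifiability simulation study |
| `breathlearn.regressors` | stimulus-space back-transform, valence-split certainty and prediction-error magnitudes, BIDS-style event tables (8 regressors), representative-subject selection, logistic validation on unseen cohorts |
| `breathlearn.fdt_metacognition` | type-1 d′/c, maximum-likelihood meta-d′ and Mratio, session summaries (threshold filters, metacognitive bias) |
| `breathlearn.group_stats` | Anderson-Darling-gated t / rank-sum group comparisons with Bonferroni families, Pearson/Spearman correlation matrices with FDR, permutation-tested PCA and component-score comparisons |
| `breathlearn.pipeline` / `breathlearn.cli` | end-to-end orchestration with explicit seeds and delimited-table outputs |

## Command line

```bash
breathlearn all --seed 1 --out-dir study_out          # full pipeline
breathlearn simulate --seed 1 --out-dir study_out     # schedule + cohort only
breathlearn recovery --seed 1 --out-dir study_out     # recovery study
breathlearn fdt --seed 1 --n-observers 60 --out-dir study_out
breathlearn stats --seed 1 --out-dir study_out        # group stats + PCA
```

Options can also come from a YAML config (`--config study.yml`) whose keys
mirror `breathlearn.pipeline.StudyConfig`. Every output table starts with a
`# breathlearn <version> seed=<seed>` header line; reruns with identical
seeds are byte-identical.

## Notes

- All randomness flows through explicit integer seeds; there is no global
  RNG state.
- HGF fixed parameters and fitting priors are documented reconstructions
  (see module docstrings) and are fully overridable.
- meta-d′ is estimated per subject by maximum likelihood rather than by a
  hierarchical group sampler; group comparisons then use standard tests.
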