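"""Grid search over training hyperparameters with ANOVA/Tukey summary.

The full default grid crosses 288 combinations; here a reduced grid keeps
the example quick. Every combination is scored on the same seeded 80/20
partitions, then each hyperparameter is summarised marginally: one-way
ANOVA over its levels plus Tukey compact letters (levels sharing a letter
are statistically indistinguishable at alpha = 0.05).
"""

import mtmepred as mp

print(f"default grid: {mp.default_grid().n_combinations} combinations")

cfg = mp.SimConfig(n_individuals=80, n_markers=200, n_environments=1,
                   heritabilities=(0.6,), seed=4)
study = mp.simulate_study(cfg)
ds = mp.prepare_data(study.phenotypes, mp.vanraden_g(study.markers))

grid = mp.HyperGrid(activation=["tanh", "relu"], optimizer=["adam"],
                    epochs=[20, 100], batch_size=[32],
                    loss=["mean_squared_error"], metric=["mse"],
                    loss_weight=[1.0, 0.01])
print(f"reduced grid: {grid.n_combinations} combinations x 3 repetitions")
tuning = mp.grid_search(ds, grid, n_reps=3, base_seed=1, workers=1)

summary = mp.resume_hyperparameters(tuning)
for name, gc in summary.per_hyperparameter.items():
    print(f"\n{name}: F = {gc.f_statistic:.2f}, p = {gc.p_value:.3g}")
    print(gc.level_means[["mean", "se", "letters"]].round(3).to_string())
best = summary.best()
print(f"\nbest combination: {best['config']} "
      f"(mean prediction ability {best['mean_prediction_ability']:.3f})")
# Longer training should earn a higher mean prediction ability; whether the
# difference is statistically significant is what the letters report.
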