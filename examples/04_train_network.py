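"""Train the fixed-architecture network for genomic prediction.

The architecture is not tunable: three hidden layers of round(2/3 · inputs)
units with 30% dropout. Training hyperparameters come from a ModelConfig.
The same seed always reproduces the same fit.
"""

import numpy as np

import mtmepred as mp

cfg = mp.SimConfig(n_individuals=120, n_markers=250, n_environments=1,
                   heritabilities=(0.7,), seed=2)
study = mp.simulate_study(cfg)
G = mp.vanraden_g(study.markers)
ds = mp.prepare_data(study.phenotypes, G)

spec = mp.build_network(ds.X.shape[1], ds.n_traits)
print(f"architecture: {ds.X.shape[1]} inputs -> {spec.hidden_sizes} hidden -> "
      f"{spec.n_outputs} output, dropout {spec.dropout_rate}")

config = mp.ModelConfig(activation="tanh", optimizer="adam", epochs=100,
                        batch_size=32, loss="mean_squared_error",
                        loss_weight=0.01, seed=11)
tn = mp.train(ds, config)
print(f"trained {config.epochs} epochs; loss {tn.training_history[0]:.4f} -> "
      f"{tn.training_history[-1]:.4f}")

# in-sample fit versus the simulator's true breeding values
yhat = mp.predict(tn, ds.X)[:, 0]
r_pheno = mp.pearson(ds.Y[:, 0], yhat)
r_true = mp.pearson(study.truth["true_g"].to_numpy()[:, 0], yhat)
print(f"fit to phenotypes r = {r_pheno:.3f}; to true breeding values r = {r_true:.3f}")
# The loss trace should fall by an order of magnitude; correlation with the
# (normally unobservable) true breeding values shows genuine genetic signal
# rather than memorised noise.
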