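"""Train a sequence regressor to recover bifurcation parameters.

Generates synthetic windows with node parameters drawn from the training
priors (a ~ U(-1,1), omega ~ U(0.05,0.25)), trains the temporal
convolutional regressor and reports the validation normalized RMSE against
the constant-predictor baseline of 28.87.
"""

import numpy as np

import hopfbif as hb
from hopfbif.regression import TrainingConfig, constant_predictor_baseline, train_regressor

conn = hb.random_connectome(10, seed=0)
data = hb.generate_training_set(S=1000, W=50, connectome=conn, G=1.0,
                                config=hb.SimulationConfig(seed=7))
print(f"training set: windows {data.windows.shape}, labels in "
      f"[{data.labels_a.min():.2f}, {data.labels_a.max():.2f}]")

model = train_regressor(data, TrainingConfig(approach="sequence", epochs=10, seed=3))
for h in model.history[::3]:
    print(f"  epoch {h['epoch']:2d}: train nRMSE {h['train_nrmse']:.2f}  "
          f"val nRMSE {h['val_nrmse']:.2f}")
print(f"final validation nRMSE: {model.history[-1]['val_nrmse']:.2f}")
print(f"constant-predictor baseline: {constant_predictor_baseline(data.labels_a):.2f}")
# A validation nRMSE well below the baseline means the model extracts real
# information about each node's dynamical regime from a 50-sample window.
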