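"""Fit an LS-SVM soft sensor on one batch and predict a sister batch.

Trains on a full simulated batch and predicts cell concentration for a
second batch run at the same operating conditions (different noise and
inoculum).  The printed RMSE/MAE are in g/L; R^2 close to 1 means the kernel
expansion tracks the quality variable across the whole 90 h trajectory.
"""

import fermsense as fs

train_batch = fs.simulate_batch(fs.source_conditions(seed=2))
test_batch = fs.simulate_batch(fs.source_conditions(seed=3, biomass_init=0.22))

train = fs.Dataset(train_batch.aux, train_batch.C)
model = fs.lssvm_fit(train, fs.LSSVMHyperparams(gamma=125.0, sigma=10.0))

pred = model.predict(test_batch.aux)
report = fs.evaluate(test_batch.C, pred)
print(f"sister-batch RMSE = {report.rmse:.3f} g/L, MAE = {report.mae:.3f} g/L, "
      f"R^2 = {report.r2:.4f}")
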