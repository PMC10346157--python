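"""Four-variant soft-sensor comparison on a shifted transfer scenario.

Simulates two labelled source batches at reference conditions and one
unlabelled target batch at +3 degC with tweaked kinetics, then evaluates the
fixed LS-SVM, the PSO- and IPSO-tuned models, and the full adapted
BDA-IPSO-LSSVM against the held-out target labels (medians over 3 optimizer
seeds; reduced tuning budget for a quick run).  The adapted variant should
show the lowest RMSE/MAE and highest R^2 on cell concentration: the tuned
but unadapted models overfit the source operating condition.
"""

import fermsense as fs

scenario = fs.make_transfer_scenario(
    fs.source_conditions(), fs.target_conditions(), seed=0
)
config = fs.PipelineConfig(swarm_size=12, tune_iters=12)
table = fs.compare_models(scenario, seeds=[0, 1, 2], config=config, labels=("C",))

print(table.round(3).to_string(index=False))
print("\nRMSE/MAE in g/L against held-out target labels; the bda-ipso-lssvm "
      "row shows the transfer benefit.")
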