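"""Simulate one fermentation batch and inspect its trajectory.

Builds a 90 h batch at the reference operating conditions (28 degC, pH 5.0)
and prints the state of the culture at a few time points: cell concentration
C rises while substrate lasts, product P accumulates, and dissolved oxygen
dips during peak growth.
"""

import fermsense as fs

batch = fs.simulate_batch(fs.source_conditions(seed=1))
df = batch.to_dataframe()

print(df.iloc[[0, 39, 79, 119, 179]].round(3).to_string(index=False))
print(
    f"\nfinal cell concentration C = {batch.C[-1]:.2f} g/L, "
    f"product P = {batch.P[-1]:.2f} g/L "
    f"(substrate exhausted: S = {batch.S[-1]:.3f} g/L)"
)
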