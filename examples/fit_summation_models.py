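"""Fit both linear-summation models to a simulated slice.

Model 0 finds, per cell group, the lumped electrode weights that best
fit the responses to all 31 patterns by least squares.  Model 1 instead
predicts each response as the sum of the group's measured
single-electrode responses (SSER).  Each group's I-O curve (actual vs.
predicted) is then fit by a line through the origin and classified
linear when the uncentered scatter statistic R² exceeds 0.75.
"""

from casum import SliceConfig, analyze_matrix, build_slice, run_experiment

matrix = run_experiment(build_slice(SliceConfig(seed=1)), trials=3, seed=2)

for model in ("model0", "model1"):
    fits = analyze_matrix(matrix, model)
    print(
        f"{model}: {fits['linear'].mean():5.0%} of groups linear, "
        f"median slope {fits['slope'].median():.3f}, "
        f"median R² {fits['r2'].median():.3f}  (n={len(fits)})"
    )

# Slopes near 1 mean the observed response to a multi-electrode pattern
# equals the (weighted) sum of single-electrode responses: the group
# sums its inputs linearly even though each neuron is a threshold unit.
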