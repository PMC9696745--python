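"""Precision versus Z-score cutoff, averaged over repeated runs.

Recreates the evaluation design on synthetic data: 30% of query codes have
no counterpart in the reference, so their mappings are necessarily wrong.
Tightening the cutoff rejects them and raises precision, at the cost of
accepting fewer mappings. Sampling is random, so the mapper is run 30
times and the curve averaged.
"""

import math

from bglm import (
    add_mild_shift,
    generate_scenario,
    make_analyte_panel,
    run_repeated_evaluation,
)

config = make_analyte_panel(30, n_reference_only=20, seed=7, unmapped_fraction=0.3)
query, reference, truth = generate_scenario(add_mild_shift(config))

report = run_repeated_evaluation(
    query, reference, truth,
    cutoff_grid=[-7.0, -6.0, -5.0, -4.0, -3.0, 0.0, math.inf],
    n_runs=30, master_seed=17,
)

print(report.averaged.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
stat, p = report.zscore_separation
print(f"\npooled correct-vs-incorrect Z-score rank-sum: p = {p:.3e}")
print(
    "\nPrecision climbs as the cutoff tightens (accept-everything ~0.63 here,"
    "\n~1.0 at cutoff -5) while the number of accepted mappings falls; the tiny"
    "\np-value shows correct mappings carry systematically lower Z-scores."
)
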