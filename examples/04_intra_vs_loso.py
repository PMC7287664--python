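"""Compare intra-participant and leave-one-subject-out experiments.

Runs the desk-scale preset end to end in both scenarios (4 participants,
2 speeds x 2 trials x 30 s, 20 epochs; a few minutes each on one CPU) and
prints the two reports.  Errors on an unseen runner (LOSO) are larger
than on a runner the model was trained on — the generalisation gap that
motivates the input-dropout regulariser in the LOSO models.
"""

import numpy as np

from accelgait.experiment import run_experiment, scaled_config

for scenario in ("intra", "loso"):
    result = run_experiment(scaled_config(seed=1, scenario=scenario))
    print(f"\n=== {scenario} ===")
    print(result.report.to_text())
    mean_rmse = np.mean([result.report.summary.loc[f"rmse_{j}", "mean"]
                         for j in ("hip", "knee", "ankle")])
    print(f"mean RMSE over joints: {mean_rmse:.2f} deg")
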