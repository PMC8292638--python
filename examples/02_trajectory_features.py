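"""Extract the seven trajectory features for one session.

VTE trials show head sweeps at the choice point: higher integrated heading
change (IdPhi), longer choice-point dwell, and poorer single-valued
polynomial fits than smooth pass-throughs.
"""

import numpy as np

from vte_kit.pipeline import trajectory_feature_table
from vte_kit.synthetic import SimConfig, simulate_session

sess = simulate_session(SimConfig(n_trials=60, seed=1))
table = trajectory_feature_table(sess.positions, sess.trials, sess.votes)

print("features:", ", ".join(table.feature_names))
for label in ("VTE", "nonVTE"):
    rows = table.values[table.labels == label]
    means = dict(zip(table.feature_names, rows.mean(axis=0)))
    print(
        f"{label:>7}: n={len(rows):3d}  zidphi={means['zidphi']:+.2f}  "
        f"dur={means['dur']:.2f}s  r2={means['r2']:.2f}  n_coef={means['n_coef']:.1f}"
    )
# Expect positive mean zidphi, longer durations, and lower r2 for VTEs:
# a sweeping head trajectory is not a single-valued function of x.
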