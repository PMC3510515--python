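"""Null calibration of the relative local conservation score.

Draws 20,000 RLC scores from proteins with no planted motifs (every column
drifts independently, uniform disorder) and summarises how well the score
matches its nominal standard-normal reference: the mean should be near 0,
about half the scores positive, and the Gaussian tail probabilities p_RLC
roughly uniform.  The Kolmogorov-Smirnov statistic quantifies the residual
deviation of the Gaussian-tail heuristic (see docs/methods.md).
"""

import numpy as np
from scipy import stats

from slimprints.synthetic import null_rlc_sample

z = null_rlc_sample(20_000, seed=7)
p = stats.norm.sf(z)
ks = stats.kstest(p, "uniform")

print(f"n residues          : {len(z)}")
print(f"mean RLC            : {z.mean():+.4f}   (expected ~0)")
print(f"sd RLC              : {z.std():.4f}    (expected ~1)")
print(f"fraction RLC > 0    : {(z > 0).mean():.4f}   (expected ~0.5)")
print(f"KS distance to U(0,1): {ks.statistic:.4f}  (p = {ks.pvalue:.2e})")
print(
    "\nThe mean and sign balance confirm the windowed z-score is centred; "
    "the small but nonzero KS distance is the systematic cost of reading "
    "a 60-residue windowed z-score through the exact Gaussian tail."
)
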