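"""Rank competing forecasters from their loss matrices.

Three procedures consume the same observations x models RMSE matrix:
Plackett-Luce Bayesian ranking (probability of being the best), the
Model Confidence Set (survivors statistically indistinguishable from the
best at alpha = 0.05) and the Superior Predictive Ability test (is any
competitor better than a chosen benchmark?).
"""

import numpy as np

from glybench import LossMatrix, mcs, pl_ranking, spa

# synthetic per-fold-per-patient RMSE losses: "alpha" is genuinely best,
# "beta" is a close rival, "gamma" and "delta" are clearly worse
rng = np.random.default_rng(7)
base = rng.gamma(20.0, 1.0, size=(60, 1))
losses = np.hstack([
    base,
    base + rng.normal(0.3, 0.5, (60, 1)),
    base + rng.normal(3.0, 0.8, (60, 1)),
    base + rng.normal(4.0, 0.8, (60, 1)),
])
lm = LossMatrix(np.abs(losses), ("alpha", "beta", "gamma", "delta"), horizon="30")

pl = pl_ranking(lm, seed=7)
print("Plackett-Luce probability of being the best:")
for m, p, lo, hi in zip(pl.model_ids, pl.p_best, pl.ci_low, pl.ci_high):
    print(f"  {m:<7} {p:.3f}  [90% CI {lo:.3f}-{hi:.3f}]")

res = mcs(lm, alpha=0.05, n_bootstrap=1000, seed=7)
print(f"\nModel Confidence Set at alpha=0.05: {res.survivors}")
for m in res.model_ids:
    print(f"  {m:<7} p = {res.p_values[m]:.3f}")

print("\nSuperior Predictive Ability (consistent p; high = hard to beat):")
for m in lm.model_ids:
    r = spa(lm, m, n_bootstrap=1000, seed=7)
    print(f"  benchmark {m:<7} p_consistent = {r.p_consistent:.3f}")
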