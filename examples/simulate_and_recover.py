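"""Simulate one step-stress test and recover the rates with intervals.

Draws a single progressively censored dataset (40 units, 15 + 15 failures,
true rates 2, 1, 4, 2), fits the MLE, and prints 95% asymptotic and
percentile-bootstrap intervals. The intervals should usually bracket the
true rates; the stage-2 rates are estimated from the post-change exposure
only and are therefore wider.
"""

from stepstress import (
    CensoringScheme,
    PARAM_KEYS,
    RateParams,
    aci,
    bootstrap_p,
    mle,
    simulate_dataset,
    sufficient_stats,
)

true = RateParams(2.0, 1.0, 4.0, 2.0)
scheme = CensoringScheme(40, 15, 15, (0,) * 11 + (1, 1, 2, 1) + (0,) * 11 + (1, 1, 2, 1))
data = simulate_dataset(true, scheme, seed=2026)
stats = sufficient_stats(data)
est = mle(stats)
asym = aci(est, stats, level=0.95)
boot = bootstrap_p(data, B=1000, level=0.95, seed=2026)

print(f"stress change at tau = {data.tau:.4f} (15th failure)")
print(f"{'param':<10}{'true':>6}{'mle':>8}{'95% ACI':>20}{'95% boot-p':>20}")
for key in PARAM_KEYS:
    lo, hi = asym[key]
    blo, bhi = boot[key]
    print(
        f"lambda{key[0]}{key[1]:<4}{true[key]:>6.1f}{est[key]:>8.4f}"
        f"{f'({lo:.3f}, {hi:.3f})':>20}{f'({blo:.3f}, {bhi:.3f})':>20}"
    )
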