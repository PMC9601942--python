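"""Fit the packaged illustrative dataset with every point estimator.

The dataset is a simulated step-stress competing-risks life test: 30 units,
10 failures at the low stress, a stress raise at the 10th failure, 12 more
failures, and 4 units withdrawn at the end of each stage. Printed below are
the failure counts/exposures and, for each estimator, the four rate
estimates lambda_ij (stress i, cause j). Bayesian rows shrink the MLE
toward the prior; the entropy and LINEX losses penalize overestimation and
so sit below the posterior mean.
"""

from stepstress import (
    GammaPrior,
    HyperPrior,
    LossSpec,
    PARAM_KEYS,
    bayes_estimate,
    ebayes_estimate,
    hbayes_estimate,
    load_illustrative_dataset,
    mle,
    sufficient_stats,
)

data = load_illustrative_dataset()
stats = sufficient_stats(data)
print(f"counts n_ij = {stats.counts}")
print(f"exposures: stage 1 = {stats.exposure(1):.5f}, stage 2 = {stats.exposure(2):.5f}")

prior = GammaPrior.constant(0.5, 0.1)
hyper = HyperPrior(c=0.2, family="uniform")
rows = [("mle", mle(stats))]
for loss in (LossSpec("self"), LossSpec("elf"), LossSpec("linex", 4.0)):
    rows.append((f"bayes/{loss.loss}", bayes_estimate(stats, prior, loss)))
    rows.append((f"ebayes/{loss.loss}", ebayes_estimate(stats, hyper, loss)))
    rows.append((f"hbayes/{loss.loss}", hbayes_estimate(stats, hyper, loss)))

header = "".join(f"lambda{i}{j}".rjust(10) for i, j in PARAM_KEYS)
print(f"{'estimator':<14}{header}")
for name, est in rows:
    print(f"{name:<14}" + "".join(f"{est[k]:10.4f}" for k in PARAM_KEYS))
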