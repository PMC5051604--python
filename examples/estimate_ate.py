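"""Estimate the ATE on one simulated dataset with all six estimators.

Uses correctly specified parametric nuisance models on a good-overlap draw,
so every method should land near the true effect of 0.4.
"""

from drbench import (
    DGPConfig,
    bcm,
    fit_outcome_parametric,
    fit_ps_parametric,
    gcomp,
    iptw,
    naive_estimator,
    ps_match,
    simulate_dataset,
    tmle,
    wls,
)

ds = simulate_dataset(DGPConfig(1, n=1000, seed=7))

g = fit_ps_parametric(ds, terms="true_ps")
q_pooled = fit_outcome_parametric(ds, terms="true_outcome")
q_by_arm = fit_outcome_parametric(ds, terms="true_outcome", stratify_by_arm=True)
gv = g.propensity(ds.W)

estimates = [
    naive_estimator(ds),
    gcomp(q_pooled, ds),
    iptw(gv, ds),
    wls(gv, ds),
    ps_match(gv, ds)[1],
    bcm(gv, q_by_arm, ds),
    tmle(gv, q_pooled, ds)[1],
]
print(f"{'method':8s} {'psi_hat':>8s} {'se':>7s}   95% CI        (truth 0.4)")
for est in estimates:
    print(f"{est.method:8s} {est.psi_hat:8.4f} {est.se:7.4f}   "
          f"[{est.ci_lo:.3f}, {est.ci_hi:.3f}]")

# The naive mean difference is confounded in expectation (about 20% relative
# bias over replications of this DGP, though any single draw is noisy); the
# adjusted methods all cover the true effect 0.4 with their 95% intervals.
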