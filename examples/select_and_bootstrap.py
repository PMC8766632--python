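"""Cross-validated model selection followed by bootstrap uncertainty.

Selects the mislabeling rates and L1 budget by repeated 75/25 random-split
cross-validation of the validation likelihood, then quantifies uncertainty
with a non-parametric within-group bootstrap: posterior summaries of the
mislabeling rates (including the posterior mass on perfect labeling) and 95%
intervals for the coefficients.
"""

import numpy as np

from colabel import (
    CvPlan,
    GridSpec,
    MislabelBounds,
    SolverConfig,
    SyntheticSpec,
    bootstrap_fit,
    cross_validate,
    generate,
    posterior_mislabeling,
)

spec = SyntheticSpec(
    n_binary=3,
    n_continuous=1,
    complement_pairs=False,
    true_alpha=[1.5, -2.0, 1.0, 0.8, -0.6],
    flip=np.array([[0.90, 0.05], [0.10, 0.95]]),
    group_sizes=(2000,),
    seed=3,
)
dataset, _ = generate(spec)

bounds = MislabelBounds.uniform(0.0, 0.2)
grid = GridSpec.from_bounds(bounds, step=0.05, c_values=(2.0, 8.0))
config = SolverConfig(n_restarts=1)

report = cross_validate(
    dataset, bounds, grid, ("logit",), CvPlan(n_repeats=20, seed=0), config
)
print("CV-selected flip rates:", report.chosen_offs, "C =", report.chosen_c)

ens = bootstrap_fit(dataset, bounds, grid, "logit", config, B=30, seed=1)
post = posterior_mislabeling(ens)
for name, entry in post["entries"].items():
    print(f"{name}: mean {entry['mean']:.3f}  95% CI [{entry['ci_lo']:.2f}, {entry['ci_hi']:.2f}]")
print("posterior mass on perfect labeling:", post["perfect_labeling_fraction"])
print(ens.alpha_summary().round(2))
# With 10%/5% corruption the perfect-labeling posterior mass is small and the
# bootstrap means of the flip rates sit near the truth (0.10, 0.05). The CV
# choice applies a one-standard-error rule that prefers the least-mislabeling
# model among statistically indistinguishable grid points, so at modest
# repeat counts it errs toward smaller rates than the posterior mean.
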