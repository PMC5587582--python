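"""Power of the joint test vs univariate-Bonferroni and TATES-style baselines.

A diffuse effect alternates in sign across five traits that are
positively correlated (rho = 0.5): each marginal effect is modest but the
multivariate signal is strong. Rejection frequencies at alpha = 0.05.
"""

from pleioscan.simulate import power_experiment

table = power_experiment(
    [0.0, 0.05, 0.08, 0.11],
    scenario="diffuse",
    n=1000,
    k=5,
    rho=0.5,
    alpha=0.05,
    n_reps=300,
    seed=2,
)
print(table.pivot(index="effect", columns="method", values="power").round(3))
print(
    "\neffect 0.0 is the null (all methods should sit near 0.05); at larger\n"
    "effects the MANOVA column dominates because it models the trait\n"
    "correlation that the per-trait baselines ignore."
)
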