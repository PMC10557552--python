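"""Power of both tests against a real cross-correlation (scaled-down grid).

Under a genuine dependence (rho = 0.4 innovation correlation, Spearman
cross-correlation ~ 0.39) the classical test rejects more often — its extra
power is bought with the inflated type-I error seen in the null study — and
both powers approach 1 as n grows.
"""

from srdcor import StudyGrid, power_curve, true_spearman_var1

grid = StudyGrid(
    model="var1",
    params=(0.6,),
    rhos=(0.4,),
    ns=(40, 100, 200, 500),
    reps=1000,
    methods=("classical", "modified"),
    seed=2,
)
result = power_curve(grid)
print(f"true Spearman cross-correlation: {true_spearman_var1(0.4):.4f}\n")
print(result.table.pivot_table(index="n", columns="method", values="rejection_rate").round(3))
print(
    "\nRows are sample sizes; entries are rejection frequencies over 1000\n"
    "simulations at alpha=0.05 (the observed power). Both columns rise toward 1;\n"
    "the modified test pays a moderate power price for its level correctness."
)
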