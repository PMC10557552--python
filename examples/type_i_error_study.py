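"""Type-I error of both tests as autocorrelation grows (scaled-down grid).

Reproduces the shape of the null rejection study: rejection frequency of a
two-sided Spearman test at alpha = 0.05 under zero cross-correlation, for
increasing AR(1) parameters in both components.  The classical rate climbs well
above 5% while the modified rate stays near it.
"""

from srdcor import StudyGrid, run_rejection_study

grid = StudyGrid(
    model="var1",
    params=(0.0, 0.4, 0.8),  # phi_x = phi_y
    rhos=(0.0,),
    ns=(40, 200),
    reps=2000,
    methods=("classical", "modified"),
    seed=1,
)
result = run_rejection_study(grid)
table = result.table.pivot_table(index=["param", "n"], columns="method", values="rejection_rate")
print(table.round(3))
print(
    "\nEach cell is the fraction of 2000 null simulations rejected at alpha=0.05\n"
    "(Monte-Carlo SE ~ 0.005-0.010). Rates near 0.05 are correct; the classical\n"
    "column inflates with phi, the modified column does not (apart from a small\n"
    "n=40 excess under phi=0.8 that fades at n=200)."
)
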