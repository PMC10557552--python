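"""Smoothing annual station series manufactures spurious significance.

Builds a synthetic network of stations with 51 years of serially independent,
mutually independent annual pairs (think flood peaks vs. temperatures), applies
the usual centered 5-year equal-weight moving average to both series, and
batch-tests every station.  Smoothing makes each series autocorrelated, so the
classical test flags far more than 5% of these truly unrelated stations; the
modified test keeps the false-discovery fraction near the nominal level.
"""

from srdcor import TestConfig, batch_station_test, synthetic_station_network

table = synthetic_station_network(n_stations=300, n_years=51, dependent_fraction=0.0, seed=3)
res = batch_station_test(table, TestConfig(alpha=0.05), window=5, methods=("classical", "modified"))

for method in ("classical", "modified"):
    k = res.n_significant(method)
    print(f"{method:>9}: {k:3d} / {res.n_total} stations significant ({k / res.n_total:.1%})")

print(
    "\nNo station has any true cross-dependence, so ~5% significant is correct.\n"
    "The classical excess is entirely an artifact of the 5-year smoothing filter."
)
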