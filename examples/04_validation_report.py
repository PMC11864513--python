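"""A full accreditation-style validation run on simulated reference material.

Simulates the reference-standard and clinical-reference truth sets plus
wild-type loci, runs calling + the optimised filter cascade (UAO >= 3,
LLOD 0.004), and prints trueness, LLOD and analytical-range summaries.
"""

from chipvalid import SimConfig, analytical_range, reference_grid
from chipvalid.studies import llod_study, run_trueness_study

study = run_trueness_study(seed=1)
c = study.counts
print(f"confusion counts: TP {c.tp}  FN {c.fn}  FP {c.fp}  TN {c.tn}")
for _, row in study.metrics.iterrows():
    flag = "pass" if row["passed"] else "FAIL"
    print(f"  {row['metric']:12s} {row['percent']:6.1f}%  (acceptance >= 98%: {flag})")

res = llod_study(seed=1)
print("\nreplicate detection rate by VAF (8 library preparations, UAO >= 3):")
for vaf, rate in sorted(res.rates.items(), reverse=True):
    print(f"  VAF {vaf:7.4f}  {rate * 100:5.1f}%")
print(f"LLOD (>= 95% of replicates detected, contiguous): {res.llod_vaf}")

grid = reference_grid().dropna(subset=["observed_vaf"])
grid = grid[grid["expected_vaf"] >= 0.004]
fit = analytical_range(
    list(zip(grid["expected_vaf"], grid["observed_vaf"])),
    exclusions=("ASXL1:c.1934dup", "FLT3:c.2503G>T"),
    loci=list(grid["locus_id"]),
)
print(
    f"\nanalytical range on the packaged dilution grid ({fit.n} pairs): "
    f"r = {fit.r:.4f}, R^2 = {fit.r2:.4f}, fold bias = {fit.fold_bias:.2f} "
    f"[{fit.limits[0]:.2f}, {fit.limits[1]:.2f}]"
)
print(
    "\nTrueness is perfect on this synthetic material; the measured VAFs are"
    "\nhighly linear in the expected VAFs with a mild sub-unity recovery bias."
)
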