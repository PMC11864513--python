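"""Consensus calling and the variant-exclusion cascade, rule by rule.

Simulates one locus carrying a 2% clone, calls it, then pushes a small
hand-made table of problem calls through the cascade to show per-rule
provenance.
"""

from chipvalid import FilterConfig, SimConfig, VariantSpec, apply_filters, simulate_pileup
from chipvalid.consensus import call_variants
from chipvalid.types import VariantCall

spec = VariantSpec(locus_id="DNMT3A:R882H", true_vaf=0.02, consequence_tag="missense")
pile = simulate_pileup([spec], SimConfig(seed=5), n_families=2000)
(call,) = call_variants(pile)
print(
    f"{call.locus_id}: VAF {call.vaf:.4f}, depth {call.depth} reads, "
    f"UAO {call.uao} families ({call.alt_fwd}+ / {call.alt_rev}-)"
)

problem_calls = [
    call,  # the genuine clone above
    call.annotated(locus_id="X:germline", vaf=0.50),
    call.annotated(locus_id="X:too_few_molecules", uao=2, alt_fwd=1, alt_rev=1),
    call.annotated(locus_id="X:one_strand_only", uao=40, alt_fwd=40, alt_rev=0),
    call.annotated(locus_id="X:below_llod", vaf=0.002),
    call.annotated(locus_id="ASXL1:c.1934dup"),  # homopolymer locus, LLOD 0.031
]
print("\nfilter cascade provenance (empty = pass):")
for outcome in apply_filters(problem_calls, FilterConfig()):
    rules = ";".join(outcome.failed_rules) or "PASS"
    print(f"  {outcome.call.locus_id:24s} {rules}")

print(
    "\nEach call is checked against every rule; a genuine 2%-VAF clone passes,"
    "\nwhile germline-like, under-supported, single-stranded, sub-LLOD and"
    "\nhomopolymer-locus calls are excluded with named reasons."
)
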