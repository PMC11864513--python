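import math

import pytest

from chipvalid import Family, Pileup, SimConfig, VariantCall, VariantSpec


@pytest.fixture
def error_free_config():
    """Pure molecule-sampling simulator: no artifacts, no read errors."""
    return SimConfig(
        pre_consensus_error=0.0,
        post_consensus_error=0.0,
        reads_per_family_mean=1.0,
        seed=7,
    )


def make_call(**over) -> VariantCall:
    """A valid call passing every filter rule unless overridden."""
    base = dict(
        locus_id="GENE:v1",
        allele="alt",
        variant_class="SNP",
        vaf=0.03,
        depth=3000,
        uao=30,
        alt_fwd=15,
        alt_rev=15,
        ref_fwd=1485,
        ref_rev=1485,
        consequence_tag="missense",
        population_af=0.0,
    )
    base.update(over)
    return VariantCall(**base)


def make_pileup(n_alt, n_ref, alt_reads=1, ref_reads=1, locus="GENE:v1", truth_vaf=None):
    """Constructed pileup: n_alt alt families and n_ref ref families, balanced strands."""
    fams = []
    fid = 0
    for i in range(n_alt):
        fams.append(Family(fid, "alt", "+" if i % 2 else "-", alt_reads))
        fid += 1
    for i in range(n_ref):
        fams.append(Family(fid, "ref", "+" if i % 2 else "-", ref_reads))
        fid += 1
    truth = (
        (VariantSpec(locus_id=locus, true_vaf=truth_vaf),) if truth_vaf is not None else ()
    )
    return Pileup(locus_id=locus, families=tuple(fams), truth=truth)


def fisher_two_sided_oracle(a, b, c, d) -> float:
    """Exact two-sided Fisher p by hypergeometric enumeration (independent oracle)."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = math.comb(n, c1)
    def pmf(x):
        return math.comb(r1, x) * math.comb(r2, c1 - x) / denom
    p_obs = pmf(a)
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    return sum(pmf(x) for x in range(lo, hi + 1) if pmf(x) <= p_obs * (1 + 1e-9))
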