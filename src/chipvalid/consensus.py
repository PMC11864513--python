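"""UMI-family consensus collapsing and variant calling.

A family's consensus allele is the majority allele among its reads, which
corrects residual per-read errors in families of two or more reads;
singleton families keep their single read's allele (uncorrectable). Ties
resolve to the reference allele, conservative against false positives.

Reported metrics follow assay convention: VAF and depth are read-level,
UAO (unique alternate observations) and strand counts are family-level —
so VAF need not equal uao/depth when alternate families are larger or
smaller than average.
"""

from __future__ import annotations

from collections import Counter

from .types import REF, Family, Pileup, VariantCall, VariantSpec


def consensus_allele(family: Family) -> str:
    """Majority allele among a family's reads; ties go to reference."""
    kept = family.read_count - family.flipped
    if kept > family.flipped:
        return family.allele
    if family.flipped > kept:
        return family.flip_allele  # type: ignore[return-value]
    return REF


def group_families(pileup: Pileup) -> list[tuple[Family, str]]:
    """Pair each family with its consensus allele."""
    return [(fam, consensus_allele(fam)) for fam in pileup.families]


def call_variants(pileup: Pileup) -> list[VariantCall]:
    """Emit one call per alternate allele supported by >= 1 consensus family.

    VAF = alternate reads / total reads; depth = total reads; UAO = number
    of consensus families supporting the alternate; strand counts are
    consensus-family counts. Calls are a pure function of the pileup.
    """
    if not pileup.families:
        return []
    grouped = group_families(pileup)
    depth = pileup.depth
    read_counts = pileup.read_allele_counts()

    fam_by_allele: Counter[str] = Counter()
    strand_counts: dict[str, Counter[str]] = {}
    for fam, allele in grouped:
        fam_by_allele[allele] += 1
        strand_counts.setdefault(allele, Counter())[fam.strand] += 1

    ref_strands = strand_counts.get(REF, Counter())
    truth_by_allele: dict[str, VariantSpec] = {v.allele: v for v in pileup.truth}

    calls = []
    for allele in sorted(a for a in fam_by_allele if a != REF):
        uao = fam_by_allele[allele]
        alt_strands = strand_counts[allele]
        truth = truth_by_allele.get(allele)
        calls.append(
            VariantCall(
                locus_id=pileup.locus_id,
                allele=allele,
                variant_class=truth.variant_class if truth else "SNP",
                vaf=read_counts.get(allele, 0) / depth,
                depth=depth,
                uao=uao,
                alt_fwd=alt_strands.get("+", 0),
                alt_rev=alt_strands.get("-", 0),
                ref_fwd=ref_strands.get("+", 0),
                ref_rev=ref_strands.get("-", 0),
                consequence_tag=truth.consequence_tag if truth else "missense",
                population_af=truth.population_af if truth else 0.0,
                true_vaf=truth.true_vaf if truth else None,
            )
        )
    return calls
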