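"""End-to-end validation studies composed from the simulator and pipeline.

Each function runs a complete study — simulate molecule-limited pileups,
collapse UMI families, call variants, apply the full filter cascade — and
measures a validation quantity: the trueness confusion matrix, the
detection rate under a UAO threshold, or the LLOD across a dilution
series. These are the entry points the acceptance checks and the worked
examples use.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .consensus import call_variants
from .filters import FilterConfig, apply_filters
from .metrics import llod, trueness
from .reference import (
    clinical_reference_variants,
    stock_depths,
    trueness_standard_variants,
    wildtype_loci,
)
from .simulate import SimConfig, VariantSpec, _rng_for, simulate_pileup
from .types import ConfusionCounts, pass_set


@dataclass(frozen=True)
class TruenessStudy:
    """Result of a full trueness validation run."""

    counts: ConfusionCounts
    metrics: pd.DataFrame
    detected_loci: tuple[str, ...]
    false_positive_loci: tuple[str, ...]


def _families_for_depth(depth_reads: float, config: SimConfig, floor: int = 1000) -> int:
    """Effective molecule budget implied by a target read depth (>= floor)."""
    return max(floor, int(round(depth_reads / config.reads_per_family_mean)))


def run_trueness_study(
    seed: int = 1234,
    config: SimConfig | None = None,
    filter_config: FilterConfig | None = None,
    clinical_families: int = 3000,
    wildtype_families: int = 3000,
) -> TruenessStudy:
    """Trueness of the optimised pipeline against reference material.

    Simulates the 23 reference-standard variants at their validated
    VAFs/depths, 36 clinical-reference variants (VAF >= 0.05, 3,000
    families), and 29 wild-type loci (true VAF 0, residual post-consensus
    error only); runs consensus calling plus the full cascade (UAO >= 3,
    LLOD 0.004 with the ASXL1:c.1934dup override); scores TP/FN on the
    truth variants and FP/TN on the wild-type loci.
    """
    config = config or SimConfig(seed=seed)
    filter_config = filter_config or FilterConfig()
    depths = stock_depths()

    positives: list[tuple[VariantSpec, int]] = []
    for spec in trueness_standard_variants():
        nfam = _families_for_depth(depths.get(spec.locus_id, 5100.0), config)
        positives.append((spec, nfam))
    for spec in clinical_reference_variants():
        positives.append((spec, clinical_families))

    detected: list[str] = []
    missed: list[str] = []
    for i, (spec, nfam) in enumerate(positives):
        rng = _rng_for(seed, 10, i)
        pile = simulate_pileup([spec], config, n_families=nfam, rng=rng)
        passing = pass_set(apply_filters(call_variants(pile), filter_config))
        hit = any(c.locus_id == spec.locus_id and c.allele == spec.allele for c in passing)
        (detected if hit else missed).append(spec.locus_id)

    wt_config = SimConfig(
        input_ng=config.input_ng,
        conversion_efficiency=config.conversion_efficiency,
        target_read_depth=config.target_read_depth,
        reads_per_family_mean=config.reads_per_family_mean,
        pre_consensus_error=0.0,
        post_consensus_error=1e-4,
        strand_artifact_rate=config.strand_artifact_rate,
        seed=config.seed,
    )
    fp_loci: list[str] = []
    for i, locus in enumerate(wildtype_loci()):
        rng = _rng_for(seed, 11, i)
        pile = simulate_pileup(
            [], wt_config, locus_id=locus, n_families=wildtype_families, rng=rng
        )
        passing = pass_set(apply_filters(call_variants(pile), filter_config))
        if passing:
            fp_loci.append(locus)

    n_wt = len(wildtype_loci())
    counts = ConfusionCounts(
        tp=len(detected), fn=len(missed), fp=len(fp_loci), tn=n_wt - len(fp_loci)
    )
    return TruenessStudy(
        counts=counts,
        metrics=trueness(counts),
        detected_loci=tuple(detected),
        false_positive_loci=tuple(fp_loci),
    )


def uao_detection_rate(
    vaf: float,
    n_families: int,
    n_replicates: int,
    uao_min: int = 3,
    seed: int = 1234,
) -> float:
    """Percent of replicate loci detected under a pure UAO >= threshold rule.

    Error-free molecule model: each replicate simulates ``n_families``
    unique molecules at the given VAF and is scored detected when the
    number of alternate consensus families reaches ``uao_min``. Converges
    to ``100 * (1 - BinomCDF(uao_min - 1; n_families, vaf))``.
    """
    config = SimConfig(
        pre_consensus_error=0.0, post_consensus_error=0.0, seed=seed
    )
    spec = VariantSpec(locus_id="locus", true_vaf=vaf)
    hits = 0
    for r in range(n_replicates):
        rng = _rng_for(seed, 12, r)
        pile = simulate_pileup([spec], config, n_families=n_families, rng=rng)
        calls = call_variants(pile)
        uao = next((c.uao for c in calls if c.allele == spec.allele), 0)
        hits += uao >= uao_min
    return 100.0 * hits / n_replicates


def llod_study(
    vaf_grid: tuple[float, ...] = (0.05, 0.0125, 0.004, 0.0031, 0.0016, 0.0008),
    n_families: int = 3121,
    n_replicates: int = 8,
    uao_min: int = 3,
    criterion: float = 0.95,
    seed: int = 1234,
):
    """LLOD from replicate detection rates across a VAF grid.

    Eight independent library preparations per VAF at the validated mean
    molecule budget; detection per the UAO rule; LLOD per the >= 95%
    replicate-detection criterion with contiguity.
    """
    rates = {}
    for vi, vaf in enumerate(vaf_grid):
        rates[vaf] = (
            uao_detection_rate(
                vaf, n_families, n_replicates, uao_min=uao_min, seed=seed + 1000 * vi
            )
            / 100.0
        )
    return llod(rates, criterion=criterion, overrides=dict())
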