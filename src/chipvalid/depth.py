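"""Read-depth normalisation and detection-rate estimation.

Depth is normalised by random subsampling of reads (not families), after
which consensus is recomputed — families whose reads all vanish drop out,
so UAO can only decrease. Detection rates are tabulated across replicates
and expected-VAF bins, with a closed-form binomial detection-probability
oracle ``1 - BinomCDF(u-1; m, f)`` for the error-free molecule model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .consensus import call_variants
from .filters import FilterConfig, apply_filters
from .simulate import SimConfig, _rng_for, molecules_from_input, simulate_pileup
from .types import Family, Pileup, VariantCall, VariantSpec, pass_set

#: read-depth grid used for depth/detection curves
DEFAULT_DEPTH_GRID = (500, 1000, 2000, 3000, 4000, 5000)

#: expected-VAF bins used in replicate-concordance reporting
DEFAULT_VAF_BINS = ((0.001, 0.005), (0.005, 0.01), (0.01, 0.02), (0.02, 1.0))


def subsample_reads(
    pileup: Pileup,
    target_depth: int,
    rng: np.random.Generator | int | None = None,
) -> Pileup:
    """Downsample a pileup to ``target_depth`` reads, uniformly without replacement.

    Families losing all reads are dropped; everything downstream (consensus,
    VAF, UAO) is recomputed from the surviving reads. The expected alternate
    read fraction is preserved (hypergeometric sampling is unbiased).
    """
    depth = pileup.depth
    if target_depth > depth:
        raise ValueError(f"target_depth {target_depth} exceeds pileup depth {depth}")
    if target_depth == depth:
        return pileup
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)

    # two read classes per family: reads on the family allele, flipped reads
    colors = np.empty(2 * len(pileup.families), dtype=np.int64)
    for i, fam in enumerate(pileup.families):
        colors[2 * i] = fam.read_count - fam.flipped
        colors[2 * i + 1] = fam.flipped
    survived = rng.multivariate_hypergeometric(colors, target_depth, method="marginals")

    families = []
    for i, fam in enumerate(pileup.families):
        kept = int(survived[2 * i])
        flip = int(survived[2 * i + 1])
        if kept + flip == 0:
            continue
        families.append(
            Family(
                family_id=fam.family_id,
                allele=fam.allele,
                strand=fam.strand,
                read_count=kept + flip,
                flipped=flip,
                flip_allele=fam.flip_allele if flip else None,
            )
        )
    return Pileup(locus_id=pileup.locus_id, families=tuple(families), truth=pileup.truth)


def detection_prob(f: float, m: int, u: int) -> float:
    """Closed-form detection probability under the binomial molecule model.

    Probability that at least ``u`` of ``m`` unique molecules carry an
    allele of frequency ``f``: ``1 - BinomCDF(u-1; m, f)``. Monotone
    increasing in ``f`` and ``m``, decreasing in ``u``.
    """
    if not 0.0 <= f <= 1.0:
        raise ValueError("f must be in [0, 1]")
    if m < 0 or u < 0:
        raise ValueError("m and u must be >= 0")
    if u == 0:
        return 1.0
    return float(scipy.stats.binom.sf(u - 1, m, f))


def _detected(call_sets: Sequence[Sequence[VariantCall]], spec: VariantSpec) -> list[bool]:
    return [
        any(c.locus_id == spec.locus_id and c.allele == spec.allele for c in calls)
        for calls in call_sets
    ]


def detection_rate(
    replicate_calls: Sequence[Sequence[VariantCall]],
    truth: Sequence[VariantSpec],
    bins: Sequence[tuple[float, float]] = DEFAULT_VAF_BINS,
    expected_vafs: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Detection rates of truth variants across replicates, per expected-VAF bin.

    A variant is *concordantly* detected when present in the post-filter call
    set of every replicate (``rate_all``); ``rate_any`` uses presence in at
    least one replicate. Bins are half-open ``[lo, hi)`` on the expected VAF
    (``expected_vafs`` overrides ``spec.true_vaf`` when dilution-rounded
    values are wanted). Empty bins get NaN rates, flagged, never zero.
    """
    n_rep = len(replicate_calls)
    if n_rep == 0:
        raise ValueError("at least one replicate required")
    rows = []
    for lo, hi in bins:
        members = [
            s
            for s in truth
            if lo <= (expected_vafs or {}).get(s.locus_id, s.true_vaf) < hi
        ]
        n_all = n_any = 0
        for spec in members:
            hits = _detected(replicate_calls, spec)
            n_all += all(hits)
            n_any += any(hits)
        empty = len(members) == 0
        rows.append(
            {
                "vaf_lo": lo,
                "vaf_hi": hi,
                "n_variants": len(members),
                "n_replicates": n_rep,
                "n_detected_all": n_all,
                "rate_all": np.nan if empty else n_all / len(members),
                "n_detected_any": n_any,
                "rate_any": np.nan if empty else n_any / len(members),
                "empty_bin": empty,
            }
        )
    return pd.DataFrame(rows)


def depth_detection_curve(
    truth: Sequence[VariantSpec],
    config: SimConfig,
    depths: Sequence[int] = DEFAULT_DEPTH_GRID,
    n_replicates: int = 3,
    filter_config: FilterConfig | None = None,
    bins: Sequence[tuple[float, float]] = DEFAULT_VAF_BINS,
) -> pd.DataFrame:
    """Concordant detection rate per VAF bin across a read-depth grid.

    Simulates each truth variant at the maximum grid depth per replicate,
    normalises down to every smaller depth by read subsampling, re-calls and
    re-filters, and tabulates detection. Mirrors the depth-optimisation
    design: rates should be non-decreasing in depth and in expected VAF.
    """
    filter_config = filter_config or FilterConfig()
    depths = sorted(depths)
    full_depth = depths[-1]
    # full-depth pileups per replicate
    pileups: list[list[Pileup]] = []
    for r in range(n_replicates):
        reps = []
        for vi, spec in enumerate(truth):
            rng = _rng_for(config.seed, 3, r, vi)
            nfam = min(
                molecules_from_input(config.input_ng, config.conversion_efficiency),
                int(round(full_depth / config.reads_per_family_mean)),
            )
            reps.append(simulate_pileup([spec], config, n_families=nfam, rng=rng))
        pileups.append(reps)

    frames = []
    for depth in depths:
        call_sets = []
        for r, reps in enumerate(pileups):
            calls: list[VariantCall] = []
            for vi, pile in enumerate(reps):
                target = min(depth, pile.depth)
                sub = subsample_reads(pile, target, rng=_rng_for(config.seed, 4, depth, r, vi))
                calls.extend(pass_set(apply_filters(call_variants(sub), filter_config)))
            call_sets.append(calls)
        table = detection_rate(call_sets, truth, bins=bins)
        table.insert(0, "depth", depth)
        frames.append(table)
    return pd.concat(frames, ignore_index=True)
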