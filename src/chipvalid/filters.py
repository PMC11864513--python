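"""The ordered variant-exclusion cascade.

Eight conjunctive rules, evaluated in a fixed order with full provenance
(every failed rule is recorded, not just the first):

1.  ``population_af``   — population prevalence >= 5% (likely germline SNP)
2.  ``vaf_floor``       — allele frequency < 0.0001 (below error floor)
3.  ``strand_bias``     — significant (p <= 0.05) forward/reverse asymmetry
                          of alternate vs reference families (deamination /
                          PCR artifact signature)
4.  ``germline_window`` — VAF in [0.45, 0.55] or >= 0.95 (likely germline)
5.  ``functional_relevance`` — consequence not in the accepted category set
6.  ``cohort_prevalence``    — recurrent in > 10% of cohort samples
                               (likely sequencing artifact; cohort mode only)
7.  ``uao_min``         — fewer than 3 unique alternate observations
8.  ``llod``            — observed VAF below the validated limit of
                          detection (global 0.004, with per-locus
                          overrides such as ASXL1:c.1934dup at 0.031)

Because the rules are conjunctive, the pass/fail verdict is order
independent; only the provenance order is fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import scipy.stats

from .types import FUNCTIONAL_TAGS, FilterOutcome, VariantCall

RULE_ORDER = (
    "population_af",
    "vaf_floor",
    "strand_bias",
    "germline_window",
    "functional_relevance",
    "cohort_prevalence",
    "uao_min",
    "llod",
)


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the exclusion cascade (defaults = validated assay)."""

    population_af_max: float = 0.05
    vaf_floor: float = 0.0001
    strand_bias_alpha: float = 0.05
    germline_window: tuple[float, float] = (0.45, 0.55)
    germline_high: float = 0.95
    functional_tags: frozenset[str] = FUNCTIONAL_TAGS
    cohort_prevalence_max: float = 0.10
    uao_min: int = 3
    locus_llod_overrides: Mapping[str, float] = field(
        default_factory=lambda: {"ASXL1:c.1934dup": 0.031}
    )
    global_llod: float = 0.004

    def __post_init__(self) -> None:
        for name in ("population_af_max", "vaf_floor", "strand_bias_alpha",
                     "cohort_prevalence_max", "global_llod", "germline_high"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.uao_min < 0:
            raise ValueError("uao_min must be >= 0")

    def llod_for(self, locus_id: str) -> float:
        return self.locus_llod_overrides.get(locus_id, self.global_llod)

    def as_dict(self) -> dict:
        return {
            "population_af_max": self.population_af_max,
            "vaf_floor": self.vaf_floor,
            "strand_bias_alpha": self.strand_bias_alpha,
            "germline_window_low": self.germline_window[0],
            "germline_window_high": self.germline_window[1],
            "germline_high": self.germline_high,
            "functional_tags": sorted(self.functional_tags),
            "cohort_prevalence_max": self.cohort_prevalence_max,
            "uao_min": self.uao_min,
            "locus_llod_overrides": dict(self.locus_llod_overrides),
            "global_llod": self.global_llod,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "FilterConfig":
        d = dict(d)
        window = (d.pop("germline_window_low", 0.45), d.pop("germline_window_high", 0.55))
        tags = d.pop("functional_tags", None)
        return cls(
            germline_window=window,
            functional_tags=frozenset(tags) if tags is not None else FUNCTIONAL_TAGS,
            **d,
        )


def strand_bias_test(alt_fwd: int, alt_rev: int, ref_fwd: int, ref_rev: int) -> float:
    """Two-sided Fisher exact p-value for strand asymmetry.

    Tests the 2x2 family-count table [[alt_fwd, alt_rev], [ref_fwd,
    ref_rev]]: whether alternate support is distributed across strands
    differently from reference support.
    """
    counts = (alt_fwd, alt_rev, ref_fwd, ref_rev)
    if any(c < 0 for c in counts):
        raise ValueError("strand counts must be non-negative")
    if alt_fwd + alt_rev < 1:
        raise ValueError("strand-bias test requires at least one alternate family")
    _, p = scipy.stats.fisher_exact([[alt_fwd, alt_rev], [ref_fwd, ref_rev]])
    return float(p)


def _evaluate(call: VariantCall, config: FilterConfig,
              prevalence: float | None, cohort_mode: bool) -> FilterOutcome:
    if call.population_af is None or call.consequence_tag is None:
        return FilterOutcome(call=call, error="missing annotation (population_af/consequence_tag)")

    failed: list[str] = []
    p_strand: float | None = None

    if call.population_af >= config.population_af_max:
        failed.append("population_af")
    if call.vaf < config.vaf_floor:
        failed.append("vaf_floor")
    if call.uao >= 1:
        p_strand = strand_bias_test(call.alt_fwd, call.alt_rev, call.ref_fwd, call.ref_rev)
        if p_strand <= config.strand_bias_alpha:
            failed.append("strand_bias")
    lo, hi = config.germline_window
    if lo <= call.vaf <= hi or call.vaf >= config.germline_high:
        failed.append("germline_window")
    if call.consequence_tag not in config.functional_tags:
        failed.append("functional_relevance")
    if cohort_mode and prevalence is not None and prevalence > config.cohort_prevalence_max:
        failed.append("cohort_prevalence")
    if call.uao < config.uao_min:
        failed.append("uao_min")
    if call.vaf < config.llod_for(call.locus_id):
        failed.append("llod")

    return FilterOutcome(call=call, failed_rules=tuple(failed), strand_bias_p=p_strand)


def apply_filters(
    calls: Sequence[VariantCall],
    config: FilterConfig | None = None,
    cohort_prevalence: Mapping[str, float] | None = None,
) -> list[FilterOutcome]:
    """Evaluate every call against the full cascade.

    ``cohort_prevalence`` maps locus_id to the fraction of cohort samples
    carrying the call; when omitted, the cohort-prevalence rule is not in
    force (single-sample mode). Per-call evaluation problems yield an error
    outcome instead of raising.
    """
    config = config or FilterConfig()
    cohort_mode = cohort_prevalence is not None
    outcomes = []
    for call in calls:
        prev = cohort_prevalence.get(call.locus_id) if cohort_mode else None
        if prev is not None:
            call = call.annotated(cohort_prevalence=prev)
        outcomes.append(_evaluate(call, config, prev, cohort_mode))
    return outcomes


def cohort_prevalence_map(
    calls_by_subject: Mapping[str, Sequence[VariantCall]],
) -> dict[str, float]:
    """Fraction of subjects carrying each locus (presence, regardless of VAF)."""
    n = len(calls_by_subject)
    if n == 0:
        return {}
    counts: dict[str, int] = {}
    for subject_calls in calls_by_subject.values():
        for locus in {c.locus_id for c in subject_calls}:
            counts[locus] = counts.get(locus, 0) + 1
    return {locus: k / n for locus, k in counts.items()}


def prevalence_sweep(
    calls_by_subject: Mapping[str, Sequence[VariantCall]],
    cutoffs: Iterable[float],
) -> list[tuple[float, int]]:
    """Variants excluded by the cohort-prevalence rule alone, per cutoff.

    Counts distinct calls (subject, locus pairs) whose locus prevalence
    exceeds the cutoff; monotone non-increasing in the cutoff.
    """
    if not calls_by_subject:
        return []
    prevalence = cohort_prevalence_map(calls_by_subject)
    rows = []
    for cutoff in cutoffs:
        n_excluded = sum(
            1
            for subject_calls in calls_by_subject.values()
            for c in subject_calls
            if prevalence[c.locus_id] > cutoff
        )
        rows.append((float(cutoff), n_excluded))
    return rows
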