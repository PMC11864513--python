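"""Accreditation statistics: analytical range, precision, LLOD, trueness.

These are the quantities a clinical pathology laboratory reports when
validating a quantitative assay: linearity and fold bias of observed versus
expected VAF, coefficient-of-variation precision strata, the lower limit of
detection at a >= 95% replicate-detection criterion, confusion-matrix
trueness metrics against a >= 98% acceptance bar, and the presumed-negative
concordance accounting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .types import ConfusionCounts, VariantCall

TRUENESS_ACCEPTANCE = 98.0  # percent


@dataclass(frozen=True)
class AnalyticalRangeFit:
    """OLS fit of observed on expected VAF plus ratio-scale bias summary.

    ``fold_bias`` is the arithmetic mean of per-pair observed/expected
    ratios; ``limits`` are Bland-Altman style 95% limits,
    ``fold_bias +/- 1.96 * SD(ratios)``.
    """

    slope: float
    intercept: float
    r: float
    r2: float
    fold_bias: float
    limits: tuple[float, float]
    n: int
    excluded: tuple[str, ...] = ()


def analytical_range(
    pairs: Sequence[tuple[float, float]],
    exclusions: Iterable[str] = (),
    loci: Sequence[str] | None = None,
) -> AnalyticalRangeFit:
    """Linearity, correlation and fold bias of observed vs expected VAF.

    ``pairs`` are (expected, observed) VAFs; entries whose locus (parallel
    ``loci`` list) is in ``exclusions`` are dropped, as are non-detected
    observations recorded as None/NaN. Requires >= 3 surviving pairs.
    """
    exclusions = tuple(exclusions)
    kept = []
    for i, (exp, obs) in enumerate(pairs):
        if loci is not None and loci[i] in exclusions:
            continue
        if obs is None or (isinstance(obs, float) and math.isnan(obs)):
            continue  # ND entries are excluded, never imputed as 0
        kept.append((float(exp), float(obs)))
    if len(kept) < 3:
        raise ValueError(f"analytical range requires >= 3 detected pairs, got {len(kept)}")
    x = np.array([p[0] for p in kept])
    y = np.array([p[1] for p in kept])
    fit = scipy.stats.linregress(x, y)
    ratios = y / x
    bias = float(np.mean(ratios))
    sd = float(np.std(ratios, ddof=1)) if len(ratios) > 1 else 0.0
    return AnalyticalRangeFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r=float(fit.rvalue),
        r2=float(fit.rvalue**2),
        fold_bias=bias,
        limits=(bias - 1.96 * sd, bias + 1.96 * sd),
        n=len(kept),
        excluded=exclusions,
    )


def precision_cv(
    measurements: Mapping[str, Sequence[float]],
    stratum: str = "intra-run",
) -> pd.DataFrame:
    """Per-variant CV (sample SD / mean) of replicate VAF measurements.

    Rows with mean 0 get ``cv_undefined=True`` rather than a division
    error. Requires >= 2 measurements per variant.
    """
    rows = []
    for variant, values in measurements.items():
        values = np.asarray(list(values), dtype=float)
        if values.size < 2:
            raise ValueError(f"variant {variant!r} needs >= 2 replicate measurements")
        mean = float(values.mean())
        sd = float(values.std(ddof=1))
        undefined = mean == 0.0
        rows.append(
            {
                "variant": variant,
                "n": values.size,
                "vaf_mean": mean,
                "sd": sd,
                "cv": np.nan if undefined else sd / mean,
                "cv_undefined": undefined,
                "stratum": stratum,
            }
        )
    return pd.DataFrame(rows)


def binomial_cv(f: float, m: int) -> float:
    """CV of a VAF estimate under pure molecule-sampling noise: sqrt((1-f)/(f m))."""
    if not 0.0 < f <= 1.0 or m <= 0:
        raise ValueError("requires 0 < f <= 1 and m > 0")
    return math.sqrt((1.0 - f) / (f * m))


@dataclass(frozen=True)
class LlodResult:
    """Lower limit of detection at a replicate-detection criterion.

    ``llod_vaf`` is the smallest tested VAF such that every tested VAF at
    or above it meets the criterion (contiguity required); None when no
    VAF qualifies. ``overrides`` carries per-locus LLODs reported
    alongside the global value.
    """

    llod_vaf: float | None
    criterion: float
    rates: Mapping[float, float]
    overrides: Mapping[str, float] = field(default_factory=dict)
    diagnostic: str | None = None


def llod(
    detection_rates: Mapping[float, float],
    criterion: float = 0.95,
    overrides: Mapping[str, float] | None = None,
) -> LlodResult:
    """Determine the LLOD from per-VAF replicate detection rates.

    The clinical definition: the VAF at which >= ``criterion`` (default
    95%) of replicates detect the variant, holding contiguously for every
    tested VAF above it. E.g. rates {0.004: 1.00, 0.0031: 0.56} give an
    LLOD of 0.004.
    """
    if not detection_rates:
        raise ValueError("detection_rates must not be empty")
    vafs = sorted(detection_rates, reverse=True)  # high to low
    best: float | None = None
    for v in vafs:
        if detection_rates[v] >= criterion:
            best = v
        else:
            break  # contiguity broken
    if best is None:
        return LlodResult(
            llod_vaf=None,
            criterion=criterion,
            rates=dict(detection_rates),
            overrides=dict(overrides or {}),
            diagnostic="no tested VAF meets the detection criterion",
        )
    return LlodResult(
        llod_vaf=best,
        criterion=criterion,
        rates=dict(detection_rates),
        overrides=dict(overrides or {}),
    )


def trueness(counts: ConfusionCounts) -> pd.DataFrame:
    """The five confusion-matrix trueness metrics, as percentages.

    sensitivity = TP/(TP+FN); specificity = TN/(FP+TN); PPV = TP/(TP+FP);
    NPV = TN/(TN+FN); accuracy = (TP+TN)/(TP+FN+TN+FP). Each is flagged
    pass/fail against the >= 98% acceptance criterion; metrics with a zero
    denominator are undefined and carry no flag.
    """
    c = counts
    defs = {
        "sensitivity": (c.tp, c.tp + c.fn),
        "specificity": (c.tn, c.fp + c.tn),
        "ppv": (c.tp, c.tp + c.fp),
        "npv": (c.tn, c.tn + c.fn),
        "accuracy": (c.tp + c.tn, c.tp + c.fn + c.tn + c.fp),
    }
    rows = []
    for name, (num, den) in defs.items():
        if den == 0:
            rows.append({"metric": name, "percent": np.nan, "passed": None})
        else:
            pct = 100.0 * num / den
            rows.append({"metric": name, "percent": pct, "passed": pct >= TRUENESS_ACCEPTANCE})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class NegativeAccounting:
    """Partition of calls detected in presumed-negative samples."""

    total: int
    off_panel: int
    below_reference_llod: int
    remaining: int
    unclassifiable: int
    concordance_pct: float | None  # None when unclassifiable calls exist

    def as_dict(self) -> dict:
        return {
            "total": self.total,
            "off_panel": self.off_panel,
            "below_reference_llod": self.below_reference_llod,
            "remaining": self.remaining,
            "unclassifiable": self.unclassifiable,
            "concordance_pct": self.concordance_pct,
        }


def presumed_negative_concordance(
    detected: Sequence[VariantCall],
    reference_panel_loci: Iterable[str],
    reference_llod_map: Mapping[str, float],
) -> NegativeAccounting:
    """Reconcile calls in presumed-negative samples with a reference panel.

    Each detected call is placed in one bucket: off-panel (locus not
    covered by the reference laboratory panel), on-panel but below the
    reference laboratory's per-locus LLOD, remaining (a genuine
    discordance), or unclassifiable (on-panel with no known reference
    LLOD). Concordance is 100% iff remaining == 0; it is not computable
    while unclassifiable calls exist.
    """
    panel = set(reference_panel_loci)
    off_panel = below = remaining = unclassifiable = 0
    for call in detected:
        if call.locus_id not in panel:
            off_panel += 1
        elif call.locus_id not in reference_llod_map:
            unclassifiable += 1
        elif call.vaf < reference_llod_map[call.locus_id]:
            below += 1
        else:
            remaining += 1
    concordance = None
    if unclassifiable == 0:
        concordance = 100.0 if remaining == 0 else 100.0 * (len(detected) - remaining) / max(len(detected), 1)
    return NegativeAccounting(
        total=len(detected),
        off_panel=off_panel,
        below_reference_llod=below,
        remaining=remaining,
        unclassifiable=unclassifiable,
        concordance_pct=concordance,
    )


#: assay-utility recommendations per target VAF band: read depth, relative
#: cost/time, input DNA, and minimum UAO threshold
RECOMMENDATIONS: dict[str, dict[str, object]] = {
    ">=0.02": {
        "depth": "1,000-2,000x",
        "relative_cost": 0.8,
        "relative_time": 0.8,
        "input_ng": ">=50",
        "uao_min": 1,
    },
    "0.01-0.02": {
        "depth": "2,000-3,000x",
        "relative_cost": 1.0,
        "relative_time": 1.0,
        "input_ng": "200-400",
        "uao_min": 3,
    },
    "0.004-0.01": {
        "depth": "3,000-4,000x",
        "relative_cost": 1.1,
        "relative_time": 1.1,
        "input_ng": "400",
        "uao_min": 3,
    },
}


def recommend(target_vaf_band: str) -> dict[str, object]:
    """Depth/input/UAO recommendation for a target VAF band.

    Bands: ``>=0.02`` (CHIP), ``0.01-0.02`` (sub-CHIP), ``0.004-0.01``
    (MRD). Bands below the validated LLOD of 0.004 are an error.
    """
    key = target_vaf_band.replace("≥", ">=").replace(" ", "").replace("–", "-")
    if key in RECOMMENDATIONS:
        return dict(RECOMMENDATIONS[key])
    raise ValueError(
        f"no recommendation for VAF band {target_vaf_band!r}: "
        "bands below the validated LLOD of 0.004 are unsupported"
    )
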