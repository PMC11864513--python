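"""Pipeline driver: simulate -> call -> filter -> depth-curve -> validate.

Runs the stages on the packaged reference-standard dilution grid (or a
user-supplied truth table), writing TSV outputs, a machine-readable summary
and a manifest whose digests make every run reproducible from (config,
seed) alone.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .consensus import call_variants
from .depth import depth_detection_curve, DEFAULT_DEPTH_GRID
from .filters import FilterConfig, apply_filters
from .io import RunManifest, save_config, write_calls, write_outcomes
from .metrics import analytical_range, recommend, RECOMMENDATIONS
from .reference import LOCUS_LLOD_OVERRIDES, dilution_series, stock_depths
from .simulate import SimConfig, expected_vaf, simulate_reference_panel
from .studies import llod_study, run_trueness_study
from .types import pass_set

STAGES = ("simulate", "call", "filter", "depth-curve", "validate", "recommend", "all")


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def default_config(seed: int = 1234) -> dict:
    """Full run configuration with every default materialized."""
    sim = SimConfig(seed=seed)
    return {
        "sim": dataclasses.asdict(sim),
        "filter": FilterConfig(locus_llod_overrides=dict(LOCUS_LLOD_OVERRIDES)).as_dict(),
        "pipeline": {
            "n_replicates": 3,
            "depth_grid": list(DEFAULT_DEPTH_GRID),
            "analytical_exclusions": ["ASXL1:c.1934dup", "FLT3:c.2503G>T"],
            "analytical_vaf_min": 0.004,
        },
    }


def _configs(cfg: dict) -> tuple[SimConfig, FilterConfig, dict]:
    merged = default_config()
    for key in ("sim", "filter", "pipeline"):
        merged[key].update(cfg.get(key, {}))
    sim = SimConfig(**merged["sim"])
    filt = FilterConfig.from_dict(merged["filter"])
    return sim, filt, merged


def run_pipeline(
    config: dict | None = None,
    subcommand: str = "all",
    out_dir: str | Path = "chipvalid_run",
    seed: int | None = None,
) -> RunManifest:
    """Run one or all pipeline stages; returns the manifest.

    Deterministic given (config, seed): rerunning writes byte-identical
    outputs. Any stage failure raises :class:`StageError` naming the stage
    and nothing further is written.
    """
    if subcommand not in STAGES:
        raise ValueError(f"unknown subcommand {subcommand!r}; choose from {STAGES}")
    cfg = dict(config or {})
    if seed is not None:
        cfg.setdefault("sim", {})["seed"] = seed
    sim, filt, merged = _configs(cfg)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(seed=sim.seed, config=merged, version=__version__)
    stages = (
        ["simulate", "call", "filter", "depth-curve", "validate", "recommend"]
        if subcommand == "all"
        else [subcommand]
    )

    series = dilution_series()
    depths = stock_depths()
    panel = None
    call_rows = None

    def _need_calls():
        nonlocal panel, call_rows
        if call_rows is not None:
            return
        panel = simulate_reference_panel(
            series, sim, n_replicates=merged["pipeline"]["n_replicates"], depths=depths
        )
        rows = []
        for rep in panel:
            for conc, pileups in rep.panels.items():
                for pile in pileups:
                    for call in call_variants(pile):
                        rows.append((rep.replicate_id, conc, call))
        call_rows = rows

    for stage in stages:
        try:
            if stage == "simulate":
                _need_calls()
                n_pileups = sum(len(p) for rep in panel for p in rep.panels.values())
                manifest.stage_counts["simulate"] = {
                    "replicates": len(panel),
                    "concentrations": len(series.concentrations),
                    "pileups": n_pileups,
                }
            elif stage == "call":
                _need_calls()
                calls = [c for _, _, c in call_rows]
                path = write_calls(calls, out / "calls.tsv")
                df = pd.read_csv(path, sep="\t")
                df.insert(0, "replicate", [r for r, _, _ in call_rows])
                df.insert(1, "concentration", [c for _, c, _ in call_rows])
                df.to_csv(path, sep="\t", index=False)
                manifest.record("call", path)
                manifest.stage_counts["call"] = {"calls": len(calls)}
            elif stage == "filter":
                _need_calls()
                outcomes = apply_filters([c for _, _, c in call_rows], filt)
                path = write_outcomes(outcomes, out / "filter_outcomes.tsv")
                manifest.record("filter", path)
                per_rule: dict[str, int] = {}
                for o in outcomes:
                    for r in o.failed_rules:
                        per_rule[r] = per_rule.get(r, 0) + 1
                manifest.stage_counts["filter"] = {
                    "evaluated": len(outcomes),
                    "passed": sum(o.passed for o in outcomes),
                    "failed_per_rule": per_rule,
                }
            elif stage == "depth-curve":
                table = depth_detection_curve(
                    series.stock,
                    sim,
                    depths=merged["pipeline"]["depth_grid"],
                    n_replicates=merged["pipeline"]["n_replicates"],
                    filter_config=filt,
                )
                path = out / "depth_curve.tsv"
                table.to_csv(path, sep="\t", index=False)
                manifest.record("depth-curve", path)
                manifest.stage_counts["depth-curve"] = {"rows": len(table)}
            elif stage == "validate":
                manifest.stage_counts["validate"] = _validate_stage(
                    out, manifest, sim, filt, merged
                )
            elif stage == "recommend":
                df = pd.DataFrame(
                    [{"vaf_band": band, **rec} for band, rec in RECOMMENDATIONS.items()]
                )
                path = out / "recommendations.tsv"
                df.to_csv(path, sep="\t", index=False)
                manifest.record("recommend", path)
        except Exception as exc:
            raise StageError(f"stage {stage!r} failed: {exc}") from exc

    save_config(merged, out / "config.yaml")
    manifest.record("config", out / "config.yaml")
    manifest.save(out / "manifest.json")
    return manifest


def _validate_stage(out, manifest, sim, filt, merged) -> dict:
    import json

    # trueness on reference material
    study = run_trueness_study(seed=sim.seed, config=sim, filter_config=filt)
    # analytical range: replicate-mean observed VAF vs expected, on a fresh panel
    panel = simulate_reference_panel(
        dilution_series(), sim, n_replicates=merged["pipeline"]["n_replicates"],
        depths=stock_depths(),
    )
    obs: dict[tuple[str, float], list[float]] = {}
    for rep in panel:
        for conc, pileups in rep.panels.items():
            for pile in pileups:
                passing = pass_set(apply_filters(call_variants(pile), filt))
                spec = pile.truth[0]
                hit = next(
                    (c.vaf for c in passing if c.allele == spec.allele), None
                )
                if hit is not None:
                    obs.setdefault((spec.locus_id, conc), []).append(hit)
    pairs, loci = [], []
    for (locus, conc), values in sorted(obs.items()):
        stock_vaf = next(
            v.true_vaf for v in dilution_series().stock if v.locus_id == locus
        )
        exp = expected_vaf(stock_vaf, conc)
        if exp < merged["pipeline"]["analytical_vaf_min"]:
            continue
        pairs.append((exp, float(np.mean(values))))
        loci.append(locus)
    fit = analytical_range(
        pairs, exclusions=merged["pipeline"]["analytical_exclusions"], loci=loci
    )
    llod_res = llod_study(seed=sim.seed)

    report = {
        "trueness": {
            row["metric"]: row["percent"] for _, row in study.metrics.iterrows()
        },
        "confusion": dataclasses.asdict(study.counts),
        "analytical_range": {
            "slope": fit.slope,
            "intercept": fit.intercept,
            "r": fit.r,
            "r2": fit.r2,
            "fold_bias": fit.fold_bias,
            "limits": list(fit.limits),
            "n_pairs": fit.n,
        },
        "llod": {
            "llod_vaf": llod_res.llod_vaf,
            "criterion": llod_res.criterion,
            "rates": {str(k): v for k, v in llod_res.rates.items()},
            "overrides": dict(LOCUS_LLOD_OVERRIDES),
        },
    }
    path = out / "validation_summary.json"
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    manifest.record("validate", path)
    tsv = out / "validation_trueness.tsv"
    study.metrics.to_csv(tsv, sep="\t", index=False)
    manifest.record("validate", tsv)
    return {
        "tp": study.counts.tp,
        "tn": study.counts.tn,
        "fp": study.counts.fp,
        "fn": study.counts.fn,
        "llod": llod_res.llod_vaf,
    }
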