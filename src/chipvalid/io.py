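"""Call-table serialisation (TSV and minimal VCF), configs and manifests.

The TSV dialect is the package's canonical interchange format::

    locus_id  allele  variant_class  vaf  depth  uao
    alt_fwd  alt_rev  ref_fwd  ref_rev  consequence_tag  population_af
    cohort_prevalence  true_vaf

All fields of a call round-trip losslessly; readers validate the UAO/depth
invariants and report the offending column and line. The VCF export is a
minimal VCF 4.2 with opaque 1-based placeholder positions (loci are keys,
not genomic coordinates) and the call metrics in INFO.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .types import VariantCall

TSV_COLUMNS = (
    "locus_id",
    "allele",
    "variant_class",
    "vaf",
    "depth",
    "uao",
    "alt_fwd",
    "alt_rev",
    "ref_fwd",
    "ref_rev",
    "consequence_tag",
    "population_af",
    "cohort_prevalence",
    "true_vaf",
)

_MANDATORY = TSV_COLUMNS[:10]
_INT_FIELDS = ("depth", "uao", "alt_fwd", "alt_rev", "ref_fwd", "ref_rev")


class CallTableError(ValueError):
    """Raised for malformed or invariant-violating call tables."""


def write_calls(calls: Sequence[VariantCall], path: str | Path, dialect: str = "tsv") -> Path:
    """Serialise calls to TSV (default) or minimal VCF."""
    path = Path(path)
    if dialect == "tsv":
        rows = [{c: getattr(call, c) for c in TSV_COLUMNS} for call in calls]
        pd.DataFrame(rows, columns=list(TSV_COLUMNS)).to_csv(
            path, sep="\t", index=False
        )
    elif dialect == "vcf":
        _write_vcf(calls, path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return path


def read_calls(path: str | Path, dialect: str = "tsv") -> list[VariantCall]:
    """Read a call table, validating invariants (uao = alt_fwd + alt_rev <= depth)."""
    path = Path(path)
    if dialect == "vcf":
        return _read_vcf(path)
    if dialect != "tsv":
        raise ValueError(f"unknown dialect {dialect!r}")
    try:
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise CallTableError(f"{path}: cannot parse call table: {exc}") from exc
    missing = [c for c in _MANDATORY if c not in df.columns]
    if missing:
        raise CallTableError(f"{path}: missing mandatory column(s) {', '.join(missing)}")
    calls = []
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        kwargs = {}
        for col in TSV_COLUMNS:
            if col not in df.columns:
                kwargs[col] = None
                continue
            value = row[col]
            if pd.isna(value):
                kwargs[col] = None
            elif col in _INT_FIELDS:
                kwargs[col] = int(value)
            elif col in ("vaf", "population_af", "cohort_prevalence", "true_vaf"):
                kwargs[col] = float(value)
            else:
                kwargs[col] = str(value)
        try:
            calls.append(VariantCall(**kwargs))
        except (TypeError, ValueError) as exc:
            raise CallTableError(f"{path}, line {line}: {exc}") from exc
    return calls


_VCF_HEADER = """\
##fileformat=VCFv4.2
##contig=<ID=chr1>
##INFO=<ID=VAF,Number=1,Type=Float,Description="Read-level variant allele fraction">
##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##INFO=<ID=UAO,Number=1,Type=Integer,Description="Unique alternate observations (consensus families)">
##INFO=<ID=ALTF,Number=1,Type=Integer,Description="Alternate families, forward strand">
##INFO=<ID=ALTR,Number=1,Type=Integer,Description="Alternate families, reverse strand">
##INFO=<ID=REFF,Number=1,Type=Integer,Description="Reference families, forward strand">
##INFO=<ID=REFR,Number=1,Type=Integer,Description="Reference families, reverse strand">
##INFO=<ID=VC,Number=1,Type=String,Description="Variant class">
##INFO=<ID=CSQ,Number=1,Type=String,Description="Consequence tag">
##INFO=<ID=PAF,Number=1,Type=Float,Description="Population allele frequency">
##INFO=<ID=PREV,Number=1,Type=Float,Description="Cohort prevalence">
##INFO=<ID=TVAF,Number=1,Type=Float,Description="True (simulated) VAF">
##INFO=<ID=AL,Number=1,Type=String,Description="Allele label">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def _fmt(x: float | None) -> str:
    return "%.17g" % x


def _write_vcf(calls: Sequence[VariantCall], path: Path) -> None:
    # positions are 1-based placeholders; loci are opaque keys, not coordinates
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for pos, call in enumerate(calls, start=1):
            info = [
                f"VAF={_fmt(call.vaf)}",
                f"DP={call.depth}",
                f"UAO={call.uao}",
                f"ALTF={call.alt_fwd}",
                f"ALTR={call.alt_rev}",
                f"REFF={call.ref_fwd}",
                f"REFR={call.ref_rev}",
                f"VC={call.variant_class.replace('/', '_')}",
                f"AL={call.allele}",
            ]
            if call.consequence_tag is not None:
                info.append(f"CSQ={call.consequence_tag}")
            if call.population_af is not None:
                info.append(f"PAF={_fmt(call.population_af)}")
            if call.cohort_prevalence is not None:
                info.append(f"PREV={_fmt(call.cohort_prevalence)}")
            if call.true_vaf is not None:
                info.append(f"TVAF={_fmt(call.true_vaf)}")
            fh.write(
                f"chr1\t{pos}\t{call.locus_id}\tN\tA\t.\tPASS\t{';'.join(info)}\n"
            )


def _read_vcf(path: Path) -> list[VariantCall]:
    from cyvcf2 import VCF

    calls = []
    for rec in VCF(str(path)):
        info = dict(rec.INFO)
        try:
            calls.append(
                VariantCall(
                    locus_id=rec.ID,
                    allele=str(info.get("AL", "alt")),
                    variant_class=str(info["VC"]).replace("_", "/"),
                    vaf=float(info["VAF"]),
                    depth=int(info["DP"]),
                    uao=int(info["UAO"]),
                    alt_fwd=int(info["ALTF"]),
                    alt_rev=int(info["ALTR"]),
                    ref_fwd=int(info["REFF"]),
                    ref_rev=int(info["REFR"]),
                    consequence_tag=(str(info["CSQ"]) if "CSQ" in info else None),
                    population_af=(float(info["PAF"]) if "PAF" in info else None),
                    cohort_prevalence=(float(info["PREV"]) if "PREV" in info else None),
                    true_vaf=(float(info["TVAF"]) if "TVAF" in info else None),
                )
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise CallTableError(f"{path}: malformed VCF record {rec.ID}: {exc}") from exc
    return calls


def write_outcomes(outcomes, path: str | Path) -> Path:
    """Filter outcomes as TSV: the call columns plus semicolon-joined failed_rules."""
    path = Path(path)
    rows = []
    for o in outcomes:
        row = {c: getattr(o.call, c) for c in TSV_COLUMNS}
        row["failed_rules"] = ";".join(o.failed_rules)
        row["strand_bias_p"] = o.strand_bias_p
        row["error"] = o.error or ""
        rows.append(row)
    pd.DataFrame(rows, columns=list(TSV_COLUMNS) + ["failed_rules", "strand_bias_p", "error"]).to_csv(
        path, sep="\t", index=False
    )
    return path


def load_config(path: str | Path) -> dict:
    """Load a YAML run configuration."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def save_config(cfg: Mapping, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(dict(cfg), fh, sort_keys=True)
    return path


def file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record: config snapshot, seed, and output digests."""

    seed: int
    config: dict
    version: str = "0.1.0"
    outputs: dict[str, str] = field(default_factory=dict)
    stage_counts: dict[str, dict] = field(default_factory=dict)

    def record(self, stage: str, path: str | Path) -> None:
        self.outputs[f"{stage}:{Path(path).name}"] = file_digest(path)

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
        return path

    @classmethod
    def load(cls, path: str | Path) -> "RunManifest":
        with open(path) as fh:
            return cls(**json.load(fh))
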