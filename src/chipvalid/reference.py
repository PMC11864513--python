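"""Packaged reference-standard material: the dilution validation grid.

The packaged TSV reproduces a 15-variant x 5-concentration dilution grid of
a multi-cell-line myeloid reference standard (HD829-style) serially diluted
into wild-type leukocyte DNA: expected VAF (ddPCR-verified stock x panel
concentration), the observed VAF, read depth and UAO actually measured at
each concentration (ND cells empty). Two loci carry documented
quantitation quirks: ASXL1:c.1934dup sits in a guanine homopolymer and is
over-called at low VAF (it gets a dedicated LLOD of 0.031), and
FLT3:c.2503G>T shows a consistent 0.3-fold negative recovery bias.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .simulate import DilutionSeries
from .types import VariantSpec

#: locus-specific multiplicative recovery biases observed on the panel
LOCUS_BIASES = {"FLT3:c.2503G>T": 0.3}

#: dedicated lower limits of detection (homopolymer-context loci)
LOCUS_LLOD_OVERRIDES = {"ASXL1:c.1934dup": 0.031}

_CONSEQUENCES = {
    "INS": "frameshift",
    "DEL": "frameshift",
    "DUP/ITD": "inframe_insertion",
    "SNP": "missense",
}
_CONSEQUENCE_OVERRIDES = {"JAK2:F537-K539>L": "inframe_deletion"}


def reference_grid() -> pd.DataFrame:
    """The packaged dilution grid as a long-format DataFrame.

    Columns: gene, variant, variant_class, concentration, expected_vaf,
    observed_vaf, depth, uao; a ``locus_id`` column (``gene:variant``) is
    added. Non-detected cells have NaN observed_vaf/depth/uao.
    """
    with resources.files("chipvalid.data").joinpath("reference_grid.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    df["locus_id"] = df["gene"] + ":" + df["variant"]
    return df


def stock_variants() -> list[VariantSpec]:
    """The 15 accessible stock variants of the dilution grid (100% rows)."""
    grid = reference_grid()
    stock = grid[grid["concentration"] == 1.0]
    specs = []
    for _, row in stock.iterrows():
        locus = row["locus_id"]
        specs.append(
            VariantSpec(
                locus_id=locus,
                variant_class=row["variant_class"],
                true_vaf=float(row["expected_vaf"]),
                consequence_tag=_CONSEQUENCE_OVERRIDES.get(
                    locus, _CONSEQUENCES[row["variant_class"]]
                ),
                population_af=0.0,
                locus_bias=LOCUS_BIASES.get(locus, 1.0),
            )
        )
    return specs


def dilution_series() -> DilutionSeries:
    """The packaged stock as a five-step serial dilution series."""
    return DilutionSeries(stock=tuple(stock_variants()))


def stock_depths() -> dict[str, float]:
    """Per-variant read depths measured on the undiluted (100%) panel."""
    grid = reference_grid()
    stock = grid[grid["concentration"] == 1.0]
    return {r["locus_id"]: float(r["depth"]) for _, r in stock.iterrows()}


#: Synthetic stand-ins for the reference-standard variants assessed for
#: trueness beyond the 15 printed accessible ones (the commercial standards
#: carry more variants than the dilution grid prints, 23 assessed in total,
#: including FLT3-ITD). VAFs are manufacturer-plausible stock values >= 0.05.
SYNTHETIC_EXTRA_STANDARDS: tuple[VariantSpec, ...] = (
    VariantSpec("FLT3:ITD", "DUP/ITD", 0.05, "inframe_insertion"),
    VariantSpec("DNMT3A:R882C", "SNP", 0.05, "missense"),
    VariantSpec("TET2:Q916*", "SNP", 0.05, "nonsense"),
    VariantSpec("EZH2:Y646F", "SNP", 0.10, "missense"),
    VariantSpec("SRSF2:P95H", "SNP", 0.05, "missense"),
    VariantSpec("U2AF1:S34F", "SNP", 0.05, "missense"),
    VariantSpec("CSF3R:T618I", "SNP", 0.10, "missense"),
    VariantSpec("SETBP1:D868N", "SNP", 0.05, "missense"),
)


def trueness_standard_variants() -> list[VariantSpec]:
    """The 23 reference-standard variants assessed for trueness.

    The 15 printed stock variants plus the 8 synthetic extra standards.
    """
    return stock_variants() + list(SYNTHETIC_EXTRA_STANDARDS)


_CLINICAL_GENES = (
    "DNMT3A", "TET2", "ASXL1", "JAK2", "SF3B1", "SRSF2", "TP53", "RUNX1",
    "NRAS", "KRAS", "IDH1", "IDH2", "CBL", "EZH2", "U2AF1", "ZRSR2",
    "STAG2", "BCOR",
)


def clinical_reference_variants(n: int = 36) -> list[VariantSpec]:
    """Synthetic stand-ins for clinical reference-laboratory variants.

    ``n`` variants (default 36) at VAFs spaced evenly over [0.05, 0.40] —
    all above any reference-laboratory LLOD and below the germline window —
    across recurrent myeloid genes.
    """
    specs = []
    for i in range(n):
        vaf = 0.05 + (0.40 - 0.05) * i / max(n - 1, 1)
        gene = _CLINICAL_GENES[i % len(_CLINICAL_GENES)]
        specs.append(
            VariantSpec(
                locus_id=f"{gene}:clin{i:02d}",
                variant_class="SNP",
                true_vaf=round(vaf, 4),
                consequence_tag="missense",
            )
        )
    return specs


def wildtype_loci(n: int = 29) -> list[str]:
    """Locus keys of the wild-type (true VAF 0) reference sequences."""
    return [f"WT{i:02d}:{_CLINICAL_GENES[i % len(_CLINICAL_GENES)]}" for i in range(n)]
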