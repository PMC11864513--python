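"""Core domain containers shared across the simulation and analysis modules.

The unit of sequencing evidence is the UMI *family*: all reads derived from a
single input DNA molecule, grouped by their molecular barcode. A family is
stored compactly as its molecule allele plus the number of reads that were
flipped to a single alternative allele by residual (post-consensus) error;
this is lossless for consensus calling, read-level VAF and read subsampling
because at most one flip target exists per family in this model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

REF = "ref"

#: consequence categories accepted by the functional-relevance filter
#: (5' UTR / coding-sequence variants and their downstream effects)
FUNCTIONAL_TAGS = frozenset(
    {
        "5_prime_utr",
        "coding_sequence",
        "feature_elongation",
        "feature_truncation",
        "frameshift",
        "inframe_deletion",
        "inframe_insertion",
        "missense",
        "nonsense",
        "protein_altering",
        "start_lost",
        "stop_lost",
        "transcript_ablation",
        "transcript_amplification",
        "splice_acceptor",
        "splice_donor",
        "splice_region",
    }
)

VARIANT_CLASSES = ("SNP", "INS", "DEL", "DUP/ITD")


@dataclass(frozen=True, slots=True)
class VariantSpec:
    """Ground-truth variant used by the simulator and as truth for validation.

    Parameters
    ----------
    locus_id
        Opaque locus key, conventionally ``GENE:hgvs-like-label``; unique
        within a truth set.
    variant_class
        One of ``SNP``, ``INS``, ``DEL``, ``DUP/ITD``. Duplications /
        internal tandem duplications are modelled as insertion alleles.
    true_vaf
        True variant allele fraction in ``[0, 1]``.
    consequence_tag
        Functional-consequence category (see :data:`FUNCTIONAL_TAGS`).
    population_af
        Population allele frequency annotation (gnomAD-style prevalence).
    locus_bias
        Multiplicative recovery factor applied to ``true_vaf`` during
        simulation; e.g. 0.3 emulates the consistent 0.3-fold negative
        bias observed for FLT3 c.2503G>T.
    allele
        Allele label carried by families supporting this variant.
    """

    locus_id: str
    variant_class: str = "SNP"
    true_vaf: float = 0.0
    consequence_tag: str = "missense"
    population_af: float = 0.0
    locus_bias: float = 1.0
    allele: str = "alt"

    def __post_init__(self) -> None:
        if not 0.0 <= self.true_vaf <= 1.0:
            raise ValueError(f"true_vaf must be in [0, 1], got {self.true_vaf}")
        if self.locus_bias <= 0:
            raise ValueError(f"locus_bias must be > 0, got {self.locus_bias}")
        if self.variant_class not in VARIANT_CLASSES:
            raise ValueError(f"unknown variant_class {self.variant_class!r}")
        if not 0.0 <= self.population_af <= 1.0:
            raise ValueError("population_af must be in [0, 1]")
        if self.allele == REF:
            raise ValueError("variant allele label may not be 'ref'")


@dataclass(frozen=True, slots=True)
class Family:
    """One UMI family: the reads derived from a single input molecule.

    ``read_count - flipped`` reads carry :attr:`allele`; ``flipped`` reads
    carry :attr:`flip_allele` (residual error after molecular barcoding).
    """

    family_id: int
    allele: str
    strand: str  # '+' or '-'
    read_count: int
    flipped: int = 0
    flip_allele: str | None = None

    def __post_init__(self) -> None:
        if self.read_count < 1:
            raise ValueError("family must contain at least one read")
        if not 0 <= self.flipped <= self.read_count:
            raise ValueError("flipped reads must be within read_count")
        if self.flipped and self.flip_allele is None:
            raise ValueError("flip_allele required when flipped > 0")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def read_alleles(self) -> dict[str, int]:
        """Read-level allele counts within this family."""
        counts = {self.allele: self.read_count - self.flipped}
        if self.flipped:
            counts[self.flip_allele] = counts.get(self.flip_allele, 0) + self.flipped
        return {a: n for a, n in counts.items() if n > 0}


@dataclass(frozen=True)
class Pileup:
    """Per-locus simulated sequencing observations with truth retained."""

    locus_id: str
    families: tuple[Family, ...]
    truth: tuple[VariantSpec, ...] = ()

    def __post_init__(self) -> None:
        ids = [f.family_id for f in self.families]
        if len(ids) != len(set(ids)):
            raise ValueError("family_ids must be unique within a pileup")

    @property
    def depth(self) -> int:
        """Total read depth (sum of family read counts)."""
        return sum(f.read_count for f in self.families)

    def read_allele_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for fam in self.families:
            for allele, n in fam.read_alleles().items():
                counts[allele] = counts.get(allele, 0) + n
        return counts


@dataclass(frozen=True, slots=True)
class VariantCall:
    """A called variant with the reported assay metrics.

    VAF is a read-level fraction, depth a read count, and UAO (unique
    alternate observations) the number of consensus families supporting the
    alternate allele; strand counts are family-level.
    """

    locus_id: str
    allele: str
    variant_class: str
    vaf: float
    depth: int
    uao: int
    alt_fwd: int
    alt_rev: int
    ref_fwd: int
    ref_rev: int
    consequence_tag: str | None = None
    population_af: float | None = None
    cohort_prevalence: float | None = None
    true_vaf: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.vaf <= 1.0:
            raise ValueError(f"vaf must be in [0, 1], got {self.vaf}")
        if self.uao != self.alt_fwd + self.alt_rev:
            raise ValueError("uao must equal alt_fwd + alt_rev")
        if self.uao > self.depth:
            raise ValueError("uao cannot exceed read depth")

    def annotated(self, **kwargs) -> "VariantCall":
        return replace(self, **kwargs)


@dataclass(frozen=True, slots=True)
class FilterOutcome:
    """A call plus the ordered list of filter rules it failed.

    An empty :attr:`failed_rules` means the call passed the whole cascade.
    ``error`` records a per-call evaluation problem (e.g. a missing
    annotation) instead of raising.
    """

    call: VariantCall
    failed_rules: tuple[str, ...] = ()
    strand_bias_p: float | None = None
    error: str | None = None

    @property
    def passed(self) -> bool:
        return not self.failed_rules and self.error is None


@dataclass(frozen=True, slots=True)
class ConfusionCounts:
    """TP/FP/FN/TN accounting for trueness metrics."""

    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp,
            self.fp + other.fp,
            self.fn + other.fn,
            self.tn + other.tn,
        )


def pass_set(outcomes: Iterable[FilterOutcome]) -> list[VariantCall]:
    """Calls surviving the full filter cascade."""
    return [o.call for o in outcomes if o.passed]
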