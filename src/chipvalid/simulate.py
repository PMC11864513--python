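"""Molecule-limited UMI sequencing simulator.

Emulates the data-generating process of an anchored multiplex PCR,
molecular-barcoded targeted sequencing assay at the level that matters for
validation statistics: a limited number of input DNA molecules per locus,
each yielding one strand-labelled UMI family of one or more reads, with a
small pre-consensus artifact rate (a wild-type molecule giving rise to a
false alternate family) and a residual post-consensus per-read error.

Sequence content, alignment and primer behaviour are deliberately not
modelled; ground truth is carried alongside every pileup.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .types import REF, Family, Pileup, VariantSpec

#: haploid genome equivalents per nanogram of human DNA (3.3 pg / haploid
#: genome); 100 ng of input DNA therefore carries ~30,300 haploid copies, i.e.
#: ~15 diploid cells for an allele at 0.001 VAF.
HAPLOID_COPIES_PER_NG = 303

#: allele label used for simulated artifact (false alternate) families
ARTIFACT_ALLELE = "err"

DEFAULT_SEED = 1234


@dataclass(frozen=True, slots=True)
class SimConfig:
    """Assay-level simulation parameters.

    Parameters
    ----------
    input_ng
        Nanograms of input DNA per library.
    conversion_efficiency
        Fraction of input haploid genome copies recovered as sequenced UMI
        families. Library conversion is the single calibration knob of the
        simulator: it reconciles the naive binomial molecule model with
        realistic detection at VAF <= 0.001.
    target_read_depth
        Mean read depth aimed for per locus; together with
        ``reads_per_family_mean`` it implies a family budget.
    reads_per_family_mean
        Mean reads per UMI family (>= 1); reads per family are drawn as
        ``1 + Poisson(mean - 1)``.
    pre_consensus_error
        Probability a wild-type molecule yields a false alternate family
        (survives consensus; this is the error-corrected residual artifact
        rate, order 1e-4).
    post_consensus_error
        Residual per-read error after consensus grouping; flips individual
        reads and is corrected by majority vote in families of size >= 2.
    strand_artifact_rate
        Probability that the artifact process at a locus is single-stranded
        (all artifact families share one strand), as deamination/PCR errors
        tend to be.
    seed
        Master seed for reproducibility.
    """

    input_ng: float = 400.0
    conversion_efficiency: float = 0.25
    target_read_depth: float = 3400.0
    reads_per_family_mean: float = 1.7
    pre_consensus_error: float = 1e-4
    post_consensus_error: float = 1e-4
    strand_artifact_rate: float = 0.5
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        for name in (
            "conversion_efficiency",
            "pre_consensus_error",
            "post_consensus_error",
            "strand_artifact_rate",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.input_ng < 0:
            raise ValueError("input_ng must be >= 0")
        if self.target_read_depth < 0:
            raise ValueError("target_read_depth must be >= 0")
        if self.reads_per_family_mean < 1.0:
            raise ValueError("reads_per_family_mean must be >= 1")

    def n_families(self) -> int:
        """Family budget: molecule-limited or depth-limited, whichever binds."""
        by_molecules = molecules_from_input(self.input_ng, self.conversion_efficiency)
        by_depth = int(round(self.target_read_depth / self.reads_per_family_mean))
        return min(by_molecules, by_depth)


@dataclass(frozen=True)
class DilutionSeries:
    """A reference-standard stock serially diluted into wild-type DNA."""

    stock: tuple[VariantSpec, ...]
    concentrations: tuple[float, ...] = (1.0, 0.25, 0.0625, 0.03125, 0.015625)
    rounding: int = 4

    def __post_init__(self) -> None:
        for c in self.concentrations:
            if not 0.0 < c <= 1.0:
                raise ValueError(f"concentrations must be in (0, 1], got {c}")
        if list(self.concentrations) != sorted(self.concentrations, reverse=True) or len(
            set(self.concentrations)
        ) != len(self.concentrations):
            raise ValueError("concentrations must be strictly decreasing")

    def expected_grid(self) -> dict[str, dict[float, float]]:
        """Expected VAF per variant per concentration (rounded for reporting)."""
        return {
            v.locus_id: {
                c: expected_vaf(v.true_vaf, c, self.rounding) for c in self.concentrations
            }
            for v in self.stock
        }


@dataclass(frozen=True, slots=True)
class ArtifactSpec:
    """A recurrent artifact locus injected across cohort subjects."""

    locus_id: str
    prevalence: float
    vaf: float = 0.005
    single_stranded: bool = True
    consequence_tag: str = "missense"


@dataclass(frozen=True)
class CohortSpec:
    """An age-structured community cohort with age-increasing clone counts.

    The expected number of clones at VAF >= 0.02 per subject is linear in
    age, ``intercept + slope * age`` (clipped at zero); subjects also carry
    a Poisson number of subclonal (< 0.02 VAF) variants with log-uniform
    VAFs. Defaults calibrate the cohort mean clone count to ~1.4 at the
    mid-cohort age of ~57.5 years.
    """

    n_subjects: int = 383
    age_range: tuple[float, float] = (35.0, 80.0)
    chip_rate_intercept: float = -0.9
    chip_rate_slope: float = 0.04
    chip_vaf_range: tuple[float, float] = (0.02, 0.30)
    subclonal_count_mean: float = 20.0
    vaf_distribution: tuple[float, float] = (0.001, 0.02)
    artifact_loci: tuple[ArtifactSpec, ...] = ()

    def __post_init__(self) -> None:
        if self.n_subjects < 0:
            raise ValueError("n_subjects must be >= 0")
        lo, hi = self.age_range
        if not (18.0 <= lo <= hi <= 120.0):
            raise ValueError("age_range must lie within [18, 120]")
        if self.subclonal_count_mean < 0:
            raise ValueError("subclonal_count_mean must be >= 0")

    def expected_chip_count(self, age: float) -> float:
        return max(0.0, self.chip_rate_intercept + self.chip_rate_slope * age)


@dataclass(frozen=True)
class CohortSubject:
    subject_id: str
    age: float
    pileups: tuple[Pileup, ...]


@dataclass(frozen=True)
class PanelReplicate:
    """One independent library preparation of a dilution series."""

    replicate_id: int
    panels: dict[float, tuple[Pileup, ...]]  # concentration -> pileups


def expected_vaf(stock_vaf: float, concentration: float, rounding: int = 4) -> float:
    """Expected VAF of a stock variant after dilution.

    Multiplicative in both arguments, rounded half-up to ``rounding``
    decimal places as on a dilution worksheet (0.0500 stock at 25% panel
    concentration -> 0.0125; at 1.56% -> 0.0008).
    """
    if not 0.0 <= stock_vaf <= 1.0:
        raise ValueError(f"stock_vaf must be in [0, 1], got {stock_vaf}")
    if not 0.0 < concentration <= 1.0:
        raise ValueError(f"concentration must be in (0, 1], got {concentration}")
    product = Decimal(str(stock_vaf)) * Decimal(str(concentration))
    quantum = Decimal(1).scaleb(-rounding)
    return float(product.quantize(quantum, rounding=ROUND_HALF_UP))


def molecules_from_input(input_ng: float, conversion_efficiency: float = 1.0) -> int:
    """Haploid genome-equivalent molecules available per locus.

    At 3.3 pg per haploid genome, 1 ng carries 303 copies; 100 ng at full
    conversion therefore yields 30,300 molecules, of which a 0.001-VAF
    variant occupies ~30 alleles (~15 diploid cells).
    """
    if input_ng < 0:
        raise ValueError("input_ng must be >= 0")
    if not 0.0 <= conversion_efficiency <= 1.0:
        raise ValueError("conversion_efficiency must be in [0, 1]")
    return int(round(input_ng * HAPLOID_COPIES_PER_NG * conversion_efficiency))


def _balanced_strands(n: int, rng: np.random.Generator) -> np.ndarray:
    """Near-exactly balanced +/- labels in random order (odd one randomized)."""
    n_plus = n // 2 + (int(rng.integers(2)) if n % 2 else 0)
    labels = np.array(["+"] * n_plus + ["-"] * (n - n_plus))
    rng.shuffle(labels)
    return labels


def _rng_for(seed: int, *key: int) -> np.random.Generator:
    """Deterministic child generator from a master seed and an integer key path."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=tuple(key)))


def simulate_pileup(
    truth: list[VariantSpec] | tuple[VariantSpec, ...],
    config: SimConfig,
    *,
    locus_id: str | None = None,
    n_families: int | None = None,
    rng: np.random.Generator | None = None,
) -> Pileup:
    """Simulate the UMI families observed at one locus.

    Each of the ``n_families`` molecules independently carries a truth
    allele with probability ``true_vaf * locus_bias`` (else reference); a
    reference molecule turns into a false alternate family with probability
    ``pre_consensus_error``. Families receive a strand, ``1 + Poisson``
    reads, and post-consensus read flips. Fully reproducible given the seed.
    """
    truth = tuple(truth)
    if locus_id is None:
        locus_id = truth[0].locus_id if truth else "locus"
    if rng is None:
        rng = _rng_for(config.seed, 0)
    m = config.n_families() if n_families is None else int(n_families)
    if m <= 0:
        return Pileup(locus_id=locus_id, families=(), truth=truth)

    probs = np.array([min(1.0, v.true_vaf * v.locus_bias) for v in truth], dtype=float)
    if probs.sum() > 1.0:
        raise ValueError("combined allele probabilities exceed 1 at locus " + locus_id)
    alleles = [v.allele for v in truth]

    # molecule allele per family: 0..k-1 = truth alts, k = ref
    cut = np.concatenate([np.cumsum(probs), [1.0]])
    u = rng.random(m)
    idx = np.searchsorted(cut, u, side="right")
    idx = np.minimum(idx, len(alleles))  # guard the u == 1.0 edge

    is_ref = idx == len(alleles)
    artifact = is_ref & (rng.random(m) < config.pre_consensus_error)

    # Strand capture is duplex-balanced: both strands of each input molecule
    # are amplified, so families supporting a genuine allele split ~evenly
    # between strand labels (odd remainders randomized). Only the artifact
    # process can be chemically single-stranded (deamination/PCR error).
    strand = np.empty(m, dtype="<U1")
    genuine_groups = [np.flatnonzero((idx == k) & ~artifact) for k in range(len(alleles))]
    genuine_groups.append(np.flatnonzero(is_ref & ~artifact))
    for group in genuine_groups:
        strand[group] = _balanced_strands(len(group), rng)
    art_idx = np.flatnonzero(artifact)
    if art_idx.size:
        if rng.random() < config.strand_artifact_rate:
            strand[art_idx] = "+"  # single-stranded artifact process at this locus
        else:
            strand[art_idx] = _balanced_strands(art_idx.size, rng)

    reads = 1 + rng.poisson(config.reads_per_family_mean - 1.0, size=m)
    flips = (
        rng.binomial(reads, config.post_consensus_error)
        if config.post_consensus_error > 0
        else np.zeros(m, dtype=int)
    )

    families = []
    for i in range(m):
        if artifact[i]:
            allele = ARTIFACT_ALLELE
        elif is_ref[i]:
            allele = REF
        else:
            allele = alleles[idx[i]]
        nflip = int(flips[i])
        if nflip:
            # alt reads flip back to ref; ref reads flip to a false alt
            flip_to = REF if allele != REF else (alleles[0] if alleles else ARTIFACT_ALLELE)
        else:
            flip_to = None
        families.append(
            Family(
                family_id=i,
                allele=allele,
                strand=str(strand[i]),
                read_count=int(reads[i]),
                flipped=nflip,
                flip_allele=flip_to,
            )
        )
    return Pileup(locus_id=locus_id, families=tuple(families), truth=truth)


def simulate_reference_panel(
    series: DilutionSeries,
    config: SimConfig,
    n_replicates: int = 8,
    depths: dict[str, float] | None = None,
) -> list[PanelReplicate]:
    """Independent library preparations of a serially diluted reference standard.

    Per replicate and concentration, every stock variant is simulated at its
    diluted true VAF (``stock_vaf * concentration``, unrounded). ``depths``
    optionally maps locus_id to a per-variant target read depth (e.g. the
    printed per-variant depths of a validation worksheet); otherwise the
    config depth applies. Per-replicate generators are derived
    deterministically from the master seed, so replicates are independent
    but the whole panel is reproducible.
    """
    replicates = []
    for r in range(n_replicates):
        panels: dict[float, tuple[Pileup, ...]] = {}
        for ci, conc in enumerate(series.concentrations):
            pileups = []
            for vi, stock in enumerate(series.stock):
                diluted = VariantSpec(
                    locus_id=stock.locus_id,
                    variant_class=stock.variant_class,
                    true_vaf=stock.true_vaf * conc,
                    consequence_tag=stock.consequence_tag,
                    population_af=stock.population_af,
                    locus_bias=stock.locus_bias,
                    allele=stock.allele,
                )
                depth = (depths or {}).get(stock.locus_id, config.target_read_depth)
                nfam = min(
                    molecules_from_input(config.input_ng, config.conversion_efficiency),
                    int(round(depth / config.reads_per_family_mean)),
                )
                rng = _rng_for(config.seed, 1, r, ci, vi)
                pileups.append(
                    simulate_pileup([diluted], config, n_families=nfam, rng=rng)
                )
            panels[conc] = tuple(pileups)
        replicates.append(PanelReplicate(replicate_id=r, panels=panels))
    return replicates


def simulate_cohort(spec: CohortSpec, config: SimConfig) -> list[CohortSubject]:
    """Simulate an age-structured cohort of blood samples.

    Each subject carries a Poisson number of CHIP-level (>= 0.02 VAF) clones
    with age-linear mean, a Poisson number of subclonal variants with
    log-uniform VAFs, and any configured recurrent artifact loci (shared
    locus_ids across subjects, to exercise the cohort-prevalence filter).
    """
    subjects: list[CohortSubject] = []
    master = _rng_for(config.seed, 2)
    ages = master.uniform(*spec.age_range, size=spec.n_subjects)
    for s in range(spec.n_subjects):
        rng = _rng_for(config.seed, 2, s + 1)
        age = float(ages[s])
        pileups: list[Pileup] = []

        n_chip = rng.poisson(spec.expected_chip_count(age))
        lo, hi = spec.chip_vaf_range
        for j in range(n_chip):
            vaf = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            spec_v = VariantSpec(
                locus_id=f"S{s:04d}:chip{j}", true_vaf=vaf, consequence_tag="missense"
            )
            pileups.append(simulate_pileup([spec_v], config, rng=rng))

        n_sub = rng.poisson(spec.subclonal_count_mean)
        lo, hi = spec.vaf_distribution
        for j in range(n_sub):
            vaf = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            spec_v = VariantSpec(
                locus_id=f"S{s:04d}:sub{j}", true_vaf=vaf, consequence_tag="missense"
            )
            pileups.append(simulate_pileup([spec_v], config, rng=rng))

        for art in spec.artifact_loci:
            if rng.random() >= art.prevalence:
                continue
            spec_v = VariantSpec(
                locus_id=art.locus_id,
                true_vaf=art.vaf,
                consequence_tag=art.consequence_tag,
            )
            pile = simulate_pileup([spec_v], config, rng=rng)
            if art.single_stranded:
                fams = tuple(
                    Family(
                        family_id=f.family_id,
                        allele=f.allele,
                        strand="+" if f.allele == spec_v.allele else f.strand,
                        read_count=f.read_count,
                        flipped=f.flipped,
                        flip_allele=f.flip_allele,
                    )
                    for f in pile.families
                )
                pile = Pileup(locus_id=pile.locus_id, families=fams, truth=pile.truth)
            pileups.append(pile)

        subjects.append(
            CohortSubject(subject_id=f"S{s:04d}", age=age, pileups=tuple(pileups))
        )
    return subjects
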