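# Methods

## The measurement problem

Ultra-sensitive detection of somatic blood-cell clones is molecule-limited
before it is read-limited: 100 ng of input DNA carries ~30,300 haploid
genome copies (3.3 pg each), so a 0.001-VAF clone is represented by ~30
alleles — about 15 diploid cells — no matter how deeply the library is
sequenced. Molecular barcoding (UMIs) groups reads into per-molecule
families, which suppresses the raw sequencing error rate of 0.005–0.02 to
a residual ~1e-4 and makes the number of *unique alternate observations*
(UAO, alternate-supporting families) the natural unit of evidence.
`chipvalid` models exactly this regime and computes the validation
statistics an accredited laboratory reports.

## Generative model

Per locus, the simulator draws `m` families, with
`m = min(input_ng × 303 × conversion_efficiency, target_read_depth / reads_per_family_mean)` —
the molecule-limited or depth-limited budget, whichever binds. Each family
then receives:

1. **Molecule allele.** Alternate with probability `true_vaf × locus_bias`
   (multinomial across alleles at multi-allelic loci), else reference.
   A reference molecule becomes a false alternate ("artifact") family with
   probability `pre_consensus_error`.
2. **Strand label.** Library capture is duplex-balanced — both strands of
   every input duplex are amplified — so families supporting a genuine
   allele are assigned near-exactly balanced +/− labels (odd remainders
   randomised) within each allele class. Only the artifact process can be
   chemically single-stranded (deamination/PCR damage affects one strand):
   with probability `strand_artifact_rate` all artifact families at a
   locus share one strand. An independent-Bernoulli strand model would
   make the Fisher strand-bias rule discard a few percent of *true*
   variants by sampling noise alone, which is not how strand-balanced
   duplex-derived data behave.
3. **Reads.** `1 + Poisson(reads_per_family_mean − 1)` reads (tie-free,
   always ≥ 1); each read flips allele with `post_consensus_error`.

Families are stored compactly as (allele, strand, read_count, flipped
reads, flip target); since a family's reads can carry at most one flip
target, this is lossless for consensus, read-level VAF and subsampling.

### Consensus and calling

A family's consensus is the majority read allele (ties → reference,
conservative against false positives); singleton families are
uncorrectable. Calls report **read-level VAF and depth** but
**family-level UAO and strand counts**. The two scales are deliberately
decoupled: validated grids show observed VAF, depth and UAO combinations
inconsistent with `VAF = UAO/depth` (e.g. VAF 0.0481 at depth 1433 with
UAO 47), which is reproduced when alternate families are larger or smaller
than average.

### Filter cascade

Eight conjunctive rules in fixed order (population AF ≥ 0.05, VAF
< 0.0001, Fisher-exact strand bias p ≤ 0.05, germline window [0.45, 0.55]
∪ [0.95, 1], functional-relevance tag set, cohort prevalence > 0.10,
UAO < 3, LLOD). Every rule is evaluated for every call — provenance
records all failures, enabling per-rule exclusion accounting — and the
verdict is order-independent because the rules are conjunctive. Boundary
conventions: the germline window is inclusive on both ends; cohort
prevalence uses strict `>`; the strand test is the two-sided Fisher exact
on family counts [[alt+, alt−], [ref+, ref−]] (the standard exact choice
at UAO-scale counts) with no multiple-testing correction, matching the raw
p ≤ 0.05 operating rule. The LLOD rule compares the *observed* VAF against
the global 0.004 or a per-locus override (ASXL1:c.1934dup → 0.031, an
8-bp guanine homopolymer context notorious for over-calling).

## Key parameters

| parameter | default | units | rationale |
|---|---|---|---|
| haploid copies per ng | 303 | molecules/ng | 3.3 pg per haploid genome; makes 100 ng ↔ ~15 diploid cells at 0.001 VAF |
| `conversion_efficiency` | 0.25 | fraction | library conversion is never reported by assay vendors; 0.25 is the single calibration knob reconciling naive binomial detection with realistic sub-0.001-VAF performance |
| `reads_per_family_mean` | 1.7 | reads | back-calculated from validated grids where read depth exceeds the family count implied by UAO (~69 alt reads vs 47 alt families) |
| `pre_consensus_error` | 1e-4 | per molecule | residual error floor of UMI-corrected sequencing |
| `post_consensus_error` | 1e-4 | per read | same order; corrected by majority vote in families ≥ 2 reads |
| `target_read_depth` | 3,400 | reads | middle of the recommended 3,000–4,000× band |
| `uao_min` | 3 | families | optimised threshold: detection is largely flat up to 3 and falls steeply from ≥ 5 |
| `global_llod` | 0.004 | VAF | validated limit: 100% replicate detection at ≥ 0.004, 56% at 0.0031 |
| LLOD criterion | 0.95 | fraction | clinical definition: smallest VAF with ≥ 95% of replicates detected, contiguously across all higher tested VAFs |

Cohort defaults: 383 subjects aged 35–80; CHIP-clone count per subject
Poisson with mean `−0.9 + 0.04 × age` (≈1.4 at the mid-cohort age, range
clipped at 0); CHIP VAFs log-uniform on [0.02, 0.30]; subclonal variants
Poisson(20) per subject with log-uniform VAFs on [0.001, 0.02]. The
subclonal mean is a desk-scale choice — real cohorts at this depth carry
thousands of sub-0.02 variants per sample, which would only scale the
compute, not the logic.

## Validation statistics

- **Analytical range:** OLS of observed on expected VAF, Pearson r and R²;
  fold bias as the arithmetic mean of per-pair observed/expected ratios
  with Bland–Altman-style limits `bias ± 1.96 × SD(ratios)` (raw ratios,
  not log-ratios; the averaging convention is a documented choice).
  Non-detected entries are dropped, never imputed as 0; the two loci with
  documented locus-specific quirks (ASXL1:c.1934dup, FLT3:c.2503G>T) are
  excluded from linearity fits. On the packaged grid the eligible
  (expected ≥ 0.004) pairs give r ≈ 0.998 and mean fold ratio ≈ 0.83 —
  mean-level data cannot reproduce replicate-level correlation/bias
  figures computed from unpublished raw replicates, and no attempt is made.
- **Precision:** CV = sample SD (n−1) / mean per variant and stratum;
  undefined (flagged) at mean 0. Under pure molecule sampling the CV obeys
  `sqrt((1−f)/(f·m))`, the binomial closed form the tests check against.
- **LLOD:** smallest grid VAF meeting the ≥ 95% criterion contiguously
  from above; an explicit diagnostic (not a zero) when nothing qualifies.
- **Trueness:** the five confusion-matrix metrics as percentages against
  the ≥ 98% acceptance bar; undefined metrics (zero denominator) carry no
  pass/fail flag. Presumed-negative accounting partitions calls into
  off-panel / on-panel-below-reference-LLOD / remaining / unclassifiable;
  concordance is 100% iff nothing remains, and is not computable while
  unclassifiable calls exist.

## Study designs built in

The trueness study simulates 23 reference-standard variants (15 from the
packaged dilution grid at their undiluted VAFs and per-variant depths,
floored at 1,000 effective molecules, plus 8 synthetic extra standards at
VAF ≥ 0.05 standing in for the unprinted remainder of the commercial
standards, FLT3-ITD among them as an insertion allele), 36 synthetic
clinical-reference variants at VAFs 0.05–0.40 and 3,000 families, and 29
wild-type loci (true VAF 0, post-consensus error only). Detection-rate
studies run 1,000 replicate loci (0.02 VAF, 500 molecules) and 8 library
preparations (0.004 VAF, 3,121 molecules) under the pure UAO ≥ 3 rule.
These sizes keep the whole suite and the acceptance script in the
seconds-to-minutes range.

## What the simulator does and does not emulate

It emulates molecule-limited sampling, UMI family structure, strand
labels, residual pre/post-consensus errors, locus-specific recovery bias,
serial dilution, replicate library preparations, read subsampling (depth
normalisation re-runs consensus after uniform without-replacement read
removal), and an age-structured cohort with recurrent artifact loci. It
does **not** model sequence content, alignment, primer/GC effects,
substitution-type error spectra, split-read ITD detection (ITDs are
insertion alleles), or the additional library-conversion losses that real
assays suffer at very low VAF. Consequently the end-to-end synthetic LLOD
at a 3,121-molecule budget comes out one dilution step *lower* (~0.0016–
0.0031) than the 0.004 a real assay validates: with every modelled error
source off, detection at 0.0031 is near-certain, whereas real replicate
preparations lose molecules the model does not track. Passing tests
therefore demonstrate the correctness of the statistics and the
machinery, not the wet-lab performance of any particular assay.

## Numerical choices

- Dilution arithmetic uses decimal multiplication of the printed stock and
  concentration strings with ROUND_HALF_UP to 4 places — binary-float
  `round()` (banker's rounding) fails on worksheet values like
  0.40 × 0.015625 → 0.0063.
- Per-replicate/subject/locus RNG streams derive from
  `SeedSequence(master_seed, spawn_key)`, so replicates are independent,
  reproducible and platform-stable; identical seeds give identical output.
- Subsampling uses a multivariate hypergeometric draw over per-family read
  classes (unbiased; families with no surviving reads are dropped).
- Consensus ties resolve to reference; multi-allelic loci emit one call
  per alternate allele.
- Detection "rate" across replicates is reported both as all-replicates
  (concordant, the default) and any-replicate.

## Limitations

Opaque locus keys rather than genomic coordinates (VCF export uses
placeholder positions); no base qualities or duplex consensus; the
population-frequency annotation is a synthetic stand-in, not a gnomAD
lookup; functional relevance is a tag whitelist, not an effect predictor;
empirical cohort variant counts, replicate-level correlation/bias figures
and sub-0.001-VAF detection percentages are out of reproduction scope for
the reasons above.
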