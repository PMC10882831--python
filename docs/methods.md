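# tmseq methods

## The measurement problem

A transcription error is a base in an mRNA molecule that differs from the
DNA it was transcribed from. Measured naively from reads, the signal is
buried under sequencing errors (~10⁻³ per base) and PCR errors — both
orders of magnitude above the transcription-error rates of interest
(10⁻⁶–10⁻⁴ bp⁻¹). Two orthogonal error-correction schemes recover it:

* **UMI consensus (single cell).** All reads sharing one (cell barcode,
  UMI, transcript) key derive from one mRNA molecule. Per aligned column
  the consensus takes the majority base; with the default
  `min_reads = 2` and `min_agreement = 1.0` (unanimity), a sequencing
  artifact survives only if two independent reads hit the same position
  with the same wrong base — probability ≈ e²/3 per base for per-read
  error e, i.e. ~3×10⁻⁷ at e = 10⁻³, below the lowest signal measured.
  Columns without unanimity are masked `N` and leave every downstream
  denominator. Positions not covered by all reads of a family are
  trimmed (extent intersection), keeping the per-column read count
  constant.
* **Rolling-circle folding (bulk, CirSeq).** An RNA fragment circularized
  and copied in tandem carries its transcription errors into every
  repeat, while sequencing errors hit single copies; column-wise folding
  across ≥ 3 repeats removes the latter with residual O(e²).

Errors introduced *before* molecules are distinguishable — early PCR
duplications whose products dominate a UMI family — are not removable by
consensus. They are modelled explicitly (below) and form a quantified
floor (~10⁻⁶ × expected shared duplications per base at the default
polymerase fidelity), not a hidden bias.

## Distinguishing lesions from DNA mutations

Both a miscoding lesion and a real DNA mutation produce recurrent
identical RNA changes. Three facts separate them:

1. **Penetrance.** A DNA mutation affects ~100% of a cell's molecules at
   the site; a single-allele lesion with full bypass affects ~50%
   (`lesioned_allele_fraction × lesion_miscoding_prob`). The classifier
   pools molecule counts across cells per (transcript, position, alt)
   and labels `candidate_dna_mutation` when the pooled mutant fraction
   is ≥ `mut_frac_threshold = 0.95` at pooled coverage
   ≥ `min_mut_coverage = 10`; such sites are removed entirely
   (numerator and denominator) from the spectrum.
2. **Strand bookkeeping.** Substitution types live in mRNA-sense
   transcript space (U stored as T) and are never complement-folded: an
   O⁶-mG lesion on the template strand elevates only C→U, while a
   G:C→A:T DNA mutation would elevate G→A in transcripts of the
   opposite-sense context. The pipeline therefore treats "C→U up, G→A
   flat" as the lesion signature.
3. **Quiescence (experimental design, simulated).** Non-dividing cells
   cannot fix damage into mutations via replication, so the simulator's
   truth table gives lesions `expected_mutant_fraction = laf × bypass`
   and explicit mutations exactly 1.0.

## The estimator

For substitution X→Y in one sample:

    rate(X→Y) = (mutant molecules carrying X→Y at transcription-error sites)
                ────────────────────────────────────────────────────────────
                (unmasked consensus-molecule bases with reference base X,
                 candidate-DNA-mutation and blacklisted sites excluded)

in bp⁻¹. The numerator counts *molecules* (each mutant UMI family is one
transcription event), making the estimator an unbiased per-transcription
error rate; `unit="site"` switches to counting distinct sites instead.
A type whose denominator is zero reports NaN ("undefined") with a
warning, distinct from an observed zero. The overall N→N rate is the sum
of numerators over the sum of denominators. Pseudo-alleles are the
per-cell calls with mutant fraction strictly > 10% (the filter is strict
because "more than 10%" is the inclusion rule), at least 2 mutant
molecules (one molecule is not recurrence) and ≥ 10 total molecules
(so the 10% cut is meaningful); the ratio histogram uses right-inclusive
0.05-wide bins on (0.10, 1.00].

## Simulator design

The generator draws, per cell: lesion sites (Bernoulli per reference
base matching `lesion_ref_base`, one allele), molecule counts per
transcript (Poisson), reads per molecule (shifted Poisson with floor 2),
then layers events in biological order — DNA mutations (penetrance 1),
lesion miscoding per molecule (probability `laf × bypass`), background
transcription errors (i.i.d. per molecule base), PCR errors (binomial per
duplication on a binary tree of depth `pcr_cycles`; reads sample leaves,
inherit their root path, so an early error is shared by a read *subset* —
exactly the artifact class consensus cannot always remove), and
per-read sequencing errors. Stochastic errors are drawn as a delta
r ∈ {1,2,3} applied as (base + r) mod 4 — uniform over the three
non-current bases and commutative under stacking; lesions and mutations
carry absolute alt bases. CirSeq mode emits `repeat_count` tandem copies
per fragment with transcription errors shared across copies and
sequencing errors per copy.

Every replicate is a pure function of (config, reference, seed):
byte-identical FASTQ and truth tables on re-run.

**Two equivalent execution routes.** The record route materializes FASTQ
and runs parsing → family grouping → column-vote consensus → per-site
tally. The sparse engine observes that a consensus column can deviate
from the reference, or be masked, only where an event landed, and
performs the identical bookkeeping over event lists — same unanimity
rule, masking, call, classification and spectrum definitions. The test
suite asserts exact equality of calls and spectra between the routes on
randomized configurations (including PCR trees, fragments, mutations and
single-read families); the engine only supports the default unanimity
rule and refuses otherwise. Large parameter-recovery runs use the
engine; user-supplied FASTQ/SAM always uses the record route.

**What the generator does not emulate** — and hence what green tests do
not certify about real data: UMI sequencing errors (families are exact-
match; no directional-adjacency collapsing), barcode collision/doublet
artifacts, coverage and GC bias, splicing and isoforms, expression
heterogeneity, RNA-editing hotspots (a BED blacklist hook exists but
ships empty), alignment/realignment error (reads carry their true origin;
CirSeq consensi map via simulator tags, external data would need an
aligner), indels, and chemistry/dose kinetics of the genotoxin exposure
(abstracted into `lesion_site_rate` and `lesion_miscoding_prob`).

## Study-condition parameters

`tmseq.experiments` fixes the two simulated conditions used throughout
the recovery tests, against a 20-transcript × 1200 bp, GC-0.5 reference:

| parameter | vehicle | treated | rationale |
|---|---|---|---|
| C→U molecule-error rate | 6.7×10⁻⁶ bp⁻¹ | 6.9×10⁻⁵ bp⁻¹ | the two condition rates the experiment reproduces |
| background_tx_error_rate | 2.01×10⁻⁵ | 2.01×10⁻⁵ | uniform over types ⇒ C→U third equals the vehicle rate |
| lesion_site_rate | 0 | 1.246×10⁻⁴ per C | supplies the treated excess: rate × 0.5 × 1.0 = 6.23×10⁻⁵ |
| lesioned_allele_fraction / bypass | — | 0.5 / 1.0 | one fully miscoding lesion on a diploid locus → 50:50 pseudo-alleles |
| seq_error_rate | 10⁻³ | 10⁻³ | Illumina-scale per-base error |
| pcr_error_rate, pcr_cycles | 10⁻⁶, 12 | 10⁻⁶, 12 | high-fidelity polymerase, typical library amplification |
| molecules / cell / transcript | 4 | 4 | modest per-gene UMI depth |
| reads / molecule | 3 (min 2) | 3 (min 2) | every family collapsible at min_reads = 2 |

Scale is set by `n_cells`: recovery runs use 500 treated cells
(≈1.2×10⁷ surveyed C bases) and 1300 vehicle cells (≈3.1×10⁷), sized so
the Poisson sampling error of ≥ 200 expected error molecules sits well
inside the recovery tolerances; the 20-repetition group comparison uses
100 treated / 750 vehicle cells per replicate (≥ 100 expected events
each). The replicate count (3 vs 3) matches the demo scenario. Because
lesion errors arrive clustered (one site → ~coverage/2 mutant
molecules), the treated estimator variance is governed by the number of
lesion *sites*, not error molecules; the chosen molecule depth of 4
keeps that clustering factor mild.

## Numerical and tie-breaking choices

* Coordinates are 0-based half-open everywhere internally and in TSVs;
  only the VCF-like export is 1-based (flagged in its header).
* Consensus ties (top count = runner-up at `min_agreement < 1`) are
  always masked, never broken randomly; CirSeq folding masks a column
  whenever the winner's summed quality is below twice the runner-up's,
  so an equal-quality 2-vs-1 column keeps the majority base and a
  1-1-1 column masks.
* Period detection minimizes the self-offset mismatch fraction over
  candidate periods (mismatch ≤ 0.1, ≥ `min_repeats = 3` full repeats;
  ties to the smallest period). Chosen over FFT/suffix methods for
  transparency — it is directly checkable against an exhaustive scan.
* `min_repeats = 3` gives every column an odd vote when the read length
  is an exact multiple; partial trailing repeats still contribute to the
  columns they cover.
* Pooled-variance Student's t is the default group test (Welch behind a
  flag) and no multiple-testing correction is applied across the 12
  substitution types by default (a Bonferroni helper exists): one
  pre-specified comparison (C→U) is the primary endpoint.
* Replicate seeds are spawned from the root seed via
  `numpy.random.SeedSequence`, keeping runs reproducible and replicates
  independent.

## Known limitations

* PCR errors shared by *all* sampled reads of a family are
  indistinguishable from transcription errors at consensus level; at the
  default rates this floor is ≈ 10⁻⁶ bp⁻¹ spread over 12 types (~5% of
  the vehicle C→U signal), and it is measured, not corrected.
* Exact-match UMI families mean a sequencing error inside a UMI splits a
  family; with 10-nt UMIs and e = 10⁻³ this loses ~1% of reads and does
  not bias rates, but the limitation is logged.
* The classifier cannot distinguish a 100%-bypass homozygous-lesion site
  from a DNA mutation (both sides of the biology agree it should not,
  absent DNA sequencing); such sites are conservatively excluded.
* `classify_site` sees only cells with ≥ 1 mutant molecule at a site;
  wild-type-only cells do not enter the pooled fraction. For germline
  mutations (all cells mutant) this is immaterial; for single-cell
  mutations it makes exclusion depend on that cell's coverage alone.
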