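# Methods

This note documents the models, conventions and numerical choices
behind `srna-signature`, in the order data flows through the package.

## Coordinates, strands, and the reference

All coordinates are 1-based with both ends inclusive; "positions
294–432" is a 139-nt interval. `sense` is the orientation of the target
transcript; a read is `antisense` when its reverse complement matches
the reference. A mapped read's *biological 5′ end* is its leftmost
reference base when sense and its rightmost when antisense; reads
straddling a region boundary are assigned to the region holding that
base.

The target transgene's full sequence is not public, so the shipped
reference is synthetic: a seeded pseudorandom 720-nt ACGT sequence with
the published primer cores embedded verbatim at their published
amplicon boundaries (the 5′-fragment forward core at position 1, the
trigger forward core at 294, the reverse complement of the trigger
reverse core ending at 432). This preserves every printed coordinate
without passing invented sequence off as ground truth; any user-supplied
FASTA reference can replace it. The 5′-fragment *reverse* core is not
embedded because its position (303–322) would overlap the trigger
forward core, and overlapping motifs are rejected by contract.

The flanks are derived, not configured: 5′ flank = [1, trigger
start − 1], 3′ flank = [trigger end + 1, reference length].

## The read simulator

The generator emulates the seven-sample spray design — three
dsRNA-sprayed reporter samples (`target_ds`), three dsRNA-sprayed wild
types (`wildtype_ds`), one water-sprayed reporter (`target_water`) —
with four read sources:

* **Degradation.** Fragment lengths follow a truncated
  exponential/geometric law on the 17–29-nt window, P(L) ∝
  exp(−λ(L − 17)); start positions are uniform over placements fitting
  the source region. Only the qualitative shape (more short reads,
  log-linear histogram) is documented for the real data, so λ is a free
  parameter; the default λ = 0.25 gives an e-fold drop every 4 nt, a
  visually strong but not cliff-like decay. Lengths are drawn before
  positions, so the emitted length histogram follows the law exactly
  regardless of region size. Sprayed-dsRNA decay is confined to the
  trigger and produces both strands; mRNA turnover spans the whole
  target, sense only.
* **DCL products.** Lengths drawn from `size_probs` over {21, 22, 24}
  (default 0.3/0.4/0.3); a `phase_fraction` of reads start on the
  phased register (trigger start + k·L), the rest uniformly; strands
  50/50. Duplex geometry (2-nt 3′ overhangs) is deliberately not
  modelled — the phasing analysis reasons in 5′-register terms, and the
  register convention below keeps both strands of a phased duplex on
  one offset.
* **Transitive reads.** Antisense, silencing-sized, uniform over the
  flanks; only biologically possible in `target_ds` (the wild type has
  no transcript for RDR6 to copy — configuring a nonzero
  `transitive_fraction` there is a design error, not a silent fix).
* **Background.** A fraction (default 0.2) of off-target reads: half
  exact copies of a fixed synthetic 21-nt miR159-like decoy, half decay
  fragments of a separate background reference. The decoy gives the
  functional-normalization schemes a depth-proportional denominator.

Default library size is 50,000 reads per sample. The real libraries run
to ~7.5 million reads, which is not a desk-scale simulation target; what
matters statistically is the few hundred to few thousand target-mapping
reads per sample, and the default reproduces that regime. The analysis
drivers and calibration loops use 20,000 reads per sample.

Qualities are constant `I` (Phred 40): the analysis never reads them.
Fixing the seed fixes the byte content of every FASTQ; per-sample
generators are spawned deterministically from the experiment seed.

What the simulator does **not** model: sequencing error, quality
variation, adapter dimers, multi-locus backgrounds, partial uptake
gradients across the leaf. Passing the recovery tests therefore shows
the statistics detect the modelled signal structure, not that they are
robust to every artefact of real libraries.

## Read processing

Adapter trimming cuts at the first occurrence of the adapter's 8-nt
prefix; adapter-free reads ≥ 30 nt are discarded (a genuine small RNA
must have run into adapter on a 75-cycle read), shorter adapter-free
reads pass through. The QC window then keeps 17–29 nt, strict bounds on
both sides.

Mapping is exact (zero mismatches) and strand-aware. References here
are single sub-kilobase transgenes; exactness keeps the mapper honest
against a brute-force all-substrings oracle, which the test suite runs
on hundreds of random references. The counting stage uses a hash index
of all in-window reference substrings (equivalent by construction and
by test). Reads with more than one placement are dropped as ambiguous
and tallied, never counted; reads with non-ACGT characters are tallied
and skipped without raising. Every table carries the accounting
identity `cells + ambiguous + unmapped + out_of_range = total_reads`.

## Statistics

* **Decay fit.** OLS of ln(count) on length over nonzero lengths in
  the fit range (default 17–29). "r" is the Pearson correlation of
  that regression (sign kept); the raw-count correlation is reported
  alongside since either reading of a printed fit quality is
  defensible. Zero-count lengths are excluded and counted. Constant
  counts define rate = 0, r = 0.
* **Raw enrichment.** Two-sided pooled-variance Student *t* per length,
  no multiplicity correction (mirroring per-length figure annotations).
  Degenerate zero-variance comparisons: equal means → p = 1, unequal →
  p = 0. Type-I error under a shared-Poisson null (3 vs 3, n = 10,000
  reps) is calibrated to 5% ± 1.5 points in the acceptance suite.
* **Control normalization.** Per-length division by the water sample's
  counts. Control zeros flag cells as undefined rather than producing
  infinities; a single-replicate control is flagged in the report notes
  as a fragile denominator. The ANOVA (with Bonferroni-adjusted
  pairwise *t* post tests and a compact letter display built from
  maximal cliques of the not-distinguishable graph) runs in **both**
  orientations — conditions within a length, and lengths within a
  condition — because the published comparison is ambiguous between
  them. On the fixture, only the across-length orientation shows the
  22-nt depletion effect: the water control has a 22-nt spike (37 reads
  vs ~10 at other lengths), so normalized 22-nt ratios sit far below
  their neighbours within each condition.
* **Functional normalization.** Counts divided by a per-sample
  denominator: reads matching the miR159 decoy, or all 24-nt reads.
  Both denominators scale with the sample's RNAi throughput, making the
  schemes depth-invariant by construction in the simulator.
* **Sliding-window profile.** Mean of per-position biological-5′-end
  counts over a 10-nt window centred at each position (shrunk at the
  edges), divided by total reads; verified against an explicit-loop
  oracle and an exact accounting identity.
* **Transitivity.** Total antisense flank reads of the reporter
  samples, tested one-sided against Poisson(n · background rate) with
  the rate estimated from the wild-type samples' antisense flank
  counts. The verdict additionally requires a mean of ≥ 5 antisense
  flank reads per reporter sample, so one or two stray reads can never
  flip it when the background estimate is zero. Sense flank reads are
  mRNA decay and never contribute.
* **Phasing.** Registers are defined on sense coordinates and every
  read collapses to its leftmost base, so both strands of a diced
  duplex share an offset. Score = maximal offset occupancy; p = a
  binomial tail for that offset against its placement count under
  uniform placement, Bonferroni-corrected over the register's offsets.
  The placement-aware null matters: a 139-nt trigger admits 118
  placements of a 22-mer, which is not a multiple of 22, so a uniform
  1/22 null would be anticonservative at scale. Below 10 eligible
  reads the p-value is suppressed as underpowered.
* **Long/short ratio.** Fisher exact test on (long > 24 nt, short
  < 25 nt) × (outside, inside the trigger), oriented so that an odds
  ratio > 1 means long reads are over-represented *outside* — the
  direction expected when endogenous mRNA turnover is flatter than
  sprayed-dsRNA decay. Verified against full hypergeometric enumeration
  for every 2×2 table with total ≤ 30.

## Classification

`DCL_PROCESSED` iff any silencing size (21/22/24 nt) is significantly
*enriched* in the reporter line over the wild type, or the transitivity
verdict is true, or any phasing register is significant (Bonferroni
over registers tested). Otherwise `DEGRADATION_ONLY` requires
|pearson r| ≥ 0.9 for the **replicate-pooled** decay fit of each
dsRNA-sprayed condition; otherwise `INCONCLUSIVE`.

The pooling choice is deliberate. With only six length points per
sample (a 20–25-nt table), single-replicate log-linear correlations are
noisy — on the embedded fixture two wild-type replicates sit at
|r| ≈ 0.897–0.899 while every condition-pooled fit exceeds 0.97 — so a
per-sample gate at 0.9 would flip a clearly degradation-shaped data set
to inconclusive on replicate noise. Per-sample fits are still computed
and reported. The gate applies to the dsRNA-sprayed conditions only:
the water control measures mRNA turnover, not sprayed-dsRNA decay, and
its size profile carries the machinery-made 21/22/24-nt background.
Thresholds (0.9 decay gate, α = 0.05, 5-read transitivity floor) are
package policy, stated in the report output.

## Dose arithmetic

Molarity (µM) = concentration (ng/µl) / (length × unit mass) × 1000
with 660 g/mol per duplex base pair and 330 g/mol per single-stranded
nucleotide — the standard average constants, which reproduce every
printed molarity at its printed rounding (20 ng/µl × 139 bp → 0.22 µM;
1.4 and 14 ng/µl × 22 bp → 0.1 and 1 µM). Phased yield =
⌊length / 22⌋. The ratio helper takes an optional reference-molarity
override because treatment ratios are conventionally quoted against the
*rounded* 0.1 µM control figure (giving 26× for the 139-bp duplex at
240 ng/µl; the unrounded division gives ≈ 27×); the ≈ 150× effective
ratio is treated as a lower bound (computed ≈ 157×).

## Problem sizes and determinism

Test-suite and acceptance problem sizes are chosen as the smallest that
make each check statistically decisive: 10,000 replications for type-I
calibration, 100,000 reads for rate recovery (±10% tolerance), 20,000
reads per sample × 20 seeds for classification recovery, 200 random
references for the mapper oracle, exhaustive enumeration to n = 30 for
Fisher. All randomness flows from explicit seeds; reports are
byte-deterministic given a config (timestamps are not written).

## Known limitations

* Exact mapping cannot place reads across mismatches/edits; it is not
  suitable for genome-scale or polymorphic references.
* The transitivity background model is Poisson with a rate from three
  wild-type samples; severe overdispersion between samples would make
  the test anticonservative (the 5-read floor blunts, not removes,
  this).
* The phasing statistic is a register-occupancy maximum, a package
  construction; it is calibrated under uniform placement but is not a
  duplex-aware phasing score of the kind used for phasiRNA locus
  discovery.
* The single water control makes control-normalized statistics fragile
  by design of the emulated experiment; the report flags it.
* The positive-control siRNA's stated length (22 nt) and coordinates
  (164–187, a 24-nt span) disagree in the source material; the package
  records both and reconciles nothing.
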