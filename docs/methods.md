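# Methods

This note records the models behind each module, the parameter defaults
and why they were chosen, what the synthetic-data generator does and
does not emulate, and the numerical choices that were genuinely open.

## The biological model

An invertible promoter is a spacer of roughly 183–186 bp flanked by a
perfect inverted repeat: the left arm (default `GTTCGTTTAA`, 10 bp)
reads identically to the reverse complement of the right arm.
Site-specific recombination at the arms reverse-complements the whole
arm-to-arm segment. Two consequences drive everything downstream:

1. **The arms are invariant under inversion.** Reverse-complementing
   `arm + spacer + revcomp(arm)` yields `arm + revcomp(spacer) +
   revcomp(arm)`: only the spacer changes. The exact breakpoint inside
   the arm is therefore unobservable, and only spacer-overlapping bases
   can distinguish the two orientations.
2. **A population is a mixture.** Each cell carries each locus in one
   orientation; sequencing a culture samples the mixture, so per-locus
   ON fractions are estimable from reads exactly like a binomial
   proportion.

## Inverted-repeat discovery (`repeat_finder`)

A locus candidate is a *maximal* run of complementary position pairs on
an anti-diagonal of the sequence self-comparison: pairs `(p, q)` with
`seq[p]` complementary to `seq[q]` and `p + q` constant. Maximality
means the run can be extended in neither direction while remaining
perfectly complementary; the spacer is whatever separates the run's two
arms. The implementation seeds candidate runs with an exact k-mer index
(k = minimum arm length) and extends; the test suite checks it against
an exhaustive anti-diagonal scan.

Defaults: minimum arm 10 nt, spacer range 150–250 nt — brackets the
183–186 bp promoter spacers with margin on both sides, since the exact
search window used to find such loci in real genomes is a free choice.
Overlapping candidates are deduplicated keeping the longest arm; this
is deterministic but means a planted 10 bp-arm locus can occasionally be
masked by an overlapping chance repeat with a longer arm (observed at
the ~1–3% level in 10 kb random genomes; the acceptance report's
`planted_locus_recovery_percent` measures exactly this).

Seeded mode reports motif occurrence pairs at the motif's own length,
without maximal extension, so that a known arm yields loci with that
arm literally. De-novo hits may carry chance extensions of the planted
arm; containment, not equality, is the relation between the two modes.

**ON-orientation convention.** Coordinates alone cannot say which way a
promoter points — the locus is coordinate-symmetric. When an operon
annotation is supplied, the promoter's direction in the reference is
inferred from a strand-specific promoter motif (default
`ARACGTTCGTN`, the *Bacteroides* invertible-promoter repeat motif)
found inside the locus; ON is then the orientation pointing toward the
nearest downstream operon within 5 kb. Loci with no motif hit, an
ambiguous hit, or no operon in range keep the reference-is-ON
convention and are flagged unresolved.

## Orientation quantification (`orientation_quant`)

For each locus two haplotypes are built — the locus ± 1000 nt of flank,
in each orientation — and every read pair is aligned competitively to
both. A pair votes ON when it aligns concordantly to the ON haplotype
with ≥10 informative bases inside the spacer and aligns worse (lower
summed identity×length) or not at all to the OFF haplotype; symmetric
for OFF; everything else is ambiguous. Concordance means same
reference, opposite strands, forward–reverse orientation, insert within
100–1000 nt (generous around the ~350 bp fragment distribution; real
aligners do not publish their exact bounds, so the contract is explicit
here).

The competitive (dual-reference) design was chosen over single-reference
breakpoint logic because it handles reads ending inside the invariant
arms correctly: such reads align equally well to both haplotypes and
fall out as ambiguous rather than being miscounted.

Counts give `fraction_on = n_ON/(n_ON + n_OFF)` with a Wilson 95%
interval (well-behaved at extreme fractions, unlike the Wald interval).
The interval models pair-sampling only; at the default simulation sizes
the cell-sampling contribution is made negligible by using populations
of ≥20,000 cells.

## Long-read rearrangement detection (`longread_inversions`)

Alignment blocks of each read (from PAF/BLAST tabular input or the
internal split mapper) are filtered — reads >1000 nt; blocks >200 nt
with identity >90%, and e-value ≤1e-20 where the aligner reports one —
then chained in read order. Adjacent blocks on opposite strands emit an
inversion event; same-strand neighbours whose reference gap differs
from their read gap by more than 200 nt emit a displacement event with
that shift. The shift comparison is between *adjacent* blocks; comparing
each block to all others in the read is a possible alternative reading
of the procedure, but adjacent-pair gaps localise the breakpoint and
are what the event anchoring needs.

Events are anchored at the offending (minority-strand) block's boundary
adjacent to the junction. For a '−' block the read-start side maps to
the block's reference *end*, so a fully spanned inversion contributes
one event at each arm of the inverted segment — a read that merely ends
inside the inversion contributes one.

Event positions are binned at 1000 nt. "Hotspot" needs an explicit
threshold: the default flags bins with count ≥ max(5, the 99.9th
percentile of a Poisson with the mean events-per-bin rate), i.e. an
excess over a uniform background; the raw histogram is always returned
so any other threshold can be applied.

## Population metrics (`population_metrics`)

**VMR** is length-normalised coverage: mapped bases per genome length,
phage over host. Base counting (not read counting) keeps the estimate
invariant to read-length differences between sources; both conventions
exist in practice, so the input is just two base totals and the choice
is visible in the code.

**Burst steps.** One-step growth curves of persistently infecting phage
show a staircase of small bursts rather than one synchronous burst.
"Burst" is made operational as: binary segmentation on log10 per-capita
titers, splitting recursively at the minimum within-segment squared
error and accepting a split only when the adjacent segment means jump
by ≥ log10(1.5) (a 1.5-fold titer change — smaller jumps are within
plaque-assay noise). Zero titers are floored at half the assay
detection limit before the log transform, the standard plaque-assay
floor. The detector is idempotent: re-running it on its own fitted
piecewise-constant signal returns the same changepoints.

**Adsorption** uses the closed form `k = ln(P0/Pt)/(N·t)` for free-phage
decay on cells at density N; a titer increase yields a negative k with
a warning rather than an error. **EOP/EOCI** are plain percentages of
counts with/without phage.

## Synthetic data (`synthetic_data`)

The generator emulates the study system it is modelled on:

- genome: random sequence at 43% GC, default 5.8 Mb (scalable down;
  the tests use 10–500 kb), with five invertible loci by default, each
  `GTTCGTTTAA + spacer(183–186 nt) + TTAAACGAAC`;
- population: independent per-cell, per-locus Bernoulli orientations;
  OFF realised by reverse-complementing the arm-to-arm segment;
- short reads: 2×150 nt pairs, insert ~ Normal(350, 35) truncated at
  the read length, substitution errors at 0.1%;
- long reads: lengths log-normal with μ = ln 1882 and σ solved in
  closed form so the median is 1882 nt and the IQR 4697 nt (the two
  statistics available for the run being emulated; a log-normal is the
  simplest heavy-tailed two-parameter choice), substitution errors at
  5% — a plausible figure for the sequencing chemistry emulated, since
  no per-sample error rate is published;
- metagenome mixtures: per-read source Bernoulli with
  P(phage)/P(host) = VMR × phage_len/host_len, so the expected
  per-base coverage ratio equals the requested VMR.

Not emulated, deliberately: indels and homopolymer errors, chimeric
reads, quality-score structure, GC-biased fragment sampling, plasmids.
Passing tests therefore demonstrate correctness of the *logic* (coordinate
bookkeeping, classification, counting, thresholds) under substitution
noise, not robustness to every real-data artefact; on real libraries the
mapping step would come from a production aligner via the SAM/PAF/BLAST
interfaces rather than the internal mapper.

Every generator returns a truth table sufficient to predict each
downstream result without re-alignment, and identical seeds give
byte-identical outputs.

## The internal mapper (`io_align`)

`minimal_map` is an exact-k-mer-seed (k = 21, near-unique in megabase
genomes and robust at ≤1% error), ungapped-extension aligner reporting
only unique best hits — ties are reported unmapped so that orientation
counts are never fed ambiguous placements. `split_map` extends the same
index to local multi-block mapping: seeds are clustered per
(reference, strand, diagonal), clusters are extended under an X-drop
rule (+1 match / −3 mismatch, drop 20), and blocks are selected
greedily with ≤20 nt read overlap. The seed-cluster gap limit (150 nt)
is deliberately below the smallest locus span so that collinear flanks
on either side of an in-place inversion are never fused into one block.
Both are for synthetic, low-error data; neither models gaps or mapping
quality.

## Problem sizes and determinism

The shipped tests and the acceptance script run at desk scale by
choice: 10–50 kb genomes (500 kb for length-distribution checks),
20,000 informative pairs per locus for orientation recovery, 500
long reads for hotspot recovery, 200,000 reads per VMR point. These
sizes put Monte-Carlo noise well inside the asserted tolerances while
keeping a full run in minutes. All stochastic tests fix their seeds;
the acceptance script derives every sub-seed from its `--seed`
argument.

## Known limitations

- Imperfect (mismatched) repeat arms are not searched; arms must be
  perfect complements.
- Shufflon-type reshuffling is detected only as displacement/hotspot
  signal, not resolved structurally.
- Orientation calls are per-locus marginals; multi-locus phasing within
  single cells is out of scope.
- The hotspot threshold models a uniform background; a locally elevated
  background (e.g. repeat-rich regions) would need the configurable
  threshold or external re-thresholding of the emitted histogram.
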