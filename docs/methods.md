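# Methods

This note documents the models, rules and numerical choices behind
`tetracomb`: what each stage assumes, which parameters matter, and what the
built-in simulator does and does not emulate.

## Genotyping model

Each spore of a tetrad from a hybrid cross (parent A x parent B, e.g. an
S288c-derived strain crossed to YJM789) is sequenced and its reads aligned
against *both* parental reference genomes; the aligner's output is reduced
to per-marker pileups split into an A pool and a B pool by the genome each
read aligned to. Because alignment tolerates mismatches, a pool can contain
reads whose base at the marker matches the other parent, or neither.

For a marker in one pool, the **cumulative quality score** of candidate
genotype *g* is

    score(g) = sum of base qualities of reads showing g's allele
             - sum of base qualities of all other reads at the marker.

Scores are plain sums of the base qualities as given (no Phred-probability
transformation); this is deliberate — the decision statistic is defined
directly on quality scores. Reads in the "other" class (neither parental
allele) depress both parental scores but are never callable themselves,
since only the two expected alleles are possible genotypes at a known
marker.

A pool's **provisional call** is the highest-scoring parental genotype iff
its score *strictly* exceeds the user-chosen threshold *T*; if no genotype
passes, or more than one does, the pool reports "neither". With two-class
SNP pileups a tie above threshold is impossible under the difference
formula, but the rule matters for indels and mixed pileups.

The two pools are **reconciled** to a final call:

* agreeing calls win; conflicting calls discard the marker;
* a call supported by only one pool is accepted only when the called parent
  matches the pool's own genome (reads carrying a parent-A allele align
  preferentially to the parent-A reference, so an A-pool-only call of B is
  evidence of misalignment, not genotype);
* indels must additionally win by a factor of 2: the winning pool's score
  for the called allele must be at least twice the same allele's score in
  the other pool. An indel is an insertion in one reference and a deletion
  in the other, so a genuine indel shows strongly asymmetric alignment;
* telomere-proximal SNPs have known coordinates only in the parent-A
  reference and are decided from the A pool alone.

Indel read scoring: an insertion-supporting read contributes the quality of
the insertion's reference base — the center base for odd insertion lengths,
the right-most of the two center bases for even lengths; a
deletion-supporting read contributes the mean of the two base qualities
bordering the deleted region. Reads whose marker-overlapping bases fall
within 3 bases of either read end are excluded from indel scoring (the
edge-exclusion default), because an aligner tolerating two mismatches can
place an indel-free read across an indel when too few bases hang over one
side. SNP observations at read ends are retained; the exclusion is scoped
to indels.

Markers genotyped in all four spores form the seg file; any marker missing
a call in one spore is dropped, since a conversion event cannot be scored
unambiguously with a spore missing.

**Threshold selection.** The threshold ladder is 20, 50, 80, 100, 120,
150, 200, 250, 300, 400, 500. The recommended threshold maximizes the mean
fraction of correctly genotyped markers in the chimeric-chromosome
simulation (below) subject to a mean of at most 3 incorrectly genotyped
markers, with the 20 and 50 rungs excluded because one or two reads suffice
to reach them. Ties go to the smaller threshold (more markers callable).

**Marker-list validation.** Sequencing each haploid parent separately and
piling its reads on the candidate marker list, a marker is removed as
unreliable if, in any pool of either parental dataset, the cumulative score
of wrong-parent reads reaches half the correct-parent score. Markers with
no correct-parent reads anywhere are removed with a distinct
"unresolvable" code. The filter is idempotent.

## Event detection and classification

Markers segregating 2:2 define chromatid phase. A **crossover** is a
reciprocal genotype switch between adjacent 2:2 markers; because 2:2 holds
on both flanks, either two chromatids switch (a single CO) or all four (a
double CO). Non-2:2 markers (3:1, 1:3, 4:0, 0:4) mark **conversion
tracts**.

Connected tracts — non-2:2 markers strictly between a CO's flanking
markers — type the CO: none gives Type 0; deviation only as an offset
between the two crossing chromatids' switch points gives Type 1 (the tract
is GC Type 1); deviation only on a non-crossing chromatid gives Type 2
(GC Type 6); a 4:0 tract or deviation on both kinds of chromatid gives
Type 3; anything discontinuous or otherwise complex gives Type 4. Doubles
are Types 5 (plain), 6 (with internal GC) and 7 (complex). Within a CO
interval, runs of interior markers sharing a deviation signature become one
tract each; a run's GC label is 1 if its chromatids include a crossing
chromatid and 6 otherwise (this covers the rare 4:0 run inside a Type 3
CO, which by construction never appears in the independent GC Type 2
class).

**Merging.** Single COs are chained into clusters wherever adjacent CO
positions are strictly within the merge range (default 5 kb — in wild-type
data, inter-event distances below 5 kb form a distinct cluster attributable
to single initiation events). A cluster of two COs sharing both chromatids
becomes one GC Type 5 tract (double NCO); sharing exactly one chromatid it
becomes one CO Type 8 whose crossing chromatids are the two involved once,
with a conversion on the chromatid shared by both COs; four distinct
chromatids are kept as two COs and flagged. Three or more COs in mutual
proximity are never merged automatically — a manual-inspection flag is
raised. Double COs do not participate. With merge range 0 every reciprocal
switch stays an independent CO. Markers between a merged pair's switch
points segregate 2:2 with swapped phase; such tracts carry segregation
class "2:2" in the output.

**Detached tracts.** Remaining non-2:2 markers are grouped into maximal
runs of adjacent markers sharing segregation class and deviant chromatid
set (read against the nearest flanking 2:2 marker); a lone marker is its
own tract. Tracts touching a chromosome's first or last genotyped marker
additionally get GC Type 3 or 4. A detached tract strictly within the
association range (default 5 kb) of its nearest CO becomes Type 7 on an
involved chromatid, Type 6 otherwise; that CO's directly connected Type 1
tract is then additionally labeled Type 8 (Type 6 partner) or Type 9
(Type 7 partner). Type 1 tracts with no partner get Type 10. Remaining
3:1/1:3 tracts are independent NCOs (Type 0); remaining 4:0 tracts are
Type 2. "NCO count" in summaries means GC Types 0 + 5 + 6.

**Positions and lengths.** All positions are marker midpoints kept at
half-integer precision (no rounding, so length arithmetic never drifts by
1 bp). A simple CO sits at the midpoint of its flanking markers; a CO with
a tract on crossing chromatids sits at the midpoint of the two
per-chromatid switch midpoints. Tract boundaries are the midpoints between
the last converted and first unconverted marker on each side; the length
estimate is their difference, the minimum uses the innermost (converted)
markers — zero for a single-marker tract, whose innermost boundaries
coincide — and the maximum the outermost (flanking) markers. A tract at a
chromosome end uses the terminal marker on the open side and is flagged
open-ended. The distance from a detached tract to a CO is measured from
the nearer estimated tract boundary to the CO position; ties between
equidistant COs go to the leftmost. For a double CO the chromatid pairing
is unidentifiable from segregation data: each exchange joins one chromatid
of each parental genotype, leaving exactly two reciprocal pairings, and
one is chosen uniformly at random (seeded).

Ambiguities resolved as package policy: GC Type 6 is the tract on a
chromatid *not* involved in the nearby CO and Type 7 on an involved one
(fixed by the worked example of a Type 2 CO with its conversion on an
uninvolved chromatid); doubles are excluded from close-event merging;
category boundaries among CO Types 2/3/8 follow the 4:0-content rule only
and are not claimed to be mechanistically distinct.

## Recombination-regulation statistics

* **CO interference**: adjacent same-chromosome inter-CO distances, pooled
  across chromosomes and tetrads, fitted by maximum likelihood to a gamma
  distribution (shape solved from the digamma equation
  `log k − psi(k) = log(mean) − mean(log)` by bracketed root-finding;
  scale = mean/shape). Distances are fitted in kb so the scale parameter
  is reported in kb. Shape 1 is no interference; larger shapes mean
  stronger interference. A few hundred distances give usable estimates; a
  warning is issued below 30. Degenerate zero-variance input caps the
  shape at 1e6 with a warning. No censoring correction is applied for
  chromosome-end intervals — a known limitation shared with standard
  practice; on simulated data it biases the fitted scale a few percent
  low.
* **Chromatid interference**: adjacent CO pairs are classed by the number
  of distinct chromatids involved (2/3/4); independence predicts 1:2:1.
  The Pearson chi-square against 1:2:1 has df 2, whose survival function
  is the closed form `exp(-x/2)`; no Yates correction is applied (the
  plain statistic reproduces the published worked examples at printed
  precision). Distance-stratified pools (all pairs, closer than a cutoff,
  at least the cutoff apart) are supported. Ratios are printed normalized
  to the 2-chromatid count.
* **CO homeostasis**: Pearson correlation between per-tetrad CO and NCO
  totals (at least 3 tetrads; zero variance yields NaN with a warning).
* **Regional suppression**: per-CO distance to the centromere and to the
  nearest telomere, from an annotation table of chromosome lengths and
  centromere positions.

## The simulator

`simulate_tetrad` encodes the study conditions as defaults:

| parameter | default | rationale |
|---|---|---|
| genome | 16 yeast chromosomes, ~12.07 Mb | standard assembly lengths and centromeres |
| marker spacing | lognormal, median 56 bp, log-sd 1.521 | matches the observed median spacing and a ~67,000-marker map (mean ~178 bp) |
| CO placement | gamma renewal, shape 1.96, scale 61.7 kb | wild-type interference parameters; ~100 COs/tetrad |
| chromatid choice | independent, one strand of each parent | no chromatid interference: 1:2:1 adjacent-pair ratio |
| connected-tract fraction | 0.65 | ~65% of COs carry a simple connected conversion |
| tract length | lognormal, mean 2.3 kb, sd 1.5 kb | observed conversion-tract lengths; family is a modeling choice |
| NCO rate | 46 per tetrad (+1 independent 4:0 tract) | observed detached-conversion counts |

The renewal process starts from a long burn-in upstream of each chromosome
so pooled inter-CO distances follow the target gamma (a stationary start,
matching the fitting model). Marker maps are drawn once per batch, since
markers are a property of the cross rather than of a meiosis.

With `min_event_separation_bp` set, events whose true intervals would come
closer than the separation are thinned or re-drawn, and the ground truth
additionally demotes events the *grid* cannot resolve cleanly: events with
no intervening marker between their intervals (which fuse into a single CO
interval) and tracts whose midpoint-estimated boundaries reach within the
separation of a neighboring CO's estimated position (which are
legitimately relabeled Type 6/7). On such well-separated simulations the
classifier recovers 100% of detectable events with correct types; about
3–5% of placed events are demoted as grid-unresolvable at a 6 kb
separation.

The read simulator draws per-marker depth as Poisson(coverage), places the
marker at a uniform random cycle of a 36-base read, substitutes the base
with a per-cycle error probability growing from 0.2% to 2% across the read
(one third of errors hit the other parent's allele, two thirds an
unexpected base), assigns the cycle's quality (declining from ~38 to ~18),
and mis-assigns 10% of reads to the wrong genome pool to emulate ambiguous
alignment. The packaged profile is representative of late-cycle error
growth on short-read instruments, not a reproduction of any specific run.
The threshold-selection experiment genotypes a ~700 kb chimeric chromosome
alternating parental blocks every 140 kb (five crossovers), six replicates
per coverage level, mimicking a single spore.

What the simulator does **not** emulate: sequence-level indel realism
(indel observations are generated at the observation layer, with border
qualities, not by re-aligning reads), PCR duplicates, GC-content coverage
bias, repetitive-region misalignment hot-spots, and heteroduplex/PMS
within the main tetrad generator (PMS tests inject mother/daughter
differences directly). Passing recovery tests therefore demonstrate the
correctness of the classification logic on clean segregation data, not
robustness to every artifact of real libraries.

## Numerical and degenerate-input policy

* Positions: 1-based coordinates; distances in bp (kb only where stated).
* Genotype code 0 is the first-named parent, 1 the second; the mapping is
  metadata, not hard-coded strain names. Chromosomes are integers 1–16;
  roman-numeral aliases are accepted on read and normalized on write.
* Seg dialects: both the `spaceholder`+LF and empty-column+CRLF forms are
  read; writing emits the former, byte-stable under round-trip.
* Count files store per-(marker, pool, class) aggregates — counts and
  quality sums — which are sufficient statistics for every scoring rule;
  a verbose per-read mode exists for observation streams.
* Unknown barcodes in demultiplexing are discarded, not errors (real lanes
  contain spike-in and foreign reads); read counts are conserved.
* Empty pileups score zero everywhere and yield "neither".
* A deletion observation with a single border base is dropped with a
  warning.
* All random choices (double-CO pairing, simulation) run off seeded
  numpy generators; identical seeds give identical outputs.

## Problem sizes used in the shipped checks

The shipped test suite and `scripts/acceptance.py` run entirely on
simulated data at sizes chosen to make every statistical assertion sharp
at interactive cost: 20 tetrads for event recovery, 60 tetrads (~5,000
adjacent CO pairs) for chromatid-interference calibration, 50–60 tetrads
for merge-range behavior, 2,000 draws for gamma parameter recovery, and
six replicates at 25x coverage (~3,900 SNP markers on the 700 kb chimera)
for genotyping accuracy. The whole acceptance script completes in well
under a minute on one core.
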