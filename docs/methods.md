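# Methods

This note documents the models and procedures implemented in `xsilence`,
the parameter defaults and the reasoning behind them, and what the
synthetic-data generator does and does not emulate.

## Coordinates and orientation

All internal coordinates are 0-based half-open intervals; conversion to the
1-based closed convention happens only when reading or writing GFF3
(delegated to pyranges). Profiles, TSS distances and operator-insertion
positions share one oriented axis: the base of maximal silencer occupancy
(the nucleation site) is position 0, each promoter is mirrored if necessary
so the silenced gene's start codon lies to the right, and positions toward
the gene start (downstream of the nucleation site) are positive. Under this
convention a nucleation site 27 bp downstream of a TSS places that TSS at
−27. A single axis avoids sign errors between profile figures, TSS
histograms and construct design.

## AT-stretch scanner

A stretch is an interval that (i) starts and ends on A or T, (ii) contains
at most *k* non-A/T residues (G/C interruptions; N counts as an
interruption and can never terminate a stretch — the conservative
treatment for ambiguous bases), and (iii) has length ≥ `min_length`. Only
*maximal* stretches are reported: none is properly contained in another
interval satisfying (i)–(ii). With *k* > 0, distinct maximal stretches may
overlap; all are reported and each is counted once downstream. The
implementation finds, for each A/T start, the furthest A/T-ending extension
within budget via prefix sums, and keeps it iff no left extension to the
nearest A/T position fits the remaining budget; this is provably equivalent
to exhaustive substring enumeration reduced to maximal intervals, and the
test suite checks that equivalence against an independent brute-force
oracle.

Defaults: `max_interruptions = 5`, `min_length = 10`, with a 14–30 bp
medium-length bin available for binning — the regime where the A/T-step
trend is most visible. A/T steps are adjacent pairs reading A→T or T→A;
pairs involving G/C/N contribute nothing. Scanning is strandless (every
scanner quantity is invariant under reverse complementation) and does not
wrap circular genomes.

When comparing discrete regions (e.g. low-GC islands) rather than raw
stretch lists, `representative_stretches` picks one stretch per region: the
longest overlapping one, or — with `prefer_motif` — the longest motif-tagged
one, since the motif marks the candidate nucleation site within the region.

## Occupancy and GC profiles

Profiles are plain rolling means, window 50 bp and step 10 bp by default,
emitting only full windows (no shrinking edge windows). For GC profiles, N
is excluded from both numerator and denominator of each window. Occupancy
maxima are called on the rolling-mean coverage (`locate_max_smoothed`,
reported as the midpoint of the best window): the raw per-base argmax is
noise-sensitive on broad, flat-topped peaks, while the smoothed call is the
same quantity the profile figures display. Ties break leftmost for
determinism. Peak intervals are taken as given (from a deposited peak set
or simulation truth); peak calling is out of scope. Peak width classes:
class 1 = 500–850 bp inclusive (the boundary 850 bp is assigned to
class 1), class 2 > 850 bp, narrower peaks unclassified.

TSS are assigned to a gene when they lie within 500 bp upstream of its
start codon on the same strand (the start-codon position included; a TSS
matching several genes goes to the nearest). Multiple TSS per promoter are
dense-ranked 1..n by descending enrichment score; scores are consumed as
opaque reals. Overlay means drop grid points covered by fewer than a
configurable minimum number of profiles (default 1).

## Motif scanning

The motif is an input. With a PWM (rows = positions, columns = A, C, G, T,
each row summing to 1), every window on both strands is scored by log-odds
against an i.i.d. background at the stated GC fraction (default: the
genome's own GC); windows containing N score −∞. The reporting threshold is
a fraction of the maximal attainable score, default 0.8 — a deterministic,
documented alternative to p-value calibration, which is out of scope. With
only an IUPAC consensus, matching is exact and the threshold is ignored.
A stretch is motif-positive only when a hit lies *entirely inside* it: the
motif is an internal feature of the stretch, not a neighbor. The default
10-bp consensus `WWTAWTAWWW` is an AT-rich, A/T-step-bearing approximation
transcribed from the published logo; the true matrix is not public, so the
consensus is explicitly approximate and configurable.

## Promoter design grammar

Constructs carry a protected core (the −10/−35 boxes and TSS; 50 bp for
compact designs, 70–100 bp where the motif and nucleation site must also be
covered), the nucleation-site index, and an ordered edit log.

* **A-T/G-C swap** (outside the core): preserves length, the per-position
  GC indicator — hence the rolling GC profile exactly — and every
  AT-stretch interval and interruption count. A/T-step counts are preserved
  everywhere except in a stretch spanning a core junction, where the
  junction dinucleotide changes identity because the core stays native
  while the flank swaps; each junction can shift the count by at most 1.
  This is inherent to any core-preserving swap, and the tests assert
  exactly this statement.
* **Flank randomization**: i.i.d. per base, G/C with probability
  `target_gc` split evenly G vs C and A vs T, deterministic under its seed.
  An i.i.d. draw (rather than shuffling) is the simplest distribution
  consistent with "randomized"; the choice is recorded in the edit log.
* **Operator insertion**: position 0 splices the site immediately 5′ of the
  maximal-occupancy base; negative = upstream, positive = downstream;
  reverse orientation inserts the reverse complement. Core and nucleation
  index are re-mapped; insertion inside the core is permitted but flagged.
* **5′ truncation**: removes leading bases, re-mapping indices; truncating
  into the core or past the nucleation site is an error.

`verify_design` re-derives the original core through the edit log, checks
core integrity and GC-profile preservation (expected to fail for randomized
or length-changing designs, and reported as such), and replays the edit log
from the base sequence, which must reproduce the final sequence
byte-for-byte.

## Reporter statistics

Promoter activity is the specific reporter output: fluorescence divided by
backscatter at the timepoint nearest 5 h. Fold change is
mean(−effector)/mean(+effector). Calls use Welch's two-sided
unequal-variance t-test — the safer choice for triplicate fluorescence
data with no variance-equality guarantee; p ≥ α (default 0.05) →
unchanged, otherwise counter-silenced when the −effector mean is larger
(the factor activates by displacing the silencer), repressed otherwise.
Zero-variance equal-mean input is called unchanged. No multiple-testing
correction is applied by default (calls are per construct); a
Benjamini–Hochberg option exists for screens. Inputs are assumed
blank-corrected.

## Synthetic data

Defaults, chosen once to mirror the study system's geometry:

| parameter | default | rationale |
|---|---|---|
| genome length | 300 kb | holds 50 islands at the required spacing |
| background GC | 0.54 | the emulated chromosome's GC content |
| islands | 50, 200–600 bp, GC 0.35 | low-GC horizontally acquired islands |
| GC dip shape | cosine, minimum at center | smooth "distinct drop"; no functional form is prescribed, cosine is the simplest smooth interpolant |
| motif plant probability | 0.5 | balanced classes for enrichment estimation |
| peak amplitude / baseline | 10 / 1 a.u. | ~10:1 peak-to-background, typical of normalized occupancy tracks |
| peak width | uniform 500–1500 bp | spans both width classes |
| coverage noise sd | 0.1 a.u. (1% of amplitude) | normalized, read-averaged tracks are smooth; per-base noise well below peak curvature |
| TSS offset sd | 15 bp | TSS cluster tightly around the nucleation site |
| binding rule | p = min(0.95, L/600), ×3 with motif | bound fraction rising with length, boosted by the motif |
| reporter noise | 10% multiplicative log-normal, triplicates | typical plate-reader CV at biological-triplicate scale |

Islands are separated by at least twice the maximal peak width so every
peak maps to exactly one island/promoter. Coverage is a Gaussian bump
(sd = width/6) centered on each bound island's GC minimum over a noisy
baseline, clipped at 0. Backscatter follows a fixed logistic growth curve
sampled every 15 min; fluorescence is proportional to backscatter with a
condition-dependent level and mean-corrected log-normal noise. All
randomness flows from one seed through `SeedSequence.spawn` into four
independent streams (genome, coverage, TSS, reporter), making every
emitted file byte-reproducible.

What the generator does **not** emulate: real genomic sequence composition
(codon structure, repeats, operons), read-level sequencing noise,
silencer spreading mechanics (peaks are symmetric Gaussians), correlated
plate effects, or growth differences between strains. Passing recovery
tests therefore demonstrates correctness of the computations under the
stated statistical assumptions, not performance on real data.

## Problem sizes used by the acceptance script

The script runs the default 300-kb / 50-island conditions for the profile
metrics, a 1-Mb / 250-island genome with a planted 3-fold motif-binding
boost for enrichment recovery (≥ 200 representative stretches), and 1000
null plus 500 effect trials for classifier calibration — sizes at which
the Monte-Carlo error of each reported quantity is small relative to the
effect being measured.

## Known limitations

* The default consensus is an approximation; genome-wide hit counts with
  it are not comparable to counts obtained with the unpublished matrix.
* Degenerate consensus scanning in AT-rich regions produces incidental
  hits; enrichment analyses should treat motif tagging as noisy (the
  recovery test tolerates this contamination).
* The scanner reports all maximal stretches at a fixed interruption
  budget; per-budget censuses require separate scans at each *k*.
* Reporter analysis assumes pre-corrected, positive backscatter and does
  not model growth-curve differences between conditions.
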