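# Methods

## The generative model

`satmir.synth` emulates the dual-phase growth of a SINE/microsatellite-
derived tandem miRNA cluster.

**The elementary mouse unit** (296 nt) is assembled from designed segments:
a 75 nt 3' fragment of a 140 nt random "SINE-like" reference element, a
30 nt spacer, a 41 nt (AC)n arm, a 5 nt loop (`AACAA`, chosen so no loop
base can pair an arm base), the 41 nt (GT)n reverse-complementary arm, and a
104 nt tail. The two microsatellite arms are exact reverse complements, so
the transcribed unit folds into a perfect 41-bp stem. The SINE fragment and
the random segments are seeded draws, not database imports: the pipeline
must never require an external repeat library, and the full-length reference
element doubles as the "library entry" used for segment annotation.

**The rat unit** (197 nt) derives from the mouse master by a 5'-heavy
truncation (the unit loses the SINE fragment and most of the spacer,
leaving a 15 nt 5' flank), two 2-nt deletions inside the right hairpin arm,
and a calibrated set of point substitutions: a six-base "dead zone" of A's
at the loop-proximal end of the right arm, and three short compensatory
anchor words at staggered pairing registers (+6, +8, +10). The calibration
exists because a pure dinucleotide stem absorbs deletions silently by
slippage (G:U wobble defeats single-base anchors); the anchor words pin the
local register so the deletions must bulge out. The folded rat unit then
shows an enlarged terminal loop, a 4-nt arm-length imbalance, two asymmetric
bulges, a pairing register shifted 10 nt toward the 3' end at the mid-arm
probe position, and a hairpin-region entropy an order of magnitude above the
mouse unit's. The design was frozen after a one-off search; it is data, not
a tuning knob.

**Phase 1 (flanks):** 31 left-flank and 48 right-flank copies diverge
independently from the master at 0.13 substitutions/site and are separated
by 10-25 nt random spacers.

**Phase 2 (center):** ten "position ancestors" diverge from the master at
0.08 substitutions/site; the resulting block is duplicated 13 times
head-to-tail, each copy adding 0.025 substitutions/site. Position-specific
mutations are therefore shared by the 13 copies of a position and act as
sub-cluster synapomorphies; the model requires between-block divergence to
be smaller than within-block divergence, and the configuration rejects the
opposite ordering. Indels are Poisson-like (0.0015 events/site, geometric
sizes p=0.5 capped at 10 nt).

**miRNA units:** five designated within-block positions (x 13 blocks = 65
units) carry processable hairpins. Their hairpin regions are protected from
random substitutions and indels, but each position receives six seeded
*compensatory* stem substitutions (a base pair swapped for another
Watson-Crick pair, offsets drawn disjointly across positions) — the classic
signature of conserved hairpin evolution. This keeps every one of the 65
hairpins a perfect 41-bp stem while making the five positions
distinguishable in sequence; without it the identical hairpins pull the
miRNA-position clades together in the distance tree.

**Degradation:** (i) one within-block position has decayed in all 13 blocks
to a 70 nt heavily mutated remnant — sequence loss plus mutation beyond
recognition — which leaves a reproducible spacing anomaly at a fixed cyclic
phase, the footprint from which the inference reconstructs the tenth
position; (ii) three central copies (in three different non-miRNA positions)
are corrupted at 0.55 substitutions/site, far below any detection threshold;
(iii) every copy that is not a designated miRNA unit has a seeded 16-22 nt
tract of its hairpin overwritten with `N` — hairpin decay represented the
way masked/unalignable repeat DNA conventionally is. The `N` tract scores as
mismatches in alignments, is excluded from pairwise-deletion distances (so
decay does not distort the tree), and marks the copy as unfoldable for the
structure classifier. Hairpin regions are indel-protected in central and
rat copies so arm lengths stay uniform; decay, not indels, is the modelled
destruction channel.

Recognizable copies: 31 + 48 + (13x10 - 13 - 3) = 193. The rat-style
cluster is a single-phase array of 236 copies (220 rat-like, 16 ancestral
mouse-like, 0-6 nt spacers); exactly one mouse-like copy keeps an intact
hairpin — the rat's single miRNA gene. A full-length copy of the SINE-like
element marks the 3' border of both clusters.

**What the generator does not emulate:** realistic genomic base
composition, insertion-age structure, CpG effects, or any annotation noise
beyond the processes above. Passing recovery tests therefore demonstrates
that the pipeline inverts *this* generative model at realistic divergences,
not that it would handle every artifact of real genome assemblies.

## The analysis pipeline

1. **Blind seed consensus.** FFT autocorrelation of the one-hot sequence
   estimates the elementary period (searched in 150-500 nt); three
   consecutive period-length windows from the array center are aligned and
   majority-called.
2. **Iterative refinement.** Each cycle scans with the current consensus,
   re-aligns the hit sequences with 50 nt of context, majority-calls, and
   trims. The length anchor: a tandem unit is one array period long, with
   the period taken as the median near-modal start-to-start spacing (5-nt
   bins, +-1 bin) and an inter-copy spacer subtracted only when it is large
   (> 8 nt) and the gap sequences are mutually dissimilar (similar gaps mean
   the gaps are unit material the current consensus does not yet cover).
   The unit window is the contiguous stretch of that length maximizing
   total column support; end columns below 0.75 support (smeared spacer
   columns) are stripped. Convergence: length change <= 2 nt between
   consecutive refined consensi.
3. **Phase anchoring.** A tandem consensus is defined only up to rotation;
   when a reference element is supplied the consensus is rotated so the
   SINE-fragment match starts at position 0 (the conventional unit
   boundary), keeping fragment and hairpin contiguous.
4. **Scanning.** Exact Smith-Waterman (match +1, mismatch -1, gap open -2,
   extend -1; a gap of length k costs open + k*ext), both strands. A
   linear-memory score sweep finds candidate end points; candidates are
   re-aligned with traceback in local windows and accepted greedily by
   descending score subject to non-overlap; remaining gaps are re-scanned
   until nothing qualifying is left. Thresholds: identity >= 0.65 over
   aligned columns, length >= half the consensus. On small inputs the
   procedure reduces to full DP.
5. **Phylogeny.** Copies are aligned progressively (k-mer guide tree +
   profile alignment; gap open 10, extend 0.2 after the classic DNA
   defaults, match 1.9); distances use pairwise deletion under p, K2P, or a
   Tamura-Nei-form model with alignment-wide pooled base frequencies (the
   composite-likelihood surrogate); neighbor joining with smallest-pair tie
   breaking and negative-branch truncation; 100 bootstrap replicates
   (scaled down from the conventional 1000 — supports for the clades of
   interest are near 100 either way); branches below 50% support collapsed.
   Sub-clusters are the maximal supported clades of size >= 10 of the
   midpoint-rooted collapsed tree whose complements are also >= 10 (a
   "clade" of nearly all leaves merely reflects outliers on the other side
   of the root); all other copies are reported as unclustered.
6. **Higher-order unit.** The label cycle tiling the central labelled run
   is detected, tolerating missing copies; a consistent extra gap at a
   fixed cyclic phase (>= 15% of a unit) adds the decayed positions;
   block count and span come from the cycle walk.
7. **Structure verdicts.** Each detected copy's hairpin locus (the
   consensus hairpin region mapped through the copy's alignment) is folded
   with 30 nt of genomic context; a unit is pre-miRNA-like when the stem
   has >= 30 bp, at most one asymmetric bulge, mean hairpin entropy at most
   half the flank mean, and >= 20 nt of 5' flanking sequence. Copies with a
   decayed (`N`) hairpin fail outright. The per-species entropy-contrast
   statistic is the hairpin/flank entropy ratio of the folded consensus
   unit.

## The energy model

Folding uses a deliberately simplified nearest-neighbour model (full Turner
tables are out of scope; the claims made here — morphology and relative
entropy contrasts — are robust to the simplification):

* pairs AU/UA, CG/GC, GU/UG; minimum loop 3 nt
* hairpin loop of size l: `4.8 + 1.08 ln(l/3)` kcal/mol
* stack: `-0.9 - (w_outer + w_inner)/2` with `w` = 2.0 (CG/GC), 1.3
  (AU/UA), 0.8 (GU/UG)
* interior loop/bulge, sides l1+l2 <= 30: `1.6 + 0.45(l1+l2) + 0.65|l1-l2|`;
  larger interior loops are disallowed (the standard enumeration cap)
* multiloop: `3.4 + 0.4` per branch (closing pair included), unpaired free
* exterior bases free

Loop energies are temperature-independent structural constants; temperature
(default 310.15 K) enters only through the Boltzmann factor, which makes
mean entropy provably non-decreasing in temperature. The partition function
runs in a rescaled linear domain (a factor 1/kappa per nucleotide, kappa
set from the MFE) so Z never overflows; log Z is recovered exactly. The MFE
and partition recursions and the exhaustive-enumeration oracle in the test
suite implement the same decomposition independently and agree to 1e-8 on
hundreds of short sequences. Entropies are reported in nats. Centroid =
all pairs with P > 0.5 (two such pairs can never cross, so the result is a
valid structure). MFE tracebacks break ties deterministically toward
5'-most pairings. DNA input is transcribed internally; coordinates are
reported on the input.

## Numerical and design choices

* Identity = identical columns / aligned columns (gap columns count in the
  denominator); stated because identity definitions vary.
* Greedy best-score-first non-overlap resolution, ties to the leftmost
  start; full DP is the reference the windowed scanner must match.
* Substitution kernel: uniform over the three alternative bases (a
  sub_rate-1 mutation never resamples the original base); indel sizes
  geometric (p=0.5), capped at 10 nt.
* The progressive aligner exposes only match/mismatch/gap parameters; the
  historical alignment tool's divergence-delay and matrix options are
  treated as provenance, not emulated — acceptance is via blind recovery,
  not column-identity to any specific aligner.
* End-trimming thresholds (0.6 support, 0.5 occupancy, 0.75 end support)
  and the scanner thresholds (0.65 identity, half-length) are this
  package's own defaults and are recorded in run provenance.
* Microsatellite calls use purity-scored extension (match +1, mismatch -2,
  stop 5 below the running maximum), motifs reported as the
  lexicographically minimal rotation of the primitive root.
* Bootstrap supports are mapped onto the full-alignment NJ tree (no
  majority-rule consensus tree); midpoint rooting for clade extraction.
* Saturated K2P/TN distances raise an error carrying the p-distance
  fallback; the matrix kernel falls back silently.
* Desk-scale sizes: the default clusters are ~60 kb / ~48 kb; a full blind
  run (scan + refinement + 100-replicate bootstrap + per-copy folding)
  takes ~10-15 s per species on one CPU after JIT compilation.

## Known limitations

* The simplified energy model reproduces morphology and entropy contrasts,
  not absolute folding free energies; no pseudoknots, no suboptimal
  ensembles beyond the centroid, no Drosha/Dicer site prediction.
* NJ tie-breaking depends on label order when distances tie exactly;
  bootstrap supports are permutation-invariant only up to floating-point
  summation order (a few percent on knife-edge splits).
* The refinement cannot recover unit sequence that is absent from every
  scan window (it extends boundaries, not interior deletions of the seed).
* `detect_period` needs >= 6 hits and a lag profile with a clear minimum to
  call a higher-order period; irregular arrays correctly return none.
* The pre-miRNA classifier is calibrated for hairpins in the designed size
  range (~80-90 nt region); it is a recovery instrument for this model,
  not a general miRNA gene finder.
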