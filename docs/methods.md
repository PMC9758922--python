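# Methods

## Scope and model

`npgreat` assembles one subtelomere per invocation. Its model of the region
is a linear architecture, centromere → telomere: unique (1-copy) DNA, a
segmental-duplication (SD) region of large near-identical blocks possibly
containing VNTR arrays, and the terminal (TTAGGG)n tract. Two inputs carry
complementary information: high-accuracy linked-read contigs (correct at the
base level, unreliable across tandem repeats) and ultralong nanopore reads
(noisy at the base level, structurally reliable across the whole region).
Every design decision below follows from that division of trust: bases come
from contigs wherever contigs exist; structure, repeat lengths and gap
sequence come from reads.

Internally everything is 0-based, half-open, and the telomere tract sits at
the *right* end of the layout for both arms; p-arm output is
reverse-complemented only at write time. Soft masking travels as explicit
intervals on each record, never as letter case, so comparisons are
case-insensitive by construction.

## Alignment engine

No published scoring exists for this method's "Segment Pair" score, so the
package defines one: match +1, mismatch −1, gap −2 to open plus −1 per base.
All decision thresholds are identity percentages, which are robust to the
particular scoring; the score only breaks ties (orientation conflicts).

Two engines implement one contract:

* **exact** — affine-gap Smith–Waterman (numba-compiled, full traceback),
  used whenever the DP table fits 16 M cells. It is the canonical
  definition of the local score and is validated against an independent
  quadratic-time oracle in the tests.
* **seeded** — for ultralong inputs: exact 13-mer anchors (k-mers occurring
  more than 50 times in the target are skipped; with masking on, no anchor
  is taken from a masked target span), clustered by diagonal (split at
  jumps > 500), chained by longest-increasing-subsequence, split into
  segments wherever the implied indel exceeds 100 bp, and each segment
  re-aligned globally with edlib. Each segment is then trimmed to its
  maximal-scoring sub-path (Kadane over cigar runs, optimal because runs
  score uniformly) — without this, a chance k-mer collision near a
  cluster's diagonal band can drag a segment end into non-homologous
  sequence.

Segments deliberately break at indels > 100 bp so correction can read the
inter-segment gaps; colinear chaining (gap ≤ 2,000 bp, overlap ≤ 100 bp
tolerated) reassembles them into one placement. The repeat masker is a
self-contained k-mer over-representation masker (k = 15, > 8 occurrences
within the read, both strands): tandem arrays and telomere tracts — the
repeats that cause ambiguous seeding — are caught, while SD blocks present
in ~3 copies are deliberately left unmasked so contigs can still place.

## Screening and scaffolding

The telomere screen counts non-overlapping 24-base perfect-repeat matches
within the GATC-delimited read end; a pure tract of ≥ 48 bases passes, as it
must for the 500–5,000 bp terminal tracts ultralong reads carry. Counting
two disjoint *runs* instead would reject exactly those reads. Degenerate
repeats (a sequencing error inside a 24-mer) do not count toward
occurrences but may lie between counted ones.

Probe acceptance (anchor screen) defaults to ≥ 85% identity over ≥ 50% of
the probe; read-overlap edges require ≥ 80% identity over ≥ 5,000 bp. Both
are exposed in the configuration; neither is sharply critical because the
synthetic and real error regimes sit far from the thresholds (5%-error reads
align to probes at ~95% and to each other at ~90%).

Orientation propagates from the telomeric anchors over the overlap graph as
a maximum-score spanning forest: a read joins the oriented set through its
best overlap, which resolves conflicting paths in favour of the stronger
evidence and makes the layout independent of input order. Offsets follow the
same tree from the longest telomeric read; contained reads are dropped.

## Correction

Discrepancy = |read gap − contig gap| **strictly greater** than 100 bp
(a delta of exactly 100 is not an event; the boundary is tested). Border
localisation re-aligns the 1 kb contig flanks unmasked into a padded read
window; if a border fails at 75% identity the event is kept but
unclassified and no edit is applied. Classification uses two kinds of
evidence, either sufficient:

* the contig's gap sequence (the collapsed units) matches the read gap at
  ≥ 3 distinct co-optimal infix positions (edlib `HW` locations), or
* the read gap is periodic: the histogram of recurrence distances of its
  repeated 8-mers has a mode carrying at least 5% of the segment length.
  A plain "align the segment to itself shifted by p" test is *not* used:
  for any sequence that alignment costs at most 2p edits (shift in, shift
  out), so it cannot distinguish small periods from noise.

Both event kinds are repaired by the same split-and-patch: pieces remain
verbatim substrings of the input contig, the patch is a verbatim read
segment, and contig expansions (read gap shorter than contig gap) use the
same mechanism so the conservation invariant — corrected contig re-aligns to
its read span with no residual discrepancy > 100 bp — holds sign-agnostically.
Multiple events apply left-to-right on one shared coordinate frame (they are
disjoint by construction; overlapping refinements keep the earlier event).

## Assembly

Overlapping placements merge with the junction cut at the overlap midpoint
after an agreement check: the two contigs' copies of a 1 kb junction window
are compared by infix alignment (with 300 bp of slack absorbing placement
misregistration) and must disagree by ≤ 2%; on failure both contigs are kept
and joined end-to-start without blending. Gap candidates are taken from
every layout read that spans the gap plus 2 kb of each flanking contig —
requiring a read to span the *entire* flanking contigs would exclude nearly
every real read, so the flank window is what "covers both flanks" means
here. The filler is the argmax of average flanking identity, ties to longer
flank alignment, then lexicographic read id. Terminal gaps are one-sided:
the distal extension comes from a telomeric read and runs verbatim through
the tract to the read end, and its "average" identity is the single
available flank's identity. Unbridgeable internal gaps emit an N-run sized
by layout distance rather than silently dropping sequence. Provenance rows
partition the output exactly and are asserted on every run.

## Evaluation

Assembly-to-reference comparison chains seeded local alignments into the
best colinear block set per strand. Gaps in the chain are first offered to a
patch step — if both sides have comparable unaligned lengths (ratio ≤ 3) and
align globally at ≥ 80% identity, the pair becomes an aligned block. This
recovers regions that have no unique seeds at all, notably the telomere
tract, whose k-mers exceed the seed occurrence cap; without it a perfect
assembly would be reported as < 100% covered. Remaining internal gaps
> 1 kb count as misassemblies; terminal deficits reduce covered fraction
instead. Misassembly counts are defined by these colinearity rules and are
comparable, not bit-identical, to external evaluators. The weighted percent
identity is the exact weighted mean over block columns; a single block
returns its identity verbatim.

## Synthetic data

The generator's defaults are the study condition: 100 kb of 1-copy sequence,
45 kb of SD as three copies of one template at 2% divergence, one VNTR of
40 × 37 bp, and a 2,502 bp terminal tract (~150 kb total — about one third
of a real 500 kb subtelomere window, chosen so an end-to-end run takes
seconds, not hours). Reads tile the reference every ~30 kb (±2 kb jitter)
at 44–54 kb length, on random strands, with the last read pinned to the
chromosome end so its terminal tract falls in the real 500–5,000 bp range;
probes are 3 kb 1-copy slices every 25 kb, emulating a wide bait set. Read
errors follow a 40:30:30 substitution:insertion:deletion mix (a generic
long-read profile; configurable). Contigs tile the non-tract region with two
2 kb overlaps and one 2 kb gap, collapse each covered VNTR to 3 units, and
carry one planted 1.5 kb deletion; they are exact reference substrings
otherwise, matching the high accuracy of linked-read consensus.

What the simulator does **not** emulate: homopolymer-biased nanopore error
profiles, chimeric reads, heterozygosity, SD paralogy shared *between*
subtelomeres, and coverage dropout. Passing tests therefore demonstrate the
mechanics and bookkeeping of the method under controlled structure and
noise, not performance on real basecalls.

## Numerical choices and degeneracies

* All generators and pipeline stages are deterministic given (inputs, seed);
  tie-breaks are total orders (score, then coordinates, then ids).
* Alignment identity thresholds compare weighted chain identity; "aligned
  length" in the orientation conflict rule means aligned columns.
* Zero-length pieces after a split are dropped with a log line; a
  discrepancy whose refined gap inverts is left unclassified.
* Empty selections are warnings, not errors; a missing telomeric anchor is a
  hard error (exit code 2 in the CLI) because nothing can be oriented
  without it; unplaceable contigs degrade to a nanopore-only output with a
  warning.

## Limitations

Tandem-repeat collapses at a contig *terminus* produce no inter-alignment
gap and are not detected (the flanking read still supplies the sequence
through the gap-filling path). Contigs mapping to two genuinely different
loci keep only their best chain. Connector segments are single-read, not
consensus, so their identity is bounded by the read error rate; polishing
patches with linked reads would lift it but is out of scope.
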