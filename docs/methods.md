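# Methods

## The model

Proximity-ligation libraries are modelled at the level of restriction
digests: the genome is partitioned per chromosome into the intervals
between consecutive cut sites of the chosen enzyme(s), and every read
pair is interpreted through the digests its 5' ends fall into.  The
pipeline assumes palindromic enzymes that leave 5' overhangs or blunt
ends (HindIII `A^AGCTT`, DpnII `^GATC`, and user-declared enzymes of the
same class).  Cutting splits the site into `flank5 + overhang + flank3`;
re-ligation after biotin fill-in produces the junction
`flank5 + overhang + overhang + flank3` (two consecutive overhang
copies, `AAGCTAGCTT` for HindIII), while protocols without fill-in
(Capture-C) regenerate the plain recognition site.  For enzyme mixes,
every ordered pair (A, B) contributes a hybrid junction
`flank5_A + overhang_A + overhang_B + flank3_B`; all members of this set
are searched during truncation.

Coordinates are 1-based inclusive wherever a user sees them (digest
file, reports), matching SAM convention; a cut at inter-base position
`c` assigns base `c` to the left digest.  GC content excludes `N` from
numerator and denominator; an all-N digest is assigned GC 0 (arbitrary
but stable).  `N` never matches a recognition site, so padded assembly
gaps produce no phantom digests.

## Truncation

Reads are scanned 5'→3' for the leftmost occurrence of any junction.
The retained prefix ends with the first fragment's reconstructed end
(`flank5 + overhang` for fill-in, `flank5` otherwise): that sequence is
genomic at the first digest's locus, so keeping it maximizes mappable
length.  The boundary is configurable (`--cut-at-junction` retains only
the pre-junction prefix).  Truncation is idempotent: the retained
remnant is a proper prefix of the junction and cannot itself complete
one.

Reads that *end inside* a fill-in junction deserve care: bases past
`flank5 + overhang` belong to the duplicated overhang copy and are not
genomic, so such reads fail exact mapping even though no complete
junction is present.  `capqc` therefore also truncates when a proper
junction prefix longer than the retained remnant is a suffix of the
read.  At 100 bp reads and a 10 bp junction this affects roughly 3% of
chimeric pairs; the false-positive cost is negligible (a chance match of
the ≥6 bp prefix trims a few terminal bases from a genomic read without
moving its 5' end).  Plain junctions need no such handling — their
prefixes are genomic at the first digest's locus.  Pairs in which either
truncated mate falls below `min_length` (default 20 bp, the shortest
read we consider reliably mappable against a mammalian-sized genome) are
dropped whole, since an unmappable mate makes the pair unusable anyway.

## Classification

Mates are mapped independently in single-end mode and re-joined by read
name.  Pairs with an unmapped mate, or a mate that is multimapped
(secondary/supplementary records, or MAPQ < 30 by default) are counted
and excluded.  Deduplication keys on the canonically ordered pair of
(chromosome, 5' position, strand) tuples — swapping which file a mate
came from does not evade it — and keeps the first-seen pair (stable and
order-documented; qualities are not compared).

The decision tree, in order: (1) trans pairs are chimeric by
construction; (2) opposite-strand pairs on a single digest are
un-ligated (inward) or self-ligated (outward); (3) opposite-strand pairs
across digests are still un-ligated when `lu ≤ max_unligated_size` or
self-ligated when `ls ≤ max_selfligation_size` — incomplete digestion
makes these indistinguishable from short-range ligations, so the size
threshold is the only usable evidence; (4) same-strand pairs on one
digest are "strange internal" (no ligation geometry explains them),
across digests chimeric; (5) chimeric pairs are size-filtered on `lr`
into too-short / too-long / valid.  Orientation ties (equal 5'
coordinates, opposite strands) break to inward; the case is negligibly
rare and needs only a deterministic answer.

Segment sizes always run to the nearest digest boundary; uncut internal
sites from incomplete digestion shorten `lr` relative to the true
fragment and no rescue is attempted.  Dangling ends are counted — a
forward mate's 5' at its digest's start, or a reverse mate's 5' at its
digest's end (the reverse-strand convention mirrors the forward one) —
but never removed, because they may stem from incomplete ligation of
genuine products.

Default thresholds: `max_unligated_size` 1000 bp, `max_selfligation_size`
3000 bp, valid `lr` range [50, 1000] bp, `min_mapq` 30.  Only the orders
of magnitude are dictated by the chemistry (shearing selects a few
hundred bp; digests average a few kb); all are configurable and the
defaults are deliberately permissive.

"Chimeric" in reports counts all pairs reaching the size filter, i.e.
including too-short/too-long; the size-valid subset is reported
separately (`valid`, and YCP alongside `ycp_valid`), so either
convention of "yield" can be read off.  The NSI denominator is the
chimeric count, the convention under which the published reference
tables reproduce; percentages and ratios round half-up to two decimals.

## The simulator

`capqc.simulate` emulates the protocol on an i.i.d. random genome
(default: two 400 kb chromosomes, GC 0.5, HindIII fill-in — about 100
digests per chromosome at the six-cutter mean spacing of 4^6 = 4096 bp).
Fragments are assembled from digest-end segments exactly as ligation
would: valid products join the 3' end segment of one digest to the 5'
end segment of another through the junction insert; self-ligations join
the two ends of a single digest; un-ligated fragments are contiguous
digest slices, half of them anchored at a digest boundary to create
dangling ends.  Shearing sizes are uniform on [150, 500] bp (a normal
option exists), read length is 100 bp (matching the reference
experiments), and interacting digest pairs are kept ≥10 kb apart so that
no valid product can fall under an artefact threshold.  Each category
defaults to 10^4 fragments.  Reads are the fragment's two outermost
100-mers, error-free, on a random strand; truth records carry category,
source digests, junction offsets within each read and dangling flags.

The bundled toy mapper indexes genomic 20-mers and reports exact
full-read matches (both strands): unique hits as MAPQ-60 records,
multiple hits as primary+secondary records at MAPQ 0, no hit as
unmapped.  It stands in for a real aligner only where reads are exact
substrings — i.e. on simulator output.

What the simulator does *not* model: sequencing errors and SNVs (hooks
exist, default off), coverage and GC bias, capture efficiency, chimeric
reads with more than one junction, and incomplete digestion.  Passing
the end-to-end tests therefore demonstrates the correctness of the
classification logic and bookkeeping under clean mapping, not robustness
to alignment noise — that burden falls on the external aligner in real
use.  Random cross-ligation is not generated separately because its
products are sequence-identical to valid ligations; it is diagnosable
only population-wise (cis:trans ratio, singleton excess).

Expected residual imperfection: distinct fragments occasionally collide
in coordinates (boundary-anchored un-ligated fragments with equal shear
size are the common case) and deduplication removes one of them; at
4×10^4 pairs this costs ~0.3% of pairs, which is why end-to-end category
recovery is asserted at ≥99% rather than 100%.

## Determinism and numerics

All randomness flows from a single integer seed through
`numpy.random.default_rng`; FASTQ/SAM/interaction files and JSON reports
are byte-identical across reruns.  Output orderings are canonical
(digest pairs sorted by coordinates), so interaction files are invariant
under read input order.  Digest lookup is a binary search over digest
starts; the digest file stores GC with full float precision (`repr`) so
write→read round-trips exactly.

## Problem sizes

The test suite and the acceptance script run the full pipeline at
4×10^4 pairs over 2×400 kb genomes, digest-map statistics at 1 Mb, the
classifier/oracle comparison at 10^4 randomized pairs and determinism at
2×10^3 pairs — sizes chosen so the complete suite runs in well under a
minute per component while keeping all counting statistics far from
small-sample noise.
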