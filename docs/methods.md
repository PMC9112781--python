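# Methods

## Haplotype DAG

One level per biallelic heterozygous site, in position order per
chromosome; sibling node 1 carries REF, sibling 2 ALT. This assignment
is a deterministic stand-in for an arbitrary initial phase: the path
optimisation treats siblings symmetrically, so output is invariant to
it (asserted by a relabel-invariance test). Edges join adjacent levels
only, so the graph is acyclic and a block is already topologically
sorted by level; at most four edges can join a level pair.

Only biallelic heterozygous SNPs and simple INDELs (one allele of
length 1) become levels. Multiallelic, half-missing, homozygous and
complex (MNP) records are skipped and tallied. Two heterozygous records
at one position are rejected as input errors.

## Fragments

A fragment is one molecule's allele observations: a long read, or both
primary alignments sharing a query name (mates merged). Rules:

* secondary/supplementary/duplicate alignments are excluded; defaults
  `min_mapq = 20`, `min_baseq = 13` (CLI-configurable) — conventional
  filters, declared rather than inherited;
* a SNP observation needs the aligned base to equal REF or ALT; an
  INDEL observation needs the CIGAR to encode the *full* event (exact
  inserted sequence / exact deletion length) with the alignment
  continuing past it — partial overlap yields nothing;
* mates disagreeing at a site cancel that observation (conflicting
  evidence within one molecule is uninformative);
* fragments with fewer than two observations carry no phase information
  and are dropped.

A fragment is *continuous* if its observed levels form one consecutive
run, otherwise *discontinuous*: its maximal consecutive sub-runs still
count as continuous evidence, and each gap becomes a span from the last
observed node before it to the first observed node after it.

Alignments are read by a single sequential scan (no index needed), so
plain-text SAM works; the header's sort-order tag is checked.

## Edge construction

Counters start at 1 and gain +1 per spanning fragment, so one
supporting molecule yields counter 2, and induced edges sit at 1 until
direct evidence arrives — this floor is what gives an induced pair its
0.5/0.5 weights downstream.

Gap spans from all fragments are processed after all continuous
evidence, sorted by target level ascending, then source level
descending (remaining ties: target then source sibling index, for
order-independence of the result). Each span runs a pre-order DFS from
its source; at each expanded parent the look-ahead step either

* (sibling observed by a read *and* holding edges to both children)
  induces edges from the parent to both children — local ambiguity is
  propagated; or
* induces an edge to each child that had no incoming edge, never to the
  target's sibling when the next level is the target level.

Two clarifications the published description leaves open, resolved
here: branch conditions are evaluated against the edge set **as of the
span's start** (induced edges join the "pre-existing" framework between
spans, not within one traversal — this is what lets every intermediate
node of an ambiguous gap connect to the target, as the worked figures
require); and each node is expanded at most once per span (an unbounded
pre-order traversal is exponential in gap width for no benefit at two
nodes per level). Identical spans are traversed once: a repeat carries
no new evidence because induced counters never increment. "Observed"
means covered by an allele observation of any retained fragment;
induced-only coverage never counts.

## Weights and path optimisation

`w = counter / (sum of counters over edges sharing the source)`;
`cost = -log w` (natural log; the base cannot change the argmin). All
computation stays in cost space, so products of many small
probabilities never underflow. Dummy cap nodes attach to both boundary
siblings with cost 0, leaving block ends unconstrained.

The forward sweep keeps, per node, the minimum cost and predecessor;
backtracking reads off the path; haplotype 2 is the per-level sibling.
Exactly tied costs are broken toward the lower sibling index at the
first divergence (nested-tuple path keys), which makes output
deterministic. Floating-point ties are detected at 1e-9.

Partitioning guarantees each internal level pair has an edge, but a
*complete* start-to-end path can still be missing when lone edges chain
through alternating nodes (e.g. only v1->v1 between one pair and only
v2->v2 between the next). Such blocks are split at the first
unreachable level, logged, and re-optimised piecewise rather than
crashing.

## Evaluation

Per block, predicted haplotype 1 is compared to the truth haplotype
under both orientations; the better orientation's mismatch count is the
block's error count (haplotype labels are arbitrary). The rate divides
total errors by total evaluated genomic span in Mb — span is the only
per-block quantity in base pairs, and block length throughout is the
first-to-last-variant span (inclusive). A conventional adjacent-pair
switch count is reported alongside, clearly labelled, for comparability
with the wider literature. Evaluation is confined to truth phase sets;
blocks crossing a set boundary are scored piecewise and tallied.
Predicted sites absent from truth are excluded and counted. N50 is the
block length at which the descending cumulative sum first reaches half
the total phased length.

## Simulator

Emulates: a uniform-random reference region; heterozygous sites by a
discrete Poisson process (default 1/kb, human-like) with a small
exclusion zone so INDEL events never overlap; alternates are random
substitutions or, with probability 0.1, insertions/deletions of 1-20 bp
(the short-INDEL regime); a fair-coin truth phase per site; paired-end
fragments (default 2x150 bp, insert Normal(500, 50) — inner gap around
200 bp, so variants regularly fall in the unsequenced middle and
discontinuous fragments actually arise) or long reads (exponential
length, default mean 8 kb); uniform per-base substitution errors.

Reads are written pre-aligned with exact CIGARs at their true
coordinates (read-boundary-clipped insertions become soft clips);
mapping is outside the scope of the phasing problem, so no mapper runs.
A JSON sidecar logs each read's source haplotype and injected error
positions. All outputs are byte-deterministic in the seed.

Not emulated: position- or context-dependent error profiles
(homopolymer bias, indel errors in reads), chimeras, mapping ambiguity,
structural variants, GC bias. Passing end-to-end tests therefore
demonstrate correctness of the graph/phasing machinery under clean
alignments, not robustness to real-world mapping artefacts.

## Default problem sizes

Unit and property tests use graphs of up to 10 levels (checked against
exhaustive enumeration, which is exact up to 2^L paths) and simulated
regions of 20-100 kb; the end-to-end acceptance checks use a 100 kb
region at 10-25x coverage, sizes at which every behaviour of interest
(ambiguity scenarios, discontinuous bridging, block fragmentation)
occurs many times per run.

## Known limitations

* **Tied optima at induced bridges.** A discontinuous fragment's
  source-target allele pairing is carried only by the induced edge
  *structure*, never by counters. When a level pair interior to a gap
  has no direct read evidence, the relative phase across it can be
  genuinely undetermined by the graph: several complete paths share the
  exact minimum cost, and the deterministic tie-break picks the true
  phase only by chance. Exhaustive enumeration on affected blocks shows
  an error-free path always among the tied optima. Consequence: even at
  error-free 25x coverage, a handful of bridged sites per 100 kb can be
  mis-phased; the end-to-end noiseless-recovery test documents this
  when it trips.
* Singleton levels (no linking fragment) are reported but unphased;
  levels split off by the unreachable-path repair are likewise left
  unphased.
* Polyploid genomes, population/pedigree phasing, CRAM input and
  variant calling are out of scope.
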