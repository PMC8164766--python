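# Methods

## The motif and its probabilistic model

The target element is a dual stem-loop RNA: two hairpins joined by a short
linker. Family-defining constraints are hard-coded as `MotifConstraints`:
hexanucleotide loops (fixed), adenine at loop position 1 and guanine at loop
position 4 of each loop, stems of 3–10 contiguous canonical pairs (A-U, G-C
and G-U wobble), and a linker of 2–25 nt. The curation rule admits at most
one mismatch across the four conserved loop positions *per motif*; the
per-loop reading (one variation in each loop) is reachable by setting
`max_conserved_position_violations=2`. We chose the per-motif reading as the
default because the family's loop consensus is strongly conserved and the
stricter reading better matches a manually curated hit list; both behaviors
are tested.

A `MotifProfile` is estimated from a seed alignment (Stockholm, `#=GC
SS_cons` with exactly two hairpins) and scores a candidate decomposition in
bits as a sum of independent log-odds terms against a background model:

* **loop terms** — per-column nucleotide log-odds,
  `log2(((n_b + κ·q_b) / (N + κ)) / q_b)` with Laplace pseudocount κ = 1 and
  background `q`;
* **stem pair terms** — log-odds of the candidate's pair types against the
  background distribution over the six canonical pair types, with counts
  pooled across positions within each stem (seed stems vary in depth;
  pooling avoids sparse columns);
* **stem depth terms** — one per stem, `log2(P(depth)/uniform)` over depths
  3–10, estimated from the per-row count of pairable stem columns. Without
  this term candidates of different depths are compared on unequal footing:
  in a 65% GC background every additional G-C pair contributes a free
  positive increment, and shallow (3 bp) chance candidates with lucky loops
  conversely escape penalty. The depth term makes the score a log-odds over
  the candidate's entire anatomy and empirically separates planted motifs
  (~34 bits) from the genomic background tail (~10 bits);
* **linker term** — `log2(P(length)/uniform)` over 2–25 nt, from the
  observed (ungapped) seed linker lengths.

The background defaults to the scanned genome's mononucleotide frequencies
(a flag forces uniform): in high-GC genomes a uniform background would
inflate the score of generic GC-rich stems. `max_score` maximizes each
additive term and is attained exactly by the profile's argmax candidate.
Bulges and internal loops are not modeled; stems are contiguous.

The score plays the filtering role of a covariance-model bit score but is on
this package's own scale — thresholds from other tools do not transfer.

## Scanning

Hairpin enumeration is exhaustive: for every 6-nt loop window the stem is
extended outward while pairs are canonical, and *every* sub-stem depth from
3 bp up to the maximal extension is emitted, so the scorer (not the
enumerator) chooses the stem extent. Hairpins are paired when the gap
between them is 2–25 nt; no candidate may span an N. Both strands are
scanned (reverse complement), with all coordinates reported on the + frame
and loop/linker sequences strand-local. Hits pass curation, then the score
threshold; overlapping hits (> 50% of the shorter span) are deduplicated
keeping the highest score, ties to the leftmost start and then the + strand.
When ORF annotations are supplied, only hits lying 500 nt upstream to 100 nt
downstream of the start of a same-strand ORF are retained; without
annotations that filter defers to the context module. Identical motif
sequences from strains of one species collapse to a single representative
with a multiplicity count.

## Threshold calibration and negative controls

Dinucleotide-preserving shuffles use the Eulerian-trail construction: the
sequence is a trail in the multigraph whose edges are its dinucleotides;
a random last-edge arborescence into the terminal vertex is rejection-sampled
and the remaining edge orders randomized, giving a uniformly random trail
with the same endpoints and the exact dinucleotide count vector.
Mononucleotide shuffles are uniform permutations. All randomness flows
through per-(seed, source, replicate) streams derived by stable hashing, so
outputs are bit-reproducible and order-independent.

The scan threshold is the 99.9th percentile of the null candidate-score
distribution, where candidates are enumerated and curated exactly as in the
scan. The default null is 5,000 dinucleotide shuffles of the profile's
consensus motif — composition-matched decoys whose score tail stochastically
dominates the genomic background's (measured: null 99.9th percentile ≈ 11–17
bits across study seeds vs a genomic background maximum ≈ 10, with true
motifs ≈ 34). Two alternative nulls are available: a dinucleotide-shuffled
copy of the genome itself (matches the background population exactly, and
therefore necessarily passes ~0.1% of genomic candidates at this quantile)
and per-RNA shuffles of the seed sequences (the classic 30 × 500 control
set, which we keep as the *false-positive assay* — short seed rows yield too
few curated candidates for stable quantile estimation). The FP assay counts
null sequences containing at least one surviving hit; per-hit totals are
also reported.

## Genomic context

Classification uses the flank-inclusive span (motif ± 10 nt) against the
nearest same-strand ORF whose start lies within 500 nt downstream to 100 nt
upstream of the hit (cis-regulation motivates the same-strand rule; the
nearest start wins, ties to the lower coordinate). Precedence:

1. **SEQUESTER_RBS_OR_AUG** — the flank-inclusive span overlaps the start
   codon or the ORF's detected RBS;
2. **INSIDE_ORF** — the motif 5' end lies strictly after the ORF start,
   within 100 nt of it, and the motif is contained in the ORF;
3. **INTERGENIC** — the 3' flank end lies 15–500 nt upstream of the start;
4. otherwise **UNASSIGNED** (including the deliberate 1–14 nt gap, which is
   reported rather than silently absorbed into a category). A flag measures
   the intergenic distance motif-only instead of flank-inclusive.

Minus-strand geometry is handled by mirroring hit and annotations into a
local plus frame, which makes the classifier strand-covariant by
construction. RBS detection scans windows of length 6, then 5, then 4 at
spacers 0–15 nt: a window qualifies with at least four purines and at most
one non-purine; the longest qualifying window wins, then the most purines,
then the smallest spacer. Alternate ORFs (ATG/GTG/TTG start, in-frame stop,
≥ 60 nt, RBS at spacer 0–15) can rescue UNASSIGNED hits into categories 1–2.
The intrinsic-terminator surrogate searches the hit's 3' region plus 40 nt
downstream for a hairpin of ≥ 4 bp with ≥ 60% G-C pairs and a 3–8 nt loop,
followed within 2 nt by ≥ 4 U in an 8-nt window; it reports whether the
terminator's 5' arm intersects stem 2. It imitates no confidence scores —
terminator prediction in high-GC genomes is flagged as unreliable territory.

## Conservation statistics

Pairwise identity is matches over alignment columns of a global alignment
(match 1, mismatch 0, linear gap −1). Clustering is single linkage on the
graph with edges at identity ≥ cutoff; components smaller than 2 are counted
and discarded; cutoffs sweep 0.30–0.60. Per-cluster alignments are
reference-projected star alignments (each member aligned to the longest,
insertions relative to the reference dropped) — adequate for column
statistics of tight clusters, not a general MSA.

Folding maximizes Σ pair weights (G-C = 3, A-U = 2, G-U = 1) with a minimum
loop of 3 nt and no pseudoknots; energy is the negated optimum in surrogate
units. These are deliberately not Turner free energies, so thermodynamic
values from other tools (e.g. a kcal/mol MFE) are not comparable targets.
Traceback deterministically pairs the leftmost base with its farthest
optimal partner. SCI folds the column-majority consensus with each pair
weight scaled by the fraction of rows able to form a canonical pair at those
columns, divided by the mean folding energy of the individual rows: identical
rows give SCI = 1 exactly; structurally incompatible rows drive it to 0. The
folding z-score standardizes a sequence's energy against ≥ 30
composition-preserving shuffles (z = 0 when the shuffle set is degenerate);
negative z means unusually stable structure. An advisory functional flag
(SCI ≥ 0.4 and mean z ≤ −0.5, both configurable) stands in for an external
trained classifier and is never used as a filter. Covariation is reported as
per-pair mutual information in bits, gaps excluded pairwise.

## Synthetic data

The simulator emulates the study's substrate: i.i.d. background genomes at
65% GC (actinobacteria-like; order-1 backgrounds can be had by shuffling a
template), non-overlapping ORFs of 300 nt with ATG/TAA boundaries and an
AGGAGG RBS at a 4–10 nt spacer, and motifs planted at geometries realizing a
configured context mix — default 39/37/24% intergenic/sequester/inside,
the family's observed category split. Sequester placements omit the planted
RBS (the motif itself occupies the start-codon neighbourhood). Loci
alternate strands. Every placement is verified by running the context
classifier on the emitted annotations at generation time.

Planted motifs are profile-consensus instances (5 bp stems, the seed
architecture) with controlled mutations: loop positions mutate independently
to a random other base; stem pairs mutate **compensatorily** by default
(pair type changes, pairing preserved), with one-sided pair-breaking
substitutions behind a flag. Compensatory is the realistic default for a
structured RNA family — conserved pairing with diverged sequence is the
family's defining property and the reason covariance search works at all —
while the pair-breaking mode exists to stress the curation filter and the
covariation statistics.

What the simulator does *not* emulate: real gene content and codon usage,
operon structure, phylogenetic correlation between genomes, sequencing
artifacts, and background sequence with motif-like composition gradients.
Passing recovery tests therefore demonstrates correctness of the scanning
and classification machinery under controlled conditions, not expected
sensitivity on real genomes, where diverged family members and
annotation errors dominate the error budget.

## Problem sizes and numerics

The recovery study uses a 200 kb genome with 25 planted motifs, a 5,000-
sequence calibration null and 5,000-sequence FP assays; the folding oracle
enumerates all structures for 1,000 sequences of length ≤ 12; the context
oracle re-evaluates 10,000 random geometries. These sizes give stable
statistics while keeping a full test run in tens of seconds. Quantiles use
the "higher" order statistic (so quantile 1.0 is the observed maximum and
thresholds are conservative). Score ties in deduplication resolve leftmost-
then-plus-strand; all RNG streams derive from a single integer seed.

## Known limitations

Contiguous stems only (no bulges), so family members with interrupted stems
are found only via their longest clean sub-stems; pooled stem statistics
ignore position-specific pair preferences; the star alignment degrades for
loose clusters; the bit score is not comparable across profiles built from
different seeds or backgrounds; and terminator calls are heuristic flags,
not predictions with calibrated confidence.
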