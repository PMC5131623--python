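# Methods

This note documents the models, algorithms and design choices behind
`plastsurvey`, in the order a survey runs them.

## Quadripartite partitioning

The inverted repeat is found by exact matching: the longest pair of
disjoint circular substrings that are reverse complements of each other.
Plastome IR copies are typically identical (intramolecular gene conversion
homogenises them), so exact matching avoids heuristic alignment entirely.
The search binary-searches the repeat length; at each candidate length it
hashes all circular windows of the sequence and of its reverse complement
(polynomial rolling hash modulo 2^61−1) and verifies every hash hit by
direct string comparison, so collisions cannot create false positives.
Monotonicity holds because any valid pair of length L contains a valid
pair of length L−1. Complexity is O(n log n) with small constants; a full
plastome partitions in well under a second.

Outputs are canonicalised as LSC → IRa → SSC → IRb in circular order with
LSC the longer single-copy region, which makes the partition invariant
under rotation and whole-genome reverse complementation (coordinates move,
region lengths never do). Two distinct maximal pairs of equal length raise
a structured tie error naming both candidates rather than guessing.
`min_ir` defaults to 10 kb — real plastome IRs run ~20–30 kb, and the
floor suppresses short dispersed repeats; tests on small synthetic circles
pass 100 bp. An O(n²) all-pairs scan (`brute_force_longest_ir`) serves as
an independent oracle on sequences up to a few kb.

## Region and class accounting

GC content is (G+C)/(A+C+G+T); IUPAC ambiguity codes and N are excluded
from numerator and denominator, matching conventional reporting on
deposits that contain Ns. Sequence classes are painted onto the circle
with the fixed precedence CDS > tRNA > rRNA > intron > intergenic, so
overlapping annotations (e.g. a pseudogene overlapping a functional gene
at an IR junction) are counted once and class lengths always sum to the
genome length. No community convention exists for the overlap rule or for
whether IR-duplicated loci are counted once or twice; this package counts
both IR copies (annotation features are tallied as they appear) and
treats the precedence rule as a reporting convention, not a biological
claim. Cohort summaries use the sample (n−1) standard deviation.

## Marker extraction

Introns are the gaps between consecutive exon parts of a spliced gene,
numbered in transcript order and strand-normalised; the trans-spliced
first intron of plastid *rps12* (exon parts on opposite strands, tens of
kb apart) is skipped with a warning since it is not an amplifiable locus.
Spacers are the gaps between adjacent gene-level features on the circle,
named `left-right spacer` in genome order, with IR duplicates
disambiguated by `/1`, `/2` suffixes. When a genome is oriented opposite
to the rest of the cohort its spacers surface under reversed names;
collation folds those onto the first-seen orientation (reverse-
complementing), but only when the contributing genome does not itself
carry the direct name — a small circle genuinely has both `A-B` and `B-A`
spacers as distinct loci.

"Suitable size for PCR" is implemented as a cohort-mean spacer length in
[400, 1600] bp, configurable; published survey means for such markers run
roughly 640–1060 bp, and the band brackets what single-pass Sanger reads
amplify comfortably. All introns are retained regardless of length.

## Alignment statistics

Gaps and all ambiguity codes are treated as missing throughout: a variable
site needs ≥2 distinct unambiguous bases, a parsimony-informative site
needs ≥2 bases each in ≥2 taxa, and K80 distances use pairwise deletion
(markers have ragged ends; complete deletion would discard most columns).
The K80 correction d = −½ ln[(1−2P−Q)√(1−2Q)] is undefined when either
log argument is non-positive; such saturated pairs raise a structured
error and are excluded from mean distances and dropped from bootstrap
replicates, always with a logged warning.

Degenerate recoding replaces every leucine codon with YTN, arginine with
MGN, and serine with TCN or AGY by family — the IUPAC codon covering each
synonymous family. This removes the synonymous signal of the six-fold
amino acids (including the first-position TTR↔CTN and AGR↔CGN exchanges,
absorbed by Y and M) while preserving alignment length and reading frame,
and it is idempotent because recoded codons contain ambiguity codes,
which the recoder leaves untouched. Translation uses the bacterial/
plastid genetic code (translation table 11); pure-gap codons translate to
`-`, partially gapped or ambiguous codons to `X`, a terminal stop column
is dropped and internal stops become `X` with a warning.

The poorly-aligned-site filter is a deterministic stand-in for
interactive masking tools: any sliding window (default 5 columns) whose
mean gap+ambiguity fraction exceeds 0.5 has all its columns removed.
Clean edge columns caught inside a majority-gap window are removed too;
that is inherent to window masking and documented test behavior. Real
masking programs use randomised scoring, so column counts of filtered
schemes are not comparable across tools.

Six analysis schemes are assembled from per-marker alignments of genomes
with one IR copy removed (the circle is cut at the LSC start and IRb
dropped, so duplicated loci are represented once): (1) all non-coding,
(2) non-coding filtered, (3) coding, (4) coding degenerate-recoded,
(5) protein, (6) filtered non-coding + coding. Markers are concatenated
in sorted-name order over the taxon union, gap-filling absentees, and
each scheme carries a partition map (RAxML-style text on disk).

## Tree inference and comparison

The built-in engine is neighbor joining on K80 distance matrices —
deliberately distance-based and deterministic (Q-criterion ties break on
the lexicographically smallest taxon label of each cluster, negative
branch lengths clamp to zero) so the whole pipeline is self-contained and
desk-scale. Users with a maximum-likelihood tree can inject it anywhere a
Newick tree is accepted; bootstrap values from an NJ engine are not
numerically comparable to ML bootstrap values on real data, and the
package makes no claim that they are. Topology agreement is asserted only
on simulated data where the truth is known.

Bootstrap supports come from column resampling: each replicate draws its
own counter-derived RNG stream (`default_rng([seed, replicate])`), so
results depend only on the seed and replicate index, never on scheduling.
Robinson–Foulds distance is the unnormalised symmetric-difference count of
nontrivial unrooted bipartitions (even integers for binary trees, max
2(n−3)); polytomies simply contribute fewer bipartitions.

## Composite informativeness score

score = (1·v_rel + 2·b_rel + 3·d_rel)/6, with v = number of variable
sites, b = mean bootstrap of the marker's own tree, d = RF distance to
the reference tree (by default the pipeline's own full-scheme tree).
"Relative value" is division by the survey-wide column maximum, with RF
inverted (d_rel = 1 − d/max d) so topological agreement scores high; this
is the simplest normalisation producing [0, 1] values, and on the
published Melastomataceae metric columns it reproduces the published
top-10 order exactly — provided the survey-wide maxima (507 variable
sites, bootstrap 82, RF 22) are used rather than subset maxima, which is
why `rank_markers` accepts explicit column maxima. A min–max variant sits
behind a switch but only the default is anchored to published output. A
metric column whose maximum is zero carries no signal and contributes its
best value (for RF, "no disagreement anywhere"). Markers whose tree
cannot be built (too few taxa, saturation) are reported unranked with a
reason code. Ties in score break on marker name.

## The simulator

The generator emulates the statistical structure the survey assumes — one
shared gene architecture whose loci evolve along a single phylogeny at
locus-specific rates — not the mutational realism of plastome evolution.
Specifically:

- **Tree**: ultrametric Yule, rescaled to a root-to-tip depth of 0.05
  expected substitutions/site by default (pairwise distances up to ~0.1,
  the within-family plastome range). Draws are conditioned, by rejection,
  on every internal branch being ≥ 0.002 substitutions/site: a pure Yule
  process occasionally produces near-simultaneous speciations that no
  finite alignment can resolve, and the simulated study design assumes an
  identifiable tree. Setting the floor to 0 restores the unconditioned
  process.
- **Sequence evolution**: K80 with transition/transversion rate ratio
  κ = 2 by default, i.i.d. columns, uniform root composition, exact
  per-branch transition probabilities (no discretisation). Branch lengths
  are expected substitutions/site; a marker's rate multiplier scales them
  linearly.
- **Architecture**: the default toy plastome is ~65 kb with an 8.5 kb IR,
  27 protein-coding genes (two duplicated in the IR), 7 tRNAs, 4 rRNAs, six
  spliced genes (including a two-intron *clpP* analogue and an
  intron-bearing tRNA) and ten PCR-sized named spacers among smaller
  anonymous pads — small enough for fast tests, structurally faithful
  enough to exercise every extraction rule. IRb is the literal reverse
  complement of the evolved IRa, and the four bases flanking the repeat
  copies are adjusted when needed so the planted repeat is also the
  maximal one (otherwise a 1-in-4 coincidence per junction would extend
  it).
- **No indels by default**, so collated markers are already alignments
  and site counts/distances have exact expectations; an optional indel
  mode punches aligned gap blocks (geometric lengths, non-coding markers
  only) purely to exercise gap handling and the mask.

What passing on simulated data does **not** show: robustness to
alignment error (sequences are column-homologous by construction),
rate heterogeneity across sites, base-composition bias, microstructural
mutation (real spacer length variation), IR boundary shifts, or gene
rearrangement. Those belong to real-data validation against deposited
genomes.

## Problem sizes and numerics

Default test and acceptance runs use 4–16 taxa, the ~65 kb toy
architecture, 12–100 bootstrap replicates and 20–50 kb recovery
alignments — sizes chosen so the full suite and the acceptance script
each complete in minutes on one core while keeping every statistical
check comfortably powered. All randomness flows through
`numpy.random.default_rng` seeded from a single integer; per-replicate
and per-segment streams are derived by counter, so outputs are
byte-reproducible for a fixed seed and input set.

Known limitations: exact-match IR detection will underestimate the IR if
the two copies differ by even one base (real deposits occasionally do);
junction reporting assumes the annotation uses gene-level features; the
collation-as-alignment shortcut is only valid for simulator output —
real marker sets must be aligned externally before statistics are
meaningful.
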