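# Methods

`plastomics` re-implements, as a tested pipeline, the comparative analysis
workflow applied to clades of closely related chloroplast genomes: detect
the quadripartite architecture of each plastome, characterize the
single-copy/inverted-repeat junctions, detect gene-order rearrangements,
partition the genomes into homologous coding and non-coding regions, build
concatenated partition schemes, and rank non-coding regions as candidate
PCR markers by variability and tree distance.  This note records the models,
the defaults, and the design choices that were genuinely open.

## Coordinates and genome representation

All intervals are 0-based half-open on a circular sequence; a segment whose
end is not greater than its start wraps through the origin.  GenBank's
1-based inclusive coordinates are converted only at the file boundary.
Multi-exon features store their segments 5'→3' on the feature strand
(descending genomic order on the minus strand), so concatenating the
per-segment extractions always yields the feature's own sequence.  Rotation
and whole-genome reverse complement are lossless transforms; canonical
presentation puts the LSC first (order LSC–IRa–SSC–IRb), with the strand
chosen so the LSC holds the larger number of forward-strand CDS (ties broken
lexicographically on the sequence).

## Inverted-repeat detection

The IR search seeds exact k-mer matches (k = 21 by default) between the
genome and its reverse complement.  For a true inverted-repeat pair every
matching position pair lies on one anti-diagonal (`p + partner ≡ const mod
L`), so seeds are grouped by anti-diagonal and the densest diagonal is
extended base-by-base around the circle.  The default demands exact copies
(`max_mismatch_frac = 0`) because finished plastome IRs are identical; a
mismatch-tolerant greedy extension is available for degraded inputs.  The
four compartments must tile the genome; the longer single-copy interval is
the LSC.  Detection is compared against an independent longest-common-
substring (sequence vs reverse complement) dynamic program on small genomes
in the test suite.

## Synthetic plastomes

The generator defines the study conditions for every downstream test.  A
profile instantiates an ordered gene/spacer template into an ancestral
genome:

- **default** profile: ~110 unique loci (86 CDS, 8 rRNA and a full tRNA
  set, 16 of them intron-bearing; one trans-spliced locus split into its 5'
  and 3' parts; trnQ-UUG duplicated in the LSC), total ~161 kb with LSC
  ~89 kb, IR ~26 kb, SSC ~20 kb before expansion.
- **reduced** profile: 26 loci, ~30 kb (LSC 15.4 kb, IR 4.4 kb, SSC
  5.6 kb), used by the test suite and the acceptance script.

Spacer lengths are drawn once per profile from a fixed profile-local RNG as
a long/short mixture (long ≈ 0.5–1 kb, short ≈ 0.1–0.3 kb), emulating the
contrast between tight operon-like gene clusters and the PCR-amplifiable
intergenic spacers between them; the user seed changes sequence content
only, so planted event coordinates are reproducible across seeds.  CDS
sequences begin with ATG and end with TAA.

Evolution proceeds along a rooted tree (branch lengths in expected
substitutions per site at coding positions).  Defaults: JC69 substitutions
(K80 with configurable kappa available), non-coding positions at 1.5× the
coding rate, spacer-restricted indels at 0.02 events per spacer site per
unit branch length with geometric(0.3) lengths.  The default 13-taxon tree
has ten congeneric ingroup taxa (pairwise divergence roughly 1–4%) and
three deeper outgroups (up to ~20% on spacers) — values chosen once as
realistic for a species-level plastome study of closely related taxa; the
generator makes no claim to estimate them from any real data set.

The genome state is carried as its *core* (LSC + IRa + SSC); IRb is always
materialized as the exact reverse complement of IRa with derived mirror
annotations.  IR lockstep evolution — the homogenization real IRs show —
therefore holds by construction; disabling lockstep applies an additional
tip-wise round of substitutions to IRb.

**IR boundary shifts.**  Expansion into the SSC is a pure boundary move:
the IR unit absorbs the SSC head, so the absorbed tract is duplicated into
IRb, the SSC shrinks by `amount`, each IR grows by `amount`, and the genome
grows by `amount` — the duplication mechanism that makes IR-expanded
plastomes larger than their relatives.  A gene wholly inside the absorbed
tract gains a complete duplicate; a gene split by the new boundary keeps
its full copy spanning the IRa/SSC junction while its truncated mirror
fragment is flagged as a pseudogene.  Contraction is the exact inverse
(SSC +a, IR −a, genome −a; the mirror copy of the released tract is lost).
The standard planted scenario puts one expansion on the ingroup stem that
fully absorbs ycf1 and splits rps15, two LSC inversions on different
branches with different gene blocks, and one IR inversion block planted in
parallel on two branches — four inversions in total, all with endpoints in
spacers.

**Junction pinning.**  Planted IR boundaries must be recoverable exactly,
but a chance substitution adjacent to a junction could extend the true
inverted repeat by a base.  After every branch the generator sets one
spacer base per single-copy flank equal to its partner base across the
junction; since no nucleotide is its own complement, boundary extension is
impossible.  This is a synthetic-data device with no biological analogue;
it affects four spacer positions per genome.

**What the generator does not emulate**: base-composition heterogeneity
and rate variation across sites, selection on codons, microsatellite slip-
page, IR-mediated flip-flop isomers, recombination, and sequencing error.
Passing planted-truth tests therefore demonstrates correctness of the
detectors under clean, model-generated data, not robustness to annotation
error or assembly artifacts in real accessions.

## Structural summaries and junctions

GC% is reported to one decimal, rounded half-up.  Gene counts are given
under both conventions in circulation — every `(name, copy)` feature, and
unique locus names — rather than silently choosing one.  For each of the
four junctions the report lists the nearest feature on each flank with a
signed distance (negative = the feature overlaps the junction by that many
bp), so a locus spanning a junction appears on both flanks with its two
overlap extents.

## Gene-order rearrangements

The unit of comparison is the annotated locus, which is robust to spacer
divergence.  Orders are restricted to shared locus labels (IR duplicates
matched by copy tag after canonicalization; loci with unequal copy numbers
across two genomes drop out of their comparison), then decomposed greedily
into maximal collinear or reversed-and-sign-flipped runs.  The greedy
decomposition is provably minimal for this segmentation and is checked
against an exhaustive dynamic program on small orders.  Breakpoints are
counted as orientation-normalized signed adjacencies, including the
circular wrap pair.  Translocations are collinear blocks outside a
maximum-weight increasing subsequence of block positions (weight = loci per
block), which pins the small displaced block rather than its large
neighbours.  No minimal rearrangement scenario is computed.  Because each
IR inversion is mirrored in both copies, one planted IR event appears as
two inverted blocks in gene-order space; the tests assert exactly that
mapping.  Whether every rearrangement endpoint falls between loci is
reported as a checkable flag, not assumed.

## Region partitioning and homology grouping

One IR (IRb) is excluded before fragmentation to avoid duplicated
characters.  Coding regions are the concatenated exons of each functional
CDS/tRNA/rRNA locus; introns and intergenic spacers are non-coding;
pseudogene spans are treated as plain intergenic DNA.  Overlapping loci are
cut at the midpoint of their overlap — symmetric and deterministic — so no
base is emitted twice (audited).  Regions shorter than 50 bp are dropped
(length ≥ 50 retained).

Global similarity is Needleman–Wunsch identity over alignment length.  The
alignment costs behind the published "default costs" are not recoverable,
so this package pins match +1, mismatch −1, gap open −4, gap extend −1
(a gap of length g costs 4 + g) and exposes all four.  Every non-reference
region is assigned to the reference region of the same role with the
highest similarity, if that similarity reaches the 65% threshold; one
member per genome is kept (best score wins) and unassigned regions are
reported, never dropped.  Length-ratio and shared-11-mer prefilters skip
hopeless pairs before the quadratic alignment; the length-ratio bound is
rigorous, the k-mer screen heuristic but far below the threshold regime.

## Alignment, filtering, schemes

The built-in aligner is center-star progressive: the member with the
highest summed pairwise similarity is the center, all others are aligned to
it globally, and gaps in the center propagate.  Coding mode uses gap open
−8, non-coding −4 (mimicking global vs long-gap strategies).  On tiny
instances the sum-of-pairs cost is within the classic 2× bound of the
exhaustive optimum (tested).  An external aligner (e.g. `mafft`) can be
named in configuration and produces the same alignment type.

Block filtering follows the classic conserved-block rules: with n rows a
column is conserved if one residue occurs in more than n/2 rows and highly
conserved at ≥ 0.85·n; any gap makes a column non-conserved (the strictest
gap rule); stretches of more than 8 contiguous non-conserved columns are
rejected; surviving blocks are trimmed to highly conserved flanks and
dropped below 10 columns.  The filter is idempotent.

The outlier screen scores each row by mean pairwise identity over shared
non-gap columns (so length variation does not masquerade as non-homology)
and removes rows below `max(0.5, mean − 2·sd)`, where mean and sd describe
the pooled distribution of all pairwise identities; anchoring the spread on
pairs keeps uniformly divergent alignments intact (divergence widens the
pair distribution symmetrically) while a true non-homolog drags its row
mean far below the cutoff.  Never more than ⌈n/3⌉ rows are removed.
Manual alignment curation is not algorithmic; the "edited" pathway is
operationalized as outlier removal followed by re-alignment with no block
filter, plus a hook for ingesting a hand-curated alignment file.  The
"filtered" pathway is block filter then outlier removal.  With a divergent
outgroup among a dozen close ingroup taxa the 2-sd rule will sometimes
flag the outgroup in fast-evolving spacers; the ranking stage therefore
roots each per-region tree with whichever outgroups survive in that
region.

Five partition schemes are assembled: coding, non-coding edited,
non-coding filtered, and the two combined sets.  Lengths, variable sites
(≥ 2 distinct unambiguous nucleotides in a column; gaps and N ignored) and
percent variation (one decimal) are additive over member regions.

## Trees, the Kendall–Colijn metric, and marker ranking

Built-in inference is JC69 distances (pairwise deletion; p ≥ 3/4 is a
saturation error, never an infinite distance) and Saitou–Nei neighbor
joining with the standard Q criterion; negative branch estimates are
clamped to zero and logged; ties break deterministically.  Bootstrap
support is column resampling with NJ on each replicate.  Tree inference is
not the contribution here — externally computed newick trees can be used
anywhere a tree is expected.

The Kendall–Colijn vector of a rooted tree holds, for every unordered tip
pair, `(1−λ)·m + λ·M` where m and M are the root-to-MRCA depth in edges
and in branch length, followed by one entry per tip (`(1−λ) + λ·pendant`).
λ = 0 is the topology metric, λ = 1 the branch-length metric; tree distance
is the Euclidean norm of the vector difference.  The λ=0 vectors are
verified against an independent depth computation on all 945 rooted
topologies with six tips.

Markers are screened from the non-coding groups: median unaligned member
length within [500, 1100] bp (amplifiable by PCR) and no overlap between
the reference interval and any detected rearrangement breakpoint — the
operational proxy for "recombination free"; it is a proxy, not a
recombination test.  Rankings standardize percent variation upward
(`(v−min)/(max−min)`) and both KC distances downward
(`1 − (d−min)/(max−min)`), so 1 is always best and a region whose tree
matches the reference topology scores exactly 1 on topology; the composite
is the unweighted mean of the three scores (weights configurable).  If a
metric is constant across regions its standardization is degenerate and
every region scores 1 on it, with a warning.

The ranking's discriminative power is validated on a constructed scenario
that mirrors the marker-screening situation: the reference tree carries the
plastome-average branch lengths (what a concatenated analysis estimates),
background spacers evolve at one third of that scale — single spacers at
species level are information-poor and often fail to resolve the topology —
and the candidate marker at three times the background.  The candidate then
wins on all three standardized axes.  When background regions carry as much
signal as the reference scale, every region resolves the topology and the
branch-length axis structurally favours slower regions; the ranking is not
expected to (and does not) prefer the fastest region in that regime.

## Pipeline and determinism

The pipeline runs structure → rearrangement → partitioning →
alignment/filtering → schemes → trees → ranking, writing every stage
artifact before the next stage and echoing the configuration verbatim.
All thresholds default to the study values (50 bp region floor, 65%
similarity, 500–1,100 bp marker window, block-filter 8/10, outlier 2 sd
with 0.5 floor).  Every random draw derives from the single configured
seed, and byte-identical outputs across repeated runs are part of the
acceptance checks.  Reported problem sizes: the test suite and the
acceptance script use the reduced profile (13 taxa, ~30 kb genomes),
20-seed sweeps for stochastic properties, and 20–50 bootstrap replicates;
the default profile (~161 kb, ~131 features) is exercised for template
construction and IR detection.

## Known limitations

- Homology grouping requires a reference genome; regions absent from the
  reference cannot form groups (they are reported as unassigned).
- Gene-level rearrangement comparison cannot see breakpoints that fall
  strictly inside unannotated sequence between the same flanking loci.
- The center-star aligner is an approximation; for publication-grade
  alignments an external aligner should be configured.
- The "recombination free" screen is a breakpoint-overlap proxy.
- The outlier rule measures divergence, not misalignment; a legitimately
  distant outgroup can be flagged in fast-evolving regions (handled at the
  ranking stage, but the scheme statistics then exclude that row for the
  affected region).
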