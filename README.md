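# plastomics

Comparative plastome architecture and phylogenetic marker selection for
clades of closely related plants.

Chloroplast genomes are circular molecules of roughly 120–220 kb with a
quadripartite layout: a large and a small single-copy region (LSC, SSC)
separated by two identical inverted repeats (IRa, IRb).  Although this
architecture is broadly conserved, some lineages show IR expansions that
compress the SSC, duplicate boundary genes (a full extra copy of *ycf1*, a
truncated pseudogene copy of *rps15*), and carry several large inversions —
all of which complicate assembly, homology assessment, and alignment.
`plastomics` implements the full comparative workflow such a study needs:

- **Structure** — detect the maximal inverted-repeat pair (exact k-mer
  seeding on the anti-diagonal, base-level extension), canonicalize the
  rotation and strand, and report lengths, GC%, gene inventories, and the
  gene context at all four junctions.
- **Rearrangements** — reduce each genome to its signed gene order,
  decompose shared loci into collinear/inverted synteny blocks, and count
  orientation-aware breakpoints on the circle.
- **Partitioning** — fragment genomes (one IR excluded) into coding regions,
  introns, and spacers (≥ 50 bp); group homologs across taxa against a
  reference genome at ≥ 65% Needleman–Wunsch global similarity; assemble the
  five standard partition schemes (coding, non-coding edited/filtered, and
  the two combinations).
- **Alignment QC** — center-star multiple alignment (or an external aligner),
  conserved-block filtering (columns conserved when one residue exceeds n/2
  rows, blocks trimmed to 85% flanks, gappy stretches > 8 columns rejected,
  blocks < 10 columns dropped), and outlier-row removal.
- **Markers** — JC69 + neighbor-joining trees with bootstrap; rooted-tree
  comparison with the Kendall–Colijn metric
  (`v_λ(T)[i,j] = (1−λ)·m_ij + λ·M_ij` over root-to-MRCA depths; λ = 0 is
  topology, λ = 1 branch lengths); candidate spacers screened to 500–1,100 bp
  amplicons away from rearrangement breakpoints and ranked by the mean of
  standardized variability, topology distance, and branch-length distance.
- **Synthetic data** — a generator that builds annotated quadripartite
  plastomes with planted ground truth (true tree, IR boundaries, inversions,
  IR expansion with pseudogene creation, homologous regions), so every
  stage is testable end to end without downloads.

See `docs/methods.md` for models, defaults, and design decisions.

## Worked example

Simulate a 13-taxon data set (ten congeneric ingroup taxa plus three
outgroups, an IR expansion on the ingroup stem, four planted inversions)
and run the whole pipeline:

```bash
plastome run --config run.toml
```

with `run.toml`:

```toml
output_dir = "out"
seed = 5
bootstrap_reps = 50
```

The run prints the partition-scheme summary:

```
                   scheme  alignment_length  variable_sites  pct_variation  n_regions
                   coding             12610            4400           34.9         26
         noncoding_edited             12946            5894           45.5         34
       noncoding_filtered             12901            5877           45.6         34
  coding+noncoding_edited             25556           10294           40.3         60
coding+noncoding_filtered             25511           10277           40.3         60
```

Non-coding regions are more variable than coding ones (the generator's
spacers evolve at 1.5× the coding rate), and the combined schemes are the
exact sums of their parts.  The top of the standardized marker ranking
(percent variation, and Kendall–Colijn topology and branch-length
distances to the best combined-data tree, each standardized so 1 = best):

```
         region  pct_variation  topo_dist  brlen_dist  std_topo  composite  rank
trnG-UCC_intron           47.6   0.000000    0.026790  1.000000   0.878635     1
  trnG-UCC-rbcL           49.8   0.000000    0.070693  1.000000   0.840398     2
  psbM-trnG-UCC           46.1   0.000000    0.029747  1.000000   0.791535     3
```

A topology distance of 0 means the region's own tree matches the reference
topology exactly, hence the standardized topology score of 1.  `out/` also
contains the structure table (the IR-expanded ingroup shows a smaller SSC,
a larger IR, and a longer genome than the outgroups), the rearrangement
matrix, per-region alignments, and scheme trees with bootstrap supports.

The same stages are available individually (`plastome simulate`,
`plastome structure`, `plastome rearrange`, `plastome convert`) and as
library functions (`plastomics.structure.find_inverted_repeats`,
`plastomics.phylo.kc_distance`, ...).

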