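"""Fragmentation into coding/non-coding regions and reference-based homology grouping.

A canonical genome is cut into coding regions (the exon sequence of each
CDS/tRNA/rRNA locus) and non-coding regions (introns and intergenic spacers),
with one IR excluded to avoid duplicated characters.  Regions from all taxa
are then grouped against the regions of a chosen reference genome by global
(Needleman–Wunsch) similarity, and the grouped, aligned regions are
assembled into the five standard partition schemes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from Bio import Align

from plastomics.io import AnnotatedGenome, RegionSeq, extract_sequence
from plastomics.structure import QuadripartiteLayout, round_half_up

logger = logging.getLogger("plastomics")

#: Needleman–Wunsch scoring used for "global similarity".  A gap of length g
#: costs open + g*extend.  These are pinned for reproducibility and exposed
#: as configuration.
DEFAULT_ALIGN_COSTS = {"match": 1.0, "mismatch": -1.0, "gap_open": -4.0, "gap_extend": -1.0}

MIN_REGION_LENGTH = 50  # bp; regions shorter than this are excluded
SIMILARITY_THRESHOLD = 0.65

SCHEME_NAMES = (
    "coding",
    "noncoding_edited",
    "noncoding_filtered",
    "coding+noncoding_edited",
    "coding+noncoding_filtered",
)


# ---------------------------------------------------------------------------
# Fragmentation
# ---------------------------------------------------------------------------

def fragment_genome(
    genome: AnnotatedGenome,
    layout: QuadripartiteLayout,
    min_len: int = MIN_REGION_LENGTH,
) -> list[RegionSeq]:
    """Cut one genome into coding and non-coding regions.

    IRb is excluded first.  Coding regions are the concatenated exons of each
    functional CDS/tRNA/rRNA locus; introns and intergenic spacers are
    non-coding.  Pseudogene spans are treated as plain intergenic DNA.
    Loci that overlap are truncated at the midpoint of their overlap so that
    no base is emitted twice; regions shorter than ``min_len`` are dropped.
    """
    L = genome.length
    domain_end = layout.irb[0]  # [0, l3): LSC + IRa + SSC

    # collect functional loci within the domain, as (span, feature)
    loci = []
    pseudo_spans = []
    for f in genome.features:
        s, e = f.span(L)
        if e <= s or e > domain_end:
            continue  # IRb copy or wrapping feature
        if f.kind == "pseudogene":
            pseudo_spans.append((s, e))
            continue
        loci.append([s, e, f])
    loci.sort(key=lambda x: x[0])

    # resolve overlaps at the midpoint (neighbours share no characters)
    for a, b in zip(loci, loci[1:]):
        if b[0] < a[1]:
            mid = (b[0] + a[1]) // 2
            logger.debug(
                "%s: overlap %s/%s cut at %d", genome.id, a[2].label, b[2].label, mid
            )
            a[1] = mid
            b[0] = mid

    regions: list[RegionSeq] = []

    def emit(name, role, start, end, strand="+"):
        if end - start < min_len:
            return
        seq = extract_sequence(genome, (start, end, strand))
        regions.append(RegionSeq(genome.id, name, role, seq, (start, end, strand)))

    prev_end = 0
    prev_name = "origin"
    for s, e, f in loci:
        emit(f"{prev_name}-{f.label}", "noncoding", prev_end, s)
        # coding part: exon segments clipped to the (possibly truncated) span
        segs = [(max(ss, s), min(ee, e), st) for ss, ee, st in f.segments]
        segs = [(ss, ee, st) for ss, ee, st in segs if ee > ss]
        exon_len = sum(ee - ss for ss, ee, _ in segs)
        if exon_len >= min_len:
            seq = "".join(extract_sequence(genome, seg) for seg in segs)
            regions.append(
                RegionSeq(genome.id, f.label, "coding", seq, (s, e, f.strand))
            )
        # introns: gaps between consecutive exon segments, genomic order
        genomic = sorted(segs)
        for k, (g1, g2) in enumerate(zip(genomic, genomic[1:]), start=1):
            emit(f"{f.label}_intron{k if len(genomic) > 2 else ''}",
                 "noncoding", g1[1], g2[0], f.strand)
        prev_end, prev_name = e, f.label
    emit(f"{prev_name}-end", "noncoding", prev_end, domain_end)
    return regions


def audit_disjoint(regions: list[RegionSeq], genome_length: int) -> None:
    """Raise if any genome position is emitted by two different regions.

    Intron intervals lie inside their locus span, so coding (exonic) and
    intron extents are reconstructed from the source intervals before the
    pairwise check.
    """
    cover = {}
    for r in regions:
        s, e, _ = r.source_interval
        key = (s, e)
        for other in cover:
            os, oe = other
            if s < oe and os < e:
                # introns are within their gene span by construction;
                # anything else overlapping is an error
                a, b = sorted([key, other])
                if not (a[0] <= b[0] and b[1] <= a[1]):
                    raise AssertionError(f"regions overlap: {cover[other]} vs {r.region_name}")
        cover[key] = r.region_name


# ---------------------------------------------------------------------------
# Global similarity
# ---------------------------------------------------------------------------

def _make_aligner(costs=None) -> Align.PairwiseAligner:
    c = dict(DEFAULT_ALIGN_COSTS, **(costs or {}))
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = c["match"]
    aligner.mismatch_score = c["mismatch"]
    aligner.open_gap_score = c["gap_open"] + c["gap_extend"]
    aligner.extend_gap_score = c["gap_extend"]
    return aligner


def global_similarity(a: str, b: str, costs: dict | None = None) -> float:
    """Fraction of identical positions in the optimal global alignment.

    Needleman–Wunsch with the pinned costs (match +1, mismatch -1, gap open
    -4, gap extend -1); similarity = identities / alignment length.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    aligner = _make_aligner(costs)
    aln = aligner.align(a, b)[0]
    counts = aln.counts()
    return counts.identities / aln.length


def _kmer_set(s: str, k: int = 11) -> set:
    return {s[i : i + k] for i in range(0, len(s) - k + 1)}


# ---------------------------------------------------------------------------
# Grouping
# ---------------------------------------------------------------------------

@dataclass
class RegionGroup:
    """A reference-anchored homologous region across taxa."""

    region_name: str
    role: str
    members: dict[str, RegionSeq] = field(default_factory=dict)
    similarity_to_ref: dict[str, float] = field(default_factory=dict)

    @property
    def n_members(self) -> int:
        return len(self.members)

    def sequences(self) -> dict[str, str]:
        return {gid: m.sequence for gid, m in self.members.items()}

    def member_lengths(self) -> list[int]:
        return [len(m.sequence) for m in self.members.values()]


def group_by_similarity(
    regions_by_genome: dict[str, list[RegionSeq]],
    reference_id: str,
    threshold: float = SIMILARITY_THRESHOLD,
    costs: dict | None = None,
) -> tuple[list[RegionGroup], list[RegionSeq]]:
    """Assign every region to the best-matching reference region.

    Each non-reference region goes to the reference region (of the same
    role) with the highest global similarity, provided that similarity is at
    least ``threshold``; at most one member per genome is kept per group
    (the best-scoring candidate wins).  Unassigned regions are returned, not
    silently dropped.

    Candidate pairs are prefiltered before the quadratic alignment: a length
    ratio below the threshold rigorously bounds similarity below it
    (identities <= min length, alignment length >= max length), and pairs
    sharing no 11-mer are skipped as a heuristic — homologs anywhere near
    the 65% threshold essentially always share at least one exact 11-mer.
    """
    if reference_id not in regions_by_genome:
        raise ValueError(f"reference genome {reference_id!r} missing from inputs")
    ref_regions = regions_by_genome[reference_id]
    groups = {
        r.region_name: RegionGroup(r.region_name, r.role, {reference_id: r}, {reference_id: 1.0})
        for r in ref_regions
    }
    ref_kmers = {r.region_name: _kmer_set(r.sequence) for r in ref_regions}
    unassigned: list[RegionSeq] = []

    for gid, regions in sorted(regions_by_genome.items()):
        if gid == reference_id:
            continue
        for region in regions:
            best = (0.0, None)
            rk = _kmer_set(region.sequence)
            for ref in ref_regions:
                if ref.role != region.role:
                    continue
                la, lb = len(region.sequence), len(ref.sequence)
                if min(la, lb) / max(la, lb) < threshold:
                    continue  # similarity <= min/max < threshold
                if not (rk & ref_kmers[ref.region_name]):
                    continue  # no shared 11-mer: far below any usable similarity
                sim = global_similarity(region.sequence, ref.sequence, costs)
                if sim > best[0]:
                    best = (sim, ref.region_name)
            sim, name = best
            if name is None or sim < threshold:
                unassigned.append(region)
                logger.info(
                    "%s:%s unassigned (best similarity %.3f)", gid, region.region_name, sim
                )
                continue
            grp = groups[name]
            if gid in grp.members and grp.similarity_to_ref[gid] >= sim:
                unassigned.append(region)
                continue
            if gid in grp.members:
                unassigned.append(grp.members[gid])
            grp.members[gid] = region
            grp.similarity_to_ref[gid] = sim
    return list(groups.values()), unassigned


# ---------------------------------------------------------------------------
# Partition schemes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PartitionScheme:
    name: str
    region_names: tuple[str, ...]
    alignment_length: int
    variable_sites: int
    percent_variation: float
    alignments: dict  # region_name -> Alignment


def _scheme_stats(alignments: dict) -> tuple[int, int, float]:
    from plastomics.alignment import variable_site_stats

    total_len = 0
    total_var = 0
    for aln in alignments.values():
        length, var, _ = variable_site_stats(aln)
        total_len += length
        total_var += var
    pct = round_half_up(100.0 * total_var / total_len, 1) if total_len else 0.0
    return total_len, total_var, pct


def build_schemes(
    coding_alignments: dict,
    noncoding_edited: dict,
    noncoding_filtered: dict,
) -> dict[str, PartitionScheme]:
    """Assemble the five partition schemes from aligned region groups.

    Inputs map region name -> Alignment; the two non-coding variants come
    from the outlier-removal ("edited") and block-filter ("filtered")
    pathways.  Per-scheme length, variable sites, and percent variation are
    additive over member regions.
    """
    combos = {
        "coding": [coding_alignments],
        "noncoding_edited": [noncoding_edited],
        "noncoding_filtered": [noncoding_filtered],
        "coding+noncoding_edited": [coding_alignments, noncoding_edited],
        "coding+noncoding_filtered": [coding_alignments, noncoding_filtered],
    }
    schemes = {}
    for name, parts in combos.items():
        merged = {}
        for part in parts:
            merged.update(part)
        if not merged:
            raise ValueError(f"scheme {name!r} is empty")
        length, var, pct = _scheme_stats(merged)
        schemes[name] = PartitionScheme(
            name=name,
            region_names=tuple(sorted(merged)),
            alignment_length=length,
            variable_sites=var,
            percent_variation=pct,
            alignments=merged,
        )
    return schemes


def concatenate_scheme(scheme: PartitionScheme, taxa: list[str]) -> dict[str, str]:
    """Concatenated supermatrix rows for the given taxa (missing = gaps)."""
    rows = {t: [] for t in taxa}
    for name in scheme.region_names:
        aln = scheme.alignments[name]
        width = aln.length
        for t in taxa:
            rows[t].append(aln.rows.get(t, "-" * width))
    return {t: "".join(parts) for t, parts in rows.items()}
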