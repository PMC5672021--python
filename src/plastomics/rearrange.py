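"""Signed gene orders and gene-level rearrangement detection.

Comparison works at the level of annotated loci, not sequence blocks: each
genome is reduced to its signed gene order on the canonical rotation, shared
loci are decomposed into maximal collinear or inverted synteny blocks, and
orientation-aware breakpoints (including the circular wrap adjacency) are
counted.  No minimal rearrangement scenario is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from plastomics.io import AnnotatedGenome
from plastomics.structure import QuadripartiteLayout

logger = logging.getLogger("plastomics")


class InsufficientHomologyError(ValueError):
    """Fewer than two loci are shared between the genomes being compared."""


@dataclass(frozen=True)
class SignedLocus:
    label: str  # name or name#copy_tag
    sign: int  # +1 forward strand, -1 reverse
    compartment: str
    start: int
    end: int


@dataclass
class GeneOrder:
    genome_id: str
    loci: list[SignedLocus]

    def labels(self) -> list[str]:
        return [l.label for l in self.loci]

    def signed(self) -> list[tuple[str, int]]:
        return [(l.label, l.sign) for l in self.loci]


@dataclass(frozen=True)
class SyntenyBlock:
    ref_start: int  # indices into the shared-locus reference order
    ref_end: int  # half-open
    target_start: int
    target_end: int
    orientation: str  # "collinear" | "inverted"
    displaced: bool
    loci: tuple[str, ...]


def gene_order(
    genome: AnnotatedGenome,
    layout: QuadripartiteLayout,
    include_pseudogenes: bool = True,
) -> GeneOrder:
    """Signed locus order on the canonical rotation.

    IR-duplicate copies are kept, disambiguated by their copy tags; the sign
    encodes the annotated strand.
    """
    loci = []
    L = genome.length
    for f in genome.features:
        if not include_pseudogenes and f.kind == "pseudogene":
            continue
        s, e = f.span(L)
        loci.append(
            SignedLocus(
                label=f.label,
                sign=1 if f.strand == "+" else -1,
                compartment=layout.compartment_of(s),
                start=s,
                end=e,
            )
        )
    loci.sort(key=lambda l: l.start)
    return GeneOrder(genome.id, loci)


def _shared(ref: GeneOrder, target: GeneOrder):
    shared = set(ref.labels()) & set(target.labels())
    if len(shared) < 2:
        raise InsufficientHomologyError(
            f"{ref.genome_id} vs {target.genome_id}: {len(shared)} shared loci"
        )
    r = [l for l in ref.loci if l.label in shared]
    t = [l for l in target.loci if l.label in shared]
    return r, t


def detect_blocks(ref: GeneOrder, target: GeneOrder) -> list[SyntenyBlock]:
    """Decompose the shared locus set into maximal synteny blocks.

    Both orders are restricted to shared loci; maximal runs that are order-
    and sign-consistent (collinear) or reversed-and-sign-flipped (inverted)
    are extended greedily along the reference.  A single shared locus forms
    a block on its own (collinear if its sign agrees, else inverted).
    """
    r, t = _shared(ref, target)
    t_pos = {l.label: i for i, l in enumerate(t)}
    t_sign = {l.label: l.sign for l in t}
    r_sign = [l.sign for l in r]

    blocks: list[SyntenyBlock] = []
    i, n = 0, len(r)
    while i < n:
        j = i + 1
        p0 = t_pos[r[i].label]
        same0 = t_sign[r[i].label] == r_sign[i]
        # try collinear extension (target positions ascending, signs equal)
        if same0:
            while (
                j < n
                and t_pos[r[j].label] == t_pos[r[j - 1].label] + 1
                and t_sign[r[j].label] == r_sign[j]
            ):
                j += 1
            if j > i + 1:
                blocks.append(_mk_block(r, t_pos, i, j, "collinear"))
                i = j
                continue
        # try inverted extension (target positions descending, signs flipped)
        if t_sign[r[i].label] == -r_sign[i]:
            while (
                j < n
                and t_pos[r[j].label] == t_pos[r[j - 1].label] - 1
                and t_sign[r[j].label] == -r_sign[j]
            ):
                j += 1
            if j > i + 1:
                blocks.append(_mk_block(r, t_pos, i, j, "inverted"))
                i = j
                continue
        blocks.append(
            _mk_block(r, t_pos, i, i + 1, "collinear" if same0 else "inverted")
        )
        i += 1

    # displacement: blocks whose position in the target is inconsistent with
    # the reference block order.  The maximal-weight increasing subsequence
    # of target ranks (weight = loci per block) is taken as "in place"; the
    # remaining collinear blocks are displaced (translocated).  Weighting by
    # block size pins the small moved block, not its large neighbours.
    ranks = [b.target_start for b in blocks]
    kept = _max_weight_increasing(ranks, [b.ref_end - b.ref_start for b in blocks])
    out = []
    for bi, blk in enumerate(blocks):
        displaced = blk.orientation == "collinear" and bi not in kept
        out.append(
            SyntenyBlock(
                blk.ref_start, blk.ref_end, blk.target_start, blk.target_end,
                blk.orientation, displaced, blk.loci,
            )
        )
    return out


def _max_weight_increasing(ranks: list[int], weights: list[int]) -> set[int]:
    """Indices of a maximum-weight increasing subsequence (first-found on ties)."""
    n = len(ranks)
    best_w = [0] * n
    prev = [-1] * n
    for i in range(n):
        best_w[i] = weights[i]
        for j in range(i):
            if ranks[j] < ranks[i] and best_w[j] + weights[i] > best_w[i]:
                best_w[i] = best_w[j] + weights[i]
                prev[i] = j
    if n == 0:
        return set()
    end = max(range(n), key=lambda i: (best_w[i], -i))
    kept = set()
    while end != -1:
        kept.add(end)
        end = prev[end]
    return kept


def _mk_block(r, t_pos, i, j, orientation) -> SyntenyBlock:
    tps = [t_pos[l.label] for l in r[i:j]]
    return SyntenyBlock(
        ref_start=i,
        ref_end=j,
        target_start=min(tps),
        target_end=max(tps) + 1,
        orientation=orientation,
        displaced=False,
        loci=tuple(l.label for l in r[i:j]),
    )


def _adjacency_set(order: list[tuple[str, int]]) -> set:
    """Signed circular adjacencies, orientation-normalized.

    The adjacency (a, b) read along one strand equals (-b, -a) read along
    the other; both spellings map to one canonical key.
    """
    adj = set()
    n = len(order)
    for idx in range(n):
        a, sa = order[idx]
        b, sb = order[(idx + 1) % n]
        key = ((a, sa), (b, sb))
        mirror = ((b, -sb), (a, -sa))
        adj.add(min(key, mirror))
    return adj


def breakpoint_count(ref: GeneOrder, target: GeneOrder) -> int:
    """Number of signed circular adjacencies of the target absent from the
    reference (restricted to shared loci)."""
    r, t = _shared(ref, target)
    ref_adj = _adjacency_set([(l.label, l.sign) for l in r])
    tgt_adj = _adjacency_set([(l.label, l.sign) for l in t])
    return len(tgt_adj - ref_adj)


def breakpoint_intervals(ref: GeneOrder, target: GeneOrder) -> list[tuple[int, int]]:
    """Reference-coordinate gaps at which the target's order is broken.

    For each reference adjacency absent from the target, the interval
    between the two flanking loci (in reference coordinates) is returned;
    marker screening uses these to exclude regions overlapping breakpoints.
    """
    r, t = _shared(ref, target)
    tgt_adj = _adjacency_set([(l.label, l.sign) for l in t])
    out = []
    n = len(r)
    for idx in range(n):
        a, b = r[idx], r[(idx + 1) % n]
        key = ((a.label, a.sign), (b.label, b.sign))
        mirror = ((b.label, -b.sign), (a.label, -a.sign))
        if min(key, mirror) not in tgt_adj:
            out.append((a.end, b.start))  # may wrap for the circular pair
    return out


def rearrangement_matrix(
    genomes: list[tuple[AnnotatedGenome, QuadripartiteLayout]],
    ref_id: str,
    include_pseudogenes: bool = True,
) -> pd.DataFrame:
    """Per-genome block/inversion/translocation/breakpoint counts vs a reference.

    ``noncoding_endpoints`` records whether every non-collinear block boundary
    falls between loci (in a spacer) rather than inside an annotated gene —
    a checkable flag for the observation that structural changes tend to
    involve non-coding DNA.
    """
    orders = {
        g.id: gene_order(g, lay, include_pseudogenes) for g, lay in genomes
    }
    if ref_id not in orders:
        raise KeyError(f"reference {ref_id!r} not among genomes")
    ref = orders[ref_id]
    rows = []
    for gid, order in orders.items():
        if gid == ref_id:
            rows.append(
                {"genome": gid, "n_blocks": 1, "n_inversions": 0,
                 "n_translocations": 0, "n_breakpoints": 0,
                 "noncoding_endpoints": True}
            )
            continue
        blocks = detect_blocks(ref, order)
        n_inv = sum(1 for b in blocks if b.orientation == "inverted")
        n_tra = sum(1 for b in blocks if b.displaced)
        bps = breakpoint_count(ref, order)
        # endpoint check: block boundaries in the *target* must fall in gaps
        t = [l for l in order.loci if l.label in {x for b in blocks for x in b.loci}]
        noncoding = True
        for b in blocks:
            if b.orientation == "collinear" and not b.displaced:
                continue
            for edge_idx in (b.target_start - 1, b.target_end - 1):
                if 0 <= edge_idx < len(t) - 1:
                    left, right = t[edge_idx], t[edge_idx + 1]
                    if left.end > right.start:  # loci overlap: breakpoint in a gene
                        noncoding = False
        rows.append(
            {"genome": gid, "n_blocks": len(blocks), "n_inversions": n_inv,
             "n_translocations": n_tra, "n_breakpoints": bps,
             "noncoding_endpoints": noncoding}
        )
    return pd.DataFrame(rows)
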