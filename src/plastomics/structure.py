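"""Quadripartite layout detection, junction context, and structural summaries.

The inverted-repeat search seeds exact k-mer matches between the genome and
its reverse complement, groups them by anti-diagonal (for a true IR pair all
matching position pairs ``(p, partner)`` satisfy ``p + partner = const mod
L``), and extends the best run base-by-base around the circle.  The canonical
rotation places the LSC start at position 0 in the order LSC–IRa–SSC–IRb; of
the two strand presentations, the one whose LSC carries more forward-strand
CDS wins, ties broken lexicographically by sequence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from plastomics.io import (
    AnnotatedGenome,
    revcomp,
    reverse_complement_genome,
    rotate_genome,
)

logger = logging.getLogger("plastomics")

_COMP = dict(zip("ACGTN", "TGCAN"))


class StructureNotFoundError(ValueError):
    """No inverted repeat of the required length: genome is not quadripartite."""


@dataclass(frozen=True)
class QuadripartiteLayout:
    """Compartment intervals on the canonical rotation (0-based half-open)."""

    lsc: tuple[int, int]
    ira: tuple[int, int]
    ssc: tuple[int, int]
    irb: tuple[int, int]
    ir_identity: float

    @property
    def lsc_length(self) -> int:
        return self.lsc[1] - self.lsc[0]

    @property
    def ssc_length(self) -> int:
        return self.ssc[1] - self.ssc[0]

    @property
    def ir_length(self) -> int:
        return self.ira[1] - self.ira[0]

    @property
    def genome_length(self) -> int:
        return self.irb[1]

    def compartment_of(self, pos: int) -> str:
        for name, (s, e) in zip(
            ("LSC", "IRa", "SSC", "IRb"), (self.lsc, self.ira, self.ssc, self.irb)
        ):
            if s <= pos < e:
                return name
        raise ValueError(f"position {pos} outside genome of {self.genome_length} bp")


# ---------------------------------------------------------------------------
# IR detection
# ---------------------------------------------------------------------------

def _arcs_overlap(s1: int, len1: int, s2: int, len2: int, L: int) -> bool:
    return ((s2 - s1) % L) < len1 or ((s1 - s2) % L) < len2


def _find_ir_pair(seq: str, min_len: int, max_mismatch_frac: float, k: int):
    """Locate the maximal inverted-repeat pair on the circular sequence.

    Returns ``(a_start, length, c)``: copy A occupies ``length`` bp from
    ``a_start`` (circularly); the partner copy runs from ``(c - a_start -
    length) % L``; ``c = a_start + b_end mod L`` is the anti-diagonal.
    """
    L = len(seq)
    if L < 2 * min_len:
        raise StructureNotFoundError(
            f"genome too short ({L} bp) for an IR of >= {min_len} bp"
        )
    doubled = seq + seq[: k - 1]
    rc = revcomp(seq)
    rc_doubled = rc + rc[: k - 1]
    index: dict[str, list[int]] = {}
    for r in range(L):
        index.setdefault(rc_doubled[r : r + k], []).append(r)

    diagonals: dict[int, list[int]] = {}
    for p in range(L):
        for r in index.get(doubled[p : p + k], ()):
            q = (L - r - k) % L  # partner window start on the forward strand
            if p == q:
                continue
            c = (p + q + k) % L
            diagonals.setdefault(c, []).append(p)

    def match(p: int, c: int) -> bool:
        partner = (c - 1 - p) % L
        if partner == p % L:
            return False
        return _COMP[seq[p % L]] == seq[partner]

    min_seeds = max(1, min_len - k + 1) if max_mismatch_frac == 0 else 1
    best = None
    for c, ps in sorted(diagonals.items(), key=lambda kv: -len(kv[1])):
        if len(ps) < min_seeds:
            break
        if best is not None and len(ps) + 2 * k < best[1] - 2 * k:
            continue  # cannot beat the current best
        p0 = ps[0]
        lo, hi = p0, p0 + k
        mism = 0
        while hi - lo < L // 2 + 1:
            if match(hi, c):
                hi += 1
            elif max_mismatch_frac > 0 and (mism + 1) <= max_mismatch_frac * (hi - lo + 1):
                mism += 1
                hi += 1
            else:
                break
        while hi > lo and not match(hi - 1, c):
            hi -= 1
        while hi - lo < L // 2 + 1:
            if match(lo - 1, c):
                lo -= 1
            elif max_mismatch_frac > 0 and (mism + 1) <= max_mismatch_frac * (hi - lo + 1):
                mism += 1
                lo -= 1
            else:
                break
        while hi > lo and not match(lo, c):
            lo += 1
        length = hi - lo
        if length < min_len or length > L // 2:
            continue
        a_start = lo % L
        b_start = (c - hi) % L
        if _arcs_overlap(a_start, length, b_start, length, L):
            continue
        if best is None or length > best[1]:
            best = (a_start, length, c)
    if best is None:
        raise StructureNotFoundError(
            f"no inverted repeat of >= {min_len} bp found (non-quadripartite genome)"
        )
    return best


def _ir_identity(seq: str, ira: tuple[int, int], irb: tuple[int, int]) -> float:
    a = seq[ira[0] : ira[1]]
    b = revcomp(seq[irb[0] : irb[1]])
    same = sum(1 for x, y in zip(a, b) if x == y)
    return same / max(len(a), 1)


def canonicalize(
    genome: AnnotatedGenome,
    min_len: int = 1000,
    max_mismatch_frac: float = 0.0,
    k: int = 21,
) -> tuple[AnnotatedGenome, QuadripartiteLayout]:
    """Rotate/flip a genome into the canonical LSC–IRa–SSC–IRb presentation."""
    L = genome.length
    a_start, ir_len, c = _find_ir_pair(genome.sequence, min_len, max_mismatch_frac, k)
    a_end = (a_start + ir_len) % L
    b_start = (c - a_start - ir_len) % L
    b_end = (c - a_start) % L
    glen_ab = (b_start - a_end) % L  # gap from copy A end to copy B start
    glen_ba = (a_start - b_end) % L
    if glen_ab >= glen_ba:
        lsc_start, lsc_len, ssc_len = a_end, glen_ab, glen_ba
    else:
        lsc_start, lsc_len, ssc_len = b_end, glen_ba, glen_ab

    def build(g: AnnotatedGenome, start: int):
        rot = rotate_genome(g, start)
        l1 = lsc_len
        l2 = l1 + ir_len
        l3 = l2 + ssc_len
        layout = QuadripartiteLayout(
            lsc=(0, l1),
            ira=(l1, l2),
            ssc=(l2, l3),
            irb=(l3, L),
            ir_identity=_ir_identity(rot.sequence, (l1, l2), (l3, L)),
        )
        return rot, layout

    fwd, fwd_layout = build(genome, lsc_start)
    rcg = reverse_complement_genome(genome)
    rev, rev_layout = build(rcg, (L - (lsc_start + lsc_len)) % L)

    def n_forward_cds(g: AnnotatedGenome) -> int:
        return sum(
            1
            for f in g.features
            if f.kind == "CDS" and f.strand == "+" and f.span(L)[1] <= lsc_len
        )

    nf, nr = n_forward_cds(fwd), n_forward_cds(rev)
    if nf != nr:
        return (fwd, fwd_layout) if nf > nr else (rev, rev_layout)
    return (fwd, fwd_layout) if fwd.sequence <= rev.sequence else (rev, rev_layout)


def find_inverted_repeats(
    genome: AnnotatedGenome,
    min_len: int = 1000,
    max_mismatch_frac: float = 0.0,
    k: int = 21,
) -> QuadripartiteLayout:
    """Layout of the maximal inverted-repeat pair, on the canonical rotation."""
    _, layout = canonicalize(genome, min_len, max_mismatch_frac, k)
    return layout


# ---------------------------------------------------------------------------
# Junction context
# ---------------------------------------------------------------------------

JUNCTION_NAMES = ("LSC-IRa", "IRa-SSC", "SSC-IRb", "IRb-LSC")


@dataclass(frozen=True)
class JunctionSide:
    """Nearest feature on one flank; a negative distance is the number of bp
    by which that feature overlaps the junction."""

    feature: str | None
    distance: int | None


def junction_context(genome: AnnotatedGenome, layout: QuadripartiteLayout) -> dict:
    """Nearest feature on each flank of the four compartment junctions.

    Returns ``{junction_name: {"left": JunctionSide, "right": JunctionSide}}``.
    The left distance is ``junction - feature_end``, the right distance
    ``feature_start - junction``; a feature spanning a junction appears on
    both flanks with its two (negative) overlap extents.
    """
    L = genome.length
    junctions = [layout.lsc[1], layout.ira[1], layout.ssc[1], L]
    spans = []
    for f in genome.features:
        s, e = f.span(L)
        if e <= s:
            e += L  # wrapping feature, unrolled
        spans.append((s, e, f.label))

    report = {}
    for name, j in zip(JUNCTION_NAMES, junctions):
        best_left = best_right = None
        for s, e, label in spans:
            # consider the feature at its three circular unrollings
            for off in (-L, 0, L):
                ss, ee = s + off, e + off
                if ss < j:  # candidate for the left flank
                    d = j - ee
                    if -(ee - ss) < d and (best_left is None or d < best_left[0]):
                        best_left = (d, label)
                if ee > j:  # candidate for the right flank
                    d = ss - j
                    if -(ee - ss) < d and (best_right is None or d < best_right[0]):
                        best_right = (d, label)
        report[name] = {
            "left": JunctionSide(best_left[1], best_left[0]) if best_left else JunctionSide(None, None),
            "right": JunctionSide(best_right[1], best_right[0]) if best_right else JunctionSide(None, None),
        }
    return report


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def round_half_up(x: float, ndigits: int = 1) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class GenomeSummary:
    genome_id: str
    total_length: int
    lsc_length: int
    ssc_length: int
    ir_length: int
    gc_percent: float
    n_cds: int  # distinct (name, copy_tag) functional CDS features
    n_trna: int
    n_rrna: int
    n_cds_unique: int  # IR duplicates and other copies counted once
    n_trna_unique: int
    n_rrna_unique: int
    pseudogenes: tuple[str, ...]


def genome_summary(genome: AnnotatedGenome, layout: QuadripartiteLayout) -> GenomeSummary:
    """Structural summary: lengths, GC% (one decimal, half-up), gene counts.

    Counts are reported under both conventions — every (name, copy) feature,
    and unique locus names — since gene totals in the literature are quoted
    either way.  Pseudogenes are excluded from CDS counts and listed.
    """
    seq = genome.sequence
    gc = 100.0 * (seq.count("G") + seq.count("C")) / len(seq)
    counts = {"CDS": set(), "tRNA": set(), "rRNA": set()}
    pseudo = []
    for f in genome.features:
        if f.kind == "pseudogene":
            pseudo.append(f.label)
        elif f.kind in counts:
            counts[f.kind].add((f.name, f.copy_tag))
    return GenomeSummary(
        genome_id=genome.id,
        total_length=genome.length,
        lsc_length=layout.lsc_length,
        ssc_length=layout.ssc_length,
        ir_length=layout.ir_length,
        gc_percent=round_half_up(gc, 1),
        n_cds=len(counts["CDS"]),
        n_trna=len(counts["tRNA"]),
        n_rrna=len(counts["rRNA"]),
        n_cds_unique=len({n for n, _ in counts["CDS"]}),
        n_trna_unique=len({n for n, _ in counts["tRNA"]}),
        n_rrna_unique=len({n for n, _ in counts["rRNA"]}),
        pseudogenes=tuple(sorted(pseudo)),
    )


def cross_species_structure_table(
    genomes: list[AnnotatedGenome],
    min_len: int = 1000,
    max_mismatch_frac: float = 0.0,
    k: int = 21,
) -> pd.DataFrame:
    """One row per genome: summary fields plus junction gene context.

    Genomes in which no qualifying IR is found are flagged
    (``quadripartite=False``) and the remaining fields left missing; the
    comparison continues for the others.
    """
    if len(genomes) < 2:
        raise ValueError("need at least two genomes to compare")
    rows = []
    for g in genomes:
        row: dict = {"genome": g.id, "quadripartite": True}
        try:
            canon, layout = canonicalize(g, min_len, max_mismatch_frac, k)
        except StructureNotFoundError as exc:
            logger.warning("%s: %s", g.id, exc)
            row.update({"quadripartite": False})
            rows.append(row)
            continue
        summ = genome_summary(canon, layout)
        row.update(
            total_length=summ.total_length,
            lsc_length=summ.lsc_length,
            ssc_length=summ.ssc_length,
            ir_length=summ.ir_length,
            gc_percent=summ.gc_percent,
            n_cds=summ.n_cds,
            n_trna=summ.n_trna,
            n_rrna=summ.n_rrna,
            n_cds_unique=summ.n_cds_unique,
            pseudogenes=";".join(summ.pseudogenes),
            ir_identity=layout.ir_identity,
        )
        jc = junction_context(canon, layout)
        for jname, sides in jc.items():
            row[f"{jname}:left"] = sides["left"].feature
            row[f"{jname}:left_dist"] = sides["left"].distance
            row[f"{jname}:right"] = sides["right"].feature
            row[f"{jname}:right_dist"] = sides["right"].distance
        rows.append(row)
    return pd.DataFrame(rows)


def structure_table_from_files(paths, **kwargs) -> pd.DataFrame:
    """Convenience wrapper: GenBank files in, structure comparison table out."""
    from plastomics.io import read_genbank

    return cross_species_structure_table([read_genbank(p) for p in paths], **kwargs)
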