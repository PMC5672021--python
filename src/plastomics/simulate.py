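"""Synthetic annotated plastomes with planted, replayable ground truth.

The generator builds an ancestral quadripartite genome from a gene template,
then evolves it along a rooted tree: per-branch nucleotide substitutions
(JC69 or K80), spacer-restricted indels, and structural events (inversions,
IR boundary shifts, gene loss, pseudogenization).  Every event is recorded in
an :class:`EventLog` so downstream detectors can be tested against truth.

Internal representation
-----------------------
A genome is carried as its *core* — LSC + IRa + SSC — plus the two IR
boundaries.  IRb is always materialized as the exact reverse complement of
IRa, with mirror features derived from the core annotation.  This gives IR
lockstep evolution (the homogenization observed in real plastomes) by
construction; disabling lockstep applies an extra, independent round of
substitutions to the materialized IRb.

IR expansion is a pure boundary move: the IR unit absorbs the SSC head, so
the absorbed tract (and any gene in it) is duplicated into IRb, the SSC
shrinks by ``amount``, each IR grows by ``amount`` and the genome grows by
``amount`` — the duplication mechanism that makes IR-expanded plastomes
larger than their relatives.  A gene split by the new boundary keeps its
full-length copy spanning the IRa/SSC junction while its truncated mirror
fragment is flagged as a pseudogene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import dendropy
import numpy as np

from plastomics.io import (
    AnnotatedGenome,
    Feature,
    assign_copy_tags,
    order_segments,
    revcomp,
    write_genbank,
)

logger = logging.getLogger("plastomics")

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
_CODE[ord("N")] = 0  # generator sequences are N-free; defensive only


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)].astype(np.uint8)


def _decode(arr: np.ndarray) -> str:
    return _BASES[arr].tobytes().decode()


def _revcomp_arr(arr: np.ndarray) -> np.ndarray:
    return (3 - arr)[::-1]


# ---------------------------------------------------------------------------
# Templates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneSpec:
    name: str
    kind: str  # CDS | tRNA | rRNA
    length: int  # total exonic length, bp
    strand: str
    compartment: str  # LSC | IR | SSC
    introns: tuple[int, ...] = ()  # intron lengths, bp


@dataclass
class TemplateMap:
    """Ordered gene/spacer layout instantiating a quadripartite plastome."""

    profile: str
    gene_table: list[GeneSpec]
    spacer_lengths: dict[str, list[int]]  # compartment -> spacer lengths
    ir_gene_set: frozenset[str]
    total_range: tuple[int, int]
    ir_range: tuple[int, int]


# (name, kind, length, strand, introns) per compartment.  Lengths are
# plausible angiosperm values; CDS lengths are forced to a multiple of 3.
_DEFAULT_LSC = [
    ("trnH-GUG", "tRNA", 75, "+", ()), ("psbA", "CDS", 1062, "+", ()),
    ("trnK-UUU", "tRNA", 72, "+", (2520,)), ("matK", "CDS", 1530, "+", ()),
    ("rps16", "CDS", 261, "+", (870,)), ("trnQ-UUG", "tRNA", 72, "+", ()),
    ("trnQ-UUG", "tRNA", 72, "+", (150,)), ("psbK", "CDS", 186, "+", ()),
    ("psbI", "CDS", 111, "+", ()), ("trnS-GCU", "tRNA", 88, "+", ()),
    ("trnG-UCC", "tRNA", 71, "-", (690,)), ("trnR-UCU", "tRNA", 72, "-", ()),
    ("atpA", "CDS", 1524, "+", ()), ("atpF", "CDS", 555, "+", (720,)),
    ("atpH", "CDS", 246, "+", ()), ("atpI", "CDS", 744, "+", ()),
    ("rps2", "CDS", 711, "+", ()), ("rpoC2", "CDS", 4140, "+", ()),
    ("rpoC1", "CDS", 2052, "+", (750,)), ("rpoB", "CDS", 3213, "+", ()),
    ("trnC-GCA", "tRNA", 71, "-", ()), ("petN", "CDS", 90, "-", ()),
    ("psbM", "CDS", 105, "+", ()), ("trnD-GUC", "tRNA", 74, "+", ()),
    ("trnY-GUA", "tRNA", 84, "+", ()), ("trnE-UUC", "tRNA", 73, "+", ()),
    ("trnT-GGU", "tRNA", 72, "-", ()), ("psbD", "CDS", 1062, "-", ()),
    ("psbC", "CDS", 1386, "-", ()), ("trnS-UGA", "tRNA", 93, "+", ()),
    ("psbZ", "CDS", 189, "-", ()), ("trnfM-CAU", "tRNA", 74, "+", ()),
    ("rps14", "CDS", 303, "+", ()), ("psaB", "CDS", 2205, "+", ()),
    ("psaA", "CDS", 2253, "+", ()), ("ycf3", "CDS", 507, "+", (740, 780)),
    ("trnS-GGA", "tRNA", 87, "+", ()), ("rps4", "CDS", 606, "+", ()),
    ("trnT-UGU", "tRNA", 73, "+", ()), ("trnL-UAA", "tRNA", 85, "-", (500,)),
    ("trnF-GAA", "tRNA", 73, "-", ()), ("ndhJ", "CDS", 477, "+", ()),
    ("ndhK", "CDS", 678, "+", ()), ("ndhC", "CDS", 363, "+", ()),
    ("trnV-UAC", "tRNA", 72, "+", (590,)), ("trnM-CAU", "tRNA", 74, "-", ()),
    ("atpE", "CDS", 402, "+", ()), ("atpB", "CDS", 1497, "+", ()),
    ("rbcL", "CDS", 1428, "-", ()), ("accD", "CDS", 1464, "-", ()),
    ("psaI", "CDS", 111, "-", ()), ("ycf4", "CDS", 555, "-", ()),
    ("cemA", "CDS", 690, "-", ()), ("petA", "CDS", 963, "-", ()),
    ("psbJ", "CDS", 123, "+", ()), ("psbL", "CDS", 117, "+", ()),
    ("psbF", "CDS", 120, "+", ()), ("psbE", "CDS", 252, "+", ()),
    ("petL", "CDS", 96, "-", ()), ("petG", "CDS", 114, "-", ()),
    ("trnW-CCA", "tRNA", 74, "+", ()), ("trnP-UGG", "tRNA", 74, "+", ()),
    ("psaJ", "CDS", 129, "-", ()), ("rpl33", "CDS", 201, "-", ()),
    ("rps18", "CDS", 306, "-", ()), ("rpl20", "CDS", 354, "+", ()),
    ("rps12_5end", "CDS", 114, "+", ()), ("clpP", "CDS", 591, "+", (800, 620)),
    ("psbB", "CDS", 1527, "-", ()), ("psbT", "CDS", 108, "-", ()),
    ("psbN", "CDS", 132, "+", ()), ("psbH", "CDS", 222, "-", ()),
    ("petB", "CDS", 648, "-", (750,)), ("petD", "CDS", 483, "-", (700,)),
    ("rpoA", "CDS", 1014, "+", ()), ("rps11", "CDS", 417, "+", ()),
    ("rpl36", "CDS", 114, "+", ()), ("infA", "CDS", 234, "+", ()),
    ("rps8", "CDS", 405, "+", ()), ("rpl14", "CDS", 369, "+", ()),
    ("rpl16", "CDS", 408, "+", (1000,)), ("rps3", "CDS", 657, "+", ()),
    ("rpl22", "CDS", 360, "+", ()), ("rps19", "CDS", 279, "+", ()),
]
_DEFAULT_IR = [
    ("rpl2", "CDS", 1491, "+", (660,)), ("rpl23", "CDS", 282, "+", ()),
    ("trnI-CAU", "tRNA", 74, "+", ()), ("ycf2", "CDS", 6912, "-", ()),
    ("trnL-CAA", "tRNA", 81, "+", ()), ("ndhB", "CDS", 1533, "+", (680,)),
    ("rps7", "CDS", 468, "+", ()), ("rps12_3end", "CDS", 354, "+", ()),
    ("trnV-GAC", "tRNA", 72, "-", ()), ("rrn16", "rRNA", 1491, "-", ()),
    ("trnI-GAU", "tRNA", 72, "-", (940,)), ("trnA-UGC", "tRNA", 73, "-", (800,)),
    ("rrn23", "rRNA", 2810, "-", ()), ("rrn4.5", "rRNA", 103, "-", ()),
    ("rrn5", "rRNA", 121, "-", ()), ("trnR-ACG", "tRNA", 74, "-", ()),
    ("trnN-GUU", "tRNA", 72, "+", ()),
]
_DEFAULT_SSC = [
    ("ycf1", "CDS", 5580, "-", ()), ("rps15", "CDS", 273, "-", ()),
    ("ndhH", "CDS", 1182, "+", ()), ("ndhA", "CDS", 1080, "+", (1070,)),
    ("ndhI", "CDS", 504, "+", ()), ("ndhG", "CDS", 531, "+", ()),
    ("ndhE", "CDS", 306, "+", ()), ("psaC", "CDS", 246, "+", ()),
    ("ndhD", "CDS", 1503, "+", ()), ("ccsA", "CDS", 960, "-", ()),
    ("trnL-UAG", "tRNA", 80, "-", ()), ("rpl32", "CDS", 174, "-", ()),
    ("ndhF", "CDS", 2235, "+", ()),
]

_REDUCED_LSC = [
    ("trnH-GUG", "tRNA", 75, "+", ()), ("psbA", "CDS", 900, "+", ()),
    ("trnQ-UUG", "tRNA", 72, "+", ()), ("trnQ-UUG", "tRNA", 72, "+", (150,)),
    ("atpA", "CDS", 900, "+", ()), ("atpF", "CDS", 450, "+", (450,)),
    ("rpoB", "CDS", 900, "+", ()), ("trnC-GCA", "tRNA", 71, "-", ()),
    ("petN", "CDS", 90, "-", ()), ("psbM", "CDS", 105, "+", ()),
    ("trnG-UCC", "tRNA", 71, "-", (620,)), ("rbcL", "CDS", 900, "+", ()),
    ("psbJ", "CDS", 123, "+", ()), ("psbE", "CDS", 252, "+", ()),
    ("clpP", "CDS", 450, "+", (650, 380)), ("psbB", "CDS", 900, "+", ()),
]
_REDUCED_IR = [
    ("rpl2", "CDS", 750, "+", (350,)), ("trnV-GAC", "tRNA", 72, "-", ()),
    ("rrn16", "rRNA", 1200, "-", ()), ("rrn23", "rRNA", 1400, "-", ()),
]
_REDUCED_SSC = [
    ("ycf1", "CDS", 930, "-", ()), ("rps15", "CDS", 273, "-", ()),
    ("ndhA", "CDS", 660, "+", (700,)), ("rpl32", "CDS", 174, "-", ()),
    ("trnL-UAG", "tRNA", 80, "-", ()), ("ndhF", "CDS", 750, "+", ()),
]

# Intergenic spacers are drawn from a long/short mixture: real plastomes mix
# short gaps inside operon-like gene clusters with PCR-amplifiable spacers of
# 500-1100 bp between clusters, and the marker screen needs both kinds.
_PROFILES = {
    "default": dict(
        lsc=_DEFAULT_LSC, ir=_DEFAULT_IR, ssc=_DEFAULT_SSC,
        spacer_long_frac={"LSC": 0.32, "IR": 0.28, "SSC": 0.32},
        spacer_long=(480, 900), spacer_short=(80, 280),
        head_spacer=200, ssc_tail_spacer=900,
        total_range=(120_000, 165_000), ir_range=(20_000, 31_000),
    ),
    "reduced": dict(
        lsc=_REDUCED_LSC, ir=_REDUCED_IR, ssc=_REDUCED_SSC,
        spacer_long_frac={"LSC": 0.35, "IR": 0.20, "SSC": 0.35},
        spacer_long=(500, 700), spacer_short=(70, 180),
        head_spacer=150, ssc_tail_spacer=800,
        total_range=(15_000, 30_000), ir_range=(3_000, 9_000),
    ),
}

# Spacer lengths are a fixed property of each profile (drawn once from a
# profile-local RNG) so that planted event coordinates are reproducible
# across user seeds; only sequence content varies with the user seed.
_SPACER_SEED = 202017


def _spacer_lengths(profile_cfg, n_by_comp):
    rng = np.random.default_rng(_SPACER_SEED)
    out = {}
    lo_l, hi_l = profile_cfg["spacer_long"]
    lo_s, hi_s = profile_cfg["spacer_short"]
    for comp, n in n_by_comp.items():
        frac = profile_cfg["spacer_long_frac"][comp]
        is_long = rng.random(n) < frac
        longs = rng.integers(lo_l, hi_l, size=n)
        shorts = rng.integers(lo_s, hi_s, size=n)
        out[comp] = np.where(is_long, longs, shorts).tolist()
    return out


def build_template(profile: str = "default", seed: int = 0):
    """Instantiate a profile into a TemplateMap and its ancestral genome.

    The ancestor is canonical (LSC at 0, order LSC-IRa-SSC-IRb), the two IRs
    are exact reverse complements, and junction-adjacent spacer bases are
    pinned so the planted IR is the maximal inverted repeat.
    """
    if profile not in _PROFILES:
        raise ValueError(f"unknown profile {profile!r}")
    cfg = _PROFILES[profile]
    rng = np.random.default_rng(seed)

    table: list[GeneSpec] = []
    for comp, rows in (("LSC", cfg["lsc"]), ("IR", cfg["ir"]), ("SSC", cfg["ssc"])):
        for name, kind, length, strand, introns in rows:
            if kind == "CDS":
                length += (-length) % 3
            table.append(GeneSpec(name, kind, length, strand, comp, tuple(introns)))

    n_by_comp = {
        "LSC": sum(1 for g in table if g.compartment == "LSC") + 1,
        "IR": sum(1 for g in table if g.compartment == "IR") + 1,
        "SSC": sum(1 for g in table if g.compartment == "SSC") + 1,
    }
    spacers = _spacer_lengths(cfg, n_by_comp)
    spacers["LSC"][0] = cfg["head_spacer"]
    spacers["SSC"][0] = cfg["head_spacer"]
    spacers["SSC"][-1] = cfg["ssc_tail_spacer"]

    core_parts: list[str] = []
    feats: list[Feature] = []
    pos = 0
    boundaries = {}

    def _random_dna(n):
        return _decode(rng.integers(0, 4, size=n).astype(np.uint8))

    def _gene_sequence(spec: GeneSpec):
        """Return (span_sequence, exon_segments_relative) for one gene."""
        if spec.kind == "CDS":
            coding = "ATG" + _random_dna(spec.length - 6) + "TAA"
        else:
            coding = _random_dna(spec.length)
        if not spec.introns:
            return coding, [(0, spec.length)]
        n_ex = len(spec.introns) + 1
        cut = np.linspace(0, spec.length, n_ex + 1).astype(int)
        exons = [coding[cut[i]: cut[i + 1]] for i in range(n_ex)]
        parts, segs, off = [], [], 0
        for i, ex in enumerate(exons):
            segs.append((off, off + len(ex)))
            parts.append(ex)
            off += len(ex)
            if i < len(spec.introns):
                parts.append(_random_dna(spec.introns[i]))
                off += spec.introns[i]
        return "".join(parts), segs

    for comp in ("LSC", "IR", "SSC"):
        comp_start = pos
        genes = [g for g in table if g.compartment == comp]
        sp = spacers[comp]
        for i, gene in enumerate(genes):
            core_parts.append(_random_dna(sp[i]))
            pos += sp[i]
            span_seq, rel_segs = _gene_sequence(gene)
            if gene.strand == "-":
                span_seq = revcomp(span_seq)
                span_len = len(span_seq)
                rel_segs = [(span_len - e, span_len - s) for s, e in rel_segs]
            segs = order_segments(
                (pos + s, pos + e, gene.strand) for s, e in rel_segs
            )
            feats.append(Feature(gene.name, gene.kind, segs))
            core_parts.append(span_seq)
            pos += len(span_seq)
        core_parts.append(_random_dna(sp[len(genes)]))
        pos += sp[len(genes)]
        boundaries[comp] = (comp_start, pos)

    core = "".join(core_parts)
    l1 = boundaries["LSC"][1]
    l2 = boundaries["IR"][1]
    state = _State(_encode(core), feats, l1, l2)
    _pin_junctions(state)

    tm = TemplateMap(
        profile=profile,
        gene_table=table,
        spacer_lengths=spacers,
        ir_gene_set=frozenset(g.name for g in table if g.compartment == "IR"),
        total_range=cfg["total_range"],
        ir_range=cfg["ir_range"],
    )
    ancestor = _materialize(state, "ancestor")
    L = ancestor.length
    lo, hi = tm.total_range
    if not lo <= L <= hi:
        raise ValueError(f"template length {L} outside profile range {tm.total_range}")
    ir_len = l2 - l1
    if not tm.ir_range[0] <= ir_len <= tm.ir_range[1]:
        raise ValueError(f"IR length {ir_len} outside {tm.ir_range}")
    return tm, ancestor


# ---------------------------------------------------------------------------
# Core state and materialization
# ---------------------------------------------------------------------------

@dataclass
class _State:
    """Core genome (LSC+IRa+SSC) with IR boundaries; IRb is derived."""

    seq: np.ndarray  # uint8 codes, length l3
    feats: list[Feature]  # core features only
    l1: int
    l2: int

    @property
    def l3(self) -> int:
        return len(self.seq)

    def copy(self) -> "_State":
        return _State(self.seq.copy(), list(self.feats), self.l1, self.l2)


def _pin_junctions(state: _State) -> None:
    """Make IR boundary extension impossible by pinning one flank base.

    A base can never equal its own complement, so setting the LSC head base
    equal to the LSC tail base (and the SSC tail base equal to the SSC head
    base) guarantees the planted IR is maximal.  All four pinned positions
    lie in spacers by template construction.
    """
    state.seq[0] = state.seq[state.l1 - 1]
    state.seq[state.l3 - 1] = state.seq[state.l2]


def _materialize(state: _State, genome_id: str) -> AnnotatedGenome:
    """Build the full circular genome: core + IRb mirror (sequence + features)."""
    l1, l2, l3 = state.l1, state.l2, state.l3
    full = np.concatenate([state.seq, _revcomp_arr(state.seq[l1:l2])])
    feats = list(state.feats)
    for f in state.feats:
        s, e = f.span(l3)
        if e <= l1 or s >= l2:
            continue
        partial = s < l1 or e > l2
        msegs = []
        for ss, ee, st in f.segments:
            cs, ce = max(ss, l1), min(ee, l2)
            if ce <= cs:
                continue
            ms, me = l3 + (l2 - ce), l3 + (l2 - cs)
            msegs.append((ms, me, "-" if st == "+" else "+"))
        if not msegs:
            continue
        msegs = order_segments(msegs)
        kind = "pseudogene" if partial else f.kind
        feats.append(Feature(f.name, kind, tuple(msegs), copy_tag=f.copy_tag))
    genome = AnnotatedGenome(genome_id, _decode(full), feats)
    assign_copy_tags(genome)
    return genome


def _state_boundaries(state: _State) -> tuple[int, int, int, int]:
    L = state.l3 + (state.l2 - state.l1)
    return state.l1, state.l2, state.l3, L


# ---------------------------------------------------------------------------
# Substitutions and indels
# ---------------------------------------------------------------------------

def _jc69_p(t: float) -> float:
    return 0.75 * (1.0 - np.exp(-4.0 * t / 3.0))


def _k80_probs(t: float, kappa: float) -> tuple[float, float]:
    """(P(transition), P(one specific transversion)) after branch length t."""
    e1 = np.exp(-4.0 * t / (kappa + 2.0))
    e2 = np.exp(-2.0 * (kappa + 1.0) * t / (kappa + 2.0))
    p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
    p_tv = 0.25 - 0.25 * e1
    return float(p_ts), float(p_tv)


def _substitute(arr: np.ndarray, t: float, model: str, kappa: float,
                rng: np.random.Generator, mask: np.ndarray) -> None:
    """Apply substitutions in place to positions where mask is True."""
    if t <= 0 or not mask.any():
        return
    idx = np.flatnonzero(mask)
    if model == "JC69":
        p = _jc69_p(t)
        hit = idx[rng.random(idx.size) < p]
        if hit.size:
            shift = rng.integers(1, 4, size=hit.size).astype(np.uint8)
            arr[hit] = (arr[hit] + shift) % 4
    elif model == "K80":
        p_ts, p_tv = _k80_probs(t, kappa)
        u = rng.random(idx.size)
        ts_hit = idx[u < p_ts]
        tv_hit = idx[(u >= p_ts) & (u < p_ts + 2 * p_tv)]
        arr[ts_hit] ^= 2  # A<->G, C<->T
        if tv_hit.size:
            pick = rng.integers(0, 2, size=tv_hit.size).astype(np.uint8)
            arr[tv_hit] = (arr[tv_hit] ^ 1) ^ (pick * 2)
    else:
        raise ValueError(f"unknown substitution model {model!r}")


def mutate_sequence(seq: str, t: float, model: str = "JC69", kappa: float = 2.0,
                    rng: np.random.Generator | None = None) -> str:
    """Evolve a bare sequence for branch length ``t`` (exposed for calibration)."""
    rng = rng or np.random.default_rng()
    arr = _encode(seq)
    _substitute(arr, t, model, kappa, rng, np.ones(arr.size, dtype=bool))
    return _decode(arr)


def _coding_mask(state: _State) -> np.ndarray:
    """True at exonic positions of functional loci in the core."""
    mask = np.zeros(state.l3, dtype=bool)
    for f in state.feats:
        if f.kind == "pseudogene":
            continue
        for s, e, _ in f.segments:
            mask[s:e] = True
    return mask


def _spacer_intervals(state: _State, margin: int = 4) -> list[tuple[int, int]]:
    """Intergenic intervals of LSC and SSC eligible for indels."""
    spans = sorted(f.span(state.l3) for f in state.feats)
    out = []
    prev = 0
    for s, e in spans + [(state.l3, state.l3)]:
        if s - prev > 2 * margin:
            out.append((prev + margin, s - margin))
        prev = max(prev, e)
    # exclude anything touching the IR or the pinned junction flanks
    trimmed = []
    for s, e in out:
        if s < state.l1 and e > state.l1:
            e = state.l1 - margin
        if s < state.l2 and e > state.l2:
            s = state.l2 + margin
        if e <= s:
            continue
        if s >= state.l1 and e <= state.l2:
            continue  # IR spacers evolve in lockstep; no indels there
        trimmed.append((max(s, margin), min(e, state.l3 - margin)))
    return [(s, e) for s, e in trimmed if e > s]


def _shift_features(feats: list[Feature], pos: int, delta: int) -> list[Feature]:
    out = []
    for f in feats:
        segs = tuple(
            (s + delta if s >= pos else s, e + delta if e > pos else e, st)
            for s, e, st in f.segments
        )
        out.append(replace(f, segments=segs))
    return out


def _apply_indels(state: _State, t: float, indel_rate: float, indel_p: float,
                  rng: np.random.Generator) -> int:
    """Spacer-restricted insertions/deletions; returns the number applied."""
    if indel_rate <= 0 or t <= 0:
        return 0
    spacers = _spacer_intervals(state)
    if not spacers:
        return 0
    site_total = sum(e - s for s, e in spacers)
    n = rng.poisson(indel_rate * t * site_total)
    applied = 0
    for _ in range(n):
        spacers = _spacer_intervals(state)
        if not spacers:
            break
        weights = np.array([e - s for s, e in spacers], dtype=float)
        k = rng.choice(len(spacers), p=weights / weights.sum())
        s, e = spacers[k]
        length = int(rng.geometric(indel_p))
        if rng.random() < 0.5:  # insertion
            pos = int(rng.integers(s, e))
            ins = rng.integers(0, 4, size=length).astype(np.uint8)
            state.seq = np.concatenate([state.seq[:pos], ins, state.seq[pos:]])
            delta = length
        else:  # deletion, clipped to the spacer
            length = min(length, e - s - 1)
            if length <= 0:
                continue
            pos = int(rng.integers(s, e - length))
            state.seq = np.concatenate([state.seq[:pos], state.seq[pos + length:]])
            delta = -length
        state.feats = _shift_features(state.feats, pos, delta)
        if pos < state.l1:
            state.l1 += delta
            state.l2 += delta
        elif pos < state.l2:
            raise AssertionError("indel placed inside the IR")
        applied += 1
    return applied


# ---------------------------------------------------------------------------
# Structural events
# ---------------------------------------------------------------------------

class GenerationError(ValueError):
    """A structural event could not be applied where the template requires."""


@dataclass(frozen=True)
class Event:
    """A planted structural event, addressed to a branch of the tree.

    ``branch`` is a tip label or a frozenset of tip labels (the event applies
    on the edge above the MRCA of those tips).
    """

    branch: object
    kind: str  # inversion | ir_expansion | ir_contraction | gene_loss | pseudogenization
    params: dict = field(default_factory=dict)


@dataclass(frozen=True)
class EventRecord:
    branch: str
    kind: str
    details: dict


def _locus_span(state: _State, name: str) -> tuple[int, int]:
    cands = [f for f in state.feats if f.name == name]
    if not cands:
        raise GenerationError(f"locus {name} not present")
    f = min(cands, key=lambda g: g.segments[0][0])
    return f.span(state.l3)


def _spacer_midpoint(state: _State, coord: int, side: str) -> int:
    """Midpoint of the intergenic gap adjacent to ``coord`` on ``side``."""
    spans = sorted(f.span(state.l3) for f in state.feats)
    if side == "left":
        left_end = max((e for s, e in spans if e <= coord), default=0)
        gap = (left_end, coord)
    else:
        right_start = min((s for s, e in spans if s >= coord), default=state.l3)
        gap = (coord, right_start)
    if gap[1] - gap[0] < 2:
        raise GenerationError(f"no spacer room at {coord} ({side})")
    return (gap[0] + gap[1]) // 2


def _apply_inversion(state: _State, first: str, last: str) -> dict:
    """Invert the tract from the spacer before ``first`` to the one after ``last``."""
    s_first, _ = _locus_span(state, first)
    _, e_last = _locus_span(state, last)
    if e_last <= s_first:
        raise GenerationError(f"inversion block {first}..{last} is not forward-ordered")
    a = _spacer_midpoint(state, s_first, "left")
    b = _spacer_midpoint(state, e_last, "right")
    for f in state.feats:
        s, e = f.span(state.l3)
        if s < a < e or s < b < e:
            raise GenerationError(f"inversion endpoint inside locus {f.label}")
    same_comp = (b <= state.l1) or (a >= state.l1 and b <= state.l2) or a >= state.l2
    if not same_comp:
        raise GenerationError("inversion crosses a compartment boundary")
    state.seq[a:b] = _revcomp_arr(state.seq[a:b])
    newfeats = []
    affected = []
    for f in state.feats:
        s, e = f.span(state.l3)
        if e <= a or s >= b:
            newfeats.append(f)
            continue
        segs = order_segments(
            (a + b - ee, a + b - ss, "-" if st == "+" else "+")
            for ss, ee, st in f.segments
        )
        newfeats.append(replace(f, segments=segs))
        affected.append(f.label)
    state.feats = newfeats
    comp = "LSC" if b <= state.l1 else ("IR" if b <= state.l2 else "SSC")
    return {"start": a, "end": b, "compartment": comp, "loci": sorted(affected)}


def _apply_ir_shift_state(state: _State, direction: str, amount: int) -> dict:
    l1, l2, l3 = state.l1, state.l2, state.l3
    if direction == "expand_into_ssc":
        if amount >= l3 - l2:
            raise GenerationError(
                f"expansion {amount} would exhaust the SSC ({l3 - l2} bp)"
            )
        new_l2 = l2 + amount
        absorbed, split = [], []
        for f in state.feats:
            s, e = f.span(l3)
            if l2 <= s and e <= new_l2:
                absorbed.append(f.label)
            elif s < new_l2 < e:
                split.append(f.label)
        state.l2 = new_l2
        _pin_junctions(state)
        return {
            "amount": amount, "absorbed": absorbed,
            "split_pseudogene": split,
        }
    if direction == "contract":
        if amount >= l2 - l1:
            raise GenerationError("contraction exceeds IR length")
        released = []
        for f in state.feats:
            s, e = f.span(l3)
            if s < l2 and e > l2 - amount:
                released.append(f.label)
        state.l2 = l2 - amount
        _pin_junctions(state)
        return {"amount": amount, "released": released}
    raise ValueError(f"unknown direction {direction!r}")


def _apply_gene_loss(state: _State, name: str) -> dict:
    spans = [f.span(state.l3) for f in state.feats if f.name == name]
    if not spans:
        raise GenerationError(f"gene {name} not present")
    s, e = spans[0]
    if not (e <= state.l1 or s >= state.l2):
        raise GenerationError("gene loss inside the IR is not supported")
    state.seq = np.concatenate([state.seq[:s], state.seq[e:]])
    state.feats = _shift_features(
        [f for f in state.feats if f.name != name], s, -(e - s)
    )
    if e <= state.l1:
        state.l1 -= e - s
        state.l2 -= e - s
    return {"gene": name, "excised_bp": e - s}


def _apply_pseudogenization(state: _State, name: str) -> dict:
    if not any(f.name == name for f in state.feats):
        raise GenerationError(f"gene {name} not present")
    state.feats = [
        replace(f, kind="pseudogene") if f.name == name else f
        for f in state.feats
    ]
    return {"gene": name}


def apply_ir_shift(genome: AnnotatedGenome, direction: str, amount: int,
                   boundaries: tuple[int, int, int] | None = None):
    """Shift the IR/SSC boundaries of a canonical genome.

    ``expand_into_ssc`` absorbs the SSC head into the IR unit: the absorbed
    tract is duplicated into IRb, so the SSC shrinks by ``amount``, each IR
    grows by ``amount``, and the genome grows by ``amount``.  A locus split
    by the new boundary keeps its full copy across the junction; its
    truncated IRb mirror is flagged as a pseudogene.  Returns
    ``(new_genome, details)``.
    """
    if boundaries is None:
        from plastomics.structure import find_inverted_repeats

        layout = find_inverted_repeats(genome)
        boundaries = (layout.lsc[1], layout.ira[1], layout.ssc[1])
    l1, l2, l3 = boundaries
    core_feats = [f for f in genome.features if f.span(genome.length)[1] <= l3]
    state = _State(_encode(genome.sequence[:l3]), core_feats, l1, l2)
    details = _apply_ir_shift_state(state, direction, amount)
    return _materialize(state, genome.id), details


# ---------------------------------------------------------------------------
# Evolution along a tree
# ---------------------------------------------------------------------------

@dataclass
class EvolParams:
    """Branch-wise evolution settings.

    ``tree`` is a rooted newick string (or dendropy Tree) with branch lengths
    in expected substitutions per site at coding positions; non-coding
    positions evolve at ``spacer_rate_multiplier`` times that rate.
    """

    tree: object
    model: str = "JC69"
    kappa: float = 2.0
    indel_rate: float = 0.02
    indel_p: float = 0.3
    spacer_rate_multiplier: float = 1.5
    ir_lockstep: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.model not in ("JC69", "K80"):
            raise ValueError("substitution model must be JC69 or K80")
        if not 0 < self.indel_p <= 1:
            raise ValueError("indel_p must be in (0, 1]")


@dataclass
class SimulationResult:
    genomes: list[AnnotatedGenome]
    tree: dendropy.Tree
    event_log: list[EventRecord]
    boundaries: dict[str, tuple[int, int, int, int]]  # id -> (l1, l2, l3, L)
    inversion_counts: dict[str, int]
    params: EvolParams
    template: TemplateMap | None = None
    ancestor: AnnotatedGenome | None = None


def _prepare_tree(tree) -> dendropy.Tree:
    if isinstance(tree, dendropy.Tree):
        t = tree.clone(depth=1)
    else:
        t = dendropy.Tree.get(
            data=str(tree), schema="newick", preserve_underscores=True
        )
    t.is_rooted = True
    i = 0
    for node in t.preorder_node_iter():
        if node.is_leaf():
            node.sim_label = node.taxon.label.replace(" ", "_")
        else:
            i += 1
            node.sim_label = node.label or f"N{i}"
    return t


def _resolve_events(tree: dendropy.Tree, events: list[Event]) -> dict[str, list[Event]]:
    by_branch: dict[str, list[Event]] = {}
    tips = {n.sim_label: n for n in tree.leaf_node_iter()}
    for ev in events:
        if isinstance(ev.branch, (set, frozenset)):
            taxa = [tips[t].taxon for t in ev.branch]
            node = tree.mrca(taxa=taxa)
        else:
            node = tips.get(ev.branch)
            if node is None:
                node = next(
                    (n for n in tree.preorder_node_iter() if n.sim_label == ev.branch),
                    None,
                )
        if node is None or node.parent_node is None:
            raise GenerationError(f"event branch {ev.branch!r} not found in tree")
        by_branch.setdefault(node.sim_label, []).append(ev)
    return by_branch


def evolve_along_tree(ancestral: AnnotatedGenome, params: EvolParams,
                      events: list[Event] | None = None) -> SimulationResult:
    """Simulate tip genomes along a rooted tree with planted events.

    Substitutions and indels are applied per branch after that branch's
    structural events; IR copies evolve in lockstep by default.
    """
    tree = _prepare_tree(params.tree)
    by_branch = _resolve_events(tree, events or [])
    rng = np.random.default_rng(params.seed)

    # reconstruct core state from the (canonical) ancestor
    from plastomics.structure import find_inverted_repeats

    layout = find_inverted_repeats(ancestral)
    l1, l2, l3 = layout.lsc[1], layout.ira[1], layout.ssc[1]
    core_feats = [
        f for f in ancestral.features if f.span(ancestral.length)[1] <= l3
    ]
    root_state = _State(_encode(ancestral.sequence[:l3]), core_feats, l1, l2)

    log: list[EventRecord] = []
    tip_states: dict[str, _State] = {}
    inv_counts: dict[str, int] = {}

    def _walk(node, state: _State, n_inv: int):
        for child in node.child_nodes():
            cstate = state.copy()
            c_inv = n_inv
            t = child.edge.length or 0.0
            for ev in by_branch.get(child.sim_label, []):
                if ev.kind == "inversion":
                    details = _apply_inversion(cstate, ev.params["first"], ev.params["last"])
                    c_inv += 1
                elif ev.kind in ("ir_expansion", "ir_contraction"):
                    direction = "expand_into_ssc" if ev.kind == "ir_expansion" else "contract"
                    details = _apply_ir_shift_state(cstate, direction, ev.params["amount"])
                elif ev.kind == "gene_loss":
                    details = _apply_gene_loss(cstate, ev.params["gene"])
                elif ev.kind == "pseudogenization":
                    details = _apply_pseudogenization(cstate, ev.params["gene"])
                else:
                    raise ValueError(f"unknown event kind {ev.kind!r}")
                log.append(EventRecord(child.sim_label, ev.kind, details))
            if t > 0:
                coding = _coding_mask(cstate)
                _substitute(cstate.seq, t, params.model, params.kappa, rng, coding)
                _substitute(
                    cstate.seq, t * params.spacer_rate_multiplier,
                    params.model, params.kappa, rng, ~coding,
                )
                _apply_indels(cstate, t, params.indel_rate, params.indel_p, rng)
                _pin_junctions(cstate)
            if child.is_leaf():
                tip_states[child.sim_label] = cstate
                inv_counts[child.sim_label] = c_inv
            else:
                _walk(child, cstate, c_inv)

    _walk(tree.seed_node, root_state, 0)

    root_dist = {
        leaf.sim_label: leaf.distance_from_root() for leaf in tree.leaf_node_iter()
    }
    genomes, bounds = [], {}
    for label in sorted(tip_states):
        st = tip_states[label]
        g = _materialize(st, label)
        if not params.ir_lockstep:
            # IRb diverges from its lockstep mirror by one tip-wise round of
            # substitutions over the root-to-tip path (a coarse model of
            # suspended homogenization; structural events still re-copy IRa).
            irb = _encode(g.sequence[st.l3:])
            _substitute(irb, root_dist[label], params.model, params.kappa,
                        rng, np.ones(irb.size, dtype=bool))
            g = AnnotatedGenome(g.id, g.sequence[: st.l3] + _decode(irb), g.features)
        genomes.append(g)
        bounds[label] = _state_boundaries(st)
    return SimulationResult(
        genomes=genomes, tree=tree, event_log=log, boundaries=bounds,
        inversion_counts=inv_counts, params=params,
    )


# ---------------------------------------------------------------------------
# Study-scale defaults
# ---------------------------------------------------------------------------

#: Rooted tree used by default: ten ingroup taxa mirroring a congeneric clade
#: plus three more distant outgroups.
DEFAULT_TREE = (
    "((((((A_biternatum:0.012,(A_allamandiflorum:0.010,A_peregrinum:0.011):0.006):0.008,"
    "(A_subspicatum:0.012,(A_nervosum:0.010,(A_aurantiacum:0.008,A_bracteatum:0.009):0.004):0.004):0.008)"
    ":0.010,N_candolleana:0.018):0.006,A_cristicalyx:0.020):0.006,A_pedunculatum:0.022):0.040,"
    "(C_cujete:0.050,(T_tetragonolobum:0.045,O_europaea:0.080):0.015):0.020):0.0;"
)

INGROUP = (
    "A_allamandiflorum", "A_aurantiacum", "A_biternatum", "A_bracteatum",
    "A_cristicalyx", "A_nervosum", "A_pedunculatum", "A_peregrinum",
    "A_subspicatum", "N_candolleana",
)
OUTGROUP = ("C_cujete", "T_tetragonolobum", "O_europaea")


def default_events(template: TemplateMap, ancestor: AnnotatedGenome) -> list[Event]:
    """The standard planted scenario: an IR expansion on the ingroup stem
    (fully absorbing ycf1 and splitting rps15), two LSC inversions on
    different branches with different gene blocks, and one IR inversion block
    planted in parallel on two branches (four inversions in total)."""
    # expansion amount: cover SSC head spacer + ycf1 + next spacer + 100 bp of rps15
    spans = {}
    L = ancestor.length
    for f in ancestor.features:
        if f.name in ("ycf1", "rps15") and f.name not in spans:
            spans[f.name] = f.span(L)
    from plastomics.structure import find_inverted_repeats

    layout = find_inverted_repeats(ancestor)
    l2 = layout.ira[1]
    amount = (spans["rps15"][0] - l2) + 100
    if template.profile == "reduced":
        lsc_inv_1 = ("atpA", "rpoB")
        lsc_inv_2 = ("psbJ", "psbE")
        ir_inv = ("trnV-GAC", "rrn16")
    else:
        lsc_inv_1 = ("trnC-GCA", "psbM")
        lsc_inv_2 = ("psbJ", "psbE")
        ir_inv = ("trnV-GAC", "rrn16")
    ingroup = frozenset(INGROUP)
    clade_d2 = frozenset({"A_subspicatum", "A_nervosum", "A_aurantiacum", "A_bracteatum"})
    clade_d1 = frozenset({"A_biternatum", "A_allamandiflorum", "A_peregrinum"})
    return [
        Event(ingroup, "ir_expansion", {"amount": int(amount)}),
        Event(clade_d2, "inversion", {"first": lsc_inv_1[0], "last": lsc_inv_1[1]}),
        Event("A_cristicalyx", "inversion", {"first": lsc_inv_2[0], "last": lsc_inv_2[1]}),
        Event(clade_d1, "inversion", {"first": ir_inv[0], "last": ir_inv[1]}),
        Event("A_pedunculatum", "inversion", {"first": ir_inv[0], "last": ir_inv[1]}),
    ]


def simulate_dataset(profile: str = "reduced", seed: int = 0,
                     params: EvolParams | None = None,
                     events: list[Event] | str | None = "default") -> SimulationResult:
    """One-call generator: template -> ancestor -> tips, with the default
    study-like scenario (13 taxa, IR expansion in the ingroup, 4 inversions)."""
    template, ancestor = build_template(profile, seed)
    if params is None:
        params = EvolParams(tree=DEFAULT_TREE, seed=seed)
    if events == "default":
        events = default_events(template, ancestor)
    result = evolve_along_tree(ancestor, params, events or [])
    result.template = template
    result.ancestor = ancestor
    return result


def write_simulation(result: SimulationResult, outdir) -> None:
    """Write one GenBank per tip, the true tree, the event log, and a config echo."""
    import json
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for g in result.genomes:
        write_genbank(g, out / f"{g.id}.gb")
    result.tree.write(path=str(out / "true_tree.nwk"), schema="newick",
                      unquoted_underscores=True)
    with open(out / "events.tsv", "w") as fh:
        fh.write("branch\tkind\tdetails\n")
        for rec in result.event_log:
            fh.write(f"{rec.branch}\t{rec.kind}\t{json.dumps(rec.details, sort_keys=True)}\n")
    p = result.params
    cfg = {
        "model": p.model, "kappa": p.kappa, "indel_rate": p.indel_rate,
        "indel_p": p.indel_p, "spacer_rate_multiplier": p.spacer_rate_multiplier,
        "ir_lockstep": p.ir_lockstep, "seed": p.seed,
        "profile": result.template.profile if result.template else None,
    }
    with open(out / "sim_config.json", "w") as fh:
        json.dump(cfg, fh, indent=2, sort_keys=True)
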