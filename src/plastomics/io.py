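"""Reading, writing, and coordinate arithmetic for annotated circular plastomes.

Internal convention: 0-based half-open intervals on a circular sequence.
A segment ``(start, end, strand)`` with ``end <= start`` wraps through the
origin and denotes ``[start, L) + [0, end)``.  GenBank's 1-based inclusive
coordinates are converted at the file boundary only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("plastomics")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
#: GenBank feature types retained as loci.
FEATURE_KINDS = ("CDS", "tRNA", "rRNA")
VALID_KINDS = ("CDS", "tRNA", "rRNA", "intron", "pseudogene")


class PlastomeParseError(ValueError):
    """Raised for malformed GenBank/FASTA input."""


class AlphabetError(ValueError):
    """Raised when a sequence contains characters outside {A,C,G,T,N}."""


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Feature:
    """A strand-aware annotated locus, possibly multi-exon or origin-wrapping.

    ``segments`` are listed 5'->3' on the feature strand; each is a
    ``(start, end, strand)`` tuple in 0-based half-open circular coordinates.
    ``copy_tag`` disambiguates duplicated loci (IR copies, trnQ-UUG copies).
    """

    name: str
    kind: str
    segments: tuple[tuple[int, int, str], ...]
    copy_tag: str = ""

    def __post_init__(self):
        if self.kind not in VALID_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if not self.segments:
            raise ValueError(f"feature {self.name}: empty segment list")

    @property
    def label(self) -> str:
        return f"{self.name}#{self.copy_tag}" if self.copy_tag else self.name

    @property
    def strand(self) -> str:
        return self.segments[0][2]

    def span(self, genome_length: int) -> tuple[int, int]:
        """Smallest (start, end) interval covering all segments.

        For an origin-wrapping feature the returned interval wraps too
        (start > end).  The anchor is chosen to minimize the covered arc, so
        the result is well defined for any locus shorter than the genome.
        """
        L = genome_length
        best = None
        for anchor, _, _ in self.segments:
            extent = max(
                (s - anchor) % L + seg_len(s, e, L) for s, e, _ in self.segments
            )
            if best is None or extent < best[1]:
                best = (anchor, extent)
        a, ext = best
        end = (a + ext) % L
        return a, end if end else L

    def length(self, genome_length: int) -> int:
        return sum(seg_len(s, e, genome_length) for s, e, _ in self.segments)


def seg_len(start: int, end: int, genome_length: int) -> int:
    """Length of a circular half-open segment (wrapping allowed)."""
    if end > start:
        return end - start
    return genome_length - start + end


def order_segments(segments) -> tuple:
    """Sort exon segments 5'->3' on the feature strand.

    Forward-strand features list segments in ascending genomic order,
    reverse-strand features in descending order, so concatenating the
    per-segment extractions always yields the feature's own sequence.
    """
    segs = list(segments)
    if not segs:
        return tuple(segs)
    reverse = segs[0][2] == "-"
    return tuple(sorted(segs, key=lambda s: s[0], reverse=reverse))


@dataclass
class AnnotatedGenome:
    """A circular annotated genome: sequence plus ordered feature list."""

    id: str
    sequence: str
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self):
        if not self.sequence:
            raise ValueError("empty sequence")
        bad = set(self.sequence.upper()) - set("ACGTN")
        if bad:
            raise AlphabetError(
                f"{self.id}: non-DNA characters {sorted(bad)} in sequence"
            )
        self.sequence = self.sequence.upper()
        self.sort_features()

    @property
    def length(self) -> int:
        return len(self.sequence)

    def sort_features(self) -> None:
        self.features.sort(key=lambda f: (f.segments[0][0], f.name, f.copy_tag))

    def feature_sequence(self, feat: Feature) -> str:
        """Strand-resolved sequence of a feature, segments concatenated 5'->3'."""
        return "".join(
            extract_sequence(self, seg) for seg in feat.segments
        )

    def get(self, name: str, copy_tag: str = "") -> Feature:
        for f in self.features:
            if f.name == name and f.copy_tag == copy_tag:
                return f
        raise KeyError(f"{name}#{copy_tag} not in {self.id}")


@dataclass(frozen=True)
class RegionSeq:
    """One extracted coding or non-coding region from one genome."""

    genome_id: str
    region_name: str
    role: str  # "coding" | "noncoding"
    sequence: str
    source_interval: tuple[int, int, str]


def normalize_interval(start: int, end: int, length: int) -> tuple[int, int]:
    """Reduce coordinates modulo the genome length (end of L stays L)."""
    ns = start % length
    ne = end % length
    if ne == 0 and end != 0:
        ne = length
    return ns, ne


def extract_sequence(
    genome: AnnotatedGenome, interval: tuple[int, int, str]
) -> str:
    """Extract a (possibly wrapping) interval; '-' returns reverse complement."""
    start, end, strand = interval
    L = genome.length
    start %= L
    end = end % L
    if end > start:
        s = genome.sequence[start:end]
    else:  # wraps the origin (end == start means wrap of full remainder+end)
        s = genome.sequence[start:] + genome.sequence[:end]
    return revcomp(s) if strand == "-" else s


def rotate_genome(genome: AnnotatedGenome, offset: int) -> AnnotatedGenome:
    """Rotate so that old position ``offset`` becomes position 0 (lossless)."""
    L = genome.length
    offset %= L
    seq = genome.sequence[offset:] + genome.sequence[:offset]
    feats = []
    for f in genome.features:
        segs = []
        for s, e, st in f.segments:
            ns = (s - offset) % L
            ne = (e - offset) % L
            if ne == 0:
                ne = L
            segs.append((ns, ne, st))
        feats.append(replace(f, segments=tuple(segs)))
    return AnnotatedGenome(genome.id, seq, feats)


def reverse_complement_genome(genome: AnnotatedGenome) -> AnnotatedGenome:
    """Strand-flip the whole genome, remapping every feature."""
    L = genome.length
    seq = revcomp(genome.sequence)

    def flip_seg(seg):
        s, e, st = seg
        # position p maps to L-1-p; interval [s,e) -> [L-e, L-s)
        if e > s:
            ns, ne = L - e, L - s
        else:  # wrapping
            ns, ne = (L - e) % L, (L - s) % L
        return (ns % L, ne if ne else L, "-" if st == "+" else "+")

    feats = []
    for f in genome.features:
        segs = tuple(flip_seg(seg) for seg in reversed(f.segments))
        feats.append(replace(f, segments=segs))
    return AnnotatedGenome(genome.id, seq, feats)


# ---------------------------------------------------------------------------
# GenBank
# ---------------------------------------------------------------------------

def _location_to_segments(loc, length: int) -> tuple[tuple[int, int, str], ...]:
    """Convert a Biopython location to internal segments, 5'->3' feature order.

    Adjacent parts meeting at the origin are merged into one wrapping segment.
    """
    strand = "-" if loc.strand == -1 else "+"
    raw = [(int(p.start), int(p.end)) for p in loc.parts]
    if strand == "-" and len(raw) > 1 and raw[0][0] < raw[-1][0]:
        # complement(join(...)) parts come in genomic order; feature
        # 5'->3' order on the minus strand is the reverse
        raw = raw[::-1]
    # merge origin-spanning adjacent parts (…,L) + (0,…)
    merged: list[tuple[int, int]] = []
    for s, e in raw:
        if merged:
            ps, pe = merged[-1]
            if strand == "+" and pe % length == 0 and s == 0:
                merged[-1] = (ps, e)
                continue
            if strand == "-" and ps == 0 and e % length == 0:
                merged[-1] = (s, pe)
                continue
        merged.append((s, e))
    return order_segments(
        (s % length, e if 0 < e <= length else e % length, strand)
        for s, e in merged
    )


def read_genbank(path) -> AnnotatedGenome:
    """Read a single-record GenBank flat file into an AnnotatedGenome.

    1-based inclusive coordinates become 0-based half-open; ``join()``
    locations become multi-segment features; ``complement`` is strand '-';
    a ``/pseudo`` or ``/pseudogene`` qualifier forces kind ``pseudogene``.
    Ambiguity codes other than N are mapped to N with a warning.
    """
    try:
        record = SeqIO.read(str(path), "genbank")
    except Exception as exc:  # Biopython raises assorted ValueError subtypes
        raise PlastomeParseError(f"{path}: malformed GenBank record: {exc}") from exc
    seq = str(record.seq).upper()
    cleaned = []
    n_amb = 0
    for c in seq:
        if c in "ACGTN":
            cleaned.append(c)
        elif c in "RYSWKMBDHV":
            cleaned.append("N")
            n_amb += 1
        else:
            raise AlphabetError(f"{path}: non-DNA character {c!r}")
    if n_amb:
        logger.warning("%s: %d ambiguity codes mapped to N", record.id, n_amb)
    seq = "".join(cleaned)
    L = len(seq)

    feats: list[Feature] = []
    for sf in record.features:
        if sf.type not in FEATURE_KINDS:
            continue
        quals = sf.qualifiers
        name = (quals.get("gene") or quals.get("locus_tag") or ["?"])[0]
        kind = sf.type
        if "pseudo" in quals or "pseudogene" in quals:
            kind = "pseudogene"
        segs = _location_to_segments(sf.location, L)
        tag = (quals.get("note") or [""])[0]
        tag = tag.split("copy_tag=")[1] if "copy_tag=" in tag else ""
        feats.append(Feature(name=name, kind=kind, segments=segs, copy_tag=tag))

    genome = AnnotatedGenome(record.id or record.name, seq, feats)
    assign_copy_tags(genome)
    return genome


def assign_copy_tags(genome: AnnotatedGenome) -> None:
    """Give duplicated locus names deterministic copy tags ('1', '2', ...).

    Tags are assigned by ascending start coordinate; already-tagged features
    are left alone unless the (name, copy_tag) pair collides.
    """
    seen: dict[str, list[Feature]] = {}
    for f in genome.features:
        seen.setdefault(f.name, []).append(f)
    newfeats = []
    for f in genome.features:
        group = seen[f.name]
        if len(group) == 1:
            newfeats.append(f)
            continue
        tags = [g.copy_tag for g in group]
        if len(set(tags)) == len(tags) and all(tags):
            newfeats.append(f)  # fully pre-tagged, consistent
        else:
            idx = sorted(group, key=lambda g: g.segments[0][0]).index(f)
            newfeats.append(replace(f, copy_tag=str(idx + 1)))
    genome.features = newfeats
    genome.sort_features()


def write_genbank(genome: AnnotatedGenome, path) -> None:
    """Write an AnnotatedGenome as a circular GenBank flat file (round-trip safe)."""
    record = SeqRecord(
        Seq(genome.sequence),
        id=genome.id,
        name=genome.id[:16].replace(" ", "_").replace("|", "_").replace(".", "_"),
        description="synthetic annotated plastome",
        annotations={"molecule_type": "DNA", "topology": "circular"},
    )
    L = genome.length
    for f in genome.features:
        locs = []
        for s, e, st in f.segments:
            strand = -1 if st == "-" else 1
            if e > s:
                locs.append(SimpleLocation(s, e, strand))
            else:  # wrapping: split at origin, part order 5'->3'
                a = SimpleLocation(s, L, strand)
                b = SimpleLocation(0, e, strand)
                locs.extend([a, b] if st == "+" else [b, a])
        loc = locs[0] if len(locs) == 1 else CompoundLocation(locs)
        ftype = f.kind if f.kind in FEATURE_KINDS else "CDS"
        quals = {"gene": [f.name]}
        if f.copy_tag:
            quals["note"] = [f"copy_tag={f.copy_tag}"]
        if f.kind == "pseudogene":
            quals["pseudo"] = [""]
        record.features.append(SeqFeature(loc, type=ftype, qualifiers=quals))
    SeqIO.write([record], str(path), "genbank")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def write_fasta(seqs, path) -> None:
    """Write RegionSeq objects or (header, sequence) pairs as 80-column FASTA.

    Aligned sets (any sequence containing '-') must share one length.
    """
    records = []
    for item in seqs:
        if isinstance(item, RegionSeq):
            records.append((f"{item.genome_id}|{item.region_name}", item.sequence))
        else:
            records.append(tuple(item))
    if not records:
        raise ValueError("empty sequence set")
    if any("-" in s for _, s in records):
        lengths = {len(s) for _, s in records}
        if len(lengths) != 1:
            raise ValueError(f"aligned set with unequal lengths: {sorted(lengths)}")
    with open(path, "w") as fh:
        for header, seq in records:
            fh.write(f">{header}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def read_fasta(path) -> dict[str, str]:
    """Read FASTA into an ordered {header: sequence} mapping."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        out[rec.description] = str(rec.seq).upper()
    if not out:
        raise PlastomeParseError(f"{path}: no FASTA records")
    return out
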