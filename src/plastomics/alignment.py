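"""Multiple alignment, conserved-block filtering, and outlier-row removal.

The built-in aligner is a center-star progressive method: the member with
the highest summed pairwise similarity is the center, every other sequence
is aligned to it globally, and the pairwise alignments are merged
("once a gap, always a gap").  Coding mode penalizes gap opening more than
non-coding mode, mimicking the global vs long-gap strategies used for exons
and spacers.  An external aligner can be substituted via configuration; it
must produce the same :class:`Alignment` type.

Block filtering follows the classic conserved-block selection rules: with n
rows a column is conserved when one residue occurs in more than n/2 rows and
highly conserved when it reaches 85% of rows; any gap makes a column
non-conserved; stretches of more than 8 contiguous non-conserved columns are
rejected; surviving blocks are trimmed back to highly conserved flanks and
dropped when shorter than 10 columns.
"""

from __future__ import annotations

import logging
import shutil
import subprocess
import tempfile
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from plastomics.regions import DEFAULT_ALIGN_COSTS, _make_aligner, global_similarity
from plastomics.structure import round_half_up

logger = logging.getLogger("plastomics")

#: Gap-opening penalties by alignment mode (match/mismatch/extend shared).
MODE_GAP_OPEN = {"coding": -8.0, "noncoding": -4.0}


@dataclass
class Alignment:
    """A gapped alignment of one region across taxa."""

    region_name: str
    rows: dict[str, str]
    provenance: str = "raw"  # raw | edited | filtered

    def __post_init__(self):
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError(
                f"{self.region_name}: unequal row lengths {sorted(lengths)}"
            )

    @property
    def length(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def ungapped(self, genome_id: str) -> str:
        return self.rows[genome_id].replace("-", "")

    def columns(self) -> np.ndarray:
        mat = np.array([list(s) for s in self.rows.values()])
        return mat


@dataclass(frozen=True)
class BlockMask:
    """Kept column intervals (half-open) and the parameters that produced them."""

    intervals: tuple[tuple[int, int], ...]
    params: dict

    @property
    def n_kept(self) -> int:
        return sum(e - s for s, e in self.intervals)


# ---------------------------------------------------------------------------
# Multiple alignment
# ---------------------------------------------------------------------------

def _merge_center_star(center_id: str, center_seq: str,
                       pairwise: list[tuple[str, str, str]]) -> dict[str, str]:
    """Merge pairwise (center, other) alignments into one MSA.

    ``pairwise`` holds ``(other_id, center_aligned, other_aligned)``.  Gaps
    introduced into the center by any pairwise alignment are propagated to
    all rows.
    """
    master = list(center_seq)  # center with accumulated gaps
    rows: dict[str, list[str]] = {center_id: master}
    for other_id, c_al, o_al in pairwise:
        new_master: list[str] = []
        new_rows: dict[str, list[str]] = {gid: [] for gid in rows}
        new_other: list[str] = []
        i = j = 0
        while i < len(master) or j < len(c_al):
            m_char = master[i] if i < len(master) else None
            c_char = c_al[j] if j < len(c_al) else None
            if m_char == "-" and (c_char != "-" or c_char is None):
                # gap already in master only
                new_master.append("-")
                for gid in rows:
                    new_rows[gid].append(rows[gid][i])
                new_other.append("-")
                i += 1
            elif c_char == "-" and (m_char != "-" or m_char is None):
                # new gap in center from this pairwise alignment
                new_master.append("-")
                for gid in rows:
                    new_rows[gid].append("-")
                new_other.append(o_al[j])
                j += 1
            else:  # both real characters (or both gaps, kept in sync)
                new_master.append(m_char)
                for gid in rows:
                    new_rows[gid].append(rows[gid][i])
                new_other.append(o_al[j])
                i += 1
                j += 1
        master = new_master
        rows = new_rows
        rows[other_id] = new_other
        rows[center_id] = master
    return {gid: "".join(chars) for gid, chars in rows.items()}


def multiple_align(
    sequences: dict[str, str],
    mode: str = "noncoding",
    region_name: str = "",
    costs: dict | None = None,
    external_aligner: str | None = None,
) -> Alignment:
    """Center-star progressive multiple alignment.

    The center is the member maximizing summed pairwise global similarity
    (ties broken by id).  With ``external_aligner`` set (e.g. ``"mafft"``)
    the named command is run instead and parsed into the same type.
    """
    if not sequences:
        raise ValueError("empty sequence set")
    if len(sequences) == 1:
        gid, seq = next(iter(sequences.items()))
        warnings.warn(f"{region_name}: single member, passthrough alignment")
        return Alignment(region_name, {gid: seq})
    if external_aligner:
        return _run_external(external_aligner, sequences, region_name)
    c = dict(DEFAULT_ALIGN_COSTS, gap_open=MODE_GAP_OPEN.get(mode, -4.0))
    if costs:
        c.update(costs)
    aligner = _make_aligner(c)

    ids = sorted(sequences)
    sims = {gid: 0.0 for gid in ids}
    for a in range(len(ids)):
        for b in range(a + 1, len(ids)):
            s = global_similarity(sequences[ids[a]], sequences[ids[b]], c)
            sims[ids[a]] += s
            sims[ids[b]] += s
    center = max(ids, key=lambda g: (sims[g], g))

    pairwise = []
    for gid in ids:
        if gid == center:
            continue
        aln = aligner.align(sequences[center], sequences[gid])[0]
        c_al, o_al = str(aln[0]), str(aln[1])
        pairwise.append((gid, c_al, o_al))
    rows = _merge_center_star(center, sequences[center], pairwise)
    return Alignment(region_name, rows)


def _run_external(command: str, sequences: dict[str, str], region_name: str) -> Alignment:
    """Delegate to an external aligner reading/writing FASTA on stdin/stdout."""
    if shutil.which(command.split()[0]) is None:
        raise FileNotFoundError(f"external aligner {command!r} not on PATH")
    with tempfile.TemporaryDirectory() as tmp:
        fin = Path(tmp) / "in.fasta"
        with open(fin, "w") as fh:
            for gid, seq in sorted(sequences.items()):
                fh.write(f">{gid}\n{seq}\n")
        args = command.split() + ["--auto", "--quiet", str(fin)]
        proc = subprocess.run(args, capture_output=True, text=True, check=True)
        rows: dict[str, str] = {}
        gid = None
        for line in proc.stdout.splitlines():
            if line.startswith(">"):
                gid = line[1:].strip()
                rows[gid] = ""
            elif gid:
                rows[gid] += line.strip().upper()
    return Alignment(region_name, rows)


# ---------------------------------------------------------------------------
# Block filtering
# ---------------------------------------------------------------------------

def _column_status(aln: Alignment, conserved_frac: float, flank_frac: float) -> np.ndarray:
    """0 = non-conserved, 1 = conserved, 2 = highly conserved, per column."""
    mat = aln.columns()
    n = aln.n_rows
    status = np.zeros(aln.length, dtype=np.int8)
    for col in range(aln.length):
        column = mat[:, col]
        if "-" in column:
            continue
        vals, counts = np.unique(column, return_counts=True)
        top = counts.max()
        if top >= flank_frac * n:
            status[col] = 2
        elif top > conserved_frac * n:
            status[col] = 1
    return status


def block_filter(
    aln: Alignment,
    max_nonconserved_run: int = 8,
    min_block: int = 10,
    conserved_frac: float = 0.5,
    flank_frac: float = 0.85,
) -> tuple[BlockMask, Alignment]:
    """Conserved-block selection; returns the mask and the filtered alignment."""
    if aln.n_rows < 2:
        raise ValueError("block filtering needs at least two rows")
    status = _column_status(aln, conserved_frac, flank_frac)
    L = aln.length
    excluded = np.zeros(L, dtype=bool)
    i = 0
    while i < L:
        if status[i] == 0:
            j = i
            while j < L and status[j] == 0:
                j += 1
            if j - i > max_nonconserved_run:
                excluded[i:j] = True
            i = j
        else:
            i += 1

    intervals = []
    i = 0
    while i < L:
        if excluded[i]:
            i += 1
            continue
        j = i
        while j < L and not excluded[j]:
            j += 1
        s, e = i, j
        while s < e and status[s] != 2:
            s += 1
        while e > s and status[e - 1] != 2:
            e -= 1
        if e - s >= min_block:
            intervals.append((s, e))
        i = j

    mask = BlockMask(
        intervals=tuple(intervals),
        params={
            "max_nonconserved_run": max_nonconserved_run,
            "min_block": min_block,
            "conserved_frac": conserved_frac,
            "flank_frac": flank_frac,
            "gap_rule": "none",  # any gap makes a column non-conserved
        },
    )
    rows = {
        gid: "".join(seq[s:e] for s, e in intervals)
        for gid, seq in aln.rows.items()
    }
    return mask, Alignment(aln.region_name, rows, provenance="filtered")


# ---------------------------------------------------------------------------
# Outlier rows
# ---------------------------------------------------------------------------

def pairwise_identity(a: str, b: str) -> float:
    """Identity over columns where neither row has a gap (0 if none shared)."""
    shared = matches = 0
    for x, y in zip(a, b):
        if x == "-" or y == "-":
            continue
        shared += 1
        if x == y:
            matches += 1
    return matches / shared if shared else 0.0


def remove_outlier_rows(
    aln: Alignment,
    k_sd: float = 2.0,
    floor: float = 0.5,
) -> tuple[Alignment, list[str]]:
    """Drop rows whose mean identity to the others is anomalously low.

    A row is removed when its mean pairwise identity (over shared non-gap
    columns) falls below ``max(floor, mean - k_sd * sd)``, where mean and sd
    describe the pooled distribution of all pairwise identities.  Anchoring
    the spread on pairs rather than on row means keeps uniformly divergent
    alignments intact (divergence widens the pair distribution symmetrically)
    while a true non-homolog still drags its row mean far below the cutoff.
    At most ceil(n/3) rows are removed (lowest first); with fewer than three
    rows the alignment passes through unchanged.
    """
    ids = sorted(aln.rows)
    n = len(ids)
    if n < 3:
        warnings.warn(f"{aln.region_name}: <3 rows, outlier screen skipped")
        return aln, []
    pair_vals = {}
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            pair_vals[(a, b)] = pairwise_identity(aln.rows[a], aln.rows[b])
    scores = {
        gid: float(np.mean([v for k, v in pair_vals.items() if gid in k]))
        for gid in ids
    }
    pooled = list(pair_vals.values())
    mean = float(np.mean(pooled))
    sd = float(np.std(pooled, ddof=0))
    cutoff = max(floor, mean - k_sd * sd)
    flagged = sorted((gid for gid in ids if scores[gid] < cutoff), key=lambda g: scores[g])
    cap = -(-n // 3)  # ceil(n/3)
    if len(flagged) > cap:
        logger.warning(
            "%s: %d outliers flagged, capped at %d", aln.region_name, len(flagged), cap
        )
        flagged = flagged[:cap]
    if not flagged:
        return aln, []
    rows = {gid: seq for gid, seq in aln.rows.items() if gid not in flagged}
    # drop all-gap columns created by the removal
    keep = [
        col for col in range(aln.length)
        if any(seq[col] != "-" for seq in rows.values())
    ]
    rows = {gid: "".join(seq[c] for c in keep) for gid, seq in rows.items()}
    return Alignment(aln.region_name, rows, provenance="edited"), flagged


# ---------------------------------------------------------------------------
# Variability
# ---------------------------------------------------------------------------

def variable_site_stats(aln) -> tuple[int, int, float]:
    """(alignment length, variable sites, percent variation to 1 decimal).

    A column is variable when at least two distinct unambiguous nucleotides
    occur in it; gaps and N are ignored.
    """
    if isinstance(aln, Alignment):
        rows = list(aln.rows.values())
    elif isinstance(aln, dict):
        rows = list(aln.values())
    else:
        rows = list(aln)
    if not rows or not rows[0]:
        raise ValueError("empty alignment")
    length = len(rows[0])
    var = 0
    acgt = frozenset("ACGT")
    for col in range(length):
        seen = {r[col] for r in rows} & acgt
        if len(seen) >= 2:
            var += 1
    return length, var, round_half_up(100.0 * var / length, 1)
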