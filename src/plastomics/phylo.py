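"""Distance trees, Kendall–Colijn comparison, and standardized marker ranking.

Tree inference here is deliberately light: JC69-corrected distances and
neighbor joining, which are deterministic and fast at the scale of a dozen
plastomes.  Externally computed trees (e.g. from an ML program) can be
ingested as newick and used wherever a tree is expected — the substance of
this module is the comparison metrics and the ranking, not the inference.

The Kendall–Colijn vector of a rooted tree holds, for every unordered tip
pair, the blend ``(1-λ)·m + λ·M`` of the edge count m and the path length M
from the root to the pair's MRCA, followed by one entry per tip
(``(1-λ)·1 + λ·pendant length``).  λ=0 compares pure topology; λ=1 compares
branch lengths.  The distance between two trees on the same tips is the
Euclidean norm of the difference of their vectors.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger("plastomics")


class SaturationError(ValueError):
    """Observed divergence at or beyond the JC69 domain boundary (p >= 3/4)."""


class TipMismatchError(ValueError):
    """Two trees being compared do not share the same tip set."""


class NonMonophyleticIngroupError(ValueError):
    """The outgroup does not attach to the ingroup by a single edge."""


@dataclass
class DistanceMatrix:
    taxa: list[str]
    matrix: np.ndarray  # symmetric, zero diagonal, finite

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.taxa), len(self.taxa)):
            raise ValueError("matrix shape does not match taxa")
        if not np.allclose(m, m.T) or not np.allclose(np.diag(m), 0):
            raise ValueError("distance matrix must be symmetric with zero diagonal")
        if not np.isfinite(m).all():
            raise ValueError("non-finite distances")
        self.matrix = m


def _alignment_rows(aln) -> dict[str, str]:
    from plastomics.alignment import Alignment

    if isinstance(aln, Alignment):
        return aln.rows
    return dict(aln)


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

def jc69_distances(aln) -> DistanceMatrix:
    """JC69-corrected pairwise distances with pairwise deletion.

    p is the mismatch fraction over sites where both rows have an unambiguous
    base; d = -(3/4)·ln(1 - (4/3)p).  p >= 3/4 raises :class:`SaturationError`
    naming the offending pair.
    """
    rows = _alignment_rows(aln)
    taxa = sorted(rows)
    if len(taxa) < 2:
        raise ValueError("need at least two rows")
    arrs = {
        t: np.frombuffer(rows[t].encode(), dtype=np.uint8) for t in taxa
    }
    valid = {t: np.isin(arrs[t], np.frombuffer(b"ACGT", dtype=np.uint8)) for t in taxa}
    n = len(taxa)
    m = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        a, b = taxa[i], taxa[j]
        both = valid[a] & valid[b]
        total = int(both.sum())
        if total == 0:
            raise ValueError(f"no shared unambiguous sites for {a} vs {b}")
        p = float((arrs[a][both] != arrs[b][both]).sum()) / total
        if p >= 0.75:
            raise SaturationError(
                f"{a} vs {b}: observed divergence p={p:.3f} is saturated (>= 0.75)"
            )
        d = -0.75 * np.log(1.0 - 4.0 * p / 3.0)
        m[i, j] = m[j, i] = d
    return DistanceMatrix(taxa, m)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou–Nei agglomeration with the standard Q criterion (unrooted).

    Negative branch-length estimates are clamped to zero and the clamped
    deficit logged.  Ties in Q are broken by the lowest taxon-index pair, so
    the result is deterministic.
    """
    n = len(dm.taxa)
    if n < 3:
        raise ValueError("neighbor joining needs at least three taxa")
    tn = dendropy.TaxonNamespace(dm.taxa)
    nodes = []
    for t in dm.taxa:
        node = dendropy.Node()
        node.taxon = tn.get_taxon(t)
        nodes.append(node)
    D = dm.matrix.copy()
    active = list(range(n))

    def clamp(x):
        if x < 0:
            logger.debug("NJ: clamped negative branch length %.4g", x)
            return 0.0
        return float(x)

    while len(active) > 3:
        k = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (k - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        flat = np.argmin(Q)
        i_loc, j_loc = divmod(flat, k)
        if i_loc > j_loc:
            i_loc, j_loc = j_loc, i_loc
        i, j = active[i_loc], active[j_loc]
        dij = D[i, j]
        li = 0.5 * dij + (r[i_loc] - r[j_loc]) / (2.0 * (k - 2))
        lj = dij - li
        parent = dendropy.Node()
        for child, length in ((nodes[i], li), (nodes[j], lj)):
            parent.add_child(child)
            child.edge.length = clamp(length)
        # distances to the new node (stored in slot i)
        newd = 0.5 * (D[i, :] + D[j, :] - dij)
        D[i, :] = newd
        D[:, i] = newd
        D[i, i] = 0.0
        nodes[i] = parent
        active.remove(j)

    a, b, c = active
    la = clamp(0.5 * (D[a, b] + D[a, c] - D[b, c]))
    lb = clamp(0.5 * (D[a, b] + D[b, c] - D[a, c]))
    lc = clamp(0.5 * (D[a, c] + D[b, c] - D[a, b]))
    center = dendropy.Node()
    for idx, length in ((a, la), (b, lb), (c, lc)):
        center.add_child(nodes[idx])
        nodes[idx].edge.length = length
    tree = dendropy.Tree(taxon_namespace=tn, seed_node=center)
    tree.is_rooted = False
    return tree


def nj_tree_from_alignment(aln) -> dendropy.Tree:
    """Convenience: JC69 distances then NJ."""
    return neighbor_joining(jc69_distances(aln))


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

def _bipartitions(tree: dendropy.Tree) -> set[frozenset]:
    """Non-trivial unrooted bipartitions as frozensets of tip labels
    (the smaller side, ties broken lexicographically)."""
    labels = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    out = set()
    for node in tree.preorder_internal_node_iter():
        if node is tree.seed_node:
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        other = frozenset(labels - side)
        if len(side) < 2 or len(other) < 2:
            continue
        canon = min(side, other, key=lambda s: (len(s), sorted(s)))
        out.add(canon)
    return out


def bootstrap_support(aln, n_reps: int = 100, seed: int = 0) -> dendropy.Tree:
    """NJ point tree with bipartition bootstrap supports (percent).

    Columns are resampled with replacement; replicates whose distances
    saturate are counted as failures for every bipartition.  With zero
    variable sites the point tree is degenerate and a warning is issued.
    """
    rows = _alignment_rows(aln)
    from plastomics.alignment import variable_site_stats

    _, var, _ = variable_site_stats(rows)
    if var == 0:
        warnings.warn("no variable sites: supports reported against a degenerate tree")
    point = nj_tree_from_alignment(rows)
    target = _bipartitions(point)
    counts = {bp: 0 for bp in target}
    rng = np.random.default_rng(seed)
    L = len(next(iter(rows.values())))
    mat = {t: np.frombuffer(s.encode(), dtype=np.uint8) for t, s in rows.items()}
    for _ in range(n_reps):
        idx = rng.integers(0, L, size=L)
        res = {t: arr[idx].tobytes().decode() for t, arr in mat.items()}
        try:
            rep = nj_tree_from_alignment(res)
        except (SaturationError, ValueError):
            continue
        found = _bipartitions(rep)
        for bp in target:
            if bp in found:
                counts[bp] += 1
    for node in point.preorder_internal_node_iter():
        if node is point.seed_node:
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        labels = {l.taxon.label for l in point.leaf_node_iter()}
        canon = min(side, frozenset(labels - side), key=lambda s: (len(s), sorted(s)))
        if canon in counts:
            node.label = str(int(round(100.0 * counts[canon] / n_reps)))
    return point


# ---------------------------------------------------------------------------
# Rooting and pruning
# ---------------------------------------------------------------------------

def root_and_prune(
    tree: dendropy.Tree,
    outgroup_taxa: list[str],
) -> dendropy.Tree:
    """Root on the outgroup edge and return the rooted ingroup subtree.

    Requires the ingroup to be monophyletic (equivalently: some edge of the
    unrooted tree separates exactly the outgroup taxa); otherwise raises
    :class:`NonMonophyleticIngroupError` naming the intruding taxa.
    """
    work = tree.clone(depth=1)
    labels = {leaf.taxon.label for leaf in work.leaf_node_iter()}
    og = set(outgroup_taxa)
    missing = og - labels
    if missing:
        raise ValueError(f"outgroup taxa not in tree: {sorted(missing)}")
    ingroup = labels - og

    target_node = None
    for node in work.preorder_node_iter():
        if node is work.seed_node:
            continue
        side = {l.taxon.label for l in node.leaf_iter()}
        if side == og or side == ingroup:
            target_node = node
            break
    if target_node is None:
        # find the smallest clade-side containing all outgroups and name intruders
        best = labels
        for node in work.preorder_node_iter():
            if node is work.seed_node:
                continue
            side = {l.taxon.label for l in node.leaf_iter()}
            for cand in (side, labels - side):
                if og <= cand and len(cand) < len(best):
                    best = cand
        raise NonMonophyleticIngroupError(
            f"ingroup not monophyletic; taxa grouping with the outgroup: "
            f"{sorted(best - og)}"
        )

    edge = target_node.edge
    half = (edge.length or 0.0) / 2.0
    work.reroot_at_edge(edge, length1=half, length2=half)
    work.is_rooted = True
    # the root now has the outgroup on one side; dropping those taxa (with
    # unifurcation suppression) leaves the rooted ingroup subtree
    work.retain_taxa_with_labels(sorted(ingroup))
    work.is_rooted = True
    return work


# ---------------------------------------------------------------------------
# Kendall–Colijn metric
# ---------------------------------------------------------------------------

def kc_vector(tree: dendropy.Tree, lam: float) -> tuple[np.ndarray, list[str]]:
    """The λ-blended KC vector of a rooted tree, with its tip-pair ordering."""
    if not tree.is_rooted:
        raise ValueError("KC vectors are defined for rooted trees")
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must be in [0, 1]")
    leaves = sorted(tree.leaf_node_iter(), key=lambda l: l.taxon.label)
    labels = [l.taxon.label for l in leaves]
    # per-node depth in edges and in branch length
    depth_e: dict[int, int] = {id(tree.seed_node): 0}
    depth_l: dict[int, float] = {id(tree.seed_node): 0.0}
    parent: dict[int, object] = {id(tree.seed_node): None}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        p = node.parent_node
        depth_e[id(node)] = depth_e[id(p)] + 1
        depth_l[id(node)] = depth_l[id(p)] + (node.edge.length or 0.0)
        parent[id(node)] = p
    path = {}
    for leaf in leaves:
        chain = []
        node = leaf
        while node is not None:
            chain.append(id(node))
            node = parent.get(id(node))
        path[leaf.taxon.label] = set(chain)
    entries = []
    for a, b in combinations(labels, 2):
        common = path[a] & path[b]
        mrca = max(common, key=lambda nid: depth_e[nid])
        entries.append((1.0 - lam) * depth_e[mrca] + lam * depth_l[mrca])
    for leaf in leaves:
        pend = leaf.edge.length or 0.0
        entries.append((1.0 - lam) * 1.0 + lam * pend)
    return np.array(entries), labels


def kc_distance(t1: dendropy.Tree, t2: dendropy.Tree, lam: float) -> float:
    """Euclidean distance between the KC vectors of two rooted trees."""
    v1, l1 = kc_vector(t1, lam)
    v2, l2 = kc_vector(t2, lam)
    if l1 != l2:
        diff = set(l1) ^ set(l2)
        raise TipMismatchError(f"tip sets differ: {sorted(diff)}")
    return float(np.linalg.norm(v1 - v2))


# ---------------------------------------------------------------------------
# Marker ranking and candidate selection
# ---------------------------------------------------------------------------

def rank_markers(
    per_region_alignments: dict,
    per_region_trees: dict[str, dendropy.Tree],
    reference_tree: dendropy.Tree,
    groups: dict | None = None,
) -> pd.DataFrame:
    """Standardized ranking of candidate marker regions.

    Per region: percent variation, KC topology distance (λ=0) and KC
    branch-length distance (λ=1) to the reference tree.  Standardization
    maps variation to (v-min)/(max-min) and each distance to
    1 - (d-min)/(max-min), so 1 is always best (a region whose tree matches
    the reference topology scores 1 on topology).  The composite is the
    unweighted mean of the three standardized scores; ranking is descending
    by composite.  If a metric is constant across regions, every region
    scores 1 on it (degenerate standardization, warned).
    """
    from plastomics.alignment import variable_site_stats

    names = sorted(per_region_trees)
    if len(names) < 2:
        raise ValueError("standardization needs at least two regions")
    rows = []
    for name in names:
        aln = per_region_alignments[name]
        length, var, pct = variable_site_stats(aln)
        d0 = kc_distance(per_region_trees[name], reference_tree, 0.0)
        d1 = kc_distance(per_region_trees[name], reference_tree, 1.0)
        row = {
            "region": name,
            "alignment_length": length,
            "variable_sites": var,
            "pct_variation": pct,
            "topo_dist": d0,
            "brlen_dist": d1,
        }
        if groups and name in groups:
            lens = groups[name].member_lengths()
            row["min_seq_length"] = int(min(lens))
            row["max_seq_length"] = int(max(lens))
        rows.append(row)
    df = pd.DataFrame(rows)

    def std_up(col):
        lo, hi = col.min(), col.max()
        if hi == lo:
            warnings.warn(f"degenerate standardization for {col.name}; all scores 1")
            return pd.Series(1.0, index=col.index)
        return (col - lo) / (hi - lo)

    def std_down(col):
        lo, hi = col.min(), col.max()
        if hi == lo:
            warnings.warn(f"degenerate standardization for {col.name}; all scores 1")
            return pd.Series(1.0, index=col.index)
        return 1.0 - (col - lo) / (hi - lo)

    df["std_variation"] = std_up(df["pct_variation"])
    df["std_topo"] = std_down(df["topo_dist"])
    df["std_brlen"] = std_down(df["brlen_dist"])
    df["composite"] = df[["std_variation", "std_topo", "std_brlen"]].mean(axis=1)
    df = df.sort_values(
        ["composite", "region"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def _intervals_overlap(a: tuple[int, int], b: tuple[int, int], L: int) -> bool:
    """Overlap of two genome intervals, either of which may wrap the origin."""
    def unroll(iv):
        s, e = iv
        return [(s, e)] if s < e else [(s, L), (0, e)]

    for s1, e1 in unroll(a):
        for s2, e2 in unroll(b):
            if s1 < e2 and s2 < e1:
                return True
    return False


def select_marker_candidates(
    groups: list,
    reference_id: str,
    breakpoints: list[tuple[int, int]],
    genome_length: int,
    min_len: int = 500,
    max_len: int = 1100,
) -> tuple[list, dict[str, str]]:
    """Screen non-coding regions for PCR-amplifiable, rearrangement-free markers.

    A region is kept when the median unaligned member length lies in
    ``[min_len, max_len]`` and its reference interval overlaps no detected
    rearrangement breakpoint (the operational proxy for "recombination
    free").  Returns (kept groups, {region: exclusion reason}).
    """
    kept = []
    excluded: dict[str, str] = {}
    for grp in groups:
        if grp.role != "noncoding":
            excluded[grp.region_name] = "coding"
            continue
        med = float(np.median(grp.member_lengths()))
        if not (min_len <= med <= max_len):
            excluded[grp.region_name] = "length"
            continue
        ref_member = grp.members.get(reference_id)
        if ref_member is None:
            excluded[grp.region_name] = "missing_in_reference"
            continue
        s, e, _ = ref_member.source_interval
        if any(
            _intervals_overlap((s, e), bp, genome_length) for bp in breakpoints
        ):
            excluded[grp.region_name] = "breakpoint"
            continue
        kept.append(grp)
    return kept, excluded


def read_newick(path_or_string, rooted: bool = True) -> dendropy.Tree:
    """Ingest an externally computed tree (newick file or literal string)."""
    import os

    if isinstance(path_or_string, str) and not os.path.exists(path_or_string):
        tree = dendropy.Tree.get(
            data=path_or_string, schema="newick", preserve_underscores=True
        )
    else:
        tree = dendropy.Tree.get(
            path=str(path_or_string), schema="newick", preserve_underscores=True
        )
    tree.is_rooted = rooted
    return tree
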