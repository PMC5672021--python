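"""Fragmentation rules, global similarity, homology grouping, scheme assembly."""

import numpy as np
import pytest

from plastomics.io import AnnotatedGenome, Feature
from plastomics.regions import (
    RegionGroup,
    audit_disjoint,
    build_schemes,
    fragment_genome,
    global_similarity,
    group_by_similarity,
)
from plastomics.structure import QuadripartiteLayout, canonicalize

from conftest import by_id


def _toy_genome(rng, spacer_after_b=120):
    """LSC with three genes (one intronic), tiny IRs, one SSC gene."""
    parts = []
    feats = []
    pos = 0

    def spacer(n):
        nonlocal pos
        parts.append("".join(rng.choice(list("ACGT"), size=n)))
        pos += n

    def gene(name, exons, strand="+", kind="CDS"):
        nonlocal pos
        segs = []
        for exon, intron in exons:
            seq = "".join(rng.choice(list("ACGT"), size=exon))
            segs.append((pos, pos + exon, strand))
            parts.append(seq)
            pos += exon
            if intron:
                spacer_seq = "".join(rng.choice(list("ACGT"), size=intron))
                parts.append(spacer_seq)
                pos += intron
        feats.append(Feature(name, kind, tuple(segs)))

    spacer(100)
    gene("geneA", [(200, 0)])
    spacer(49)  # below the retention floor: must be dropped
    gene("geneB", [(90, 80), (60, 0)])  # one 80 bp intron
    spacer(spacer_after_b)
    gene("geneC", [(150, 0)], strand="-")
    spacer(60)
    lsc_end = pos
    ir = "".join(rng.choice(list("ACGT"), size=400))
    parts.append(ir)
    pos += 400
    ira_end = pos
    spacer(50)
    gene("geneS", [(120, 0)])
    spacer(70)
    ssc_end = pos
    from plastomics.io import revcomp

    parts.append(revcomp(ir))
    pos += 400
    g = AnnotatedGenome("toy", "".join(parts), feats)
    layout = QuadripartiteLayout(
        (0, lsc_end), (lsc_end, ira_end), (ira_end, ssc_end), (ssc_end, pos), 1.0
    )
    return g, layout


def test_fragment_names_roles_and_floor(rng):
    g, layout = _toy_genome(rng)
    regions = fragment_genome(g, layout, min_len=50)
    names = {r.region_name for r in regions}
    coding = [r for r in regions if r.role == "coding"]
    noncoding = [r for r in regions if r.role == "noncoding"]
    assert {"geneA", "geneB", "geneC", "geneS"} <= names
    assert "geneB_intron" in names  # 80 bp intron retained
    assert "geneA-geneB" not in names  # 49 bp spacer dropped
    assert "geneB-geneC" in names  # 120 bp spacer kept
    assert all(len(r.sequence) >= 50 for r in regions)
    # geneB coding region excludes its intron
    gb = next(r for r in coding if r.region_name == "geneB")
    assert len(gb.sequence) == 150
    audit_disjoint(regions, g.length)
    # no region from the excluded IRb
    assert all(r.source_interval[1] <= layout.irb[0] for r in regions)
    assert len(noncoding) >= 3


def test_fragment_50bp_boundary_inclusive(rng):
    g, layout = _toy_genome(rng, spacer_after_b=50)
    regions = fragment_genome(g, layout, min_len=50)
    assert "geneB-geneC" in {r.region_name for r in regions}


def test_overlapping_genes_split_at_midpoint(rng):
    seq = "".join(rng.choice(list("ACGT"), size=1000))
    feats = [
        Feature("x", "CDS", ((100, 300, "+"),)),
        Feature("y", "CDS", ((280, 500, "+"),)),  # 20 bp overlap
    ]
    g = AnnotatedGenome("ov", seq, feats)
    layout = QuadripartiteLayout((0, 600), (600, 750), (750, 850), (850, 1000), 1.0)
    regions = fragment_genome(g, layout, min_len=50)
    x = next(r for r in regions if r.region_name == "x")
    y = next(r for r in regions if r.region_name == "y")
    assert x.source_interval[1] == 290 and y.source_interval[0] == 290
    audit_disjoint(regions, g.length)


def test_pseudogene_treated_as_noncoding(rng):
    seq = "".join(rng.choice(list("ACGT"), size=1000))
    feats = [
        Feature("real", "CDS", ((100, 250, "+"),)),
        Feature("dead", "pseudogene", ((400, 520, "+"),)),
    ]
    g = AnnotatedGenome("ps", seq, feats)
    layout = QuadripartiteLayout((0, 600), (600, 750), (750, 850), (850, 1000), 1.0)
    regions = fragment_genome(g, layout, min_len=50)
    assert "dead" not in {r.region_name for r in regions if r.role == "coding"}
    # its bases are still emitted, inside the surrounding spacer, which runs
    # to the end of the retained domain (LSC+IRa+SSC)
    spacer = next(r for r in regions if r.region_name == "real-end")
    assert spacer.source_interval == (250, 850, "+")


@pytest.mark.parametrize(
    "a,b,expected",
    [
        ("ACGTACGT", "ACGTACGT", 1.0),
        ("AAAA", "TTTT", 0.0),
        ("ACGTACGT", "ACGTTCGT", 7 / 8),  # single optimal alignment, one mismatch
    ],
)
def test_global_similarity_examples(a, b, expected):
    assert global_similarity(a, b) == pytest.approx(expected)


def test_global_similarity_empty_errors():
    with pytest.raises(ValueError):
        global_similarity("", "ACGT")


def test_group_by_similarity_threshold_semantics(rng):
    from plastomics.io import RegionSeq
    from plastomics.simulate import mutate_sequence

    base = "".join(rng.choice(list("ACGT"), size=400))
    near = mutate_sequence(base, 0.05, rng=np.random.default_rng(1))
    far = "".join(rng.choice(list("ACGT"), size=400))  # unrelated

    def reg(gid, name, seq):
        return RegionSeq(gid, name, "noncoding", seq, (0, len(seq), "+"))

    regions = {
        "ref": [reg("ref", "spacer1", base)],
        "t1": [reg("t1", "spacer1", near)],
        "t2": [reg("t2", "whatever", far)],
    }
    groups, unassigned = group_by_similarity(regions, "ref", threshold=0.65)
    g = groups[0]
    assert set(g.members) == {"ref", "t1"}
    assert g.similarity_to_ref["t1"] >= 0.65
    assert [r.genome_id for r in unassigned] == ["t2"]


def test_group_by_similarity_requires_reference():
    with pytest.raises(ValueError, match="reference"):
        group_by_similarity({"a": []}, "missing")


def test_group_by_similarity_deterministic(sim42):
    regs = {}
    for gid in ("A_biternatum", "A_peregrinum", "C_cujete"):
        g, lay = canonicalize(by_id(sim42, gid), min_len=1000)
        regs[gid] = [r for r in __import__("plastomics.regions", fromlist=["fragment_genome"]).fragment_genome(g, lay)][:25]
    g1, u1 = group_by_similarity(regs, "A_biternatum")
    g2, u2 = group_by_similarity(regs, "A_biternatum")
    key = lambda grps: sorted((g.region_name, tuple(sorted(g.members))) for g in grps)
    assert key(g1) == key(g2)
    assert [r.region_name for r in u1] == [r.region_name for r in u2]


def test_build_schemes_additivity():
    from plastomics.alignment import Alignment

    c1 = Alignment("g1", {"a": "ACGT", "b": "ACGA"})  # 1 variable site
    c2 = Alignment("g2", {"a": "AACCGG", "b": "AACCGG"})  # 0 variable
    n1 = Alignment("s1", {"a": "AAATT", "b": "AATTT"})  # sites 3..? variable: pos2,? compute
    schemes = build_schemes({"g1": c1, "g2": c2}, {"s1": n1}, {"s1": n1})
    coding = schemes["coding"]
    combined = schemes["coding+noncoding_edited"]
    assert coding.alignment_length == 10
    assert coding.variable_sites == 1
    assert combined.alignment_length == coding.alignment_length + schemes["noncoding_edited"].alignment_length
    assert combined.variable_sites == coding.variable_sites + schemes["noncoding_edited"].variable_sites
    assert set(schemes) == {
        "coding", "noncoding_edited", "noncoding_filtered",
        "coding+noncoding_edited", "coding+noncoding_filtered",
    }


def test_build_schemes_empty_errors():
    with pytest.raises(ValueError, match="empty"):
        build_schemes({}, {}, {})
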