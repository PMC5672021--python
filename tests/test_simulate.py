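"""Generator ground truth: determinism, substitution calibration, IR shifts,
and replay of the structural event log."""

import numpy as np
import pytest

from plastomics.io import revcomp
from plastomics.simulate import (
    DEFAULT_TREE,
    EvolParams,
    Event,
    apply_ir_shift,
    build_template,
    evolve_along_tree,
    mutate_sequence,
    simulate_dataset,
)
from plastomics.structure import find_inverted_repeats

from conftest import by_id


def test_same_seed_identical_genomes():
    a = simulate_dataset("reduced", seed=9)
    b = simulate_dataset("reduced", seed=9)
    for ga, gb in zip(a.genomes, b.genomes):
        assert ga.id == gb.id and ga.sequence == gb.sequence
        assert [f.segments for f in ga.features] == [f.segments for f in gb.features]


def test_zero_branch_lengths_no_events_gives_identical_tips(reduced_template):
    _, anc = reduced_template
    tree = "((a:0.0,b:0.0):0.0,(c:0.0,d:0.0):0.0):0.0;"
    res = evolve_along_tree(anc, EvolParams(tree=tree, seed=4), events=[])
    for tip in res.genomes:
        assert tip.sequence == anc.sequence


def test_jc69_divergence_matches_closed_form():
    rng = np.random.default_rng(77)
    n = 10_000
    seq = "".join(rng.choice(list("ACGT"), size=n))
    t = 0.1
    out = mutate_sequence(seq, t, model="JC69", rng=np.random.default_rng(123))
    p_obs = sum(1 for a, b in zip(seq, out) if a != b) / n
    p_exp = 0.75 * (1 - np.exp(-4 * t / 3))  # ~0.0937
    se = np.sqrt(p_exp * (1 - p_exp) / n)
    assert abs(p_obs - p_exp) <= 3 * se


def test_k80_transition_bias():
    rng = np.random.default_rng(5)
    seq = "".join(rng.choice(list("ACGT"), size=20_000))
    out = mutate_sequence(seq, 0.2, model="K80", kappa=8.0, rng=np.random.default_rng(6))
    ts = tv = 0
    pairs = {frozenset("AG"), frozenset("CT")}
    for a, b in zip(seq, out):
        if a == b:
            continue
        if frozenset((a, b)) in pairs:
            ts += 1
        else:
            tv += 1
    assert ts > tv  # kappa >> 1 must bias changes toward transitions


def test_ir_copies_exact_reverse_complements(sim42):
    for g in sim42.genomes:
        l1, l2, l3, L = sim42.boundaries[g.id]
        ira = g.sequence[l1:l2]
        irb = g.sequence[l3:L]
        assert irb == revcomp(ira)


def test_ir_expansion_bookkeeping(reduced_template):
    _, anc = reduced_template
    lay0 = find_inverted_repeats(anc)
    expanded, details = apply_ir_shift(
        anc, "expand_into_ssc", 2000,
        boundaries=(lay0.lsc[1], lay0.ira[1], lay0.ssc[1]),
    )
    lay1 = find_inverted_repeats(expanded)  # verified by re-running detection
    assert lay1.ssc_length == lay0.ssc_length - 2000
    assert lay1.ir_length == lay0.ir_length + 2000
    assert expanded.length == anc.length + 2000
    assert lay1.lsc_length == lay0.lsc_length


def test_ir_expansion_zero_is_identity(reduced_template):
    _, anc = reduced_template
    lay = find_inverted_repeats(anc)
    same, _ = apply_ir_shift(
        anc, "expand_into_ssc", 0, boundaries=(lay.lsc[1], lay.ira[1], lay.ssc[1])
    )
    assert same.sequence == anc.sequence


def test_ir_expansion_crossing_gene_creates_pseudogene_copy(reduced_template):
    template, anc = reduced_template
    lay = find_inverted_repeats(anc)
    l2 = lay.ira[1]
    ycf1 = anc.get("ycf1")
    rps15 = anc.get("rps15")
    amount = rps15.span(anc.length)[0] - l2 + 50  # boundary lands inside rps15
    expanded, details = apply_ir_shift(
        anc, "expand_into_ssc", amount, boundaries=(lay.lsc[1], l2, lay.ssc[1])
    )
    assert "ycf1" in details["absorbed"]
    assert "rps15" in details["split_pseudogene"]
    pseudo = [f for f in expanded.features if f.kind == "pseudogene"]
    assert any(f.name == "rps15" for f in pseudo)
    assert sum(1 for f in expanded.features if f.name == "ycf1") == 2


def test_ir_expansion_exhausting_ssc_errors(reduced_template):
    from plastomics.simulate import GenerationError

    _, anc = reduced_template
    lay = find_inverted_repeats(anc)
    with pytest.raises(GenerationError, match="exhaust"):
        apply_ir_shift(
            anc, "expand_into_ssc", lay.ssc_length,
            boundaries=(lay.lsc[1], lay.ira[1], lay.ssc[1]),
        )


def test_ir_contraction_inverse_bookkeeping(reduced_template):
    _, anc = reduced_template
    lay = find_inverted_repeats(anc)
    shrunk, _ = apply_ir_shift(
        anc, "contract", 500, boundaries=(lay.lsc[1], lay.ira[1], lay.ssc[1])
    )
    lay1 = find_inverted_repeats(shrunk)
    assert lay1.ir_length == lay.ir_length - 500
    assert lay1.ssc_length == lay.ssc_length + 500  # tract released, copy lost
    assert shrunk.length == anc.length - 500


def test_spacer_restricted_inversion_rejects_genic_endpoint(reduced_template):
    from plastomics.simulate import GenerationError

    _, anc = reduced_template
    with pytest.raises(GenerationError):
        evolve_along_tree(
            anc,
            EvolParams(tree="(a:0.01,b:0.01):0.0;", seed=1),
            [Event("a", "inversion", {"first": "atpA", "last": "trnH-GUG"})],
        )


def test_gene_loss_excises_sequence(reduced_template):
    _, anc = reduced_template
    res = evolve_along_tree(
        anc,
        EvolParams(tree="(a:0.0,b:0.0):0.0;", seed=1, indel_rate=0.0),
        [Event("a", "gene_loss", {"gene": "ycf4"})]
        if any(f.name == "ycf4" for f in anc.features)
        else [Event("a", "gene_loss", {"gene": "rbcL"})],
    )
    tip = by_id(res, "a")
    other = by_id(res, "b")
    lost = "ycf4" if any(f.name == "ycf4" for f in anc.features) else "rbcL"
    assert not any(f.name == lost for f in tip.features)
    assert any(f.name == lost for f in other.features)
    assert tip.length < other.length


# ---------------------------------------------------------------------------
# Event-log replay oracle
# ---------------------------------------------------------------------------

def _strip(label):
    return label.split("#")[0]


def _replay_orders(sim):
    """Independent permutation-level replay of the event log.

    Produces the expected signed gene-name order for every tip by applying
    the logged events to the ancestral core order and mirroring the IR
    segment, without touching any sequence.
    """
    anc = sim.ancestor
    lay = find_inverted_repeats(anc)
    l1, l2, l3 = lay.lsc[1], lay.ira[1], lay.ssc[1]
    core = []
    for f in sorted(anc.features, key=lambda f: f.span(anc.length)[0]):
        s, e = f.span(anc.length)
        if e > l3:
            continue  # IRb mirror
        if e <= l1:
            comp = "LSC"
        elif s >= l1 and e <= l2:
            comp = "IR"
        else:
            comp = "SSC"
        core.append([_strip(f.label), 1 if f.strand == "+" else -1, comp])

    events_by_branch = {}
    for rec in sim.event_log:
        events_by_branch.setdefault(rec.branch, []).append(rec)

    def path_to(tip_label):
        node = next(
            l for l in sim.tree.leaf_node_iter() if l.sim_label == tip_label
        )
        chain = []
        while node is not None:
            chain.append(getattr(node, "sim_label", None))
            node = node.parent_node
        return list(reversed(chain))

    expected = {}
    for g in sim.genomes:
        order = [row[:] for row in core]
        for branch in path_to(g.id):
            for rec in events_by_branch.get(branch, []):
                if rec.kind == "inversion":
                    names = {_strip(x) for x in rec.details["loci"]}
                    idx = [i for i, row in enumerate(order) if row[0] in names]
                    lo, hi = min(idx), max(idx) + 1
                    assert hi - lo == len(idx), "inverted loci not contiguous"
                    block = [[n, -sgn, c] for n, sgn, c in reversed(order[lo:hi])]
                    order[lo:hi] = block
                elif rec.kind == "ir_expansion":
                    absorbed = {_strip(x) for x in rec.details["absorbed"]}
                    split = {_strip(x) for x in rec.details["split_pseudogene"]}
                    for row in order:
                        if row[0] in absorbed or row[0] in split:
                            row[2] = "IR"
                elif rec.kind == "gene_loss":
                    order = [r for r in order if r[0] != rec.details["gene"]]
                # pseudogenization does not alter the order
        mirror = [[n, -sgn] for n, sgn, c in reversed(order) if c == "IR"]
        expected[g.id] = [[n, sgn] for n, sgn, _ in order] + mirror
    return expected


def test_event_log_replay_reproduces_tip_gene_orders(sim42):
    from plastomics.rearrange import gene_order
    from plastomics.structure import canonicalize

    expected = _replay_orders(sim42)
    for g in sim42.genomes:
        canon, lay = canonicalize(g, min_len=1000)
        got = [
            [_strip(l.label), l.sign] for l in gene_order(canon, lay).loci
        ]
        assert got == expected[g.id], g.id


def test_planted_inversion_detected_as_single_inverted_block(reduced_template):
    from plastomics.rearrange import detect_blocks, gene_order
    from plastomics.structure import canonicalize

    _, anc = reduced_template
    res = evolve_along_tree(
        anc,
        EvolParams(tree="(a:0.001,b:0.001):0.0;", seed=2, indel_rate=0.0),
        [Event("a", "inversion", {"first": "atpA", "last": "rpoB"})],
    )
    ca, la = canonicalize(by_id(res, "a"), min_len=1000)
    cb, lb = canonicalize(by_id(res, "b"), min_len=1000)
    blocks = detect_blocks(gene_order(cb, lb), gene_order(ca, la))
    inverted = [b for b in blocks if b.orientation == "inverted"]
    assert len(inverted) == 1
    assert {_strip(x) for x in inverted[0].loci} == {"atpA", "atpF", "rpoB"}


def test_default_tree_and_events_shape(sim42):
    assert len(sim42.genomes) == 13
    assert len([r for r in sim42.event_log if r.kind == "inversion"]) == 4
    assert len([r for r in sim42.event_log if r.kind == "ir_expansion"]) == 1
    # outgroups carry no structural events
    for og in ("C_cujete", "T_tetragonolobum", "O_europaea"):
        assert sim42.inversion_counts[og] == 0


def test_template_profile_ranges():
    for profile in ("reduced", "default"):
        tm, anc = build_template(profile, seed=0)
        assert tm.total_range[0] <= anc.length <= tm.total_range[1]
        lay = find_inverted_repeats(anc)
        assert tm.ir_range[0] <= lay.ir_length <= tm.ir_range[1]
        assert lay.lsc_length >= lay.ssc_length
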