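"""phylo: NJ exactness, JC, RF vs dendropy oracle, bootstrap, discordance."""

import itertools
import math

import dendropy
import numpy as np
import pytest

from svmprecomb import msa, phylo
from svmprecomb.architecture import DomainBoundaries


# -- distances --------------------------------------------------------------


def test_p_distance_matrix_pairwise_deletion():
    aln = msa.MultipleAlignment(["a", "b"], ["ACG-T", "ACGGT"])
    dm = phylo.p_distance_matrix(aln)
    assert dm.values[0, 1] == pytest.approx(0.0)
    aln2 = msa.MultipleAlignment(["a", "b"], ["AAAA", "AAAT"])
    assert phylo.p_distance_matrix(aln2).values[0, 1] == pytest.approx(0.25)


def test_jc_correct_examples():
    assert phylo.jc_correct(0.0) == pytest.approx(0.0)
    # closed form at p = 0.1
    assert phylo.jc_correct(0.1) == pytest.approx(-0.75 * math.log(1 - 0.4 / 3))
    # small p: JC distance ~ p
    assert phylo.jc_correct(0.001) == pytest.approx(0.001, rel=1e-2)
    with pytest.raises(ValueError):
        phylo.jc_correct(0.75)
    with pytest.raises(ValueError):
        phylo.jc_correct(-0.1)


def test_jc_correct_inverts_expected_saturation():
    # simulate the JC forward map p(d) then invert
    for d in (0.05, 0.2, 0.5):
        p = 0.75 * (1 - math.exp(-4 * d / 3))
        assert phylo.jc_correct(p) == pytest.approx(d)


# -- neighbor joining -------------------------------------------------------


def _additive_matrix_from_tree(tree: dendropy.Tree, ids):
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    n = len(ids)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = pdm.distance(taxa[ids[i]], taxa[ids[j]])
    return out


def _random_dendropy_tree(rng, n_taxa):
    taxa = dendropy.TaxonNamespace([f"t{k}" for k in range(n_taxa)])
    tree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n_taxa,
        taxon_namespace=taxa, rng=rng,
    )
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length = 0.1 + rng.random()
    tree.is_rooted = False
    return tree


def test_nj_hand_example_additive_four_taxa():
    # tree ((A:1,B:2):1,(C:3,D:4)); additive distances
    ids = ["A", "B", "C", "D"]
    d = np.array(
        [
            [0, 3, 5, 6],
            [3, 0, 6, 7],
            [5, 6, 0, 7],
            [6, 7, 0, 0],
        ],
        dtype=float,
    )
    d[2, 3] = d[3, 2] = 7.0
    tree = phylo.nj_tree(phylo.DistanceMatrix(ids, d))
    assert tree.splits() == {frozenset({"C", "D"})}  # anchor A: split {C,D}|{A,B}
    # branch length of the internal edge is 1
    internal = [
        n for n in tree.root.postorder()
        if n.children and n is not tree.root
    ]
    assert any(abs(n.length - 1.0) < 1e-9 for n in internal)


def test_nj_exact_on_random_additive_matrices():
    rng = np.random.default_rng(17)
    import random as _random

    for rep in range(30):
        pyrng = _random.Random(int(rng.integers(0, 2**31)))
        n_taxa = int(rng.integers(6, 11))
        dtree = _random_dendropy_tree(pyrng, n_taxa)
        ids = sorted(t.label for t in dtree.taxon_namespace)
        mat = _additive_matrix_from_tree(dtree, ids)
        got = phylo.nj_tree(phylo.DistanceMatrix(ids, mat))
        # compare split sets against the generating topology
        anchor = min(ids)
        all_leaves = frozenset(ids)
        expect = set()
        for bipart in dtree.encode_bipartitions():
            names = frozenset(
                t.label for t in bipart.leafset_taxa(dtree.taxon_namespace)
            )
            if 2 <= len(names) <= len(ids) - 2:
                side = names if anchor not in names else all_leaves - names
                expect.add(side)
        assert got.splits() == expect, f"rep {rep}: topology not recovered"
        # additive matrices are reproduced exactly by path lengths
        pdm = {frozenset(p): v for p, v in _tree_path_lengths(got).items()}
        for i, j in itertools.combinations(range(len(ids)), 2):
            assert pdm[frozenset({ids[i], ids[j]})] == pytest.approx(
                mat[i, j], abs=1e-8
            )


def _tree_path_lengths(tree: phylo.Tree) -> dict[tuple, float]:
    leaves = tree.leaf_names()
    # collect root-to-leaf path lengths via parent map
    parent = {}
    for node in tree.root.postorder():
        for ch in node.children:
            parent[ch] = node
    node_of = {leaf.name: leaf for leaf in tree.root.leaves()}

    def path(n):
        out = []
        while n in parent:
            out.append(n)
            n = parent[n]
        return out

    dists = {}
    for a, b in itertools.combinations(leaves, 2):
        pa, pb = path(node_of[a]), path(node_of[b])
        sa, sb = set(pa), set(pb)
        total = sum(n.length for n in pa if n not in sb)
        total += sum(n.length for n in pb if n not in sa)
        dists[(a, b)] = total
    return dists


def test_nj_rejects_small_input():
    with pytest.raises(ValueError):
        phylo.nj_tree(phylo.DistanceMatrix(["a", "b"], np.zeros((2, 2))))


# -- Robinson-Foulds vs dendropy oracle -------------------------------------


def _to_dendropy(tree: phylo.Tree, tns: dendropy.TaxonNamespace) -> dendropy.Tree:
    return dendropy.Tree.get(
        data=tree.newick(), schema="newick", taxon_namespace=tns
    )


def test_rf_quartet_example():
    ids = ["A", "B", "C", "D"]

    def quartet(pair):
        d = np.full((4, 4), 2.0)
        np.fill_diagonal(d, 0.0)
        i, j = ids.index(pair[0]), ids.index(pair[1])
        d[i, j] = d[j, i] = 1.0
        k, l = [x for x in range(4) if x not in (i, j)]
        d[k, l] = d[l, k] = 1.0
        return phylo.nj_tree(phylo.DistanceMatrix(ids, d))

    t_ab = quartet("AB")
    t_ac = quartet("AC")
    assert phylo.rf_distance(t_ab, t_ab) == 0
    assert phylo.rf_distance(t_ab, t_ac) == 2


def test_rf_matches_dendropy_on_random_trees():
    rng = np.random.default_rng(29)
    import random as _random

    for rep in range(25):
        pyrng = _random.Random(int(rng.integers(0, 2**31)))
        t1 = _random_dendropy_tree(pyrng, 8)
        t2 = _random_dendropy_tree(pyrng, 8)
        ids = sorted(t.label for t in t1.taxon_namespace)
        m1 = _additive_matrix_from_tree(t1, ids)
        ids2 = sorted(t.label for t in t2.taxon_namespace)
        m2 = _additive_matrix_from_tree(t2, ids2)
        g1 = phylo.nj_tree(phylo.DistanceMatrix(ids, m1))
        g2 = phylo.nj_tree(phylo.DistanceMatrix(ids2, m2))
        tns = dendropy.TaxonNamespace(ids)
        d1 = _to_dendropy(g1, tns)
        d2 = _to_dendropy(g2, tns)
        oracle = dendropy.calculate.treecompare.symmetric_difference(d1, d2)
        assert phylo.rf_distance(g1, g2) == oracle


def test_rf_metric_properties():
    rng = np.random.default_rng(31)
    import random as _random

    trees = []
    ids = None
    for _ in range(4):
        pyrng = _random.Random(int(rng.integers(0, 2**31)))
        t = _random_dendropy_tree(pyrng, 7)
        ids = sorted(x.label for x in t.taxon_namespace)
        m = _additive_matrix_from_tree(t, ids)
        trees.append(phylo.nj_tree(phylo.DistanceMatrix(ids, m)))
    for a, b, c in itertools.permutations(trees, 3):
        assert phylo.rf_distance(a, b) == phylo.rf_distance(b, a) >= 0
        assert (phylo.rf_distance(a, b) == 0) == (a.splits() == b.splits())
        assert phylo.rf_distance(a, c) <= phylo.rf_distance(a, b) + phylo.rf_distance(b, c)


def test_rf_leafset_mismatch():
    d = np.full((4, 4), 1.0)
    np.fill_diagonal(d, 0.0)
    t1 = phylo.nj_tree(phylo.DistanceMatrix(["a", "b", "c", "d"], d))
    t2 = phylo.nj_tree(phylo.DistanceMatrix(["a", "b", "c", "e"], d))
    with pytest.raises(ValueError):
        phylo.rf_distance(t1, t2)


# -- bootstrap --------------------------------------------------------------


def _family_alignment(seed=101, ncols=300, nrows=6):
    rng = np.random.default_rng(seed)
    base = rng.integers(0, 4, ncols)
    rows = []
    ids = []
    for k in range(nrows):
        seq = base.copy()
        nmut = 10 + 12 * (k // 2)
        for pos in rng.choice(ncols, size=nmut, replace=False):
            seq[pos] = (seq[pos] + 1 + rng.integers(0, 3)) % 4
        rows.append("".join("ACGT"[i] for i in seq))
        ids.append(f"s{k}")
    return msa.MultipleAlignment(ids, rows)


def test_bootstrap_deterministic_and_bounded():
    aln = _family_alignment()
    t1 = phylo.bootstrap_support(aln, 50, seed=7)
    t2 = phylo.bootstrap_support(aln, 50, seed=7)
    assert t1.newick() == t2.newick()
    supports = [
        n.support for n in t1.root.postorder() if n.children and n.support is not None
    ]
    assert supports and all(0 <= s <= 100 for s in supports)
    t3 = phylo.bootstrap_support(aln, 50, seed=8)
    assert t3.splits() == t1.splits()  # point estimate independent of seed


def test_bootstrap_single_rep_supports_binary():
    aln = _family_alignment(seed=55)
    tree = phylo.bootstrap_support(aln, 1, seed=3)
    for node in tree.root.postorder():
        if node.children and node.support is not None:
            assert node.support in (0.0, 100.0)


def test_bootstrap_identical_sequences_star():
    aln = msa.MultipleAlignment(["a", "b", "c"], ["ACGT" * 10] * 3)
    tree = phylo.bootstrap_support(aln, 10, seed=1)
    assert tree.splits() == set()  # star: no non-trivial bipartition


# -- partition_domains ------------------------------------------------------


def test_partition_domains_drops_all_gap_rows():
    # reference covers both domains; 'p1' is gapped throughout the disintegrin
    ref = "M" * 10
    rows = {
        "ref": "MMMMMMMMMM",
        "p3": "MMMMMMMMMM",
        "p1": "MMMMM-----",
    }
    aln = msa.MultipleAlignment(list(rows), list(rows.values()), "aa")
    bounds = DomainBoundaries((1, 5), (6, 10), reference_id="ref")
    cat, dis = phylo.partition_domains(aln, bounds)
    assert sorted(cat.ids) == ["p1", "p3", "ref"]
    assert sorted(dis.ids) == ["p3", "ref"]
    assert cat.ncols == 5 and dis.ncols == 5


def test_partition_domains_requires_reference():
    aln = msa.MultipleAlignment(["a", "b"], ["MM", "MM"], "aa")
    with pytest.raises(ValueError):
        phylo.partition_domains(aln, DomainBoundaries((1, 1), (2, 2)))


# -- discordance ------------------------------------------------------------


def _nwk(s: str) -> phylo.Tree:
    return _parse_newick(s)


def _parse_newick(s: str) -> phylo.Tree:
    """Minimal Newick reader for test fixtures (supports name:len and support)."""
    pos = 0

    def parse_node():
        nonlocal pos
        node = phylo.TreeNode()
        if s[pos] == "(":
            pos += 1
            while True:
                node.add(parse_node())
                if s[pos] == ",":
                    pos += 1
                    continue
                break
            assert s[pos] == ")"
            pos += 1
            # optional internal label = support
            start = pos
            while s[pos] not in ":,();":
                pos += 1
            if pos > start:
                node.support = float(s[start:pos])
        else:
            start = pos
            while s[pos] not in ":,();":
                pos += 1
            node.name = s[start:pos]
        if s[pos] == ":":
            pos += 1
            start = pos
            while s[pos] not in ":,();":
                pos += 1
            node.length = float(s[start:pos])
        return node

    root = parse_node()
    return phylo.Tree(root)


CAT = "((a:1,x:1)95:1,(b:1,c:1)99:1,(d:1,e:1)99:1);"
DIS = "((d:1,x:1)95:1,(b:1,c:1)99:1,(a:1,e:1)99:1);"
CLASSES = {"a": "P-I", "b": "P-I", "c": "P-I", "d": "P-III", "e": "P-III", "x": "P-II"}


def test_discordance_flags_planted_chimera():
    # x sits with P-I 'a' in the catalytic tree but with P-III 'd' in the
    # disintegrin tree -> flagged
    rep = phylo.discordance_report(_nwk(CAT), _nwk(DIS), CLASSES, 70.0)
    assert "x" in rep.flagged
    assert rep.neighbor_classes["x"] == ("P-I", "P-III")


def test_discordance_concordant_family_no_flags():
    rep = phylo.discordance_report(_nwk(CAT), _nwk(CAT), CLASSES, 70.0)
    assert rep.flagged == []
    assert all(rep.concordant.values())


def test_discordance_threshold_101_no_flags():
    rep = phylo.discordance_report(_nwk(CAT), _nwk(DIS), CLASSES, 101.0)
    assert rep.flagged == []
    assert all(nc == (None, None) for nc in rep.neighbor_classes.values())


def test_discordance_restricted_to_shared_leaves():
    # 'a' exists only in the catalytic tree: it must be skipped, and its
    # absence must not create discordance for others
    dis_sub = "((d:1,x:1)95:1,b:1,(c:1,e:1)99:1);"
    rep = phylo.discordance_report(_nwk(CAT), _nwk(dis_sub), CLASSES, 70.0)
    assert rep.skipped == ["a"]
    assert "a" not in rep.neighbor_classes


def test_discordance_rf_between_domain_trees():
    rep = phylo.discordance_report(_nwk(CAT), _nwk(CAT), CLASSES, 70.0)
    assert rep.rf_distance == 0
    rep2 = phylo.discordance_report(_nwk(CAT), _nwk(DIS), CLASSES, 70.0)
    assert rep2.rf_distance and rep2.rf_distance > 0


def test_discordance_end_to_end_simulated():
    # simulated family with one interclass event: acceptor flagged by the
    # full pipeline trees stage
    from svmprecomb import architecture, pipeline, simulate

    cfg = simulate.SimulationConfig(
        seed=20404, n_leaves=8, sub_rate_coding=0.015,
        p_loss_cysrich=0.4, p_loss_disintegrin=0.15,
        n_recombinations=1, donor_p_range=(0.10, 0.15),
    )
    fam = simulate.simulate_family(cfg)
    ev = [e.detail for e in fam.event_log if e.kind == "recombination"][0]
    archs = [architecture.assign_class(r) for r in fam.records]
    _, _, report = pipeline.trees_stage(
        fam.records, archs, pipeline.PipelineConfig(seed=11)
    )
    assert report is not None
    assert ev["acceptor"] in report.flagged
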