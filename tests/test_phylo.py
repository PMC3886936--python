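"""Tree reconstruction, bootstrap, congruence and origin classification,
checked against brute-force oracles."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from panforge import phylo
from panforge.homology import ScoringScheme
from panforge.phylo import (
    GeneTree,
    Msa,
    TreeNode,
    bipartitions,
    bootstrap_supports,
    distance_matrix,
    fitch_score,
    hgt_classify,
    nj_tree,
    origin_classify,
    parse_newick,
    parsimony_tree,
    progressive_msa,
    rf_distance,
    species_tree,
)

AAS = "ACDEFGHIKLMNPQRSTVWY"


# ---------------------------------------------------------------------------
# alignment


def _oracle_nw(a: str, b: str, scheme: ScoringScheme) -> float:
    """Independent global affine alignment score: explicit gap-length
    recursion."""
    sub = {
        (x, y): int(scheme.matrix[i, j])
        for i, x in enumerate(AAS)
        for j, y in enumerate(AAS)
    }
    NEG = -1e12
    m, n = len(a), len(b)
    H = [[NEG] * (n + 1) for _ in range(m + 1)]
    H[0][0] = 0.0
    for i in range(m + 1):
        for j in range(n + 1):
            cand = []
            if i and j:
                cand.append(H[i - 1][j - 1] + sub[(a[i - 1], b[j - 1])])
            for g in range(1, i + 1):
                cand.append(H[i - g][j] + scheme.gap_open + (g - 1) * scheme.gap_extend)
            for g in range(1, j + 1):
                cand.append(H[i][j - g] + scheme.gap_open + (g - 1) * scheme.gap_extend)
            if cand:
                H[i][j] = max(H[i][j], max(cand))
    return H[m][n]


def _msa_score(msa: Msa, scheme: ScoringScheme) -> float:
    a, b = msa.rows
    total, in_gap = 0.0, False
    for x, y in zip(a, b):
        if x == "-" or y == "-":
            total += scheme.gap_extend if in_gap else scheme.gap_open
            in_gap = True
        else:
            total += int(scheme.matrix[scheme.encode(x)[0], scheme.encode(y)[0]])
            in_gap = False
    return total


class TestProgressiveMsa:
    def test_identical_sequences_no_gaps(self):
        msa = progressive_msa({"a": "MKTAYIAK", "b": "MKTAYIAK", "c": "MKTAYIAK"})
        assert all("-" not in r for r in msa.rows)

    def test_two_sequences_match_global_dp_oracle(self):
        scheme = ScoringScheme()
        rng = np.random.default_rng(13)
        for _ in range(20):
            a = "".join(rng.choice(list(AAS), size=int(rng.integers(5, 20))))
            b = "".join(rng.choice(list(AAS), size=int(rng.integers(5, 20))))
            msa = progressive_msa([("a", a), ("b", b)], scheme)
            assert _msa_score(msa, scheme) == pytest.approx(_oracle_nw(a, b, scheme))

    def test_ungapping_recovers_inputs(self):
        rng = np.random.default_rng(17)
        seqs = {
            f"s{i}": "".join(rng.choice(list(AAS), size=int(rng.integers(10, 30))))
            for i in range(6)
        }
        msa = progressive_msa(seqs)
        for name, seq in seqs.items():
            assert msa.ungapped(name) == seq

    def test_single_sequence_passthrough(self):
        msa = progressive_msa({"only": "MKT"})
        assert msa.rows == ["MKT"]


class TestDistances:
    def test_identical_rows_zero(self):
        D, _ = distance_matrix(Msa(["a", "b"], ["MKT", "MKT"]), "poisson")
        assert D[0, 1] == 0.0

    def test_poisson_closed_form(self):
        rows = ["A" * 90 + "C" * 10, "A" * 100]
        D, _ = distance_matrix(Msa(["a", "b"], rows), "poisson")
        assert D[0, 1] == pytest.approx(-math.log(0.9), abs=1e-9)
        assert D[0, 1] == pytest.approx(0.10536, abs=1e-4)

    def test_matches_exact_column_bookkeeping(self):
        rng = np.random.default_rng(3)
        chars = list("ACDE-")
        rows = ["".join(rng.choice(chars, size=60)) for _ in range(4)]
        names = [f"s{i}" for i in range(4)]
        D, _ = distance_matrix(Msa(names, rows), "p")
        for i, j in itertools.combinations(range(4), 2):
            shared = [
                (x, y) for x, y in zip(rows[i], rows[j]) if x != "-" and y != "-"
            ]
            expect = sum(x != y for x, y in shared) / len(shared)
            assert D[i, j] == pytest.approx(expect)

    def test_saturated_poisson_capped(self):
        D, _ = distance_matrix(Msa(["a", "b"], ["AAAA", "CCCC"]), "poisson")
        assert D[0, 1] == phylo.DIST_CAP


def _random_tree(names, rng) -> TreeNode:
    """Random binary unrooted topology with random positive branch lengths."""
    nodes = [TreeNode(n, float(rng.uniform(0.1, 1.0))) for n in names[:3]]
    root = TreeNode()
    for n in nodes:
        root.add(n)
    for name in names[3:]:
        cands = [n for n in root.postorder() if n.parent is not None]
        target = cands[int(rng.integers(len(cands)))]
        parent = target.parent
        split = TreeNode(None, float(rng.uniform(0.1, 1.0)))
        parent.children[parent.children.index(target)] = split
        split.parent = parent
        split.add(target)
        split.add(TreeNode(name, float(rng.uniform(0.1, 1.0))))
    return root


def _path_lengths(root: TreeNode) -> dict[tuple[str, str], float]:
    out = {}

    def collect(node, acc):
        if node.is_leaf:
            acc[node.name] = 0.0
            return {node.name: node.length}
        below = {}
        for c in node.children:
            sub = collect(c, acc)
            for pair in itertools.product(below, sub):
                out[tuple(sorted(pair))] = below[pair[0]] + sub[pair[1]]
            below.update(sub)
        return {k: v + node.length for k, v in below.items()}

    collect(root, {})
    return out


class TestNeighborJoining:
    def test_three_taxa_exact(self):
        D = np.array([[0, 5, 9], [5, 0, 10], [9, 10, 0]], float)
        tree = nj_tree(D, ["a", "b", "c"])
        lengths = {n.name: n.length for n in tree.root.children}
        assert lengths == {"a": 2.0, "b": 3.0, "c": 7.0}

    def test_additive_five_taxon_exact_recovery(self):
        rng = np.random.default_rng(5)
        names = ["a", "b", "c", "d", "e"]
        true = _random_tree(names, rng)
        paths = _path_lengths(true)
        D = np.zeros((5, 5))
        for (x, y), d in paths.items():
            i, j = names.index(x), names.index(y)
            D[i, j] = D[j, i] = d
        got = nj_tree(D, names)
        assert bipartitions(got) == bipartitions(true)
        recovered = _path_lengths(got.root)
        for pair, d in paths.items():
            assert recovered[pair] == pytest.approx(d, abs=1e-9)

    def test_recovers_100_random_additive_matrices(self):
        rng = np.random.default_rng(99)
        for _ in range(100):
            n = int(rng.integers(4, 11))
            names = [f"t{k}" for k in range(n)]
            true = _random_tree(names, rng)
            paths = _path_lengths(true)
            D = np.zeros((n, n))
            for (x, y), d in paths.items():
                i, j = names.index(x), names.index(y)
                D[i, j] = D[j, i] = d
            assert bipartitions(nj_tree(D, names)) == bipartitions(true)

    def test_taxon_permutation_gives_isomorphic_tree(self):
        rng = np.random.default_rng(2)
        names = ["a", "b", "c", "d", "e", "f"]
        true = _random_tree(names, rng)
        paths = _path_lengths(true)

        def matrix(order):
            D = np.zeros((6, 6))
            for (x, y), d in paths.items():
                i, j = order.index(x), order.index(y)
                D[i, j] = D[j, i] = d
            return D

        base = bipartitions(nj_tree(matrix(names), names))
        perm = ["d", "a", "f", "b", "e", "c"]
        assert bipartitions(nj_tree(matrix(perm), perm)) == base

    def test_small_matrix_rejected(self):
        with pytest.raises(ValueError):
            nj_tree(np.zeros((2, 2)), ["a", "b"])


# ---------------------------------------------------------------------------
# parsimony


def _oracle_fitch(root: TreeNode, columns: dict[str, str]) -> int:
    """Set-based Fitch, written independently of the bitmask version."""
    total = 0
    n_cols = len(next(iter(columns.values())))
    for ci in range(n_cols):
        def score(node):
            nonlocal_cost = 0
            if node.is_leaf:
                c = columns[node.name][ci]
                return ({c} if c not in "-X" else set("ACDEFGHIKLMNPQRSTVWY")), 0
            sets, cost = [], 0
            for ch in node.children:
                s, c = score(ch)
                sets.append(s)
                cost += c
            acc = sets[0]
            for s in sets[1:]:
                if acc & s:
                    acc = acc & s
                else:
                    acc = acc | s
                    cost += 1
            return acc, cost

        _, c = score(root)
        total += c
    return total


def _oracle_topologies(names):
    """Independent enumeration of unrooted topologies (nested-tuple form)."""
    if len(names) == 3:
        yield (names[0], names[1], names[2])
        return

    def insert(tree, leaf):
        # tree is a tuple (children...) at top level (3 children), internal
        # nodes are 2-tuples, leaves are strings
        def edges(sub, path):
            yield path
            if isinstance(sub, tuple) and len(sub) == 2:
                yield from edges(sub[0], path + (0,))
                yield from edges(sub[1], path + (1,))

        def replace(sub, path, value):
            if not path:
                return value
            lst = list(sub)
            lst[path[0]] = replace(lst[path[0]], path[1:], value)
            return tuple(lst)

        for i, top in enumerate(tree):
            for path in edges(top, ()):
                target = top
                for p in path:
                    target = target[p]
                new_top = replace(top, path, (target, leaf))
                yield tuple(t if k != i else new_top for k, t in enumerate(tree))

    trees = [(names[0], names[1], names[2])]
    for leaf in names[3:]:
        trees = [t2 for t in trees for t2 in insert(t, leaf)]
    seen = set()
    for t in trees:
        key = frozenset(_tuple_bips(t))
        if key not in seen:
            seen.add(key)
            yield t


def _tuple_bips(tree):
    def leaves(sub):
        if isinstance(sub, str):
            return frozenset({sub})
        return frozenset().union(*(leaves(c) for c in sub))

    all_leaves = leaves(tree)
    out = []

    def walk(sub):
        if isinstance(sub, str):
            return
        for c in sub:
            ls = leaves(c)
            if 2 <= len(ls) <= len(all_leaves) - 2:
                out.append(frozenset(ls))
            walk(c)

    walk(tree)
    canon = set()
    anchor = min(all_leaves)
    for s in out:
        canon.add(frozenset(all_leaves - s) if anchor in s else s)
    return canon


def _tuple_to_tree(tree) -> TreeNode:
    root = TreeNode()

    def build(sub):
        if isinstance(sub, str):
            return TreeNode(sub)
        node = TreeNode()
        for c in sub:
            node.add(build(c))
        return node

    for c in tree:
        root.add(build(c))
    return root


class TestParsimony:
    def test_clean_split_recovered(self):
        msa = Msa(
            ["a", "b", "c", "d"],
            ["AAAA", "AAAA", "CCCC", "CCCC"],
        )
        tree = parsimony_tree(msa, alphabet="nt")
        assert frozenset({"c", "d"}) in bipartitions(tree.root) or frozenset(
            {"a", "b"}
        ) in bipartitions(tree.root)

    def test_fitch_score_matches_set_union_oracle(self):
        rng = np.random.default_rng(21)
        names = ["a", "b", "c", "d", "e", "f"]
        for _ in range(10):
            rows = {
                n: "".join(rng.choice(list("ACDE"), size=12)) for n in names
            }
            tree = _random_tree(names, rng)
            msa = Msa(names, [rows[n] for n in names])
            from panforge.phylo import _encode_leaves

            codes = _encode_leaves(msa, "protein")
            assert fitch_score(tree, codes) == _oracle_fitch(tree, rows)

    def test_best_score_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(31)
        names = ["a", "b", "c", "d", "e", "f"]
        for _ in range(5):
            rows = {n: "".join(rng.choice(list("ACGT"), size=15)) for n in names}
            msa = Msa(names, [rows[n] for n in names])
            from panforge.phylo import _encode_leaves

            codes = _encode_leaves(msa, "nt")
            topos = list(_oracle_topologies(names))
            assert len(topos) == 105
            oracle_best = min(
                _oracle_fitch_nt(_tuple_to_tree(t), rows) for t in topos
            )
            got = parsimony_tree(msa, alphabet="nt")
            assert fitch_score(got.root, codes) == oracle_best

    def test_fewer_than_four_taxa_falls_back_to_nj(self):
        msa = Msa(["a", "b", "c"], ["AAA", "AAC", "CCC"])
        tree = parsimony_tree(msa, alphabet="nt")
        assert sorted(tree.leaf_names) == ["a", "b", "c"]


def _oracle_fitch_nt(root: TreeNode, rows: dict[str, str]) -> int:
    total = 0
    n_cols = len(next(iter(rows.values())))
    for ci in range(n_cols):
        def score(node):
            if node.is_leaf:
                c = rows[node.name][ci]
                return ({c} if c in "ACGT" else set("ACGT")), 0
            sets, cost = [], 0
            for ch in node.children:
                s, k = score(ch)
                sets.append(s)
                cost += k
            acc = sets[0]
            for s in sets[1:]:
                if acc & s:
                    acc = acc & s
                else:
                    acc = acc | s
                    cost += 1
            return acc, cost

        total += score(root)[1]
    return total


# ---------------------------------------------------------------------------
# bootstrap


def _nj_builder(msa: Msa) -> GeneTree:
    D, names = distance_matrix(msa, "p")
    return nj_tree(D, names)


class TestBootstrap:
    def test_identical_repeated_columns_full_support(self):
        rows = {
            "a": "AAAAAAAAAA",
            "b": "AAAAAAAAAC",
            "c": "CCCCCCCCCA",
            "d": "CCCCCCCCCC",
            "e": "GGGGGGGGGG",
        }
        # strong, repeated signal: every replicate sees the same splits
        msa = Msa(list(rows), [r * 5 for r in rows.values()])
        tree = bootstrap_supports(msa, _nj_builder, B=50, seed=1)
        assert tree.supports
        assert all(v == 100.0 for v in tree.supports.values())

    def test_single_replicate_supports_binary(self):
        rng = np.random.default_rng(4)
        rows = ["".join(rng.choice(list("ACGT"), size=30)) for _ in range(5)]
        msa = Msa([f"s{i}" for i in range(5)], rows)
        tree = bootstrap_supports(msa, _nj_builder, B=1, seed=2)
        assert set(tree.supports.values()) <= {0.0, 100.0}

    def test_true_splits_better_supported_than_false(self, small_sim):
        from panforge.simulate import SpeciesTree

        true_bips = parse_newick(SpeciesTree().newick_text).bipartitions()
        rng = np.random.default_rng(0)
        diffs = []
        for seed in range(20):
            # fresh clean alignments simulated on the species tree
            from panforge.simulate import SimConfig, simulate_pangenome

            cfg = SimConfig(
                n_core_families=1,
                n_accessory_families=0,
                n_specific_families=0,
                n_hgt_families=0,
                mean_gene_len=150,
                seed=100 + seed,
            )
            sim = simulate_pangenome(cfg)
            fam_genes = [
                (s.strain_id, s.records[0].protein) for s in sim.strains
            ]
            msa = progressive_msa(fam_genes)
            tree = bootstrap_supports(msa, _nj_builder, B=50, seed=seed)
            for bip, sup in tree.supports.items():
                diffs.append((bip in true_bips, sup))
        true_sup = [s for ok, s in diffs if ok]
        false_sup = [s for ok, s in diffs if not ok]
        if false_sup:
            assert np.mean(true_sup) > np.mean(false_sup)
        else:
            assert np.mean(true_sup) > 50


# ---------------------------------------------------------------------------
# species tree and congruence


class TestSpeciesTree:
    def test_recovers_generating_topology(self, small_sim, small_clusters):
        from panforge import pipeline
        from panforge.simulate import SpeciesTree

        clusters, _ = small_clusters
        msas = pipeline.single_copy_msas(small_sim, clusters)
        assert msas
        tree = species_tree(msas, B=50, seed=3)
        true = parse_newick(SpeciesTree().newick_text)
        assert rf_distance(tree, true) == 0

    def test_single_cluster_equals_gene_tree(self, small_sim, small_clusters):
        from panforge import pipeline

        clusters, _ = small_clusters
        msas = pipeline.single_copy_msas(small_sim, clusters)
        tree = species_tree(msas[:1], B=5, seed=0)
        D, names = distance_matrix(msas[0], "poisson")
        gene = nj_tree(D, names)
        assert bipartitions(tree.root) == bipartitions(gene.root)

    def test_congruent_genes_give_full_support(self):
        rows = {"a": "AAAAA", "b": "AAAAC", "c": "CCCCA", "d": "CCCCC"}
        msa = Msa(list(rows), list(rows.values()))
        tree = species_tree([msa] * 5, B=20, seed=1)
        assert all(v == 100.0 for v in tree.supports.values())

    def test_no_clusters_rejected(self):
        with pytest.raises(ValueError):
            species_tree([])


class TestRobinsonFoulds:
    def test_identical_trees_zero(self):
        t = parse_newick("((a,b),(c,d),e);")
        assert rf_distance(t, parse_newick("((a,b),(c,d),e);")) == 0

    def test_all_five_taxon_pairs_match_bipartition_brute_force(self):
        names = ["a", "b", "c", "d", "e"]
        topos = list(_oracle_topologies(names))
        assert len(topos) == 15
        trees = [GeneTree(_tuple_to_tree(t)) for t in topos]
        keys = [_tuple_bips(t) for t in topos]
        for (t1, k1), (t2, k2) in itertools.combinations(zip(trees, keys), 2):
            assert rf_distance(t1, t2) == len(k1 ^ k2)

    def test_caterpillar_pair_attains_upper_bound(self):
        n = 7
        left = parse_newick("(a,b,(c,(d,(e,(f,g)))));")
        right = parse_newick("(g,e,(c,(a,(f,(b,d)))));")
        assert rf_distance(left, right) == 2 * (n - 3)

    def test_leaf_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rf_distance(parse_newick("((a,b),c,d);"), parse_newick("((a,b),c,e);"))

    def test_metric_properties_on_five_taxon_set(self):
        names = ["a", "b", "c", "d", "e"]
        trees = [GeneTree(_tuple_to_tree(t)) for t in _oracle_topologies(names)]
        for t in trees[:5]:
            assert rf_distance(t, t) == 0
        for t1, t2 in itertools.combinations(trees[:6], 2):
            assert rf_distance(t1, t2) == rf_distance(t2, t1)
        for t1, t2, t3 in itertools.combinations(trees[:5], 3):
            assert rf_distance(t1, t3) <= rf_distance(t1, t2) + rf_distance(t2, t3)

    def test_matches_dendropy_on_random_trees(self):
        import dendropy

        rng = np.random.default_rng(55)
        names = [f"t{k}" for k in range(8)]
        for _ in range(10):
            a = GeneTree(_random_tree(names, rng))
            b = GeneTree(_random_tree(names, rng))
            tns = dendropy.TaxonNamespace()
            da = dendropy.Tree.get(data=a.newick(), schema="newick", taxon_namespace=tns)
            db = dendropy.Tree.get(data=b.newick(), schema="newick", taxon_namespace=tns)
            expected = dendropy.calculate.treecompare.symmetric_difference(da, db)
            assert rf_distance(a, b) == expected


# ---------------------------------------------------------------------------
# HGT / origin classification


def _labeled_tree(newick: str, supports_value: float = 100.0) -> GeneTree:
    tree = parse_newick(newick)
    tree.supports = {b: supports_value for b in tree.bipartitions()}
    return tree


INGROUP_LEAVES = {"g1", "g2", "g3"}
LABELS = {
    "bac1": "bacteria",
    "bac2": "bacteria",
    "grn1": "green_algae",
    "grn2": "green_algae",
    "red1": "red_algae",
    "red2": "red_algae",
    "euk1": "other_eukaryote",
    "euk2": "other_eukaryote",
}


class TestHgtClassify:
    def _tree(self, sister: str, support=100.0):
        return _labeled_tree(
            f"((((g1,g2),g3),({sister}1,{sister}2)),((euk1,euk2),(red1,red2)),(grn1,grn2));"
            if sister == "bac"
            else f"((((g1,g2),g3),({sister}1,{sister}2)),((euk1,euk2),(bac1,bac2)),"
            + ("(red1,red2));" if sister == "grn" else "(grn1,grn2));"),
            support,
        )

    def test_bacterial_sister_in_both_trees(self):
        t = self._tree("bac")
        call = hgt_classify("fam", t, t, INGROUP_LEAVES, LABELS)
        assert call.call == "hgt_bacterial"
        assert call.agreement

    def test_eukaryote_sister_is_vertical(self):
        t = _labeled_tree(
            "((((g1,g2),g3),(euk1,euk2)),((bac1,bac2),(red1,red2)),(grn1,grn2));"
        )
        call = hgt_classify("fam", t, t, INGROUP_LEAVES, LABELS)
        assert call.call == "vertical"

    def test_disagreeing_trees_unresolved_never_hgt(self):
        t_bac = self._tree("bac")
        t_grn = self._tree("grn")
        call = hgt_classify("fam", t_bac, t_grn, INGROUP_LEAVES, LABELS)
        assert call.call == "unresolved"
        assert not call.agreement

    def test_impossible_support_collapses_to_unresolved(self):
        t = self._tree("bac")
        call = hgt_classify("fam", t, t, INGROUP_LEAVES, LABELS, support_min=101)
        assert call.call == "unresolved"

    def test_unlabeled_leaf_rejected(self):
        t = self._tree("bac")
        labels = dict(LABELS)
        del labels["euk2"]
        with pytest.raises(ValueError, match="unlabeled"):
            hgt_classify("fam", t, t, INGROUP_LEAVES, labels)


class TestOriginClassify:
    def test_red_sister(self):
        t = _labeled_tree(
            "((((g1,g2),g3),(red1,red2)),((euk1,euk2),(bac1,bac2)),(grn1,grn2));"
        )
        assert origin_classify("fam", t, t, INGROUP_LEAVES, LABELS) == "red"

    def test_conflicting_sisters_unresolved(self):
        t1 = _labeled_tree(
            "((((g1,g2),g3),(red1,red2)),((euk1,euk2),(bac1,bac2)),(grn1,grn2));"
        )
        t2 = _labeled_tree(
            "((((g1,g2),g3),(grn1,grn2)),((euk1,euk2),(bac1,bac2)),(red1,red2));"
        )
        assert origin_classify("fam", t1, t2, INGROUP_LEAVES, LABELS) == "unresolved"

    def test_planted_families_recovered(self, small_sim):
        from panforge import pipeline

        fams = sorted(small_sim.references)[:4]
        cls = pipeline.classify_families(small_sim, B=50, seed=5, family_ids=fams)
        origin_of = dict(
            small_sim.truth.table.drop_duplicates("family")[["family", "origin"]].values
        )
        correct = sum(
            fc.origin == origin_of[fc.family_id]
            for fc in cls
            if origin_of[fc.family_id] in {"host", "green", "red"}
        )
        scored = sum(1 for fc in cls if origin_of[fc.family_id] in {"host", "green", "red"})
        assert scored >= 3
        assert correct / scored >= 0.75
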