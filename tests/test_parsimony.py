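"""Fitch scoring, branch-and-bound optimality, monophyly."""

import itertools
import random

import pytest

from lectinscape.parsimony import (
    CharacterMatrix,
    UnrootedTree,
    branch_and_bound_search,
    fitch_score,
    is_monophyletic,
    pad_alignment,
)


def enumerate_topologies(n):
    """Independent exhaustive topology enumerator (edge insertion)."""
    trees = [(1, 2)]
    for k in range(3, n):
        grown = []
        for t in trees:
            grown.extend(_insertions(t, k))
        trees = grown
    return trees


def _insertions(node, leaf):
    yield (node, leaf)
    if not isinstance(node, int):
        for left in _insertions(node[0], leaf):
            yield (left, node[1])
        for right in _insertions(node[1], leaf):
            yield (node[0], right)


def sankoff_oracle(tree: UnrootedTree, matrix: CharacterMatrix) -> int:
    """Brute-force minimum changes: enumerate every internal-node state
    assignment per site (small alphabets only)."""
    taxa_index = {t: i for i, t in enumerate(matrix.taxa)}
    # collect edges + internal nodes of the (leaf0, structure) rooted tree
    nodes = []

    def walk(node):
        nodes.append(node)
        if not isinstance(node, int):
            walk(node[0])
            walk(node[1])

    walk(tree.structure)
    internal = [n for n in nodes if not isinstance(n, int)]
    alphabet = sorted({c for row in matrix.rows for c in row})

    total = 0
    for site in range(matrix.length):
        leaf_state = {
            i: matrix.rows[taxa_index[t]][site] for i, t in enumerate(tree.taxa)
        }

        def state_of(node, assign):
            return leaf_state[node] if isinstance(node, int) else assign[id(node)]

        best = None
        for combo in itertools.product(alphabet, repeat=len(internal) + 1):
            assign = {id(n): s for n, s in zip(internal, combo[:-1])}
            root_state = combo[-1]
            changes = 0
            # root joins leaf 0 and the structure top
            changes += root_state != leaf_state[0]
            changes += root_state != state_of(tree.structure, assign)

            def count(node):
                nonlocal changes
                if isinstance(node, int):
                    return
                me = assign[id(node)]
                for child in node:
                    changes += me != state_of(child, assign)
                    count(child)

            count(tree.structure)
            if best is None or changes < best:
                best = changes
        total += best
    return total


class TestFitch:
    def test_identical_sequences_zero(self):
        m = CharacterMatrix(("a", "b", "c", "d"), ("ACGT",) * 4)
        for t in enumerate_topologies(4):
            assert fitch_score(UnrootedTree.from_structure(m.taxa, t), m) == 0

    def test_textbook_four_taxon_single_site(self):
        m = CharacterMatrix(("t1", "t2", "t3", "t4"), ("A", "A", "T", "T"))
        good = UnrootedTree.from_groups(m.taxa, ("t1", "t2"), ("t3", "t4"))
        bad = UnrootedTree.from_groups(m.taxa, ("t1", "t3"), ("t2", "t4"))
        assert fitch_score(good, m) == 1
        assert fitch_score(bad, m) == 2

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_state_enumeration_oracle(self, seed):
        rng = random.Random(seed)
        n = 5
        taxa = tuple(f"x{i}" for i in range(n))
        rows = tuple("".join(rng.choice("AC-T") for _ in range(8)) for _ in range(n))
        m = CharacterMatrix(taxa, rows)
        for t in rng.sample(enumerate_topologies(n), 4):
            tree = UnrootedTree.from_structure(taxa, t)
            assert fitch_score(tree, m) == sankoff_oracle(tree, m)

    def test_invariant_under_leaf_permutation(self):
        rng = random.Random(3)
        taxa = ("a", "b", "c", "d", "e")
        rows = tuple("".join(rng.choice("ACDEF") for _ in range(10)) for _ in taxa)
        m = CharacterMatrix(taxa, rows)
        tree = UnrootedTree.from_groups(taxa, ("a", "b"), (("c", "d"), "e"))
        perm = ("c", "e", "a", "d", "b")
        m2 = CharacterMatrix(perm, tuple(rows[taxa.index(t)] for t in perm))
        assert fitch_score(tree, m) == fitch_score(tree, m2)

    def test_gap_is_a_state_by_default(self):
        m = CharacterMatrix(("a", "b", "c", "d"), ("A", "A", "-", "-"))
        tree = UnrootedTree.from_groups(m.taxa, ("a", "b"), ("c", "d"))
        assert fitch_score(tree, m) == 1
        assert fitch_score(tree, m, gaps_as_missing=True) == 0

    def test_taxa_mismatch_rejected(self):
        m = CharacterMatrix(("a", "b", "c"), ("A", "A", "A"))
        tree = UnrootedTree.from_groups(("a", "b", "x"), "a", "b", "x")
        with pytest.raises(ValueError, match="taxa"):
            fitch_score(tree, m)


class TestBranchAndBound:
    def test_three_taxa_single_topology(self):
        m = CharacterMatrix(("a", "b", "c"), ("AG", "AT", "CT"))
        score, trees = branch_and_bound_search(m)
        assert len(trees) == 1
        assert score == fitch_score(trees[0], m)

    @pytest.mark.parametrize("seed", range(8))
    def test_equals_exhaustive_enumeration(self, seed):
        rng = random.Random(seed)
        n = rng.randint(4, 7)
        taxa = tuple(f"t{i}" for i in range(n))
        rows = tuple(
            "".join(rng.choice("ACDEFGHIKL-") for _ in range(15)) for _ in range(n)
        )
        m = CharacterMatrix(taxa, rows)
        score, trees = branch_and_bound_search(m)

        best, bestset = None, set()
        for t in enumerate_topologies(n):
            s = fitch_score(UnrootedTree.from_structure(taxa, t), m)
            if best is None or s < best:
                best, bestset = s, {UnrootedTree.from_structure(taxa, t).structure}
            elif s == best:
                bestset.add(UnrootedTree.from_structure(taxa, t).structure)
        assert score == best
        assert {t.structure for t in trees} == bestset

    def test_beats_any_random_topology(self):
        rng = random.Random(11)
        taxa = tuple(f"t{i}" for i in range(6))
        rows = tuple("".join(rng.choice("ACDE") for _ in range(20)) for _ in taxa)
        m = CharacterMatrix(taxa, rows)
        score, _ = branch_and_bound_search(m)
        for t in rng.sample(enumerate_topologies(6), 20):
            assert score <= fitch_score(UnrootedTree.from_structure(taxa, t), m)

    def test_planted_clades_recovered(self):
        # two strongly divergent groups: a triplet vs a quartet
        clade1 = {f"eul{i}": "AAAAAAAAAACCCCC" for i in range(3)}
        clade2 = {f"ric{i}": "TTTTTTTTTTGGGGG" for i in range(4)}
        seqs = {}
        rng = random.Random(2)
        for i, (name, base) in enumerate({**clade1, **clade2}.items()):
            pos = rng.randrange(len(base))
            seqs[name] = base[:pos] + rng.choice("ACGT") + base[pos + 1:]
        m = pad_alignment(seqs)
        _score, trees = branch_and_bound_search(m)
        assert trees
        for t in trees:
            assert is_monophyletic(t, set(clade1))
            assert is_monophyletic(t, set(clade2))

    def test_too_many_taxa_refused(self):
        taxa = tuple(f"t{i}" for i in range(16))
        m = CharacterMatrix(taxa, ("A",) * 16)
        with pytest.raises(ValueError, match="guard"):
            branch_and_bound_search(m)


class TestMonophyly:
    def test_single_taxon_always_true(self):
        t = UnrootedTree.from_groups(("A", "B", "C", "D"), ("A", "B"), ("C", "D"))
        for taxon in t.taxa:
            assert is_monophyletic(t, {taxon})

    def test_cross_clade_pair_false(self):
        t = UnrootedTree.from_groups(("A", "B", "C", "D"), ("A", "B"), ("C", "D"))
        assert not is_monophyletic(t, {"A", "C"})
        assert is_monophyletic(t, {"A", "B"})
        assert is_monophyletic(t, {"C", "D"})  # complement side

    def test_unknown_taxon_rejected(self):
        t = UnrootedTree.from_groups(("A", "B", "C", "D"), ("A", "B"), ("C", "D"))
        with pytest.raises(ValueError, match="unknown"):
            is_monophyletic(t, {"Z"})

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_dendropy_bipartitions(self, seed):
        dendropy = pytest.importorskip("dendropy")
        rng = random.Random(seed)
        n = rng.randint(4, 7)
        taxa = tuple(f"t{i}" for i in range(n))
        structure = rng.choice(enumerate_topologies(n))
        tree = UnrootedTree.from_structure(taxa, structure)

        # independent oracle: enumerate dendropy edge bipartitions
        dtree = dendropy.Tree.get(data=tree.newick(), schema="newick")
        labels = frozenset(taxa)
        sides = set()
        for node in dtree.preorder_node_iter():
            leaf_set = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
            sides.add(leaf_set)
            sides.add(labels - leaf_set)
        for size in range(1, n):
            for subset in itertools.combinations(taxa, size):
                assert is_monophyletic(tree, subset) == (frozenset(subset) in sides)
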