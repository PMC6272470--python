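"""Small-scale maximum-parsimony tree search.

Fitch small parsimony scores a fixed unrooted topology as the minimum
number of character-state changes over all sites; the branch-and-bound
search (max-mini style: stepwise taxon addition with a lower bound
pruning partial trees) returns the globally optimal topology set.  The
intended use is family-level checks on a handful of aligned lectin
domains — e.g. whether EUL homologs form a clade separate from ricin B
homologs — so the search is guarded to a taxon count where exact search
is cheap.

Gaps are treated as a 21st character state by default (an indel is
evidence, not ignorance); ``gaps_as_missing=True`` switches them to
fully ambiguous states.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

from Bio import SeqIO

__all__ = [
    "CharacterMatrix",
    "UnrootedTree",
    "fitch_score",
    "branch_and_bound_search",
    "is_monophyletic",
    "pad_alignment",
]

MAX_SEARCH_TAXA = 15


@dataclass(frozen=True)
class CharacterMatrix:
    """Aligned characters for >= 3 taxa (rows of equal length)."""

    taxa: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.rows):
            raise ValueError("one row per taxon required")
        if len(self.taxa) < 3:
            raise ValueError("need >= 3 taxa")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxon labels")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise ValueError("rows must be aligned to equal length")

    @property
    def length(self) -> int:
        return len(self.rows[0])

    @classmethod
    def from_fasta(cls, source) -> "CharacterMatrix":
        """Read an aligned FASTA (equal-length records)."""
        records = list(SeqIO.parse(source, "fasta"))
        return cls(
            taxa=tuple(r.id for r in records),
            rows=tuple(str(r.seq).upper() for r in records),
        )


def pad_alignment(sequences: dict[str, str]) -> CharacterMatrix:
    """Trivial fixture aligner: right-pad every sequence with gaps.

    Not a real aligner — it exists so tests and toy examples can build
    a CharacterMatrix from unaligned strings.
    """
    n = max(len(s) for s in sequences.values())
    return CharacterMatrix(
        taxa=tuple(sequences),
        rows=tuple(s.upper().ljust(n, "-") for s in sequences.values()),
    )


# ---------------------------------------------------------------------------
# Tree representation
#
# An unrooted binary tree over taxa (t0, t1, ..., tn-1) is stored as a
# nested tuple `structure` over the indices 1..n-1 (leaf = int, internal
# node = 2-tuple), attached to leaf 0 by the root edge.  Every node of
# `structure` corresponds to the edge above it, which gives exactly the
# 2n-3 edges of the unrooted tree (the edge above the top node is the
# root edge to leaf 0).
# ---------------------------------------------------------------------------


def _min_leaf(node) -> int:
    if isinstance(node, int):
        return node
    return min(_min_leaf(node[0]), _min_leaf(node[1]))


def _canonical(node):
    if isinstance(node, int):
        return node
    a, b = _canonical(node[0]), _canonical(node[1])
    return (a, b) if _min_leaf(a) < _min_leaf(b) else (b, a)


def _leaves(node) -> frozenset[int]:
    if isinstance(node, int):
        return frozenset((node,))
    return _leaves(node[0]) | _leaves(node[1])


@dataclass(frozen=True)
class UnrootedTree:
    """Unrooted binary tree with unique leaf labels.

    ``structure`` is the canonical nested-tuple form over taxon indices
    1..n-1; index 0 hangs off the root edge.  Trees compare equal iff
    their topologies are equal (labels and structure are canonicalized).
    """

    taxa: tuple[str, ...]
    structure: tuple | int

    @classmethod
    def from_structure(cls, taxa: Sequence[str], structure) -> "UnrootedTree":
        return cls(taxa=tuple(taxa), structure=_canonical(structure))

    @classmethod
    def from_groups(cls, taxa: Sequence[str], *groups) -> "UnrootedTree":
        """Build from nested tuples of labels, e.g. (("A","B"),("C","D"))."""
        index = {t: i for i, t in enumerate(taxa)}

        def conv(node):
            if isinstance(node, str):
                return index[node]
            if len(node) == 1:
                return conv(node[0])
            left = conv(node[0])
            for item in node[1:]:
                left = (left, conv(item))
            return left

        structure = conv(groups if len(groups) > 1 else groups[0])
        # Detach leaf 0 from wherever it sits: re-root along its edge.
        structure = _detach_zero(structure)
        return cls.from_structure(taxa, structure)

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def splits(self) -> frozenset[frozenset[str]]:
        """All edge bipartitions, each given as the side without taxa[0]."""
        out: set[frozenset[int]] = set()

        def walk(node):
            out.add(_leaves(node))
            if not isinstance(node, int):
                walk(node[0])
                walk(node[1])

        walk(self.structure)
        return frozenset(
            frozenset(self.taxa[i] for i in side) for side in out
        )

    def newick(self) -> str:
        def fmt(node):
            if isinstance(node, int):
                return self.taxa[node]
            return f"({fmt(node[0])},{fmt(node[1])})"

        s = self.structure
        if isinstance(s, int):
            return f"({self.taxa[0]},{self.taxa[s]});"
        return f"({self.taxa[0]},{fmt(s[0])},{fmt(s[1])});"


def _detach_zero(structure):
    """Re-root the nested-tuple form so that leaf 0 hangs off the top."""
    if isinstance(structure, int) or 0 not in _leaves(structure):
        raise ValueError("taxon index 0 must appear in the tree")

    def split_out(node):
        # returns (remainder, found) where remainder is node minus leaf 0
        if isinstance(node, int):
            return (None, node == 0)
        left, right = node
        if 0 in _leaves(left):
            rem, _ = split_out(left)
            return (right if rem is None else (rem, right), True)
        rem, _ = split_out(right)
        return (left if rem is None else (left, rem), True)

    remainder, _found = split_out(structure)
    return remainder


# ---------------------------------------------------------------------------
# Fitch scoring
# ---------------------------------------------------------------------------


def _encode_patterns(
    matrix: CharacterMatrix, order: Sequence[int], gaps_as_missing: bool
) -> tuple[list[tuple[int, ...]], list[int]]:
    """Site-pattern compression: unique columns (as per-taxon bitmask
    tuples, in ``order``) with multiplicities."""
    alphabet = sorted({c for row in matrix.rows for c in row})
    bit = {c: 1 << i for i, c in enumerate(alphabet)}
    full = (1 << len(alphabet)) - 1
    if gaps_as_missing and "-" in bit:
        bit["-"] = full

    counts = Counter(
        tuple(bit[matrix.rows[i][site]] for i in order)
        for site in range(matrix.length)
    )
    patterns = list(counts)
    weights = [counts[p] for p in patterns]
    return patterns, weights


def _fitch_pattern(structure, leaf0_mask: int, masks: tuple[int, ...]) -> int:
    """Changes for one site pattern on (leaf0, structure)."""
    changes = 0

    def down(node) -> int:
        nonlocal changes
        if isinstance(node, int):
            return masks[node]
        a, b = down(node[0]), down(node[1])
        inter = a & b
        if inter:
            return inter
        changes += 1
        return a | b

    top = down(structure)
    if not (top & leaf0_mask):
        changes += 1
    return changes


def fitch_score(
    tree: UnrootedTree, matrix: CharacterMatrix, *, gaps_as_missing: bool = False
) -> int:
    """Minimum number of state changes of the matrix on the tree.

    Invariant under re-rooting and leaf-order permutation.  Gap ('-')
    is a real 21st state unless ``gaps_as_missing``.
    """
    if set(tree.taxa) != set(matrix.taxa):
        raise ValueError("tree taxa and matrix taxa differ")
    order = [matrix.taxa.index(t) for t in tree.taxa]
    patterns, weights = _encode_patterns(matrix, order, gaps_as_missing)
    total = 0
    for masks, w in zip(patterns, weights):
        total += w * _fitch_pattern(tree.structure, masks[0], masks)
    return total


# ---------------------------------------------------------------------------
# Branch and bound
# ---------------------------------------------------------------------------


def _insert_everywhere(structure, leaf: int):
    """All trees obtained by attaching ``leaf`` on each edge."""
    yield (structure, leaf)
    if not isinstance(structure, int):
        for left in _insert_everywhere(structure[0], leaf):
            yield (left, structure[1])
        for right in _insert_everywhere(structure[1], leaf):
            yield (structure[0], right)


def _states_lower_bounds(patterns, weights, n_taxa: int) -> list[int]:
    """lb[k] = minimum extra changes needed to add taxa k..n-1 to any
    tree over taxa 0..k-1: one change per site per state that is the
    sole possibility of some not-yet-added taxon and cannot occur among
    the added ones.  Ambiguous (multi-bit) states never contribute
    required new states, keeping the bound valid for missing data."""
    lb = [0] * (n_taxa + 1)
    for masks, w in zip(patterns, weights):
        single_after = [0] * (n_taxa + 1)
        for i in range(n_taxa - 1, -1, -1):
            mask = masks[i]
            is_single = mask & (mask - 1) == 0
            single_after[i] = single_after[i + 1] | (mask if is_single else 0)
        seen = 0
        for k in range(n_taxa + 1):
            new = single_after[k] & ~seen
            lb[k] += w * bin(new).count("1")
            if k < n_taxa:
                seen |= masks[k]
    return lb


def branch_and_bound_search(
    matrix: CharacterMatrix, *, gaps_as_missing: bool = False
) -> tuple[int, list[UnrootedTree]]:
    """Exact maximum-parsimony search by branch and bound.

    Taxa are added stepwise in input order; a partial tree is pruned
    when its Fitch score plus a per-site new-states lower bound already
    exceeds the best complete score.  Returns the optimal score and ALL
    optimal topologies, in canonical newick sort order.
    """
    n = len(matrix.taxa)
    if n > MAX_SEARCH_TAXA:
        raise ValueError(
            f"{n} taxa exceeds the exact-search guard ({MAX_SEARCH_TAXA}); "
            "prune the matrix or use a heuristic tool for larger problems"
        )
    order = list(range(n))
    patterns, weights = _encode_patterns(matrix, order, gaps_as_missing)
    lower = _states_lower_bounds(patterns, weights, n)

    def score_structure(structure) -> int:
        total = 0
        for masks, w in zip(patterns, weights):
            total += w * _fitch_pattern(structure, masks[0], masks)
        return total

    best_score = score_structure(_grow_greedy(n))
    best: list = []

    def recurse(structure, k: int) -> None:
        nonlocal best_score, best
        s = score_structure(structure)
        if k == n:
            if s < best_score:
                best_score, best = s, [structure]
            elif s == best_score:
                best.append(structure)
            return
        if s + lower[k] > best_score:
            return
        for candidate in _insert_everywhere(structure, k):
            recurse(candidate, k + 1)

    if n == 3:
        best_score = score_structure((1, 2))
        best = [(1, 2)]
    else:
        recurse((1, 2), 3)

    trees = sorted(
        {UnrootedTree.from_structure(matrix.taxa, b) for b in best},
        key=lambda t: t.newick(),
    )
    return best_score, trees


def _grow_greedy(n: int) -> tuple:
    """A caterpillar topology used to seed the initial upper bound."""
    structure: tuple | int = (1, 2)
    for k in range(3, n):
        structure = (structure, k)
    return structure


def is_monophyletic(tree: UnrootedTree, taxa_subset: Iterable[str]) -> bool:
    """True iff some edge bipartition separates exactly this subset.

    On an unrooted tree, "monophyletic" means the subset is one side of
    some edge; a single taxon is always monophyletic (its leaf edge).
    """
    subset = frozenset(taxa_subset)
    if not subset:
        raise ValueError("empty taxon subset")
    universe = frozenset(tree.taxa)
    unknown = subset - universe
    if unknown:
        raise ValueError("unknown taxa: " + ", ".join(sorted(unknown)))
    if subset == universe:
        raise ValueError("subset must be a proper subset of the tree's taxa")
    for side in tree.splits():
        if side == subset or (universe - side) == subset:
            return True
    return False
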