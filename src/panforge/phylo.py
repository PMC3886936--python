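"""Gene and species trees: alignment, distance and parsimony reconstruction,
bootstrap, topology congruence, and sister-clade origin classification.

Two methodologically independent reconstructions are used throughout —
neighbor joining on corrected distances and Fitch parsimony with NNI
refinement — and any transfer/origin call must be supported by both, the
two-method agreement rule. Parsimony search is exact (exhaustive topology
enumeration) for small taxon sets and NNI hill-climbing above that.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np

from .homology import ScoringScheme

DIST_CAP = 10.0  # distance assigned when a correction diverges (p >= 1)
EXHAUSTIVE_PARSIMONY_MAX_TAXA = 7

PROTEIN_SYMBOLS = "ACDEFGHIKLMNPQRSTVWYX-"
NT_SYMBOLS = "ACGTX-"


# ---------------------------------------------------------------------------
# multiple sequence alignment


@dataclass
class Msa:
    """A multiple alignment: parallel ids and equal-length gapped rows."""

    names: list[str]
    rows: list[str]

    def __post_init__(self):
        if len(self.names) != len(self.rows):
            raise ValueError("names/rows length mismatch")
        if self.rows and len({len(r) for r in self.rows}) != 1:
            raise ValueError("aligned rows must have equal length")

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def __len__(self) -> int:
        return len(self.rows)

    def ungapped(self, name: str) -> str:
        return self.rows[self.names.index(name)].replace("-", "")

    def subset_columns(self, cols: Sequence[int]) -> "Msa":
        rows = ["".join(r[c] for c in cols) for r in self.rows]
        return Msa(list(self.names), rows)


def _kmer_distance(a: str, b: str, k: int = 3) -> float:
    ka = {a[i : i + k] for i in range(max(len(a) - k + 1, 0))}
    kb = {b[i : i + k] for i in range(max(len(b) - k + 1, 0))}
    if not ka or not kb:
        return 1.0
    return 1.0 - len(ka & kb) / min(len(ka), len(kb))


def _profile_counts(rows: list[str], symbols: str) -> np.ndarray:
    """cols × symbols count matrix of a profile."""
    index = {c: i for i, c in enumerate(symbols)}
    unknown = index.get("X", 0)
    out = np.zeros((len(rows[0]), len(symbols)))
    for r in rows:
        for j, c in enumerate(r):
            out[j, index.get(c, unknown)] += 1
    return out


def _symbol_score_matrix(scheme: ScoringScheme, symbols: str) -> np.ndarray:
    n = len(symbols)
    S = np.zeros((n, n))
    for i, a in enumerate(symbols):
        for j, b in enumerate(symbols):
            if a == "-" and b == "-":
                S[i, j] = 0.0
            elif a == "-" or b == "-":
                S[i, j] = scheme.gap_extend
            elif a in "ACGT" and b in "ACGT" and set(symbols) == set(NT_SYMBOLS):
                S[i, j] = 5.0 if a == b else -4.0
            else:
                ia = scheme.encode(a)[0]
                ib = scheme.encode(b)[0]
                S[i, j] = scheme.matrix[ia, ib]
    return S


def _global_affine(col_scores: np.ndarray, go: float, ge: float):
    """Needleman–Wunsch with affine gaps on a precomputed column-score
    matrix; returns the two gap patterns (True = gap) of the merged result."""
    m, n = col_scores.shape
    NEG = -1e12
    H = np.full((m + 1, n + 1), NEG)
    E = np.full((m + 1, n + 1), NEG)
    F = np.full((m + 1, n + 1), NEG)
    H[0, 0] = 0.0
    for i in range(1, m + 1):
        F[i, 0] = go + (i - 1) * ge
        H[i, 0] = F[i, 0]
    for j in range(1, n + 1):
        E[0, j] = go + (j - 1) * ge
        H[0, j] = E[0, j]
    for d in range(2, m + n + 1):
        lo = max(1, d - n)
        hi = min(m, d - 1)
        if lo > hi:
            continue
        i = np.arange(lo, hi + 1)
        j = d - i
        e = np.maximum(H[i, j - 1] + go, E[i, j - 1] + ge)
        f = np.maximum(H[i - 1, j] + go, F[i - 1, j] + ge)
        h = np.maximum(H[i - 1, j - 1] + col_scores[i - 1, j - 1], np.maximum(e, f))
        E[i, j], F[i, j], H[i, j] = e, f, h
    gaps_a: list[bool] = []
    gaps_b: list[bool] = []
    i, j = m, n
    state = "H"
    while i > 0 or j > 0:
        if state == "H":
            if i > 0 and j > 0 and H[i, j] == H[i - 1, j - 1] + col_scores[i - 1, j - 1]:
                gaps_a.append(False)
                gaps_b.append(False)
                i, j = i - 1, j - 1
            elif H[i, j] == F[i, j]:
                state = "F"
            else:
                state = "E"
        elif state == "F":
            gaps_a.append(False)
            gaps_b.append(True)
            opened = (F[i, j] == H[i - 1, j] + go) or i == 1
            i -= 1
            state = "H" if opened else "F"
        else:
            gaps_a.append(True)
            gaps_b.append(False)
            opened = (E[i, j] == H[i, j - 1] + go) or j == 1
            j -= 1
            state = "H" if opened else "E"
    return gaps_a[::-1], gaps_b[::-1]


def _merge_profiles(
    a: Msa, b: Msa, scheme: ScoringScheme, symbols: str, S: np.ndarray
) -> Msa:
    ca = _profile_counts(a.rows, symbols)
    cb = _profile_counts(b.rows, symbols)
    col_scores = (ca @ S @ cb.T) / (len(a) * len(b))
    gaps_a, gaps_b = _global_affine(col_scores, scheme.gap_open, scheme.gap_extend)

    def expand(rows: list[str], gaps: list[bool]) -> list[str]:
        out = []
        for r in rows:
            it = iter(r)
            out.append("".join("-" if g else next(it) for g in gaps))
        return out

    return Msa(a.names + b.names, expand(a.rows, gaps_a) + expand(b.rows, gaps_b))


def progressive_msa(
    seqs: dict[str, str] | list[tuple[str, str]],
    scheme: ScoringScheme | None = None,
    alphabet: str = "protein",
) -> Msa:
    """Progressive alignment: NJ guide tree on k-mer distances, then
    profile–profile merging with affine-gap dynamic programming."""
    items = list(seqs.items()) if isinstance(seqs, dict) else list(seqs)
    if not items:
        raise ValueError("no sequences")
    scheme = scheme or ScoringScheme()
    symbols = PROTEIN_SYMBOLS if alphabet == "protein" else NT_SYMBOLS
    S = _symbol_score_matrix(scheme, symbols)
    names = [n for n, _ in items]
    if len(items) == 1:
        return Msa(names, [items[0][1]])
    profiles = {n: Msa([n], [s]) for n, s in items}
    if len(items) == 2:
        return _merge_profiles(profiles[names[0]], profiles[names[1]], scheme, symbols, S)

    n = len(items)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = _kmer_distance(items[i][1], items[j][1])
    guide = nj_tree(D, names)

    def merge(node: "TreeNode") -> Msa:
        if node.is_leaf:
            return profiles[node.name]
        parts = [merge(c) for c in node.children]
        acc = parts[0]
        for p in parts[1:]:
            acc = _merge_profiles(acc, p, scheme, symbols, S)
        return acc

    return merge(guide.root)


# ---------------------------------------------------------------------------
# trees


class TreeNode:
    __slots__ = ("name", "children", "length", "parent")

    def __init__(self, name: str | None = None, length: float = 0.0):
        self.name = name
        self.children: list["TreeNode"] = []
        self.length = length
        self.parent: "TreeNode" | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    def postorder(self) -> Iterable["TreeNode"]:
        stack, out = [self], []
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return reversed(out)

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.postorder() if n.is_leaf]

    def copy(self) -> "TreeNode":
        clone = TreeNode(self.name, self.length)
        for c in self.children:
            clone.add(c.copy())
        return clone


@dataclass
class GeneTree:
    """An unrooted tree (stored rooted at an internal node) with per-edge
    bootstrap supports and a method tag."""

    root: TreeNode
    method: str = "nj"
    supports: dict[frozenset, float] = field(default_factory=dict)

    @property
    def leaf_names(self) -> list[str]:
        return self.root.leaf_names()

    def bipartitions(self) -> set[frozenset]:
        return bipartitions(self.root)

    def newick(self) -> str:
        supports = self.supports
        leaves = frozenset(self.leaf_names)

        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                return f"{node.name}:{node.length:.6f}"
            inner = ",".join(fmt(c) for c in node.children)
            label = ""
            side = frozenset(node.leaf_names())
            canon = _canonical_split(side, leaves)
            if canon is not None and canon in supports:
                label = f"{supports[canon]:.0f}"
            return f"({inner}){label}:{node.length:.6f}"

        inner = ",".join(fmt(c) for c in self.root.children)
        return f"({inner});"


def _canonical_split(side: frozenset, leaves: frozenset) -> frozenset | None:
    """Canonical form of a bipartition side; None if trivial."""
    if len(side) < 2 or len(leaves) - len(side) < 2:
        return None
    anchor = min(leaves)
    return frozenset(leaves - side) if anchor in side else frozenset(side)


def bipartitions(root: TreeNode | GeneTree) -> set[frozenset]:
    """Non-trivial bipartitions (canonical sides) of the unrooted tree."""
    if isinstance(root, GeneTree):
        root = root.root
    leaves = frozenset(root.leaf_names())
    out = set()
    for node in root.postorder():
        if node.parent is None:
            continue
        canon = _canonical_split(frozenset(node.leaf_names()), leaves)
        if canon is not None:
            out.add(canon)
    return out


def rf_distance(t1: GeneTree, t2: GeneTree) -> int:
    """Robinson–Foulds: bipartitions present in exactly one of the trees."""
    if set(t1.leaf_names) != set(t2.leaf_names):
        raise ValueError("trees must share the same leaf set")
    return len(t1.bipartitions() ^ t2.bipartitions())


def parse_newick(text: str) -> GeneTree:
    """Minimal newick reader (names, branch lengths, internal support labels)."""
    import dendropy

    dtree = dendropy.Tree.get(data=text, schema="newick")
    root = TreeNode()
    supports: dict[frozenset, float] = {}

    def convert(dnode, node):
        for child in dnode.child_nodes():
            tag = child.taxon.label.replace(" ", "_") if child.taxon else None
            new = node.add(TreeNode(tag, child.edge.length or 0.0))
            convert(child, new)
            if not new.is_leaf and child.label:
                try:
                    supports[frozenset(new.leaf_names())] = float(child.label)
                except ValueError:
                    pass

    convert(dtree.seed_node, root)
    tree = GeneTree(root)
    leaves = frozenset(tree.leaf_names)
    tree.supports = {
        c: v
        for side, v in supports.items()
        if (c := _canonical_split(side, leaves)) is not None
    }
    return tree


# ---------------------------------------------------------------------------
# distances and neighbor joining


def distance_matrix(msa: Msa, correction: str = "p") -> tuple[np.ndarray, list[str]]:
    """Pairwise distances over shared ungapped columns.

    'p' is the raw mismatch proportion; 'poisson' applies d = -ln(1 - p),
    capped at DIST_CAP when the correction diverges.
    """
    if len(msa) < 2:
        raise ValueError("need at least two rows")
    arr = np.array([list(r) for r in msa.rows])
    n = len(msa)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = (arr[i] != "-") & (arr[j] != "-")
            shared = int(ok.sum())
            if shared == 0:
                d = DIST_CAP
            else:
                p = float((arr[i][ok] != arr[j][ok]).mean())
                if correction == "p":
                    d = p
                elif correction == "poisson":
                    d = DIST_CAP if p >= 1.0 else -math.log(1.0 - p)
                else:
                    raise ValueError(f"unknown correction {correction!r}")
            D[i, j] = D[j, i] = d
    return D, list(msa.names)


def nj_tree(matrix: np.ndarray, names: Sequence[str], method_tag: str = "nj") -> GeneTree:
    """Saitou–Nei neighbor joining; ties broken on the smallest index pair.

    Negative branch-length estimates are clamped to zero. The returned tree
    is unrooted, stored with a trifurcating root.
    """
    D = np.asarray(matrix, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n) or n != len(names):
        raise ValueError("matrix must be square and match names")
    if not np.allclose(D, D.T):
        raise ValueError("matrix must be symmetric")
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")

    nodes = [TreeNode(str(nm)) for nm in names]
    active = list(range(n))
    D = D.copy()

    while len(active) > 3:
        r = len(active)
        sub = D[np.ix_(active, active)]
        row_sums = sub.sum(axis=1)
        Q = (r - 2) * sub - row_sums[:, None] - row_sums[None, :]
        np.fill_diagonal(Q, np.inf)
        best = np.unravel_index(np.argmin(Q), Q.shape)  # first minimum row-major
        ai, aj = sorted((best[0], best[1]))
        i, j = active[ai], active[aj]
        dij = D[i, j]
        li = 0.5 * dij + (row_sums[ai] - row_sums[aj]) / (2 * (r - 2))
        lj = dij - li
        new = TreeNode()
        ni, nj_ = nodes[i], nodes[j]
        ni.length = max(li, 0.0)
        nj_.length = max(lj, 0.0)
        new.add(ni)
        new.add(nj_)
        # distances to the new node
        newdist = np.zeros(D.shape[0] + 1)
        D = np.pad(D, ((0, 1), (0, 1)))
        k = D.shape[0] - 1
        for m in active:
            if m in (i, j):
                continue
            D[k, m] = D[m, k] = 0.5 * (D[i, m] + D[j, m] - dij)
        nodes.append(new)
        active = [m for m in active if m not in (i, j)] + [k]

    i, j, k = active
    root = TreeNode()
    dij, dik, djk = D[i, j], D[i, k], D[j, k]
    nodes[i].length = max(0.5 * (dij + dik - djk), 0.0)
    nodes[j].length = max(0.5 * (dij + djk - dik), 0.0)
    nodes[k].length = max(0.5 * (dik + djk - dij), 0.0)
    for m in (i, j, k):
        root.add(nodes[m])
    return GeneTree(root, method=method_tag)


# ---------------------------------------------------------------------------
# parsimony


def _encode_leaves(msa: Msa, alphabet: str) -> dict[str, np.ndarray]:
    symbols = "ACGT" if alphabet == "nt" else "ACDEFGHIKLMNPQRSTVWY"
    full = (1 << len(symbols)) - 1
    index = {c: 1 << i for i, c in enumerate(symbols)}
    codes = {}
    for name, row in zip(msa.names, msa.rows):
        codes[name] = np.array(
            [index.get(c, full) for c in row], dtype=np.uint32
        )  # gaps/ambiguity = missing (all states)
    return codes


def fitch_score(root: TreeNode, leaf_codes: dict[str, np.ndarray]) -> int:
    """Total Fitch parsimony score over all columns (bitmask states)."""
    score = 0
    states: dict[int, np.ndarray] = {}
    for node in root.postorder():
        if node.is_leaf:
            states[id(node)] = leaf_codes[node.name]
            continue
        acc = states[id(node.children[0])]
        for child in node.children[1:]:
            other = states[id(child)]
            inter = acc & other
            miss = inter == 0
            score += int(miss.sum())
            acc = np.where(miss, acc | other, inter)
        states[id(node)] = acc
    return score


def _unroot(root: TreeNode) -> TreeNode:
    """Ensure the root is an internal node of degree >= 3."""
    if len(root.children) != 2:
        return root
    a, b = root.children
    inner = a if not a.is_leaf else b
    outer = b if inner is a else a
    if inner.is_leaf:  # two-leaf tree: nothing to do
        return root
    new_root = TreeNode()
    for c in inner.children:
        new_root.add(c)
    outer.length += inner.length
    new_root.add(outer)
    return new_root


def _all_topologies(names: Sequence[str]) -> Iterable[TreeNode]:
    """All unrooted binary topologies by sequential leaf insertion."""
    names = list(names)
    base = TreeNode()
    for nm in names[:3]:
        base.add(TreeNode(nm))

    def insertions(root: TreeNode, leaf_name: str) -> Iterable[TreeNode]:
        edges = [n for n in root.postorder() if n.parent is not None]
        for pick in range(len(edges)):
            clone = root.copy()
            targets = [n for n in clone.postorder() if n.parent is not None]
            target = targets[pick]
            parent = target.parent
            split = TreeNode()
            parent.children[parent.children.index(target)] = split
            split.parent = parent
            split.add(target)
            split.add(TreeNode(leaf_name))
            yield clone

    trees = [base]
    for nm in names[3:]:
        trees = [t2 for t in trees for t2 in insertions(t, nm)]
    return trees


def _nni_neighbors(root: TreeNode) -> Iterable[TreeNode]:
    """Both NNI rearrangements around every internal edge, as fresh copies.

    Each is produced by swapping a child of the edge's lower node with a
    designated sibling subtree, which enumerates both alternative quartets.
    """
    nodes = list(root.postorder())
    internal = [
        k
        for k, n in enumerate(nodes)
        if n.parent is not None and not n.is_leaf
    ]
    for k in internal:
        for child_pos in (0, 1):
            clone = root.copy()
            cnodes = list(clone.postorder())
            v = cnodes[k]
            u = v.parent
            sib = next(c for c in u.children if c is not v)
            a = v.children[child_pos]
            vi = v.children.index(a)
            ui = u.children.index(sib)
            v.children[vi], u.children[ui] = sib, a
            sib.parent, a.parent = v, u
            yield clone


def parsimony_tree(msa: Msa, alphabet: str = "protein", start: GeneTree | None = None) -> GeneTree:
    """Fitch parsimony: exhaustive for small taxon sets, otherwise NNI
    hill-climbing from the NJ topology. Deterministic."""
    if len(msa) < 4:
        D, names = distance_matrix(msa, "p")
        tree = nj_tree(D, names, method_tag="parsimony")
        return tree
    codes = _encode_leaves(msa, alphabet)
    if len(msa) <= EXHAUSTIVE_PARSIMONY_MAX_TAXA:
        best, best_score = None, None
        for cand in _all_topologies(sorted(msa.names)):
            s = fitch_score(cand, codes)
            if best_score is None or s < best_score:
                best, best_score = cand, s
        return GeneTree(best, method="parsimony")
    if start is None:
        D, names = distance_matrix(msa, "p")
        start = nj_tree(D, names)
    current = _unroot(start.root.copy())
    current_score = fitch_score(current, codes)
    improved = True
    while improved:
        improved = False
        for cand in _nni_neighbors(current):
            s = fitch_score(cand, codes)
            if s < current_score:
                current, current_score = cand, s
                improved = True
                break
    return GeneTree(current, method="parsimony")


# ---------------------------------------------------------------------------
# bootstrap, species tree, congruence


def bootstrap_supports(
    msa: Msa,
    tree_builder: Callable[[Msa], GeneTree],
    B: int = 100,
    seed: int = 0,
    reference: GeneTree | None = None,
) -> GeneTree:
    """Column bootstrap: support = % of replicates containing each internal
    bipartition of the reference tree. Annotates and returns the tree."""
    if B < 1:
        raise ValueError("need at least one replicate")
    if reference is None:
        reference = tree_builder(msa)
    ref_bips = reference.bipartitions()
    counts = {b: 0 for b in ref_bips}
    rng = np.random.default_rng(seed)
    for _ in range(B):
        cols = rng.integers(0, msa.n_cols, size=msa.n_cols)
        rep = msa.subset_columns(list(cols))
        try:
            bips = tree_builder(rep).bipartitions()
        except ValueError:
            continue
        for b in ref_bips:
            if b in bips:
                counts[b] += 1
    reference.supports = {b: 100.0 * c / B for b, c in counts.items()}
    return reference


def concatenate(msas: Sequence[Msa]) -> Msa:
    """Concatenate alignments sharing one taxon set (e.g. strain ids)."""
    if not msas:
        raise ValueError("no alignments")
    names = sorted(msas[0].names)
    rows = {n: [] for n in names}
    for m in msas:
        if sorted(m.names) != names:
            raise ValueError("taxon sets differ between alignments")
        for n in names:
            rows[n].append(m.rows[m.names.index(n)])
    return Msa(names, ["".join(rows[n]) for n in names])


def species_tree(
    msas: Sequence[Msa], B: int = 100, seed: int = 0
) -> GeneTree:
    """Species tree: NJ on Poisson distances of the concatenated single-copy
    ortholog alignments; supports from a bootstrap over genes (not columns),
    so they measure gene-tree congruence."""
    if not msas:
        raise ValueError("no single-copy clusters")
    concat = concatenate(msas)
    D, names = distance_matrix(concat, "poisson")
    tree = nj_tree(D, names)
    ref_bips = tree.bipartitions()
    counts = {b: 0 for b in ref_bips}
    rng = np.random.default_rng(seed)
    for _ in range(B):
        pick = rng.integers(0, len(msas), size=len(msas))
        rep = concatenate([msas[i] for i in pick])
        Dr, nr = distance_matrix(rep, "poisson")
        bips = nj_tree(Dr, nr).bipartitions()
        for b in ref_bips:
            if b in bips:
                counts[b] += 1
    tree.supports = {b: 100.0 * c / B for b, c in counts.items()}
    return tree


# ---------------------------------------------------------------------------
# HGT and endosymbiotic-origin classification

INGROUP = "ingroup"

_HGT_CALL = {
    "bacteria": "hgt_bacterial",
    "green_algae": "green_origin",
    "red_algae": "red_origin",
    "host_like": "vertical",
    "other_eukaryote": "vertical",
}
_ORIGIN_CALL = {
    "green_algae": "green",
    "red_algae": "red",
    "host_like": "host",
}


@dataclass
class HgtCall:
    family_id: str
    call: str
    sister_label: str | None
    support_by_method: dict[str, float]
    min_support: float
    agreement: bool


def _sister_of_ingroup(
    tree: GeneTree,
    ingroup_leaves: set[str],
    labels: dict[str, str],
    purity_min: float = 0.9,
) -> tuple[str | None, float]:
    """Sister-group label of the (monophyletic) ingroup clade and the
    bootstrap support of the ingroup bipartition.

    Returns (None, support) when the ingroup is not monophyletic or no
    sufficiently pure sister subtree exists.
    """
    leaves = set(tree.leaf_names)
    for leaf in leaves:
        if leaf not in ingroup_leaves and leaf not in labels:
            raise ValueError(f"unlabeled leaf {leaf!r}")
    present = ingroup_leaves & leaves
    if not present or present == leaves:
        return None, 0.0

    # locate the node whose subtree is exactly the ingroup (try both
    # orientations around the root)
    target = None
    for node in tree.root.postorder():
        if node.parent is None:
            continue
        below = set(node.leaf_names())
        if below == present:
            target = node
            break
        if leaves - below == present:
            # ingroup is the complement: re-rooting view; sister subtrees are
            # the node's children
            candidates = [set(c.leaf_names()) for c in node.children]
            support = _split_support(tree, present)
            return _pick_sister(candidates, labels, purity_min), support

    if target is None:
        return None, 0.0
    parent = target.parent
    candidates = [set(c.leaf_names()) for c in parent.children if c is not target]
    if parent.parent is not None:
        candidates.append(leaves - set(parent.leaf_names()))
    support = _split_support(tree, present)
    return _pick_sister(candidates, labels, purity_min), support


def _split_support(tree: GeneTree, side: set[str]) -> float:
    leaves = frozenset(tree.leaf_names)
    canon = _canonical_split(frozenset(side), leaves)
    if canon is None:
        return 100.0  # trivial split: always present
    return tree.supports.get(canon, 0.0)


def _pick_sister(
    candidates: list[set[str]], labels: dict[str, str], purity_min: float
) -> str | None:
    pure = []
    for cand in candidates:
        if not cand:
            continue
        comp: dict[str, int] = {}
        for leaf in cand:
            comp[labels[leaf]] = comp.get(labels[leaf], 0) + 1
        top_label, top_n = max(comp.items(), key=lambda kv: (kv[1], kv[0]))
        if top_n / len(cand) >= purity_min:
            pure.append(top_label)
    if not pure:
        return None
    if len(set(pure)) == 1:
        return pure[0]
    return None


def _two_method_call(
    family_id: str,
    nj: GeneTree,
    pars: GeneTree,
    ingroup_leaves: set[str],
    labels: dict[str, str],
    support_min: float,
    mapping: dict[str, str],
    fallback: str,
) -> HgtCall:
    lab_nj, sup_nj = _sister_of_ingroup(nj, ingroup_leaves, labels)
    lab_p, sup_p = _sister_of_ingroup(pars, ingroup_leaves, labels)
    min_sup = min(sup_nj, sup_p)
    comp = {"nj": sup_nj, "parsimony": sup_p}
    agree = lab_nj is not None and lab_nj == lab_p
    if not agree or min_sup < support_min:
        return HgtCall(family_id, "unresolved", None, comp, min_sup, False)
    call = mapping.get(lab_nj, fallback)
    return HgtCall(family_id, call, lab_nj, comp, min_sup, True)


def hgt_classify(
    family_id: str,
    nj: GeneTree,
    pars: GeneTree,
    ingroup_leaves: set[str],
    labels: dict[str, str],
    support_min: float = 70.0,
) -> HgtCall:
    """Sister-clade HGT call, accepted only when neighbor-joining and
    parsimony trees agree on a well-supported, single-label sister group."""
    call = _two_method_call(
        family_id, nj, pars, ingroup_leaves, labels, support_min, _HGT_CALL, "unresolved"
    )
    if call.call == "vertical":
        # vertical inheritance is the default reading, agreement or not
        return call
    return call


def origin_classify(
    family_id: str,
    nj: GeneTree,
    pars: GeneTree,
    ingroup_leaves: set[str],
    labels: dict[str, str],
    support_min: float = 70.0,
) -> str:
    """Endosymbiotic-origin call in {green, red, host, unresolved}."""
    call = _two_method_call(
        family_id, nj, pars, ingroup_leaves, labels, support_min, _ORIGIN_CALL, "unresolved"
    )
    if call.call in {"green", "red", "host"}:
        return call.call
    return "unresolved"
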