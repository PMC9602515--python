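"""Distance computation, neighbor-joining inference, bootstrap support, and
newick interchange.

The built-in inference path is deliberately desk-scale: Kimura-corrected
protein distances, neighbor joining, and bootstrap bipartition frequencies in
the support slot.  Externally computed maximum-likelihood trees (with aLRT or
other supports) can be injected at any stage via :func:`read_newick`; the rest
of the pipeline only requires the (topology, branch lengths, per-edge support
in [0, 1]) interface.

Supports are attached to *edges*, stored on the child node of each edge; the
rerooting logic keeps them glued to their bipartition.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from ogpeel.msa_mask import GAP, Alignment, MaskedAlignment, apply_mask

#: Distance cap applied when the observed mismatch fraction is >= 0.85, where
#: the Kimura correction diverges.
DISTANCE_CAP = 5.2
MISMATCH_CAP = 0.85


class TreeError(ValueError):
    pass


class TreeNode:
    __slots__ = ("children", "parent", "length", "support", "label")

    def __init__(self, label: str | None = None, length: float = 0.0,
                 support: float | None = None):
        self.children: list[TreeNode] = []
        self.parent: TreeNode | None = None
        self.length = length
        self.support = support
        self.label = label

    def add(self, child: "TreeNode") -> None:
        child.parent = self
        self.children.append(child)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def preorder(self):
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self):
        return [n for n in self.preorder() if n.is_leaf]


class SupportTree:
    """Tree with branch lengths and per-edge supports in [0, 1].

    Unrooted trees are stored with a trifurcating root by convention.
    """

    def __init__(self, root: TreeNode):
        self.root = root
        labels = [n.label for n in root.leaves()]
        if len(labels) != len(set(labels)):
            raise TreeError("duplicate leaf labels")

    # -- basic queries ----------------------------------------------------

    def leaf_labels(self) -> list[str]:
        return sorted(n.label for n in self.root.leaves())

    def internal_edges(self) -> list[TreeNode]:
        """Child nodes of internal edges (node is internal, not the root)."""
        return [
            n for n in self.root.preorder()
            if n.parent is not None and not n.is_leaf
        ]

    def leafset(self, node: TreeNode) -> frozenset:
        return frozenset(n.label for n in node.leaves())

    def median_internal_branch_length(self) -> float:
        lengths = [n.length for n in self.internal_edges()]
        return float(np.median(lengths)) if lengths else 0.0

    def has_supports(self) -> bool:
        return any(n.support is not None for n in self.internal_edges())

    def bipartitions(self) -> dict[frozenset, TreeNode]:
        """Canonical split (side not containing the reference leaf) per edge."""
        ref = min(self.leaf_labels())
        out = {}
        for node in self.internal_edges():
            side = self.leafset(node)
            if ref in side:
                side = frozenset(self.leaf_labels()) - side
            out[side] = node
        return out

    def subtree(self, node: TreeNode) -> "SupportTree":
        """A detached copy of the clade rooted at ``node``."""
        clone, _ = _clone(node)
        clone.parent = None
        clone.length = 0.0
        return SupportTree(clone)

    # -- rerooting --------------------------------------------------------

    def rooted_at_edge(self, child: TreeNode, fraction: float = 0.5) -> "SupportTree":
        """A new tree rooted on the edge above ``child``.

        The edge is split ``fraction`` (child side) / ``1 - fraction``.
        Supports stay attached to their bipartitions.
        """
        _, mapping = _clone(self.root)
        child = mapping[child]
        parent = child.parent
        if parent is None:
            raise TreeError("cannot root at the root edge")
        total, sup = child.length, child.support
        # path from the old parent up to the old root
        path = []
        p = parent
        while p is not None:
            path.append(p)
            p = p.parent
        attrs = [(n.length, n.support) for n in path]
        parent.children.remove(child)
        child.parent = None
        for lower, upper in zip(path[:-1], path[1:]):
            upper.children.remove(lower)
        for i in range(len(path) - 1):
            lower, upper = path[i], path[i + 1]
            lower.add(upper)
            upper.length, upper.support = attrs[i]
        new_root = TreeNode()
        child.length = total * fraction
        new_root.add(child)
        parent.parent = None
        parent.length = total * (1 - fraction)
        parent.support = sup
        new_root.add(parent)
        _suppress_unifurcations(new_root)
        return SupportTree(new_root)

    # -- newick -----------------------------------------------------------

    def to_newick(self) -> str:
        def fmt(node: TreeNode) -> str:
            length = node.length + 0.0  # normalize -0.0
            if node.is_leaf:
                return f"{node.label}:{length:.10g}"
            inner = ",".join(fmt(c) for c in node.children)
            label = "" if node.support is None else f"{node.support:.10g}"
            return f"({inner}){label}:{length:.10g}"

        inner = ",".join(fmt(c) for c in self.root.children)
        label = "" if self.root.support is None else f"{self.root.support:.10g}"
        return f"({inner}){label};"


def _clone(root: TreeNode) -> tuple[TreeNode, dict]:
    mapping = {}

    def rec(node: TreeNode) -> TreeNode:
        copy = TreeNode(node.label, node.length, node.support)
        mapping[node] = copy
        for c in node.children:
            copy.add(rec(c))
        return copy

    return rec(root), mapping


def _suppress_unifurcations(root: TreeNode) -> None:
    for node in list(root.preorder()):
        while len(node.children) == 1 and node is not root:
            only = node.children[0]
            only.length += node.length
            if only.support is None:
                only.support = node.support
            parent = node.parent
            idx = parent.children.index(node)
            parent.children[idx] = only
            only.parent = parent
            node = only
    while len(root.children) == 1:
        only = root.children[0]
        for c in list(only.children):
            root.add(c)
        root.children.remove(only)
        root.support = root.support or only.support


# -- distances -----------------------------------------------------------


def protein_distance_matrix(aln: Alignment | MaskedAlignment) -> np.ndarray:
    """Kimura-corrected pairwise protein distances over retained columns.

    ``d = -ln(1 - D - 0.2 D^2)`` with ``D`` the mismatch fraction over
    mutually non-gap, non-X columns; ``D >= 0.85`` is capped at 5.2.
    """
    if isinstance(aln, MaskedAlignment):
        aln = apply_mask(aln)
    if aln.n_rows < 2:
        raise TreeError("need at least 2 rows")
    if aln.n_cols < 1:
        raise TreeError("need at least 1 retained column")
    arr = np.array([list(r) for r in aln.rows])
    valid = (arr != GAP) & (arr != "X")
    eq = arr[:, None, :] == arr[None, :, :]
    both = valid[:, None, :] & valid[None, :, :]
    comparable = both.sum(axis=-1)
    mismatch = (~eq & both).sum(axis=-1)
    n = aln.n_rows
    for i in range(n):
        for j in range(i + 1, n):
            if comparable[i, j] == 0:
                raise TreeError(
                    f"no comparable columns between {aln.ids[i]!r} and {aln.ids[j]!r}"
                )
    with np.errstate(invalid="ignore"):
        D = np.where(comparable > 0, mismatch / np.maximum(comparable, 1), 0.0)
    d = np.where(
        D >= MISMATCH_CAP, DISTANCE_CAP, -np.log(np.maximum(1.0 - D - 0.2 * D * D, 1e-12))
    )
    np.fill_diagonal(d, 0.0)
    return d


# -- neighbor joining ----------------------------------------------------


def nj_tree(dist: np.ndarray, labels: list[str]) -> SupportTree:
    """Standard neighbor joining; deterministic lowest-index tie-break.

    Negative branch lengths are clamped to 0 with the deficit transferred to
    the sibling edge.  The result is unrooted (trifurcating root), without
    supports.
    """
    tree, _ = _nj_with_splits(dist, labels)
    return tree


def _clamp(li: float, lj: float) -> tuple[float, float]:
    if li < 0:
        lj += li
        li = 0.0
    if lj < 0:
        li += lj
        lj = 0.0
    return li, max(lj, 0.0)


def _nj_with_splits(dist: np.ndarray, labels: list[str]) -> tuple[SupportTree, set]:
    D = np.asarray(dist, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise TreeError("distance matrix must be square")
    if np.isnan(D).any() or (D < 0).any():
        raise TreeError("distance matrix contains NaN or negative entries")
    if not np.allclose(D, D.T, atol=1e-8):
        raise TreeError("distance matrix must be symmetric")
    n = D.shape[0]
    if n < 2 or len(labels) != n:
        raise TreeError("need n >= 2 labels matching the matrix")

    nodes = [TreeNode(lab) for lab in labels]
    sets = [frozenset([lab]) for lab in labels]
    splits: set[frozenset] = set()
    D = D.copy()
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        cand = np.argwhere(np.isclose(Q, qmin, rtol=0, atol=1e-12))
        cand = [(int(a), int(b)) for a, b in cand if a < b]
        ai, aj = min(cand)
        i, j = active[ai], active[aj]
        dij = D[i, j]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2 * (m - 2))
        lj = dij - li
        li, lj = _clamp(li, lj)
        parent = TreeNode()
        nodes[i].length, nodes[j].length = li, lj
        parent.add(nodes[i])
        parent.add(nodes[j])
        new_set = sets[i] | sets[j]
        splits.add(new_set)
        # distances to the new node
        newD = np.zeros(D.shape[0] + 1)
        for k in active:
            if k not in (i, j):
                newD[k] = 0.5 * (D[i, k] + D[j, k] - dij)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, :-1] = newD[:-1]
        D[:-1, -1] = newD[:-1]
        nodes.append(parent)
        sets.append(new_set)
        active = [k for k in active if k not in (i, j)] + [len(nodes) - 1]

    root = TreeNode()
    if len(active) == 3:
        i, j, k = active
        li = 0.5 * (D[i, j] + D[i, k] - D[j, k])
        lj = 0.5 * (D[i, j] + D[j, k] - D[i, k])
        lk = 0.5 * (D[i, k] + D[j, k] - D[i, j])
        for idx, ln in zip((i, j, k), (li, lj, lk)):
            nodes[idx].length = max(ln, 0.0)
            root.add(nodes[idx])
    else:  # two taxa
        i, j = active
        nodes[i].length = nodes[j].length = D[i, j] / 2
        root.add(nodes[i])
        root.add(nodes[j])

    full = frozenset(labels)
    ref = min(labels)
    canonical = set()
    for s in splits:
        if 1 < len(s) < len(labels) - 1:
            canonical.add(full - s if ref in s else s)
    return SupportTree(root), canonical


def bootstrap_support(
    masked: MaskedAlignment | Alignment, n_reps: int = 100, seed: int = 0
) -> SupportTree:
    """NJ tree with bootstrap bipartition frequencies as supports.

    Retained columns are resampled with replacement; support of each internal
    edge of the full-data tree is its split frequency across replicates.
    """
    import warnings

    if n_reps < 1:
        raise TreeError("n_reps must be >= 1")
    aln = apply_mask(masked) if isinstance(masked, MaskedAlignment) else masked
    if aln.n_cols < 10:
        warnings.warn(f"only {aln.n_cols} retained columns; supports will be noisy")
    tree, _ = _nj_with_splits(protein_distance_matrix(aln), list(aln.ids))
    rng = np.random.default_rng(seed)
    arr = np.array([list(r) for r in aln.rows])
    counts: dict[frozenset, int] = {}
    n_ok = 0
    for _ in range(n_reps):
        cols = rng.integers(0, aln.n_cols, size=aln.n_cols)
        rep = Alignment(list(aln.ids), ["".join(r) for r in arr[:, cols]])
        try:
            _, splits = _nj_with_splits(protein_distance_matrix(rep), list(rep.ids))
        except TreeError:
            continue
        n_ok += 1
        for s in splits:
            counts[s] = counts.get(s, 0) + 1
    if n_ok == 0:
        raise TreeError("all bootstrap replicates failed")
    for split, node in tree.bipartitions().items():
        node.support = counts.get(split, 0) / n_ok
    return tree


# -- newick interchange --------------------------------------------------


def _from_dendropy(dnode, scale_percent: bool) -> TreeNode:
    if dnode.is_leaf():
        label = dnode.taxon.label if dnode.taxon else dnode.label
        return TreeNode(label, dnode.edge.length or 0.0)
    node = TreeNode(None, dnode.edge.length or 0.0)
    raw = dnode.label
    if raw is not None:
        try:
            sup = float(raw)
            node.support = sup / 100 if (scale_percent and sup > 1) else sup
        except ValueError:
            pass
    for c in dnode.child_nodes():
        node.add(_from_dendropy(c, scale_percent))
    return node


def read_newick(source: str | Path) -> SupportTree:
    """Parse newick; internal-node labels become supports.

    Support values > 1 are assumed to be percentages and divided by 100, so
    mixed conventions (aLRT 0-1 vs 0-100) normalize to [0, 1].
    """
    import dendropy

    try:
        is_file = Path(str(source)).is_file()
    except OSError:  # e.g. a newick string too long for a filename
        is_file = False
    text = Path(source).read_text() if is_file else str(source)
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as e:  # dendropy raises several error types
        raise TreeError(f"malformed newick: {e}") from e
    root = _from_dendropy(dtree.seed_node, scale_percent=True)
    root.length = 0.0
    root.support = None
    return SupportTree(root)


def write_newick(tree: SupportTree, path: str | Path) -> None:
    Path(path).write_text(tree.to_newick() + "\n")
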