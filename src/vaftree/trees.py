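"""Labeled rooted trees of clones and their genotype matrices.

A clonal hierarchy is a rooted labeled tree: each node is a clone, each clone
differs from its parent by exactly one new heterozygous mutation, and the
node label is that defining mutation.  With clones numbered from the root in
nondecreasing depth, the clone-membership (genotype) matrix ``A`` —
``a_ij = 1`` iff clone ``j`` carries mutation ``i`` — is unit upper
triangular with determinant 1, so the linear system ``A x = b`` relating
clone abundances ``x`` to bulk variant allele frequencies ``b`` always has a
unique solution.

Exhaustive tree enumeration uses the Prüfer bijection between labeled
unrooted trees on ``n`` nodes and sequences of length ``n - 2`` over
``{1..n}``: there are ``n**(n-2)`` trees for a fixed root and ``n**(n-1)``
rooted labeled trees overall.  Enumeration is streamed (one tree at a time)
and refuses node counts above a configurable limit, because the counts grow
super-exponentially.
"""

from __future__ import annotations

import heapq
import itertools
import logging
import time
from collections.abc import Iterable, Iterator, Mapping, Sequence
from dataclasses import dataclass, field
from typing import Hashable, Optional

import numpy as np

from .errors import EnumerationLimitError, ValidationError

logger = logging.getLogger("vaftree")

Label = Hashable

#: Reserved allele identifier for the healthy (wild-type) reference allele
#: used when the hierarchy is rooted at healthy cells.
WILDTYPE_ID = "WT"

#: Default maximum node count for exhaustive enumeration.  8**6 = 262,144
#: fixed-root trees is still interactive; anything larger must be requested
#: explicitly.
DEFAULT_ENUMERATION_LIMIT = 8


# ---------------------------------------------------------------------------
# Rooted labeled trees
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClonalTree:
    """Rooted labeled tree of clones, stored label-centric.

    Nodes are identified by their allele (mutation) identifier, so the same
    object serves founder-root mode (root = founding mutation) and
    wild-type-root mode (root = :data:`WILDTYPE_ID`).

    Parameters
    ----------
    parent
        Map node label -> parent label; the root maps to ``None``.
    root
        Root label.  Inferred from ``parent`` when omitted.
    """

    parent: Mapping[Label, Optional[Label]]
    root: Label = None

    def __post_init__(self) -> None:
        parent = dict(self.parent)
        if not parent:
            raise ValidationError("a tree needs at least one node")
        roots = [k for k, v in parent.items() if v is None]
        if len(roots) != 1:
            raise ValidationError(f"expected exactly one root, found {len(roots)}")
        object.__setattr__(self, "parent", parent)
        if self.root is None:
            object.__setattr__(self, "root", roots[0])
        elif self.root != roots[0]:
            raise ValidationError(f"declared root {self.root!r} does not match parent map")
        for child, par in parent.items():
            if par is not None and par not in parent:
                raise ValidationError(f"parent {par!r} of {child!r} is not a node")
        # connectivity / acyclicity: every node must reach the root
        for node in parent:
            seen = set()
            while node is not None:
                if node in seen:
                    raise ValidationError("parent map contains a cycle")
                seen.add(node)
                node = parent[node]

    # -- basic structure ----------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def labels(self) -> tuple[Label, ...]:
        return tuple(self.parent)

    @property
    def node_labels(self) -> dict[Label, Label]:
        """Map node -> allele identifier (identity for label-centric storage)."""
        return {k: k for k in self.parent}

    def children(self) -> dict[Label, list[Label]]:
        out: dict[Label, list[Label]] = {k: [] for k in self.parent}
        for child, par in self.parent.items():
            if par is not None:
                out[par].append(child)
        return out

    def depths(self) -> dict[Label, int]:
        out: dict[Label, int] = {}
        for node in self.parent:
            d, cur = 0, node
            while self.parent[cur] is not None:
                cur = self.parent[cur]
                d += 1
            out[node] = d
        return out

    def ancestors_or_self(self, node: Label) -> list[Label]:
        """Path from ``node`` up to the root, inclusive."""
        path = [node]
        while self.parent[path[-1]] is not None:
            path.append(self.parent[path[-1]])
        return path

    # -- derived trees ------------------------------------------------------

    def with_wildtype_root(self, wt_id: Label = WILDTYPE_ID) -> "ClonalTree":
        """Attach a healthy-cell root above the current root."""
        if wt_id in self.parent:
            raise ValidationError(f"node {wt_id!r} already present")
        parent = dict(self.parent)
        parent[self.root] = wt_id
        parent[wt_id] = None
        return ClonalTree(parent, root=wt_id)

    def edges(self) -> list[tuple[Label, Label]]:
        """(parent, child) pairs."""
        return [(p, c) for c, p in self.parent.items() if p is not None]


def depth_order(tree: ClonalTree) -> tuple[Label, ...]:
    """Clone ordering starting from the root with nondecreasing depth.

    Parents always precede their children; ties within a depth level are
    broken by ascending allele label so the ordering (and hence every
    genotype-matrix layout) is deterministic.
    """
    depths = tree.depths()
    return tuple(sorted(tree.parent, key=lambda v: (depths[v], _label_key(v))))


def _label_key(label: Label):
    # Stable total order across int and str labels.
    return (label.__class__.__name__, label)


# ---------------------------------------------------------------------------
# Genotype matrices
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenotypeMatrix:
    """Binary clone-membership matrix ``A`` in depth order.

    ``A[i, j] = 1`` exactly when the clone of column ``j`` carries the
    mutation of row ``i`` (the ancestor-or-self relation), so ``A`` is unit
    upper triangular and ``det(A) = 1``.
    """

    A: np.ndarray
    clone_order: tuple[Label, ...]   # column j -> tree node
    allele_order: tuple[Label, ...]  # row i -> allele identifier

    def __post_init__(self) -> None:
        A = np.asarray(self.A, dtype=np.int64)
        n = len(self.clone_order)
        if A.shape != (n, n) or len(self.allele_order) != n:
            raise ValidationError("genotype matrix shape mismatch")
        if not np.isin(A, (0, 1)).all():
            raise ValidationError("genotype matrix must be binary")
        if (np.diag(A) != 1).any() or np.tril(A, -1).any():
            raise ValidationError("genotype matrix must be unit upper triangular")
        object.__setattr__(self, "A", A)
        object.__setattr__(self, "clone_order", tuple(self.clone_order))
        object.__setattr__(self, "allele_order", tuple(self.allele_order))

    @property
    def n(self) -> int:
        return self.A.shape[0]

    def integer_determinant(self) -> int:
        """Exact determinant via fraction-free (Bareiss) elimination.

        Uses Python integers throughout, so the result carries no
        floating-point round-off.
        """
        m = [[int(v) for v in row] for row in self.A]
        n = len(m)
        sign, prev = 1, 1
        for k in range(n - 1):
            if m[k][k] == 0:
                swap = next((r for r in range(k + 1, n) if m[r][k] != 0), None)
                if swap is None:
                    return 0
                m[k], m[swap] = m[swap], m[k]
                sign = -sign
            for i in range(k + 1, n):
                for j in range(k + 1, n):
                    m[i][j] = (m[i][j] * m[k][k] - m[i][k] * m[k][j]) // prev
            prev = m[k][k]
        return sign * m[n - 1][n - 1]


def tree_to_genotype_matrix(tree: ClonalTree) -> GenotypeMatrix:
    """Build the depth-ordered genotype matrix of a clonal hierarchy.

    Row and column ``k`` both correspond to the ``k``-th clone in
    :func:`depth_order` (each clone is identified with its defining
    mutation), which is what makes ``A`` unit upper triangular.
    """
    order = depth_order(tree)
    index = {lab: k for k, lab in enumerate(order)}
    n = len(order)
    A = np.zeros((n, n), dtype=np.int64)
    for j, clone in enumerate(order):
        for anc in tree.ancestors_or_self(clone):
            A[index[anc], j] = 1
    return GenotypeMatrix(A=A, clone_order=order, allele_order=order)


# ---------------------------------------------------------------------------
# Prüfer bijection
# ---------------------------------------------------------------------------

def prufer_to_tree(sequence: Sequence[int], n: int | None = None) -> list[tuple[int, int]]:
    """Decode a Prüfer sequence to the unique labeled tree on ``{1..n}``.

    Returns an undirected edge list.  ``n`` defaults to ``len(sequence) + 2``.
    """
    seq = [int(s) for s in sequence]
    if n is None:
        n = len(seq) + 2
    if n < 2:
        raise ValidationError("Prüfer decoding requires n >= 2")
    if len(seq) != n - 2:
        raise ValidationError(f"sequence length must be n-2 = {n - 2}, got {len(seq)}")
    if any(s < 1 or s > n for s in seq):
        raise ValidationError(f"sequence elements must lie in 1..{n}")
    degree = [1] * (n + 1)
    for s in seq:
        degree[s] += 1
    leaves = [v for v in range(1, n + 1) if degree[v] == 1]
    heapq.heapify(leaves)
    edges: list[tuple[int, int]] = []
    for s in seq:
        leaf = heapq.heappop(leaves)
        edges.append((leaf, s))
        degree[s] -= 1
        if degree[s] == 1:
            heapq.heappush(leaves, s)
    u = heapq.heappop(leaves)
    v = heapq.heappop(leaves)
    edges.append((u, v))
    return edges


def tree_to_prufer(edges: Iterable[tuple[int, int]]) -> tuple[int, ...]:
    """Encode a labeled tree on ``{1..n}`` (edge list) as its Prüfer sequence."""
    edges = [(int(a), int(b)) for a, b in edges]
    n = len(edges) + 1
    nodes = {v for e in edges for v in e}
    if nodes != set(range(1, n + 1)):
        raise ValidationError("tree labels must be exactly 1..n")
    adj: dict[int, set[int]] = {v: set() for v in range(1, n + 1)}
    for a, b in edges:
        if a == b or b in adj[a]:
            raise ValidationError("invalid tree: self-loop or repeated edge")
        adj[a].add(b)
        adj[b].add(a)
    # acyclicity + connectivity follow from |E| = n-1 plus connectivity check
    seen = {1}
    stack = [1]
    while stack:
        for w in adj[stack.pop()]:
            if w not in seen:
                seen.add(w)
                stack.append(w)
    if len(seen) != n:
        raise ValidationError("edge list is disconnected or cyclic")
    if n == 2:
        return ()
    leaves = [v for v in adj if len(adj[v]) == 1]
    heapq.heapify(leaves)
    seq: list[int] = []
    for _ in range(n - 2):
        leaf = heapq.heappop(leaves)
        (nb,) = adj[leaf]
        seq.append(nb)
        adj[nb].discard(leaf)
        adj[leaf].clear()
        if len(adj[nb]) == 1:
            heapq.heappush(leaves, nb)
    return tuple(seq)


def _root_edges(edges: Iterable[tuple[int, int]], root: int) -> dict[int, Optional[int]]:
    """Orient an undirected edge list away from ``root`` -> parent map."""
    adj: dict[int, list[int]] = {}
    for a, b in edges:
        adj.setdefault(a, []).append(b)
        adj.setdefault(b, []).append(a)
    parent: dict[int, Optional[int]] = {root: None}
    stack = [root]
    while stack:
        v = stack.pop()
        for w in adj.get(v, ()):
            if w not in parent:
                parent[w] = v
                stack.append(w)
    return parent


# ---------------------------------------------------------------------------
# Exhaustive enumeration
# ---------------------------------------------------------------------------

def enumerate_trees(
    n: int,
    fixed_root: Optional[Label] = None,
    labels: Optional[Sequence[Label]] = None,
    limit: int = DEFAULT_ENUMERATION_LIMIT,
) -> Iterator[ClonalTree]:
    """Stream every labeled rooted tree on ``n`` nodes.

    With ``fixed_root`` set, yields each of the ``n**(n-2)`` labeled trees
    rooted at that node exactly once; without it, all ``n**(n-1)`` rooted
    labeled trees.  Node labels default to ``1..n``.

    Raises
    ------
    EnumerationLimitError
        If ``n`` exceeds ``limit`` — the counts grow as ``n**(n-2)``, so the
        operation refuses rather than silently running for hours.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    labels = tuple(labels) if labels is not None else tuple(range(1, n + 1))
    if len(labels) != n or len(set(labels)) != n:
        raise ValidationError("labels must be n distinct identifiers")
    if fixed_root is not None and fixed_root not in labels:
        raise ValidationError(f"fixed root {fixed_root!r} is not among the labels")
    if n > limit:
        count = n ** (n - 2) if fixed_root is not None else n ** (n - 1)
        kind = "n^(n-2) fixed-root" if fixed_root is not None else "n^(n-1) rooted"
        raise EnumerationLimitError(
            f"refusing exhaustive enumeration of {count} = {kind} labeled trees "
            f"on n={n} nodes (limit {limit}); raise `limit` to override"
        )
    if n == 1:
        yield ClonalTree({labels[0]: None})
        return

    roots = (fixed_root,) if fixed_root is not None else labels
    t0 = time.perf_counter()
    emitted = 0
    for root in roots:
        root_idx = labels.index(root) + 1
        for seq in itertools.product(range(1, n + 1), repeat=n - 2):
            edges = prufer_to_tree(seq, n)
            parent_idx = _root_edges(edges, root_idx)
            yield ClonalTree(
                {labels[c - 1]: (labels[p - 1] if p is not None else None)
                 for c, p in parent_idx.items()}
            )
            emitted += 1
    logger.debug(
        "enumerated %d rooted labeled trees on n=%d nodes in %.3fs",
        emitted, n, time.perf_counter() - t0,
    )


def canonical_key(tree: ClonalTree) -> tuple:
    """Deterministic sort key: (root position, Prüfer code) over sorted labels.

    Used to break residual ties in ranked reconstruction output.
    """
    order = sorted(tree.parent, key=_label_key)
    index = {lab: k + 1 for k, lab in enumerate(order)}
    if tree.n_nodes == 1:
        return (index[tree.root], ())
    edges = [(index[p], index[c]) for p, c in tree.edges()]
    return (index[tree.root], tree_to_prufer(edges))


# ---------------------------------------------------------------------------
# Newick input/output (via dendropy)
# ---------------------------------------------------------------------------

def write_newick(
    tree: ClonalTree,
    frequencies: Optional[Mapping[str, Mapping[Label, float]]] = None,
) -> str:
    """Serialize a clonal hierarchy as a Newick string.

    Node labels are the allele identifiers; per-timepoint clone frequencies,
    if given as ``{timepoint: {allele: percent}}``, are embedded as
    square-bracket comment annotations on each node.
    """
    import dendropy

    dtree = dendropy.Tree()
    nodes: dict[Label, "dendropy.Node"] = {}
    for lab in depth_order(tree):
        if lab == tree.root:
            node = dtree.seed_node
        else:
            node = dendropy.Node()
            nodes[tree.parent[lab]].add_child(node)
        node.label = str(lab)
        if frequencies:
            for tp, freqs in frequencies.items():
                if lab in freqs:
                    node.annotations.add_new(f"x_{tp}", round(float(freqs[lab]), 6))
        nodes[lab] = node
    return dtree.as_string(
        schema="newick",
        suppress_rooting=True,
        suppress_leaf_node_labels=False,
        suppress_annotations=frequencies is None,
    ).strip()


def parse_newick(newick: str) -> ClonalTree:
    """Parse a Newick string (labels on every node) back into a ClonalTree."""
    import dendropy

    dtree = dendropy.Tree.get(
        data=newick,
        schema="newick",
        suppress_internal_node_taxa=True,
        suppress_leaf_node_taxa=True,
    )
    parent: dict[Label, Optional[Label]] = {}

    def _label(node) -> Label:
        lab = node.label if node.label is not None else (
            node.taxon.label if node.taxon is not None else None)
        if lab is None:
            raise ValidationError("Newick node without a label")
        return lab

    for node in dtree.preorder_node_iter():
        lab = _label(node)
        parent[lab] = _label(node.parent_node) if node.parent_node is not None else None
    return ClonalTree(parent)
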