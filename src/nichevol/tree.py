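"""Rooted phylogenetic trees, tree sets, and tree-level transforms.

Parsing and serialisation are delegated to :mod:`dendropy` (Newick, and Nexus
with translate tables).  Internally trees are stored in a flat array layout —
integer node ids with tips first, internal nodes in postorder, the root last —
which is what the likelihood kernels consume directly.

Branch lengths are in arbitrary time units (the study scale is Myr, but
nothing downstream depends on the unit).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "PhyloTree",
    "TreeSet",
    "NodeAnchor",
    "TreeValidationError",
    "read_tree_set",
    "write_tree_set",
    "read_tree",
    "cophenetic_matrix",
    "lambda_transform",
    "resolve_anchor",
]

#: relative tolerance (× tree height) for the ultrametricity check
ULTRAMETRIC_RTOL = 1e-6


class TreeValidationError(ValueError):
    """Raised when a tree or tree set violates a structural invariant."""


class PhyloTree:
    """A rooted tree with branch lengths in a flat array layout.

    Node ids: tips are ``0 .. n_tips-1``; internal nodes follow in postorder,
    so the root is always ``n_nodes - 1`` and iterating internal ids in
    ascending order is a valid postorder traversal.

    Attributes
    ----------
    parent : ndarray of int
        Parent id per node; ``-1`` for the root.
    blen : ndarray of float
        Branch length of the edge above each node; 0.0 for the root.
    labels : list of str
        Tip labels, indexed by tip id.
    """

    def __init__(self, parent, blen, labels):
        self.parent = np.asarray(parent, dtype=np.int64)
        self.blen = np.asarray(blen, dtype=np.float64)
        self.labels = list(labels)
        self.n_tips = len(self.labels)
        self.n_nodes = len(self.parent)
        self.root = self.n_nodes - 1
        self._validate()
        self.children: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for node in range(self.n_nodes - 1):
            self.children[self.parent[node]].append(node)
        self._tip_index = {lab: i for i, lab in enumerate(self.labels)}
        self._flat = None

    # -- validation ------------------------------------------------------
    def _validate(self):
        if len(set(self.labels)) != self.n_tips:
            dupes = sorted({l for l in self.labels if self.labels.count(l) > 1})
            raise TreeValidationError(f"duplicate tip labels: {dupes}")
        if np.sum(self.parent < 0) != 1 or self.parent[-1] != -1:
            raise TreeValidationError("tree must have exactly one root, stored last")
        if np.any(self.blen[:-1] < 0):
            raise TreeValidationError("negative branch lengths")
        if np.any(self.parent[:-1] <= np.arange(self.n_nodes - 1)):
            # postorder layout: every parent id exceeds the child id
            raise TreeValidationError("node ids are not in postorder layout")

    # -- construction ----------------------------------------------------
    @classmethod
    def from_dendropy(cls, dtree: dendropy.Tree) -> "PhyloTree":
        dtree = dtree.clone(depth=1)
        dtree.suppress_unifurcations()
        nodes = list(dtree.postorder_node_iter())
        tips = [n for n in nodes if n.is_leaf()]
        internals = [n for n in nodes if not n.is_leaf()]
        ids = {}
        labels = []
        for i, n in enumerate(tips):
            ids[id(n)] = i
            if n.taxon is not None:
                labels.append(str(n.taxon.label))
            elif n.label:
                labels.append(str(n.label))
            else:
                raise TreeValidationError("unlabelled tip")
        for j, n in enumerate(internals):
            ids[id(n)] = len(tips) + j
        n_nodes = len(nodes)
        parent = np.full(n_nodes, -1, dtype=np.int64)
        blen = np.zeros(n_nodes)
        for n in nodes:
            i = ids[id(n)]
            if n.parent_node is not None:
                parent[i] = ids[id(n.parent_node)]
            if n.edge.length is not None:
                blen[i] = float(n.edge.length)
        return cls(parent, blen, labels)

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        try:
            dtree = dendropy.Tree.get(
                data=newick, schema="newick", preserve_underscores=True
            )
        except dendropy.utility.error.DataParseError as e:
            if "Duplicate taxon" in str(e):
                raise TreeValidationError(f"duplicate tip labels: {e}") from e
            raise
        return cls.from_dendropy(dtree)

    def to_dendropy(self, taxon_namespace=None) -> dendropy.Tree:
        tn = taxon_namespace or dendropy.TaxonNamespace()
        dtree = dendropy.Tree(taxon_namespace=tn)
        dnodes = [dendropy.Node() for _ in range(self.n_nodes)]
        for i, lab in enumerate(self.labels):
            dnodes[i].taxon = tn.require_taxon(label=lab)
        for i in range(self.n_nodes - 1):
            dnodes[self.parent[i]].add_child(dnodes[i])
            dnodes[i].edge.length = float(self.blen[i])
        dtree.seed_node = dnodes[self.root]
        return dtree

    def to_newick(self, precision: int = 9) -> str:
        def rec(node: int) -> str:
            if node < self.n_tips:
                core = self.labels[node]
            else:
                core = "(" + ",".join(rec(c) for c in self.children[node]) + ")"
            if node == self.root:
                return core
            return f"{core}:{self.blen[node]:.{precision}g}"

        return rec(self.root) + ";"

    def copy(self) -> "PhyloTree":
        return PhyloTree(self.parent.copy(), self.blen.copy(), list(self.labels))

    # -- geometry --------------------------------------------------------
    def depths(self) -> np.ndarray:
        """Distance from the root to every node."""
        d = np.zeros(self.n_nodes)
        for node in range(self.n_nodes - 2, -1, -1):
            d[node] = d[self.parent[node]] + self.blen[node]
        return d

    @property
    def height(self) -> float:
        return float(self.depths()[: self.n_tips].max())

    def total_length(self) -> float:
        return float(self.blen[:-1].sum())

    def is_ultrametric(self, rtol: float = ULTRAMETRIC_RTOL) -> bool:
        tip_depths = self.depths()[: self.n_tips]
        h = tip_depths.max()
        if h == 0:
            return True
        return bool(np.ptp(tip_depths) <= rtol * h)

    def is_binary(self) -> bool:
        return all(
            len(self.children[n]) == 2 for n in range(self.n_tips, self.n_nodes)
        )

    # -- topology queries ------------------------------------------------
    def tip_ids(self, labels) -> np.ndarray:
        try:
            return np.array([self._tip_index[l] for l in labels], dtype=np.int64)
        except KeyError as e:
            raise KeyError(f"tip label not in tree: {e.args[0]!r}") from None

    def mrca(self, labels) -> int:
        """Most recent common ancestor (node id) of a set of tip labels."""
        ids = self.tip_ids(labels)
        if len(ids) == 0:
            raise ValueError("empty tip set")
        # Ancestors always carry larger ids than descendants in this layout
        # (tips < internals; internals in postorder), so the minimum element
        # can never be an ancestor of another: climb it until one node is left.
        current = {int(i) for i in ids}
        while len(current) > 1:
            node = min(current)
            current.remove(node)
            current.add(int(self.parent[node]))
        return int(next(iter(current)))

    def clade_splits(self) -> frozenset:
        """Set of tip-label clades, one per internal node (topology key)."""
        return frozenset(self.clade_tips(n)
                         for n in range(self.n_tips, self.n_nodes))

    def clade_tips(self, node: int) -> frozenset:
        """Labels of all tips descending from ``node`` (inclusive for tips)."""
        stack = [node]
        out = []
        while stack:
            n = stack.pop()
            if n < self.n_tips:
                out.append(self.labels[n])
            else:
                stack.extend(self.children[n])
        return frozenset(out)

    # -- kernel plumbing -------------------------------------------------
    def flat_children(self):
        """CSR-style ``(child_ptr, child_idx)`` arrays for internal nodes.

        Children of internal node ``n_tips + j`` are
        ``child_idx[child_ptr[j]:child_ptr[j+1]]``.
        """
        if self._flat is None:
            ptr = [0]
            idx = []
            for n in range(self.n_tips, self.n_nodes):
                idx.extend(self.children[n])
                ptr.append(len(idx))
            self._flat = (
                np.array(ptr, dtype=np.int64),
                np.array(idx, dtype=np.int64),
            )
        return self._flat

    def __repr__(self):
        return f"<PhyloTree {self.n_tips} tips, height {self.height:.4g}>"


@dataclass
class TreeSet:
    """An ordered collection of trees on an identical tip-label set.

    Used for posterior samples of chronograms; ``provenance`` distinguishes a
    posterior sample from a single summary (MCC) tree.
    """

    trees: list
    provenance: str = "posterior"

    def __post_init__(self):
        if not self.trees:
            raise TreeValidationError("empty tree set")
        ref = frozenset(self.trees[0].labels)
        for i, t in enumerate(self.trees):
            if frozenset(t.labels) != ref:
                raise TreeValidationError(
                    f"tree {i} has a different tip set from tree 0"
                )

    def __len__(self):
        return len(self.trees)

    def __iter__(self):
        return iter(self.trees)

    def __getitem__(self, i):
        return self.trees[i]

    @property
    def labels(self):
        return list(self.trees[0].labels)


@dataclass(frozen=True)
class NodeAnchor:
    """A node identity that survives topology changes across a tree set.

    The node is defined as the MRCA of a fixed reference tip subset; on trees
    where extra tips fall inside that MRCA's clade the anchor still resolves,
    but the monophyly flag records the mismatch.
    """

    name: str
    tip_labels: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        object.__setattr__(self, "tip_labels", frozenset(self.tip_labels))
        if len(self.tip_labels) < 2:
            raise TreeValidationError(
                f"anchor {self.name!r}: need >= 2 reference tips"
            )


def resolve_anchor(anchor: NodeAnchor, tree: PhyloTree) -> tuple[int, bool]:
    """Resolve an anchor on one tree.

    Returns ``(node_id, monophyletic)`` where ``node_id`` is the MRCA of the
    anchor's reference tips and ``monophyletic`` is True iff the MRCA's
    descendant tip set equals the reference set exactly.
    """
    if not anchor.tip_labels <= set(tree.labels):
        missing = sorted(anchor.tip_labels - set(tree.labels))
        raise TreeValidationError(
            f"anchor {anchor.name!r}: tips not in tree: {missing}"
        )
    node = tree.mrca(anchor.tip_labels)
    return node, tree.clade_tips(node) == anchor.tip_labels


# ---------------------------------------------------------------------------
# I/O


def read_tree_set(path, format: str = "newick", provenance: str = "posterior") -> TreeSet:
    """Read a tree set from a file (one Newick per line, or a Nexus trees block)."""
    if format not in ("newick", "nexus"):
        raise ValueError(f"unknown tree format {format!r}")
    tlist = dendropy.TreeList.get(
        path=str(path), schema=format, preserve_underscores=True
    )
    if len(tlist) == 0:
        raise TreeValidationError(f"no trees found in {path}")
    return TreeSet([PhyloTree.from_dendropy(t) for t in tlist], provenance=provenance)


def read_tree(path, format: str = "newick") -> PhyloTree:
    """Read a single tree (the first in the file)."""
    return read_tree_set(path, format=format).trees[0]


def write_tree_set(tree_set, path, format: str = "newick", precision: int = 9):
    """Write trees as Newick, one per line, or as a Nexus trees block."""
    trees = tree_set.trees if isinstance(tree_set, TreeSet) else list(tree_set)
    if format == "newick":
        with open(path, "w") as fh:
            for t in trees:
                fh.write(t.to_newick(precision=precision) + "\n")
    elif format == "nexus":
        tn = dendropy.TaxonNamespace()
        tlist = dendropy.TreeList(taxon_namespace=tn)
        for t in trees:
            tlist.append(t.to_dendropy(taxon_namespace=tn))
        tlist.write(path=str(path), schema="nexus")
    else:
        raise ValueError(f"unknown tree format {format!r}")


# ---------------------------------------------------------------------------
# Tree-level quantities


def cophenetic_matrix(tree: PhyloTree) -> np.ndarray:
    """Tip×tip matrix of patristic (path-length) distances.

    ``d[i, j]`` is the sum of branch lengths on the path between tips ``i``
    and ``j``; rows/columns follow ``tree.labels`` order.
    """
    n = tree.n_tips
    depths = tree.depths()
    d = np.zeros((n, n))
    # d(i,j) = depth_i + depth_j - 2 * depth_mrca(i,j); the MRCA of a pair is
    # the first internal node whose distinct child subtrees contain them.
    tipsets: dict[int, np.ndarray] = {
        i: np.array([i], dtype=np.int64) for i in range(n)
    }
    for node in range(tree.n_tips, tree.n_nodes):
        kids = tree.children[node]
        sets = [tipsets.pop(c) for c in kids]
        for a in range(len(sets)):
            for b in range(a + 1, len(sets)):
                ii, jj = np.meshgrid(sets[a], sets[b], indexing="ij")
                val = depths[ii] + depths[jj] - 2.0 * depths[node]
                d[ii, jj] = val
                d[jj, ii] = val
        tipsets[node] = np.concatenate(sets)
    return d


def lambda_transform(tree: PhyloTree, lam: float) -> PhyloTree:
    """Pagel's λ transform of an ultrametric tree.

    Internal branch lengths are multiplied by ``lam`` and pendant (tip)
    branches are stretched so every root-to-tip depth is preserved.  ``lam=1``
    is the identity; ``lam=0`` collapses the tree to a star phylogeny.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    if not tree.is_ultrametric():
        raise TreeValidationError("lambda transform requires an ultrametric tree")
    depths = tree.depths()
    new = tree.blen * lam
    for tip in range(tree.n_tips):
        new[tip] = depths[tip] - lam * depths[tree.parent[tip]]
    new[tree.root] = 0.0
    return PhyloTree(tree.parent.copy(), new, list(tree.labels))
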