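"""Rooted reference trees with labelled internal nodes.

Trees are held in a flat array form (parent pointers + postorder) convenient
for pruning-algorithm likelihoods; newick import/export goes through dendropy.
Internal nodes carry germline labels assigned by two rules: a node with a
child at (numerically) zero branch length inherits that child's label, since
zero length implies an identical sequence; otherwise the node receives the
most resolved level of the naming hierarchy (allele > gene > family > region)
shared by all of its descendant leaves.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .nomenclature import NameParseError, parse_allele_name

ZERO_BRANCH_TOL = 1e-9


class TreeError(ValueError):
    pass


@dataclass
class Tree:
    """Rooted tree in parent-array form.

    Node 0..n_nodes-1; ``parent[root] == -1``; ``blen[i]`` is the length of the
    edge above node *i* (0 for the root).  ``labels[i]`` is the leaf allele
    name for leaves and the propagated germline label for internal nodes
    (None until :func:`label_internal_nodes` runs).  Every non-root node
    doubles as the id of the branch above it.
    """

    parent: np.ndarray                  # (n,) int
    blen: np.ndarray                    # (n,) float
    labels: list  # list[str | None]
    children: list = field(default_factory=list)   # list[list[int]]
    postorder: np.ndarray = None

    def __post_init__(self):
        n = len(self.parent)
        self.parent = np.asarray(self.parent, dtype=np.int64)
        self.blen = np.asarray(self.blen, dtype=float)
        if np.any(self.blen < 0):
            raise TreeError("negative branch length")
        self.children = [[] for _ in range(n)]
        root = -1
        for i, p in enumerate(self.parent):
            if p < 0:
                if root >= 0:
                    raise TreeError("multiple roots")
                root = i
            else:
                self.children[p].append(i)
        if root < 0:
            raise TreeError("no root")
        self._root = root
        order = []
        stack = [root]
        while stack:
            node = stack.pop()
            order.append(node)
            stack.extend(self.children[node])
        self.postorder = np.array(order[::-1], dtype=np.int64)

    @property
    def root(self) -> int:
        return self._root

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    def is_leaf(self, i: int) -> bool:
        return not self.children[i]

    @property
    def leaves(self) -> list[int]:
        return [i for i in range(self.n_nodes) if self.is_leaf(i)]

    @property
    def branches(self) -> list[int]:
        """All non-root nodes, i.e. all branch ids."""
        return [i for i in range(self.n_nodes) if self.parent[i] >= 0]

    def leaf_index(self) -> dict[str, int]:
        return {self.labels[i]: i for i in self.leaves}

    def descendant_leaves(self, node: int) -> list[int]:
        out, stack = [], [node]
        while stack:
            v = stack.pop()
            if self.is_leaf(v):
                out.append(v)
            else:
                stack.extend(self.children[v])
        return out

    # -- interchange ---------------------------------------------------

    def to_newick(self) -> str:
        def rec(i: int) -> str:
            lab = self.labels[i] or ""
            lab = lab.replace("(", "").replace(")", "").replace(",", "")
            if self.is_leaf(i):
                return f"{lab}:{self.blen[i]:.10g}"
            inner = ",".join(rec(c) for c in self.children[i])
            if self.parent[i] < 0:
                return f"({inner}){lab};"
            return f"({inner}){lab}:{self.blen[i]:.10g}"

        return rec(self.root)

    @classmethod
    def from_dendropy(cls, dtree: dendropy.Tree) -> "Tree":
        nodes = list(dtree.preorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        parent = np.full(len(nodes), -1, dtype=np.int64)
        blen = np.zeros(len(nodes))
        labels: list = [None] * len(nodes)
        for nd in nodes:
            i = index[id(nd)]
            if nd.parent_node is not None:
                parent[i] = index[id(nd.parent_node)]
                blen[i] = max(0.0, nd.edge.length or 0.0)
            if nd.taxon is not None:
                labels[i] = nd.taxon.label
            elif nd.label:
                labels[i] = nd.label
        return cls(parent=parent, blen=blen, labels=labels)

    @classmethod
    def from_newick(cls, text: str) -> "Tree":
        dtree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
        return cls.from_dendropy(dtree)

    def to_dict(self) -> dict:
        return {
            "parent": self.parent.tolist(),
            "blen": self.blen.tolist(),
            "labels": list(self.labels),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Tree":
        return cls(
            parent=np.array(d["parent"], dtype=np.int64),
            blen=np.array(d["blen"], dtype=float),
            labels=list(d["labels"]),
        )


def label_internal_nodes(tree: Tree) -> Tree:
    """Assign germline labels to internal nodes (in place; returns the tree).

    Rule 1: a node with a child at zero branch length (tolerance 1e-9)
    inherits that child's label — the implied sequences are identical.
    Rule 2: otherwise the node gets the most resolved label shared by all of
    its descendant leaves.  Idempotent: leaf labels are never touched and the
    rules depend only on them and the topology.
    """
    leaf_names = {}
    for i in tree.leaves:
        if tree.labels[i] is None:
            raise TreeError(f"leaf {i} is unlabelled")
        try:
            leaf_names[i] = parse_allele_name(tree.labels[i])
        except NameParseError as exc:
            raise TreeError(f"leaf {tree.labels[i]!r}: {exc}") from exc

    from .nomenclature import shared_label

    for i in tree.postorder:
        if tree.is_leaf(i):
            continue
        label = None
        for c in tree.children[i]:
            if tree.blen[c] <= ZERO_BRANCH_TOL and tree.labels[c] is not None:
                label = tree.labels[c]
                break
        if label is None:
            names = [leaf_names[l] for l in tree.descendant_leaves(i)]
            label = shared_label(names)
        tree.labels[i] = label
    return tree


# -- construction ------------------------------------------------------


def nj_tree(names: list[str], dist: np.ndarray) -> Tree:
    """Neighbor-joining tree (unrooted; returned with a trifurcating root)."""
    if len(names) < 3:
        raise TreeError("need at least 3 taxa for NJ")
    buf = io.StringIO()
    buf.write("," + ",".join(names) + "\n")
    for i, nm in enumerate(names):
        buf.write(nm + "," + ",".join(f"{dist[i, j]:.10f}" for j in range(len(names))) + "\n")
    buf.seek(0)
    pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(buf, delimiter=",")
    dtree = pdm.nj_tree()
    for e in dtree.preorder_edge_iter():
        if e.length is not None and e.length < 0:
            e.length = 0.0
    return Tree.from_dendropy(dtree)


def _families_monophyletic(tree: Tree) -> bool:
    fams = {}
    for i in tree.leaves:
        fam = parse_allele_name(tree.labels[i]).family
        fams.setdefault(fam, set()).add(i)
    if len(fams) < 2:
        return True
    # clade leaf sets
    below: dict[int, frozenset] = {}
    for i in tree.postorder:
        if tree.is_leaf(i):
            below[i] = frozenset([i])
        else:
            s = frozenset().union(*(below[c] for c in tree.children[i]))
            below[i] = s
    clades = set(below.values())
    return all(frozenset(v) in clades for v in fams.values())


def _reroot_on_edge(tree: Tree, child: int) -> Tree:
    """Reroot on the edge above ``child``, splitting its length in half."""
    dtree = dendropy.Tree.get(
        data=tree.to_newick(), schema="newick", preserve_underscores=True,
        suppress_internal_node_taxa=True,
    )
    # locate corresponding edge by the set of descendant leaf labels
    target = frozenset(tree.labels[l] for l in tree.descendant_leaves(child))
    for nd in dtree.preorder_node_iter():
        if nd.parent_node is None:
            continue
        leaves = frozenset(lf.taxon.label for lf in nd.leaf_iter())
        if leaves == target:
            half = (nd.edge.length or 0.0) / 2.0
            dtree.reroot_at_edge(nd.edge, length1=half, length2=half)
            return Tree.from_dendropy(dtree)
    raise TreeError("edge not found for rerooting")


def root_for_families(tree: Tree) -> Tree:
    """Root so that germline families form monophyletic clades if possible.

    Tries every internal edge as a root position and keeps the longest one
    that renders all families monophyletic; falls back to midpoint rooting.
    """
    candidates = []
    for b in tree.branches:
        if tree.is_leaf(b):
            continue
        try:
            rooted = _reroot_on_edge(tree, b)
        except TreeError:
            continue
        if _families_monophyletic(rooted):
            candidates.append((tree.blen[b], b, rooted))
    if candidates:
        candidates.sort(key=lambda x: (-x[0], x[1]))
        return candidates[0][2]
    dtree = dendropy.Tree.get(
        data=tree.to_newick(), schema="newick", preserve_underscores=True,
        suppress_internal_node_taxa=True,
    )
    dtree.reroot_at_midpoint(update_bipartitions=False)
    return Tree.from_dendropy(dtree)
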