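"""Unrooted binary trees with branch lengths, backed by flat arrays.

Internally a tree is stored rooted at an arbitrary internal node with three
children (the canonical representation of an unrooted binary tree); under a
reversible substitution model the likelihood does not depend on this choice.
Branch lengths are in expected substitutions per codon when the tree is used
with the codon models.  Newick I/O goes through dendropy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = ["PhyloTree"]


@dataclass
class PhyloTree:
    """Flat-array tree: tips are nodes ``0..n_tips-1``, root is the last node.

    ``parent[i]`` is -1 for the root; ``edge_length[i]`` is the length of the
    branch above node ``i`` (undefined for the root).
    """

    taxa: list  # tip labels, index == node id
    parent: np.ndarray  # (n_nodes,) int
    edge_length: np.ndarray  # (n_nodes,) float
    children: list = field(default_factory=list)  # per node list of child ids

    def __post_init__(self):
        self.parent = np.asarray(self.parent, dtype=int)
        self.edge_length = np.asarray(self.edge_length, dtype=float)
        if not self.children:
            ch = [[] for _ in range(self.n_nodes)]
            for i, p in enumerate(self.parent):
                if p >= 0:
                    ch[p].append(i)
            self.children = ch

    # -- basic facts -----------------------------------------------------
    @property
    def n_tips(self) -> int:
        return len(self.taxa)

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def root(self) -> int:
        return int(np.where(self.parent < 0)[0][0])

    @property
    def n_branches(self) -> int:
        """Branch count; 2n-3 for an unrooted binary tree over n tips."""
        return self.n_nodes - 1

    def branch_ids(self):
        """Node ids that carry a branch (everything but the root)."""
        return [i for i in range(self.n_nodes) if i != self.root]

    def postorder(self):
        order = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            order.append(node)
            stack.extend(self.children[node])
        return order[::-1]

    def preorder(self):
        return self.postorder()[::-1]

    # -- Newick I/O ------------------------------------------------------
    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        tree = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True
        )
        return cls.from_dendropy(tree)

    @classmethod
    def from_newick_file(cls, path) -> "PhyloTree":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    @classmethod
    def from_dendropy(cls, tree: "dendropy.Tree") -> "PhyloTree":
        seed = tree.seed_node
        kids = seed.child_nodes()
        if len(kids) == 2:
            # rooted input: suppress the degree-2 root so branch count is 2n-3
            internal = next((k for k in kids if not k.is_leaf()), None)
            if internal is None:
                raise ValueError("need at least 3 taxa")
            other = kids[0] if kids[1] is internal else kids[1]
            merged = (other.edge.length or 0.0) + (internal.edge.length or 0.0)
            seed.remove_child(internal)
            seed.remove_child(other)
            for gk in list(internal.child_nodes()):
                internal.remove_child(gk)
                seed.add_child(gk)
            other.edge.length = merged
            seed.add_child(other)

        leaves = [lf for lf in tree.leaf_node_iter()]
        taxa = [lf.taxon.label if lf.taxon else lf.label for lf in leaves]
        ids = {}
        for i, lf in enumerate(leaves):
            ids[lf] = i
        next_id = len(leaves)
        for node in tree.preorder_node_iter():
            if node.is_leaf():
                continue
            ids[node] = next_id
            next_id += 1
        # root must be the highest id for flat postorder convenience: remap
        order = sorted(ids, key=lambda n: ids[n])
        internal_nodes = [n for n in order if not n.is_leaf()]
        remap = {}
        for i, lf in enumerate(leaves):
            remap[ids[lf]] = i
        # internals: deeper-first ids, seed node last
        non_seed = [n for n in internal_nodes if n is not tree.seed_node]
        for j, node in enumerate(non_seed):
            remap[ids[node]] = len(leaves) + j
        remap[ids[tree.seed_node]] = len(leaves) + len(non_seed)

        n_nodes = next_id
        parent = np.full(n_nodes, -1, dtype=int)
        lengths = np.zeros(n_nodes)
        for node in tree.preorder_node_iter():
            nid = remap[ids[node]]
            if node.parent_node is not None:
                parent[nid] = remap[ids[node.parent_node]]
                lengths[nid] = node.edge.length or 0.0
        return cls(taxa=taxa, parent=parent, edge_length=lengths)

    def to_newick(self, fmt: str = "%.6f") -> str:
        def render(node: int) -> str:
            if node < self.n_tips:
                label = self.taxa[node]
                if any(c in label for c in " (),:;"):
                    label = "'" + label + "'"
                return f"{label}:{fmt % self.edge_length[node]}"
            inner = ",".join(render(c) for c in self.children[node])
            if node == self.root:
                return f"({inner})"
            return f"({inner}):{fmt % self.edge_length[node]}"

        return render(self.root) + ";"

    # -- editing ---------------------------------------------------------
    def with_lengths(self, lengths) -> "PhyloTree":
        new = np.array(self.edge_length)
        ids = self.branch_ids()
        new[ids] = np.asarray(lengths, dtype=float)
        return PhyloTree(
            taxa=list(self.taxa),
            parent=self.parent.copy(),
            edge_length=new,
            children=[list(c) for c in self.children],
        )

    def branch_lengths(self) -> np.ndarray:
        return self.edge_length[self.branch_ids()]

    def tip_index(self) -> dict:
        return {label: i for i, label in enumerate(self.taxa)}
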