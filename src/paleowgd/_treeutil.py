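"""Internal helpers for working with rooted dendropy trees."""

from __future__ import annotations

import numpy as np
import dendropy

__all__ = [
    "leaf_label",
    "leaf_labels",
    "species_set",
    "ensure_node_labels",
    "find_node",
    "node_depths",
    "tree_length",
    "vcv_matrix",
    "resolve_polytomies",
    "edge_table",
]


def leaf_label(node: dendropy.Node) -> str:
    return node.taxon.label if node.taxon is not None else node.label


def leaf_labels(node: dendropy.Node) -> set[str]:
    """Set of tip labels under (and including) `node`."""
    return {leaf_label(lf) for lf in node.leaf_iter()}


def species_set(node: dendropy.Node, label_map=None) -> frozenset[str]:
    """Species under a node; tips are translated through `label_map` if given."""
    tips = leaf_labels(node)
    if label_map is None:
        return frozenset(tips)
    return frozenset(label_map.species_of(t) for t in tips)


def ensure_node_labels(tree: dendropy.Tree, prefix: str = "N") -> None:
    """Assign stable preorder labels N1.. to unlabeled internal nodes."""
    i = 0
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        i += 1
        if node.label is None:
            node.label = f"{prefix}{i}"


def find_node(tree: dendropy.Tree, key) -> dendropy.Node:
    """Locate a node by internal label, tip label, or iterable of tip labels (MRCA)."""
    if isinstance(key, dendropy.Node):
        return key
    if isinstance(key, str):
        for node in tree.preorder_node_iter():
            if node.label == key or (node.taxon is not None and node.taxon.label == key):
                return node
        raise KeyError(f"no node labeled {key!r}")
    tips = set(key)
    node = tree.mrca(taxon_labels=tips)
    if node is None:
        raise KeyError(f"no MRCA for tips {sorted(tips)}")
    return node


def node_depths(tree: dendropy.Tree) -> dict[dendropy.Node, float]:
    """Distance of every node from the root (root edge ignored)."""
    depths: dict[dendropy.Node, float] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            depths[node] = 0.0
        else:
            depths[node] = depths[node.parent_node] + (node.edge.length or 0.0)
    return depths


def tree_length(tree: dendropy.Tree) -> float:
    return sum(
        node.edge.length or 0.0 for node in tree.preorder_node_iter() if node.parent_node
    )


def vcv_matrix(tree: dendropy.Tree) -> tuple[list[str], np.ndarray]:
    """Brownian-motion covariance structure of the tips.

    Returns tip labels (sorted) and the matrix of shared root-to-MRCA path
    lengths C, so that tip values under BM have covariance sigma2 * C.
    """
    depths = node_depths(tree)
    labels = sorted(leaf_labels(tree.seed_node))
    index = {lb: i for i, lb in enumerate(labels)}
    n = len(labels)
    C = np.zeros((n, n))
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            node._tipidx = [index[leaf_label(node)]]
            C[node._tipidx[0], node._tipidx[0]] = depths[node]
        else:
            groups = [c._tipidx for c in node.child_nodes()]
            d = depths[node]
            for a in range(len(groups)):
                for b in range(a + 1, len(groups)):
                    for i in groups[a]:
                        C[i, groups[b]] = d
                        C[groups[b], i] = d
            node._tipidx = [i for g in groups for i in g]
    for node in tree.postorder_node_iter():
        del node._tipidx
    return labels, C


def resolve_polytomies(tree: dendropy.Tree, rng=None) -> dendropy.Tree:
    """Clone with polytomies resolved to arbitrary bifurcations via zero-length edges."""
    tree = tree.clone(depth=1)
    tree.resolve_polytomies(limit=2, update_bipartitions=False, rng=rng)
    for node in tree.preorder_node_iter():
        if node.parent_node is not None and node.edge.length is None:
            node.edge.length = 0.0
    return tree


def edge_table(tree: dendropy.Tree) -> list[dendropy.Node]:
    """Non-root nodes in preorder; index in this list is the stable edge id
    (each edge named by its child node)."""
    return [nd for nd in tree.preorder_node_iter() if nd.parent_node is not None]
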