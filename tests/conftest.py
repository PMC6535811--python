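"""Shared fixtures and independent oracles used across the test suite."""

from __future__ import annotations

import numpy as np
import dendropy
import pytest

from paleowgd import phylo_io as pio
from paleowgd import synthetic_data as synth
from paleowgd.single_copy_filter import GeneFamily


@pytest.fixture(scope="session")
def species_tree8():
    return synth.simulate_species_tree(8, 1.0, 0.0, seed=11)


def clade_of_size(tree, target):
    """Deterministically pick the non-root internal node whose clade size is
    closest to `target` (ties to the first in preorder)."""
    best, best_d = None, None
    for nd in tree.preorder_node_iter():
        if nd.is_leaf() or nd.parent_node is None:
            continue
        d = abs(len(nd.leaf_nodes()) - target)
        if best is None or d < best_d:
            best, best_d = nd, d
    return best


def build_gene_family(newick: str, lengths: dict | None = None, fam_id="F1") -> GeneFamily:
    """Gene family from a Newick string whose tips look like 'Species@copyN'."""
    tree = pio.read_newick(newick)
    tips = [lf.taxon.label for lf in tree.leaf_node_iter()]
    lm = pio.LabelMap({t: t.split("@", 1)[0] for t in tips})
    return GeneFamily(
        family_id=fam_id,
        gene_tree=tree,
        label_map=lm,
        transcript_length=lengths or {t: 500 for t in tips},
    )


def random_gene_tree(species, rng, max_copies=2):
    """Random multilabeled gene tree: each species contributes 1..max_copies
    transcripts; topology by random sequential joins; unit branch lengths;
    support 100 everywhere."""
    tips = []
    for sp in species:
        for c in range(rng.integers(1, max_copies + 1)):
            tips.append(f"{sp}@copy{c + 1}")
    tree = dendropy.Tree()
    tree.is_rooted = True
    nodes = []
    for t in tips:
        nd = dendropy.Node()
        nd.taxon = tree.taxon_namespace.require_taxon(label=t)
        nd.edge.length = 1.0
        nd.support = None
        nodes.append(nd)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = dendropy.Node()
        parent.edge.length = 1.0
        parent.support = 100.0
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    tree.seed_node = nodes[0]
    tree.seed_node.edge.length = None
    return tree, tips


def random_family(species_tree, rng, fam_id="F1", max_copies=2) -> GeneFamily:
    species = [lf.taxon.label for lf in species_tree.leaf_node_iter()]
    gt, tips = random_gene_tree(species, rng, max_copies)
    lm = pio.LabelMap({t: t.split("@", 1)[0] for t in tips})
    return GeneFamily(
        family_id=fam_id, gene_tree=gt, label_map=lm,
        transcript_length={t: 500 for t in tips},
    )


# ---------------------------------------------------------------------------
# independent placement oracle: checks every species-tree node by definition


def _tipset(node):
    return frozenset(lf.taxon.label for lf in node.leaf_iter())


def _speciesset(node, label_map):
    return frozenset(label_map.species_of(t) for t in _tipset(node))


def oracle_place_pair(pair, family, species_tree, prune=True):
    """Brute-force placement decision: (accepted, node_label, reason).

    Walks every node of the species tree and applies the composition and
    sister rules literally, independent of the package's search code.
    """
    lm = family.label_map
    T = _speciesset(pair.mrca, lm)
    fam_species = {lm.species_of(t) for t in family.tip_labels()}
    stree = species_tree
    if prune:
        keep = sorted(
            {lf.taxon.label for lf in species_tree.leaf_node_iter()} & fam_species
        )
        stree = species_tree.clone(depth=1)
        stree.retain_taxa_with_labels(keep)
    matches = [nd for nd in stree.preorder_node_iter() if _tipset(nd) == T]
    if len(T) == 1:
        label = next(iter(T))
    else:
        label = species_tree.mrca(taxon_labels=sorted(T)).label
    if not matches:
        return (False, None, "no-matching-clade")
    node = matches[0]
    if pair.mrca.parent_node is None:
        return (False, label, "root-unplaceable")
    if node.parent_node is None:
        return (False, label, "sister-check-failed")
    S = _tipset(node.parent_node) - _tipset(node)
    G = _speciesset(pair.mrca.parent_node, lm) - T
    if G & S:
        return (True, label, None)
    return (False, label, "sister-check-failed")
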