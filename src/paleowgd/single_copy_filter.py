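"""Single-copy gene-family reduction.

Transcriptome-derived gene families contain multiple transcripts per
species (isoforms, alleles, assembly clones) that are not true paralogs.
The reduction implemented here collapses every well-supported clade whose
tips all belong to one species down to its single longest transcript, and
classifies the reduced family as single copy when each species then
occurs exactly once. Families sampled from too few species are discarded
before any downstream analysis.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import dendropy

from ._treeutil import leaf_label
from .phylo_io import LabelMap

__all__ = [
    "GeneFamily",
    "filter_orthogroups",
    "collapse_single_species_clades",
    "is_single_copy",
]


@dataclass
class GeneFamily:
    """A multilabeled gene tree with its transcript bookkeeping.

    Tips of ``gene_tree`` are transcript ids; ``label_map`` translates them
    to species; ``transcript_length`` gives nucleotide lengths (required
    only when clade reduction is requested). ``metadata`` carries
    simulator ground truth or provenance notes.
    """

    family_id: str
    gene_tree: dendropy.Tree
    label_map: LabelMap
    transcript_length: dict[str, int] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def tip_labels(self) -> list[str]:
        return [leaf_label(lf) for lf in self.gene_tree.leaf_node_iter()]

    def species_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for t in self.tip_labels():
            sp = self.label_map.species_of(t)
            counts[sp] = counts.get(sp, 0) + 1
        return counts

    def n_species(self) -> int:
        return len(self.species_counts())


def filter_orthogroups(families: list[GeneFamily], min_taxa: int) -> list[GeneFamily]:
    """Keep families sampled from at least `min_taxa` distinct species.

    The bound is inclusive: a family with exactly `min_taxa` species is
    kept. Input order is preserved.
    """
    if min_taxa < 1:
        raise ValueError("min_taxa must be >= 1")
    return [f for f in families if f.n_species() >= min_taxa]


def collapse_single_species_clades(family: GeneFamily, support_min: float = 50.0) -> GeneFamily:
    """Collapse well-supported single-species clades to their longest transcript.

    Every maximal clade whose tips all map to one species and whose
    subtending node has support >= `support_min` is replaced by the single
    tip with the longest transcript (ties broken by lexicographically
    smallest transcript id). The pass repeats until no clade qualifies, so
    a low-support single-species clade containing qualifying subclades is
    reduced from the inside out as far as support allows. Leaves are never
    collapse candidates. The input family is not modified.
    """
    if not 0 <= support_min <= 100:
        raise ValueError("support_min must be in [0, 100]")
    fam = GeneFamily(
        family_id=family.family_id,
        gene_tree=family.gene_tree.clone(depth=1),
        label_map=family.label_map,
        transcript_length=family.transcript_length,
        metadata=copy.deepcopy(family.metadata),
    )
    tree = fam.gene_tree
    changed = True
    while changed:
        changed = False
        # preorder: the first qualifying node on a root-to-tip path is maximal
        for node in tree.preorder_node_iter():
            if node.is_leaf() or node.parent_node is None:
                continue
            tips = [leaf_label(lf) for lf in node.leaf_iter()]
            species = {fam.label_map.species_of(t) for t in tips}
            if len(species) != 1:
                continue
            support = getattr(node, "support", None)
            if support is not None and support < support_min:
                continue
            _collapse_to_longest(tree, node, tips, fam.transcript_length)
            changed = True
            break
    tree.purge_taxon_namespace()
    return fam


def _collapse_to_longest(tree, node, tips, lengths) -> None:
    missing = [t for t in tips if t not in lengths]
    if missing:
        raise ValueError(f"missing transcript length for tip {missing[0]!r}")
    # longest transcript wins; ties go to the lexicographically smallest id
    best = min(tips, key=lambda t: (-lengths[t], t))
    edge_len = node.edge.length
    parent = node.parent_node
    parent.remove_child(node)
    leaf = dendropy.Node()
    leaf.taxon = tree.taxon_namespace.require_taxon(label=best)
    leaf.edge.length = edge_len
    leaf.support = None
    parent.add_child(leaf)


def is_single_copy(family: GeneFamily, support_min: float = 50.0, reduce: bool = True) -> bool:
    """True when, after reduction, every species occurs exactly once."""
    fam = collapse_single_species_clades(family, support_min) if reduce else family
    return all(k == 1 for k in fam.species_counts().values())
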