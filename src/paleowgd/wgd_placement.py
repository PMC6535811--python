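"""Gene-tree / species-tree placement of gene duplications.

A whole-genome duplication leaves, in many gene families, a pair of
paralogs whose gene-tree coalescence node corresponds to one node of the
species tree. The procedure here makes that correspondence explicit:

1. reroot each multilabeled gene tree on a preferred outgroup species;
2. enumerate every pair of transcripts from the same species;
3. for each pair, take the species composition of the gene-tree subtree
   under the pair's MRCA and find the species-tree node with exactly that
   descendant composition;
4. accept the placement only if at least one species from that node's
   sister clade in the species tree also appears in the gene-tree MRCA's
   sister subtree;
5. filter accepted placements by the MRCA's bootstrap support and tally
   per species-tree node, counting each distinct gene-tree duplication
   node once ("unique") or every pair ("all_pairs").

A concentration of unique duplications at one species-tree node across
hundreds of independent gene families is the phylogenomic signature of a
WGD on that branch.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import dendropy
import pandas as pd

from ._treeutil import leaf_label, leaf_labels, species_set
from .phylo_io import LabelMap
from .single_copy_filter import GeneFamily

__all__ = [
    "ParalogPair",
    "DuplicationRecord",
    "reroot_by_preference",
    "enumerate_paralog_pairs",
    "place_pair",
    "place_family",
    "run_placement",
    "tally",
]


@dataclass
class ParalogPair:
    """Two transcripts of the same species in one gene family."""

    family_id: str
    transcript_a: str
    transcript_b: str
    species: str
    mrca: dendropy.Node
    mrca_support: float | None

    def __post_init__(self) -> None:
        if self.transcript_a == self.transcript_b:
            raise ValueError("a paralog pair needs two distinct transcripts")


@dataclass
class DuplicationRecord:
    """Outcome of placing one paralog pair on the species tree."""

    family_id: str
    pair: ParalogPair
    species_node: str | None  # label of the matched node in the full species tree
    gene_mrca_tips: frozenset[str]  # identity of the duplication node
    mrca_support: float | None
    accepted: bool
    rejection_reason: str | None  # no-matching-clade | sister-check-failed | root-unplaceable


def reroot_by_preference(
    gene_tree: dendropy.Tree,
    label_map: LabelMap,
    preference: list[str],
) -> dendropy.Tree | None:
    """Reroot a gene tree on the first outgroup species present in it.

    The root is placed on the midpoint of the edge above the chosen
    species' transcripts (their MRCA when several are present). Returns
    ``None`` when no preference species occurs in the tree (the family is
    then excluded from placement). A tree already rooted on the chosen
    outgroup is returned unchanged.
    """
    if not preference:
        raise ValueError("preference list must be nonempty")
    tips_by_species: dict[str, list[str]] = {}
    for lf in gene_tree.leaf_node_iter():
        t = leaf_label(lf)
        tips_by_species.setdefault(label_map.species_of(t), []).append(t)
    chosen = next((sp for sp in preference if sp in tips_by_species), None)
    if chosen is None:
        return None
    tree = gene_tree.clone(depth=1)
    node = tree.mrca(taxon_labels=tips_by_species[chosen])
    if node.parent_node is None or node.parent_node.parent_node is None:
        return tree  # already rooted on (or at) the outgroup
    length = node.edge.length or 0.0
    tree.reroot_at_edge(node.edge, length1=length / 2, length2=length / 2)
    tree.suppress_unifurcations()
    return tree


def enumerate_paralog_pairs(family: GeneFamily) -> list[ParalogPair]:
    """All C(k,2) same-species transcript pairs, annotated with their MRCA."""
    by_species: dict[str, list[str]] = {}
    for t in family.tip_labels():
        by_species.setdefault(family.label_map.species_of(t), []).append(t)
    pairs: list[ParalogPair] = []
    for sp in sorted(by_species):
        transcripts = sorted(by_species[sp])
        for a, b in combinations(transcripts, 2):
            mrca = family.gene_tree.mrca(taxon_labels=[a, b])
            pairs.append(
                ParalogPair(
                    family_id=family.family_id,
                    transcript_a=a,
                    transcript_b=b,
                    species=sp,
                    mrca=mrca,
                    mrca_support=getattr(mrca, "support", None),
                )
            )
    return pairs


def place_pair(
    pair: ParalogPair,
    family: GeneFamily,
    species_tree: dendropy.Tree,
    prune_species_tree: bool = True,
) -> DuplicationRecord:
    """Map one paralog pair's MRCA onto the species tree.

    Let T be the species set of the gene subtree under the pair's MRCA.
    The pair is placed on the species-tree node whose descendant species
    set equals T exactly; with ``prune_species_tree`` (default, matching
    incomplete transcriptome sampling) the comparison is made on the
    species tree restricted to the species present in this family. The
    placement is accepted when the matched node's species-tree sister
    clade shares at least one species with the gene MRCA's sister
    subtree. The returned record names the matched node by its label in
    the full species tree (the MRCA of T there).
    """
    stree = (
        _pruned_to_family(species_tree, family) if prune_species_tree else species_tree
    )
    return _place_on(pair, family, species_tree, stree)


def _pruned_to_family(species_tree: dendropy.Tree, family: GeneFamily) -> dendropy.Tree:
    family_species = {family.label_map.species_of(t) for t in family.tip_labels()}
    present = {leaf_label(lf) for lf in species_tree.leaf_node_iter()} & family_species
    if present == {leaf_label(lf) for lf in species_tree.leaf_node_iter()}:
        return species_tree
    stree = species_tree.clone(depth=1)
    stree.retain_taxa_with_labels(sorted(present))
    return stree


def _place_on(
    pair: ParalogPair,
    family: GeneFamily,
    species_tree: dendropy.Tree,
    stree: dendropy.Tree,
) -> DuplicationRecord:
    gene_T = species_set(pair.mrca, family.label_map)
    matched = None
    for node in stree.preorder_node_iter():
        if leaf_labels(node) == gene_T:
            matched = node
            break

    def record(accepted, reason, label=None):
        return DuplicationRecord(
            family_id=pair.family_id,
            pair=pair,
            species_node=label,
            gene_mrca_tips=frozenset(leaf_labels(pair.mrca)),
            mrca_support=pair.mrca_support,
            accepted=accepted,
            rejection_reason=reason,
        )

    if matched is None:
        return record(False, "no-matching-clade")
    label = _full_tree_label(species_tree, gene_T)
    if pair.mrca.parent_node is None:
        return record(False, "root-unplaceable", label)
    if matched.parent_node is None:
        # matched clade spans the whole (pruned) species tree: no sister exists
        return record(False, "sister-check-failed", label)
    S = leaf_labels(matched.parent_node) - leaf_labels(matched)
    G = species_set(pair.mrca.parent_node, family.label_map) - gene_T
    if G & S:
        return record(True, None, label)
    return record(False, "sister-check-failed", label)


def _full_tree_label(species_tree: dendropy.Tree, species: frozenset[str]) -> str:
    if len(species) == 1:
        return next(iter(species))
    node = species_tree.mrca(taxon_labels=sorted(species))
    return node.label if node.label else ";".join(sorted(leaf_labels(node)))


def place_family(
    family: GeneFamily,
    species_tree: dendropy.Tree,
    outgroups: list[str] | None = None,
    prune_species_tree: bool = True,
) -> list[DuplicationRecord]:
    """Enumerate and place all paralog pairs of one family.

    With ``outgroups`` the gene tree is first rerooted by preference;
    unrootable families yield no records.
    """
    fam = family
    if outgroups is not None:
        rerooted = reroot_by_preference(family.gene_tree, family.label_map, outgroups)
        if rerooted is None:
            return []
        fam = GeneFamily(
            family_id=family.family_id,
            gene_tree=rerooted,
            label_map=family.label_map,
            transcript_length=family.transcript_length,
            metadata=family.metadata,
        )
    stree = (
        _pruned_to_family(species_tree, fam) if prune_species_tree else species_tree
    )
    return [
        _place_on(p, fam, species_tree, stree) for p in enumerate_paralog_pairs(fam)
    ]


def run_placement(
    families: list[GeneFamily],
    species_tree: dendropy.Tree,
    outgroups: list[str] | None = None,
    prune_species_tree: bool = True,
) -> list[DuplicationRecord]:
    records: list[DuplicationRecord] = []
    for fam in families:
        records.extend(
            place_family(fam, species_tree, outgroups, prune_species_tree)
        )
    return records


def tally(
    records: list[DuplicationRecord],
    mode: str = "unique",
    support_min: float = 80.0,
) -> pd.DataFrame:
    """Per-species-tree-node duplication counts.

    Drops records whose MRCA support is below `support_min` (absent
    support counts as 0), keeps accepted records only. ``unique`` counts
    each distinct (family, gene-tree duplication node) once;
    ``all_pairs`` counts every accepted pair. Returns a DataFrame with
    columns ``node`` and ``count`` sorted by descending count.
    """
    if mode not in ("unique", "all_pairs"):
        raise ValueError(f"unknown tally mode {mode!r}")
    if not 0 <= support_min <= 100:
        raise ValueError("support_min must be in [0, 100]")
    counts: dict[str, int] = {}
    seen: set[tuple] = set()
    for r in records:
        if not r.accepted:
            continue
        if (r.mrca_support or 0.0) < support_min:
            continue
        if mode == "unique":
            key = (r.family_id, r.gene_mrca_tips)
            if key in seen:
                continue
            seen.add(key)
        counts[r.species_node] = counts.get(r.species_node, 0) + 1
    df = pd.DataFrame(
        {"node": list(counts), "count": list(counts.values())}
    ).sort_values(["count", "node"], ascending=[False, True], ignore_index=True)
    return df
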