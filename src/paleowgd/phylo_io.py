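"""Tree and trait-table I/O, and articulation of trees with trait data.

Trees are held as rooted :class:`dendropy.Tree` objects. Internal-node
bootstrap/support values (percentages in [0, 100]) are stored on each node
as ``node.support`` (``None`` when absent). The primary Newick dialect puts
support in the internal-node label position (``(A,B)95:0.5``), matching
RAxML output; a secondary dialect with ``[&support=95]`` comments is
accepted on input but never written.

Trait tables are delimited text with header columns ``species,value`` and
an optional ``source`` column; they are carried as :class:`TraitVector`.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field

import dendropy
import pandas as pd

__all__ = [
    "TraitVector",
    "LabelMap",
    "NewickParseError",
    "read_newick",
    "write_newick",
    "read_trait_table",
    "match_tips",
    "genus_of",
]

_SUPPORT_COMMENT = re.compile(r"\[&support=([0-9]+(?:\.[0-9]+)?)\]")


class NewickParseError(ValueError):
    """Raised when a Newick string violates the tree invariants."""


@dataclass
class TraitVector:
    """Per-species continuous or count trait.

    Parameters
    ----------
    values
        Mapping species id -> trait value.
    kind
        Free-text trait kind, e.g. ``"genome_size_mb"`` or
        ``"chromosome_count_2n"``.
    provenance
        Mapping species id -> ``"exact"`` or ``"congener"`` recording
        whether the value came from the species itself or a congeneric
        substitute.
    """

    values: dict[str, float]
    kind: str = "trait"
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sp, v in self.values.items():
            if self.kind.startswith("chromosome"):
                if v <= 0 or float(v) != int(v):
                    raise ValueError(
                        f"chromosome count for {sp!r} must be a positive integer, got {v}"
                    )
            elif self.kind.startswith("genome_size") and v <= 0:
                raise ValueError(f"genome size for {sp!r} must be positive, got {v}")

    def __len__(self) -> int:
        return len(self.values)

    def __getitem__(self, species: str) -> float:
        return self.values[species]

    def species(self) -> list[str]:
        return sorted(self.values)


@dataclass
class LabelMap:
    """Transcript -> species mapping plus the genus-derivation rule.

    Genus is parsed from a species id as the substring before the first
    occurrence of ``genus_delimiter`` (binomial ids like
    ``Phoenix_dactylifera`` yield genus ``Phoenix``).
    """

    transcript_to_species: dict[str, str]
    genus_delimiter: str = "_"

    def species_of(self, transcript: str) -> str:
        try:
            return self.transcript_to_species[transcript]
        except KeyError:
            raise KeyError(f"transcript {transcript!r} has no species mapping") from None

    def genus_of(self, species: str) -> str:
        return genus_of(species, self.genus_delimiter)

    @classmethod
    def from_table(cls, source, delimiter: str = "\t", genus_delimiter: str = "_") -> "LabelMap":
        df = pd.read_csv(source, sep=delimiter, header=None, names=["transcript", "species"])
        return cls(dict(zip(df["transcript"], df["species"])), genus_delimiter)


def genus_of(species: str, delimiter: str = "_") -> str:
    """Genus part of a binomial species id (prefix before `delimiter`)."""
    return species.split(delimiter, 1)[0]


def read_newick(text: str) -> dendropy.Tree:
    """Parse a single Newick statement into a rooted tree.

    Numeric internal-node labels are interpreted as bootstrap support and
    exposed as ``node.support`` floats; ``[&support=...]`` comments are
    accepted as an alternative carrier. Raises :class:`NewickParseError`
    on unbalanced parentheses, duplicate tip labels, or negative branch
    lengths.
    """
    text = text.strip()
    if text.count("(") != text.count(")"):
        raise NewickParseError(
            f"unbalanced parentheses: {text.count('(')} '(' vs {text.count(')')} ')'"
        )
    # secondary dialect: a support comment directly after a closing paren
    text = re.sub(r"\)\s*\[&support=([0-9]+(?:\.[0-9]+)?)\]", r")\1", text)
    text = _SUPPORT_COMMENT.sub("", text)
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        msg = str(exc)
        m = re.search(r"Duplicate taxon labels: (\S+)", msg)
        if m:
            raise NewickParseError(f"duplicate tip label {m.group(1)!r}") from exc
        raise NewickParseError(msg) from exc
    seen: set[str] = set()
    for leaf in tree.leaf_node_iter():
        label = leaf.taxon.label if leaf.taxon is not None else leaf.label
        if label in seen:
            raise NewickParseError(f"duplicate tip label {label!r}")
        seen.add(label)
    for node in tree:
        if node.edge.length is not None and node.edge.length < 0:
            raise NewickParseError(
                f"negative branch length {node.edge.length} on edge above "
                f"{node.taxon.label if node.taxon else node.label or '<internal>'}"
            )
        node.support = _parse_support(node)
    tree.is_rooted = True
    return tree


def _parse_support(node) -> float | None:
    if node.is_leaf() or node.label is None:
        return None
    try:
        support = float(node.label)
    except ValueError:
        return None
    if not 0 <= support <= 100:
        raise NewickParseError(f"support {support} outside [0, 100]")
    return support


def write_newick(tree: dendropy.Tree, precision: int = 10) -> str:
    """Serialize a tree, emitting ``node.support`` as internal labels."""
    for node in tree.preorder_node_iter():
        support = getattr(node, "support", None)
        if not node.is_leaf() and support is not None:
            node.label = f"{support:g}"
    out = io.StringIO()
    tree.write(
        file=out,
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        real_value_format_specifier=f".{precision}g",
    )
    return out.getvalue().strip()


def read_trait_table(
    source,
    kind: str = "trait",
    delimiter: str = ",",
    aggregate: str = "first",
) -> TraitVector:
    """Read a ``species,value[,source]`` table into a TraitVector.

    ``aggregate`` resolves multiple records for one species: ``"first"``
    keeps the first row (the convention for curated "prime" estimates
    listed first), ``"mean"`` averages them.
    """
    df = pd.read_csv(source, sep=delimiter)
    cols = {c.lower(): c for c in df.columns}
    if "species" not in cols or "value" not in cols:
        raise ValueError("trait table must have 'species' and 'value' columns")
    df = df.rename(columns={cols["species"]: "species", cols["value"]: "value"})
    if aggregate == "first":
        df = df.groupby("species", as_index=False, sort=False).first()
    elif aggregate == "mean":
        df = df.groupby("species", as_index=False, sort=False)["value"].mean()
    else:
        raise ValueError(f"unknown aggregate {aggregate!r}")
    values = dict(zip(df["species"], df["value"].astype(float)))
    return TraitVector(values=values, kind=kind, provenance={sp: "exact" for sp in values})


def match_tips(
    tree: dendropy.Tree,
    traits: TraitVector,
    allow_congener: bool = True,
    genus_delimiter: str = "_",
) -> tuple[dendropy.Tree, TraitVector]:
    """Articulate a species tree with a trait table.

    Each tip is matched to a trait value by exact species id; tips without
    an exact match may (``allow_congener``) fall back to a congeneric
    species' value, choosing the lexicographically smallest congener id so
    the result is independent of input order. Tips that still lack a value
    are pruned; pruning preserves path lengths between retained tips.

    Returns the pruned tree (a clone; the input is untouched) and a
    TraitVector aligned to its tips, with fallback tips flagged
    ``"congener"``.
    """
    tree = tree.clone(depth=1)
    by_genus: dict[str, list[str]] = {}
    for sp in traits.values:
        by_genus.setdefault(genus_of(sp, genus_delimiter), []).append(sp)
    for g in by_genus:
        by_genus[g].sort()

    keep: list[str] = []
    values: dict[str, float] = {}
    provenance: dict[str, str] = {}
    for leaf in tree.leaf_node_iter():
        tip = leaf.taxon.label
        if tip in traits.values:
            keep.append(tip)
            values[tip] = traits.values[tip]
            provenance[tip] = "exact"
        elif allow_congener:
            congeners = by_genus.get(genus_of(tip, genus_delimiter), [])
            if congeners:
                keep.append(tip)
                values[tip] = traits.values[congeners[0]]
                provenance[tip] = "congener"
    if not keep:
        raise ValueError("no tips with trait data")
    tree.retain_taxa_with_labels(keep)
    tree.purge_taxon_namespace()
    return tree, TraitVector(values=values, kind=traits.kind, provenance=provenance)
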