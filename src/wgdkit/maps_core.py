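"""MAPS: gene-tree sorting against a ladderized species tree.

Given a pectinate (ladder) species tree with internal nodes numbered N1
(tip-most cherry ancestor) through Nk (root), each gene tree is scanned for
subtrees informative about each species-tree node, and the fraction of those
subtrees whose root is a gene duplication shared by the node's descendant
lineages is tallied.  A burst of shared duplications concentrated at one
node is the phylogenomic signature of a WGD on that branch.

A gene-tree node is a duplication under the species-overlap criterion (its
two child clades share at least one taxon) and maps to the species-tree MRCA
of the union of the child taxon sets.  An ingroup-occupancy filter (default
45% of the node's clade taxa, applied to each counted subtree and to both
children of a shared duplication) suppresses the inflation of mapped
duplications towards the root caused by sparse gene trees.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .core_io import GeneTree, Node, SpeciesTree
from .errors import StructureError

__all__ = [
    "OccupancyRule",
    "DuplicationEvent",
    "SubtreeRecord",
    "MapsProfile",
    "SpeciesIndex",
    "validate_species_tree",
    "map_duplications",
    "collect_subtrees",
    "per_tree_node_counts",
    "maps_profile",
    "family_filter",
]


@dataclass(frozen=True)
class OccupancyRule:
    """Minimum ingroup-taxon occupancy for counted subtrees."""

    fraction: float = 0.45

    def min_taxa(self, clade_size: int) -> int:
        return math.ceil(self.fraction * clade_size)


@dataclass(frozen=True)
class DuplicationEvent:
    tree_name: str
    mapped_node: str            # species-tree node label (Ni or a taxon)
    left_taxa: frozenset[str]
    right_taxa: frozenset[str]
    passes_occupancy: bool = True


@dataclass(frozen=True)
class SubtreeRecord:
    tree_name: str
    species_node: str
    taxa: frozenset[str]
    is_shared_duplication: bool


@dataclass
class MapsProfile:
    """Per species-tree node subtree and shared-duplication counts."""

    node_order: list[str]
    n_subtrees: dict[str, int] = field(default_factory=dict)
    n_dup: dict[str, int] = field(default_factory=dict)

    def pct_dup(self, node: str) -> float:
        n = self.n_subtrees.get(node, 0)
        if n == 0:
            return math.nan
        return 100.0 * self.n_dup.get(node, 0) / n

    def to_frame(self) -> pd.DataFrame:
        rows = [(n, self.n_subtrees.get(n, 0), self.n_dup.get(n, 0),
                 self.pct_dup(n)) for n in self.node_order]
        return pd.DataFrame(rows, columns=["node", "n_subtrees", "n_dup",
                                           "pct_dup"])

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False,
                               float_format="%.6g")


# ---------------------------------------------------------------------------
# species-tree indexing


class SpeciesIndex:
    """Bitmask index over a validated ladder species tree.

    Taxa get one bit each; every species-tree node carries the mask of its
    clade, which makes subset tests, species-overlap checks and MRCA lookups
    O(1) bit operations.
    """

    def __init__(self, species: SpeciesTree | Node):
        root = species.root if isinstance(species, SpeciesTree) else species
        self.root = root
        self.internal = validate_species_tree(species)
        self.taxa = sorted(root.leaf_labels())
        self.bit = {t: 1 << i for i, t in enumerate(self.taxa)}
        self.mask: dict[int, int] = {}
        self.label: dict[int, str] = {}
        self._nodes_by_mask: dict[int, Node] = {}
        for node in root.postorder():
            if node.is_leaf:
                m = self.bit[node.label]
                self.label[id(node)] = node.label
            else:
                m = 0
                for child in node.children:
                    m |= self.mask[id(child)]
            self.mask[id(node)] = m
            self._nodes_by_mask[m] = node
        for i, node in enumerate(self.internal, start=1):
            self.label[id(node)] = f"N{i}"
        # ascending clade size for MRCA lookup
        self._masks_sorted = sorted(self.mask[id(n)]
                                    for n in root.postorder())

    @property
    def node_labels(self) -> list[str]:
        return [self.label[id(n)] for n in self.internal]

    def taxon_mask(self, taxa: Iterable[str]) -> int:
        m = 0
        for t in taxa:
            try:
                m |= self.bit[t]
            except KeyError:
                raise KeyError(f"taxon {t!r} not in species tree") from None
        return m

    def mrca(self, mask: int) -> Node:
        for m in self._masks_sorted:
            if mask & ~m == 0:
                return self._nodes_by_mask[m]
        raise ValueError("mask outside the species-tree taxon set")

    def mrca_label(self, mask: int) -> str:
        return self.label[id(self.mrca(mask))]

    def clades(self) -> list[tuple[str, int, int, int]]:
        """Per internal node Ni: (label, clade mask, daughter1, daughter2)."""
        out = []
        for node in self.internal:
            d1, d2 = node.children
            out.append((self.label[id(node)], self.mask[id(node)],
                        self.mask[id(d1)], self.mask[id(d2)]))
        return out


def validate_species_tree(species: SpeciesTree | Node) -> list[Node]:
    """Check pectinate structure; return internal nodes ordered N1..Nk.

    N1 is the tip-most internal node (the cherry ancestor) and Nk the root.
    """
    root = species.root if isinstance(species, SpeciesTree) else species
    order: list[Node] = []
    node = root
    while True:
        if node.is_leaf:
            raise StructureError("species tree root is a single leaf")
        if len(node.children) != 2:
            raise StructureError(
                f"non-binary species-tree node with {len(node.children)} children")
        order.append(node)
        internal_children = [c for c in node.children if not c.is_leaf]
        if not internal_children:
            break  # the cherry
        if len(internal_children) > 1:
            leaves = ",".join(sorted(node.leaf_labels()))
            raise StructureError(
                f"species tree is not pectinate at clade ({leaves})")
        node = internal_children[0]
    n_taxa = len(root.leaf_labels())
    if not 6 <= n_taxa <= 8:
        warnings.warn(f"species tree has {n_taxa} taxa; MAPS analyses "
                      "typically use 6-8", stacklevel=2)
    return list(reversed(order))  # tip-most first


# ---------------------------------------------------------------------------
# duplication mapping


def _gene_masks(gene: GeneTree, index: SpeciesIndex) -> dict[int, int]:
    masks: dict[int, int] = {}
    for node in gene.root.postorder():
        if node.is_leaf:
            masks[id(node)] = index.taxon_mask([gene.taxon_of(node.label)])
        else:
            m = 0
            for child in node.children:
                m |= masks[id(child)]
            masks[id(node)] = m
    return masks


def map_duplications(gene: GeneTree,
                     species: SpeciesTree | SpeciesIndex) -> list[DuplicationEvent]:
    """Species-overlap duplication mapping.

    A gene-tree node is a duplication iff its child taxon sets intersect;
    the event maps to the species-tree MRCA of the union (a terminal branch
    when the union is a single taxon).
    """
    index = species if isinstance(species, SpeciesIndex) else SpeciesIndex(species)
    masks = _gene_masks(gene, index)
    inv_bit = {b: t for t, b in index.bit.items()}

    def taxa_of(mask: int) -> frozenset[str]:
        return frozenset(inv_bit[1 << i] for i in range(mask.bit_length())
                         if mask >> i & 1)

    events: list[DuplicationEvent] = []
    for node in gene.root.postorder():
        if node.is_leaf:
            continue
        ml, mr = masks[id(node.children[0])], masks[id(node.children[1])]
        if ml & mr:
            events.append(DuplicationEvent(
                tree_name=gene.name,
                mapped_node=index.mrca_label(ml | mr),
                left_taxa=taxa_of(ml), right_taxa=taxa_of(mr)))
    return events


# ---------------------------------------------------------------------------
# subtree collection and profiles


def collect_subtrees(gene: GeneTree, species: SpeciesTree | SpeciesIndex,
                     rule: OccupancyRule = OccupancyRule()) -> list[SubtreeRecord]:
    """Counted subtrees (and shared duplications) per species-tree node.

    For node Ni with clade C and daughter lineages D1, D2, the counted
    subtrees are the maximal gene-tree clades whose taxon set is inside C,
    touches both daughters and has at least ``ceil(f*|C|)`` distinct taxa.
    Such a subtree is a shared duplication at Ni when its root is a
    species-overlap duplication mapping to Ni and both child clades
    independently meet the same occupancy minimum.
    """
    index = species if isinstance(species, SpeciesIndex) else SpeciesIndex(species)
    masks = _gene_masks(gene, index)
    inv_bit = {b: t for t, b in index.bit.items()}
    records: list[SubtreeRecord] = []
    for label, clade_mask, d1, d2 in index.clades():
        min_req = rule.min_taxa(clade_mask.bit_count())
        stack = [gene.root]
        while stack:
            node = stack.pop()
            m = masks[id(node)]
            if (m & ~clade_mask) == 0 and (m & d1) and (m & d2) \
                    and m.bit_count() >= min_req:
                shared = False
                if not node.is_leaf:
                    ml = masks[id(node.children[0])]
                    mr = masks[id(node.children[1])]
                    shared = bool(ml & mr) \
                        and index.mrca_label(ml | mr) == label \
                        and ml.bit_count() >= min_req \
                        and mr.bit_count() >= min_req
                taxa = frozenset(inv_bit[1 << i]
                                 for i in range(m.bit_length()) if m >> i & 1)
                records.append(SubtreeRecord(tree_name=gene.name,
                                             species_node=label, taxa=taxa,
                                             is_shared_duplication=shared))
                continue  # maximality: do not descend into a counted clade
            stack.extend(node.children)
    return records


def per_tree_node_counts(gene: GeneTree, species: SpeciesTree | SpeciesIndex,
                         rule: OccupancyRule = OccupancyRule()) -> dict[str, tuple[int, int]]:
    """Per-node (n_subtrees, n_shared_duplications) for one gene tree."""
    index = species if isinstance(species, SpeciesIndex) else SpeciesIndex(species)
    counts: dict[str, tuple[int, int]] = {lab: (0, 0) for lab in index.node_labels}
    for rec in collect_subtrees(gene, index, rule):
        n, d = counts[rec.species_node]
        counts[rec.species_node] = (n + 1, d + int(rec.is_shared_duplication))
    return counts


def maps_profile(gene_trees: Sequence[GeneTree],
                 species: SpeciesTree | SpeciesIndex,
                 rule: OccupancyRule = OccupancyRule()) -> MapsProfile:
    """Aggregate per-node subtree/duplication counts over a tree collection."""
    if not gene_trees:
        raise ValueError("at least one gene tree is required")
    index = species if isinstance(species, SpeciesIndex) else SpeciesIndex(species)
    profile = MapsProfile(node_order=index.node_labels,
                          n_subtrees={lab: 0 for lab in index.node_labels},
                          n_dup={lab: 0 for lab in index.node_labels})
    for gene in gene_trees:
        for lab, (n, d) in per_tree_node_counts(gene, index, rule).items():
            profile.n_subtrees[lab] += n
            profile.n_dup[lab] += d
    return profile


def family_filter(gene_trees: Iterable[GeneTree],
                  taxon_set: Iterable[str]) -> list[GeneTree]:
    """Keep gene trees with at least one copy of every analysis taxon."""
    required = set(taxon_set)
    return [t for t in gene_trees if t.leaf_taxa() == required]
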