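"""Shared tree/taxon data model and readers/writers for on-disk formats.

Trees are held in a deliberately small :class:`Node` structure optimised for
the traversal-heavy algorithms downstream (duplication mapping, birth-death
simulation).  All newick parsing and serialisation is delegated to dendropy;
this module only converts between dendropy trees and :class:`Node`.

Gene sequence identifiers carry their taxon as a prefix (``Ath_00123`` means
taxon ``Ath``); :class:`TaxonMap` encapsulates that convention and also reads
explicit two-column id-to-species tables such as the readme files shipped
with MAPS data releases.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import dendropy

from .errors import BlastRowError, NewickParseError, RootingError

__all__ = [
    "Node",
    "TaxonMap",
    "GeneTree",
    "SpeciesTree",
    "Hit",
    "read_newick",
    "write_newick",
    "read_blast_tab",
    "read_maps_release",
]


class Node:
    """A rooted tree node: ``label`` (leaves), ``length`` and ``children``."""

    __slots__ = ("label", "length", "children", "parent")

    def __init__(self, label: str | None = None, length: float | None = None,
                 children: list["Node"] | None = None):
        self.label = label
        self.length = length
        self.children: list[Node] = []
        self.parent: Node | None = None
        for child in children or ():
            self.add_child(child)

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self) -> Iterator["Node"]:
        stack, out = [self], []
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return reversed(out)

    def preorder(self) -> Iterator["Node"]:
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> list["Node"]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Node({write_newick(self)})"


@dataclass(frozen=True)
class TaxonMap:
    """Mapping from gene-sequence identifier to taxon identifier.

    When an id is absent from ``entries`` it is resolved by splitting on
    ``delimiter`` and taking the prefix, the common convention for
    transcriptome assemblies.
    """

    entries: dict[str, str] = field(default_factory=dict)
    delimiter: str = "_"

    def taxon_of(self, gene_id: str) -> str:
        if gene_id in self.entries:
            return self.entries[gene_id]
        return gene_id.split(self.delimiter, 1)[0]

    @classmethod
    def from_table(cls, path: str | os.PathLike, delimiter: str = "_") -> "TaxonMap":
        """Read a two-column whitespace-delimited ``gene-id  species`` file."""
        entries: dict[str, str] = {}
        with open(path) as handle:
            for line in handle:
                parts = line.split()
                if len(parts) < 2 or parts[0].startswith("#"):
                    continue
                entries[parts[0]] = parts[1]
        return cls(entries=entries, delimiter=delimiter)


@dataclass
class GeneTree:
    """A rooted, binary gene-family tree with taxon-resolvable leaves."""

    root: Node
    taxon_map: TaxonMap = field(default_factory=TaxonMap)
    name: str = ""

    def __post_init__(self):
        # analysis-grade gene trees have >=2 leaves; one-leaf trees are
        # tolerated as degenerate unconditioned simulator output
        if not self.root.leaves():
            raise ValueError(f"gene tree {self.name!r} has no leaves")

    def leaf_taxa(self) -> set[str]:
        return {self.taxon_map.taxon_of(l) for l in self.root.leaf_labels()}

    def taxon_of(self, leaf_label: str) -> str:
        return self.taxon_map.taxon_of(leaf_label)


@dataclass
class SpeciesTree:
    """A rooted species tree over taxon identifiers.

    For MAPS analyses the tree must be pectinate (a ladder); validation and
    the N1..Nk node numbering live in :mod:`wgdkit.maps_core`.
    """

    root: Node
    outgroup: str | None = None

    def taxa(self) -> set[str]:
        return set(self.root.leaf_labels())


# ---------------------------------------------------------------------------
# newick


def _from_dendropy(tree: dendropy.Tree) -> Node:
    def convert(dnode) -> Node:
        label = None
        if dnode.is_leaf():
            label = dnode.taxon.label if dnode.taxon else dnode.label
        else:
            label = dnode.label
        node = Node(label=label, length=dnode.edge.length)
        for child in dnode.child_nodes():
            node.add_child(convert(child))
        return node

    return convert(tree.seed_node)


def _to_dendropy(root: Node) -> dendropy.Tree:
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)

    def convert(node: Node, dnode):
        dnode.edge.length = node.length
        if node.is_leaf:
            dnode.taxon = taxa.require_taxon(label=node.label)
        else:
            dnode.label = node.label
            for child in node.children:
                convert(child, dnode.new_child())

    convert(root, tree.seed_node)
    return tree


def _binarize(node: Node) -> Node:
    """Resolve polytomies deterministically by sorted-leaf-label folding."""
    for child in list(node.children):
        _binarize(child)
    if len(node.children) > 2:
        children = sorted(node.children, key=lambda c: min(c.leaf_labels()))
        acc = children[0]
        for nxt in children[1:-1]:
            joint = Node(length=0.0, children=[acc, nxt])
            acc = joint
        node.children = []
        node.add_child(acc)
        node.add_child(children[-1])
    return node


def read_newick(source: str | os.PathLike, rooted: bool = True,
                outgroup: str | None = None) -> Node:
    """Parse one newick tree from a file path (or a literal newick string).

    Polytomies (including an unrooted trifurcating root) are resolved to a
    binary tree deterministically by sorted-leaf-label folding.  When
    ``rooted`` is required and the root trifurcation cannot be resolved via
    ``outgroup``, the deterministic binarization is applied and the caller is
    responsible for the rooting semantics; pass ``outgroup`` to root
    explicitly on that taxon's edge.
    """
    text: str
    path = Path(str(source))
    if isinstance(source, (str,)) and source.strip().endswith(";") and "(" in source:
        text = source
    elif path.exists():
        text = path.read_text()
    else:
        raise FileNotFoundError(f"no such newick file: {source}")
    try:
        tree = dendropy.Tree.get(data=text, schema="newick",
                                 preserve_underscores=True,
                                 suppress_internal_node_taxa=True)
    except Exception as exc:  # dendropy raises several error classes
        offset = _error_offset(text, exc)
        raise NewickParseError(
            f"malformed newick near byte offset {offset}: {exc}") from None
    root = _from_dendropy(tree)
    if outgroup is not None:
        root = _root_on_outgroup(root, outgroup)
    if rooted and len(root.children) > 2 and outgroup is None and root.parent is None:
        # unrooted basal trifurcation with no outgroup: fall through to the
        # deterministic binarization below
        pass
    root = _binarize(root)
    if rooted and len(root.children) not in (0, 2):
        raise RootingError("could not produce a rooted binary tree")
    return root


def _error_offset(text: str, exc: Exception) -> int:
    line = getattr(exc, "line_num", None)
    col = getattr(exc, "col_num", None)
    if line:
        lines = text.splitlines(keepends=True)
        offset = sum(len(l) for l in lines[: line - 1]) + (col or 1) - 1
        return offset
    # fall back: first unbalanced position
    depth = 0
    for i, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                return i
    return len(text)


def _root_on_outgroup(root: Node, outgroup: str) -> Node:
    candidates = sorted(l.label for l in root.leaves()
                        if l.label == outgroup or l.label.startswith(outgroup))
    if not candidates:
        raise RootingError(f"outgroup {outgroup!r} not found among leaves")
    target = candidates[0]
    tree = _to_dendropy(root)
    node = tree.find_node_with_taxon_label(target)
    tree.to_outgroup_position(node, update_bipartitions=False)
    return _from_dendropy(tree)


def write_newick(root: Node, path: str | os.PathLike | None = None) -> str:
    tree = _to_dendropy(root)
    text = tree.as_string(schema="newick", suppress_rooting=True,
                          unquoted_underscores=True).strip()
    if not text.endswith(";"):
        text += ";"
    if path is not None:
        Path(path).write_text(text + "\n")
    return text


# ---------------------------------------------------------------------------
# BLAST tabular


@dataclass(frozen=True)
class Hit:
    """One row of 12-column BLAST tabular output (extra columns ignored)."""

    query: str
    subject: str
    pct_identity: float
    aln_length: int
    evalue: float
    bitscore: float


def read_blast_tab(path: str | os.PathLike) -> list[Hit]:
    """Read a 12+-column tab-separated BLAST hit table.

    Self-hits are retained; filtering happens downstream.
    """
    hits: list[Hit] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 12:
                raise BlastRowError(
                    f"{path}:{lineno}: expected >=12 tab-separated columns, "
                    f"got {len(cols)}")
            try:
                hit = Hit(query=cols[0], subject=cols[1],
                          pct_identity=float(cols[2]),
                          aln_length=int(float(cols[3])),
                          evalue=float(cols[10]), bitscore=float(cols[11]))
            except ValueError as exc:
                raise BlastRowError(f"{path}:{lineno}: {exc}") from None
            hits.append(hit)
    return hits


# ---------------------------------------------------------------------------
# MAPS data-release layout


def read_maps_release(archive_dir: str | os.PathLike,
                      delimiter: str = "_") -> tuple[list[GeneTree], list[Path], TaxonMap]:
    """Read a MAPS per-analysis release directory.

    The layout is a ``*-aln`` folder of alignments, a ``*-tre`` folder of
    newick gene trees and a readme mapping taxon identifiers to species
    names.  Trees and alignments are paired by shared basename; a tree
    without a matching alignment is kept with a warning.  The readme is
    accepted as any two-column whitespace-delimited id-to-species file.
    """
    base = Path(archive_dir)
    tre_dirs = sorted(base.glob("*-tre"))
    aln_dirs = sorted(base.glob("*-aln"))
    if not tre_dirs:
        raise FileNotFoundError(f"no '*-tre' folder under {base}")
    readmes = [p for p in base.iterdir()
               if p.is_file() and p.name.lower().startswith("readme")]
    if not readmes:
        raise FileNotFoundError(f"no readme file under {base}")
    taxon_map = TaxonMap.from_table(readmes[0], delimiter=delimiter)

    aln_by_stem: dict[str, Path] = {}
    for d in aln_dirs:
        for p in sorted(d.iterdir()):
            aln_by_stem[p.stem] = p

    trees: list[GeneTree] = []
    alignments: list[Path] = []
    for d in tre_dirs:
        for p in sorted(d.iterdir()):
            root = read_newick(p)
            trees.append(GeneTree(root=root, taxon_map=taxon_map, name=p.stem))
            aln = aln_by_stem.get(p.stem)
            if aln is None:
                warnings.warn(f"gene tree {p.name} has no matching alignment")
            else:
                alignments.append(aln)
    return trees, alignments, taxon_map
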