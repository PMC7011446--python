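"""Shared fixtures: species trees, random gene trees, random codon pairs."""

from __future__ import annotations

import random
import warnings

import numpy as np
import pytest

from wgdkit.core_io import GeneTree, Node, SpeciesTree, TaxonMap
from wgdkit.simulate import ladder_species_tree

# validate_species_tree warns for <6 taxa; toy fixtures trip that on purpose
warnings.filterwarnings("ignore", message="species tree has")


@pytest.fixture
def ladder4() -> SpeciesTree:
    """(((A,B),C),D) with unit branch lengths."""
    return ladder_species_tree(["A", "B", "C", "D"], branch_length=1.0)


@pytest.fixture
def ladder7() -> SpeciesTree:
    return ladder_species_tree(list("ABCDEFG"), branch_length=50.0)


def tuple_to_gene_tree(tree, name="g") -> GeneTree:
    """Nested-tuple topology with ``Taxon_copy`` leaf labels -> GeneTree."""
    def build(t):
        if isinstance(t, tuple):
            return Node(children=[build(t[0]), build(t[1])])
        return Node(label=t)
    return GeneTree(root=build(tree), taxon_map=TaxonMap(), name=name)


def random_gene_tuple(rng: random.Random, taxa, n_leaves: int):
    """A uniform-attachment random topology with random taxon labels."""
    counter: dict[str, int] = {}

    def leaf():
        t = rng.choice(taxa)
        counter[t] = counter.get(t, 0) + 1
        return f"{t}_{counter[t]}"

    tree = leaf()
    for _ in range(n_leaves - 1):
        new = leaf()
        nodes = _positions(tree)
        pos = rng.randrange(nodes)
        tree = _attach_at(tree, new, pos)[0]
    return tree


def _positions(tree) -> int:
    if isinstance(tree, tuple):
        return 1 + _positions(tree[0]) + _positions(tree[1])
    return 1


def _attach_at(tree, leaf, pos):
    if pos == 0:
        return (tree, leaf), -1
    if not isinstance(tree, tuple):
        return tree, pos - 1
    pos -= 1
    left, pos = _attach_at(tree[0], leaf, pos)
    if pos == -1:
        return (left, tree[1]), -1
    right, pos = _attach_at(tree[1], leaf, pos)
    return (tree[0], right), pos


_CODONS_NO_STOP = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
                   if a + b + c not in ("TAA", "TAG", "TGA")]


def random_codon_pair(rng: random.Random, n_codons: int = 100,
                      p_sub: float = 0.15) -> tuple[str, str]:
    """A stop-free codon alignment and a point-mutated copy of it."""
    seq_a = [rng.choice(_CODONS_NO_STOP) for _ in range(n_codons)]
    seq_b = []
    for codon in seq_a:
        new = codon
        for pos in range(3):
            if rng.random() < p_sub:
                new = new[:pos] + rng.choice("ACGT") + new[pos + 1:]
        if new in ("TAA", "TAG", "TGA"):
            new = codon
        seq_b.append(new)
    return "".join(seq_a), "".join(seq_b)
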