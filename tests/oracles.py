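"""Independent oracle implementations used to cross-check the package.

Everything here is deliberately written with different algorithms and data
structures than the package code: brute-force enumeration, parent-pointer
LCA walks, nested-tuple trees.  The oracles define the expected behaviour;
the package must agree with them.
"""

from __future__ import annotations

import math
from itertools import permutations

from Bio.Data.CodonTable import unambiguous_dna_by_id

# ---------------------------------------------------------------------------
# rooted binary tree topology enumeration (nested tuples)


def all_rooted_topologies(labels):
    """Every rooted binary leaf-labeled topology on ``labels`` exactly once,
    by sibling-attachment of each successive leaf at every node."""
    labels = list(labels)
    if len(labels) == 1:
        yield labels[0]
        return
    new = labels[-1]
    for base in all_rooted_topologies(labels[:-1]):
        for pos in range(_n_nodes(base)):
            yield _attach(base, new, pos)[0]


def _n_nodes(tree) -> int:
    if isinstance(tree, tuple):
        return 1 + _n_nodes(tree[0]) + _n_nodes(tree[1])
    return 1


def _attach(tree, leaf, pos):
    """Attach ``leaf`` as sibling of the node with preorder index ``pos``."""
    if pos == 0:
        return (tree, leaf), -1
    if not isinstance(tree, tuple):
        return tree, pos - 1  # this leaf consumed one preorder position
    pos -= 1
    left, pos = _attach(tree[0], leaf, pos)
    if pos == -1:
        return (left, tree[1]), -1
    right, pos = _attach(tree[1], leaf, pos)
    return (tree[0], right), pos


def tuple_to_newick(tree) -> str:
    def fmt(t):
        if isinstance(t, tuple):
            return f"({fmt(t[0])},{fmt(t[1])})"
        return t
    return fmt(tree) + ";"


# ---------------------------------------------------------------------------
# LCA-reconciliation apparent-duplication oracle


class SpeciesLCA:
    """Parent-pointer/depth LCA over a species tree given as nested tuples
    with leaf taxon names."""

    def __init__(self, tree):
        self.parent = {}
        self.depth = {}
        self.name = {}
        self._ids = {}
        self._build(tree, None, 0)

    def _key(self, subtree):
        return id(subtree) if isinstance(subtree, tuple) else subtree

    def _build(self, subtree, parent, depth):
        key = self._key(subtree)
        self.parent[key] = parent
        self.depth[key] = depth
        if isinstance(subtree, tuple):
            for child in subtree:
                self._build(child, key, depth + 1)
        else:
            self.name[subtree] = key

    def lca(self, u, v):
        while self.depth[u] > self.depth[v]:
            u = self.parent[u]
        while self.depth[v] > self.depth[u]:
            v = self.parent[v]
        while u != v:
            u, v = self.parent[u], self.parent[v]
        return u

    def lca_many(self, keys):
        it = iter(keys)
        acc = next(it)
        for k in it:
            acc = self.lca(acc, k)
        return acc


def apparent_duplications(gene_tuple, species_lca: SpeciesLCA, taxon_of):
    """LCA-reconciliation events that are *apparent* duplications: the gene
    node's mapping equals a child's mapping AND the child species sets
    intersect.  Returns a list of mapped species-node keys."""
    events = []

    def walk(tree):
        if not isinstance(tree, tuple):
            taxon = taxon_of(tree)
            return {taxon}, species_lca.name[taxon]
        sl, ml = walk(tree[0])
        sr, mr = walk(tree[1])
        m = species_lca.lca(ml, mr)
        if (m == ml or m == mr) and (sl & sr):
            events.append(m)
        return sl | sr, m

    walk(gene_tuple)
    return events


# ---------------------------------------------------------------------------
# connected components by explicit depth-first search


def dfs_components(edges):
    adj = {}
    for a, b in edges:
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    seen = set()
    comps = []
    for start in sorted(adj):
        if start in seen:
            continue
        stack, comp = [start], set()
        while stack:
            node = stack.pop()
            if node in comp:
                continue
            comp.add(node)
            stack.extend(adj[node] - comp)
        seen |= comp
        comps.append(frozenset(comp))
    return sorted(comps, key=min)


# ---------------------------------------------------------------------------
# Fisher one-sided p by exhaustive hypergeometric enumeration


def fisher_greater_pvalue(a, b, c, d) -> float:
    """P(X >= a) for the hypergeometric X with row margins (a+b, c+d) and
    column margin a+c, via explicit enumeration with exact binomials."""
    n = a + b + c + d
    row1, col1 = a + b, a + c
    total = math.comb(n, col1)
    p = 0.0
    for x in range(a, min(row1, col1) + 1):
        if col1 - x > n - row1:
            continue
        p += math.comb(row1, x) * math.comb(n - row1, col1 - x) / total
    return p


def fisher_less_pvalue(a, b, c, d) -> float:
    n = a + b + c + d
    row1, col1 = a + b, a + c
    total = math.comb(n, col1)
    p = 0.0
    for x in range(0, a + 1):
        if x > row1 or col1 - x > n - row1 or col1 - x < 0:
            continue
        p += math.comb(row1, x) * math.comb(n - row1, col1 - x) / total
    return p


# ---------------------------------------------------------------------------
# NG86 site/difference enumeration oracle

_TABLE = unambiguous_dna_by_id[1]
_AA = dict(_TABLE.forward_table)
_STOPS = set(_TABLE.stop_codons)


def syn_sites_oracle(codon: str) -> float:
    """Synonymous sites of a codon by enumerating all nine single-nucleotide
    mutations; mutations to stop codons count as nonsynonymous."""
    count = 0.0
    for pos in range(3):
        for base in "ACGT":
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1:]
            if mutant not in _STOPS and _AA[mutant] == _AA[codon]:
                count += 1
    return count / 3.0


def path_diffs_oracle(c1: str, c2: str):
    """Average synonymous/nonsynonymous differences over all mutational
    orderings between two codons, skipping orderings through stop codons;
    ``None`` when every ordering is blocked."""
    positions = [i for i in range(3) if c1[i] != c2[i]]
    if not positions:
        return 0.0, 0.0
    syn = nonsyn = 0.0
    valid = 0
    for order in permutations(positions):
        path = [c1]
        cur = c1
        for pos in order:
            cur = cur[:pos] + c2[pos] + cur[pos + 1:]
            path.append(cur)
        if any(c in _STOPS for c in path[1:]):
            continue
        valid += 1
        for prev, nxt in zip(path, path[1:]):
            if _AA[prev] == _AA[nxt]:
                syn += 1
            else:
                nonsyn += 1
    if valid == 0:
        return None
    return syn / valid, nonsyn / valid


def ks_oracle(seq_a: str, seq_b: str) -> float:
    """Full NG86 + Jukes-Cantor Ks recomputed from the per-codon oracles."""
    sites = 0.0
    diffs = 0.0
    for i in range(0, len(seq_a), 3):
        ca, cb = seq_a[i:i + 3], seq_b[i:i + 3]
        if ca not in _AA or cb not in _AA:
            continue
        d = path_diffs_oracle(ca, cb)
        if d is None:
            continue
        sites += 0.5 * (syn_sites_oracle(ca) + syn_sites_oracle(cb))
        diffs += d[0]
    ps = diffs / sites if sites else 0.0
    return -0.75 * math.log(1.0 - 4.0 * ps / 3.0)
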