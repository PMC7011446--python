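"""Gene-age (Ks) distribution construction in the DupPipe style.

The steps are: filter all-vs-all hits into duplicate pairs (>=40% identity
over >=300 bp by default), build gene families by single-linkage clustering,
estimate synonymous divergence (Ks) per pair by Nei-Gojobori (NG86) codon
counting with the Jukes-Cantor correction, and assign one Ks value to each
internal node of a family tree (the median of the cross-child pairwise
values).  An external per-pair Ks table can be passed through instead of the
counting estimator, e.g. to reuse codon-ML estimates.

Ks values whose corrected synonymous proportion reaches saturation (p >= 3/4)
are flagged rather than imputed and excluded from age distributions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import permutations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd
from Bio.Data.CodonTable import unambiguous_dna_by_id

from .core_io import GeneTree, Hit, Node
from .errors import InsufficientDataError, SaturationError

__all__ = [
    "DuplicatePair",
    "GeneFamily",
    "NodeKs",
    "AgeDistribution",
    "filter_duplicate_pairs",
    "single_linkage_families",
    "estimate_ks_pair",
    "ks_matrix_from_table",
    "node_ks_from_tree",
    "write_age_distribution",
    "read_age_distribution",
]

MIN_IDENTITY = 40.0   # % sequence similarity for a duplicate pair
MIN_ALN_LENGTH = 300  # bp
MIN_CODONS = 30       # comparable codons required for a Ks estimate
SATURATION = 0.75     # synonymous proportion at/above which JC86 diverges


@dataclass(frozen=True, order=True)
class DuplicatePair:
    gene_a: str
    gene_b: str
    pct_identity: float = 100.0
    aln_length: int = 0


@dataclass(frozen=True)
class GeneFamily:
    family_id: str
    members: frozenset[str]

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class NodeKs:
    family_id: str
    node_id: str
    ks: float


@dataclass
class AgeDistribution:
    """Per-species collection of duplication-node Ks values."""

    species: str
    records: list[NodeKs] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def values(self) -> list[float]:
        return [r.ks for r in self.records]

    def window(self, lo: float = 0.01, hi: float = 2.0) -> list[float]:
        """Ks values inside the analysis window ``(lo, hi]``."""
        return [v for v in self.values() if lo < v <= hi and math.isfinite(v)]


# ---------------------------------------------------------------------------
# duplicate pairs and families


def filter_duplicate_pairs(hits: Iterable[Hit],
                           min_identity: float = MIN_IDENTITY,
                           min_length: int = MIN_ALN_LENGTH) -> list[DuplicatePair]:
    """Filter raw hits into duplicate pairs.

    Drops self-hits, applies the identity/length thresholds, deduplicates
    (a,b)/(b,a) keeping the best identity (then longest alignment), and
    returns pairs sorted lexicographically.
    """
    best: dict[tuple[str, str], tuple[float, int]] = {}
    for hit in hits:
        if hit.query == hit.subject:
            continue
        if hit.pct_identity < min_identity or hit.aln_length < min_length:
            continue
        key = (hit.query, hit.subject) if hit.query < hit.subject \
            else (hit.subject, hit.query)
        cand = (hit.pct_identity, hit.aln_length)
        if key not in best or cand > best[key]:
            best[key] = cand
    return [DuplicatePair(a, b, pct_identity=v[0], aln_length=v[1])
            for (a, b), v in sorted(best.items())]


def single_linkage_families(pairs: Sequence[DuplicatePair]) -> list[GeneFamily]:
    """Gene families as connected components of the duplicate-pair graph."""
    graph = nx.Graph()
    for pair in pairs:
        graph.add_edge(pair.gene_a, pair.gene_b)
    families = []
    for component in nx.connected_components(graph):
        members = frozenset(component)
        families.append(GeneFamily(family_id=min(members), members=members))
    families.sort(key=lambda f: f.family_id)
    return families


# ---------------------------------------------------------------------------
# NG86 synonymous divergence

_CODON_TABLE = unambiguous_dna_by_id[1]
_STOPS = set(_CODON_TABLE.stop_codons)
_AA = dict(_CODON_TABLE.forward_table)
_BASES = "ACGT"


def _syn_site_fraction(codon: str) -> float:
    """Synonymous-site count of one codon (mutations to stops count as
    nonsynonymous)."""
    total = 0.0
    aa = _AA[codon]
    for pos in range(3):
        syn = 0
        for base in _BASES:
            if base == codon[pos]:
                continue
            mut = codon[:pos] + base + codon[pos + 1:]
            if mut not in _STOPS and _AA[mut] == aa:
                syn += 1
        total += syn / 3.0
    return total


_SYN_SITES = {c: _syn_site_fraction(c) for c in _AA}


def _path_differences(c1: str, c2: str) -> tuple[float, float] | None:
    """Average (synonymous, nonsynonymous) differences between two codons.

    Averages over all mutational orderings between the codons, excluding
    orderings that pass through a stop codon.  Returns ``None`` when every
    ordering is blocked (the codon pair is then not comparable).
    """
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return (0.0, 0.0)
    syn_total = nonsyn_total = 0.0
    n_valid = 0
    for order in permutations(diff_pos):
        cur = c1
        steps = []
        ok = True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if nxt in _STOPS:
                ok = False
                break
            steps.append(1 if _AA[cur] == _AA[nxt] else 0)
            cur = nxt
        if not ok:
            continue
        n_valid += 1
        s = sum(steps)
        syn_total += s
        nonsyn_total += len(steps) - s
    if n_valid == 0:
        return None
    return syn_total / n_valid, nonsyn_total / n_valid


def estimate_ks_pair(seq_a: str, seq_b: str, min_codons: int = MIN_CODONS) -> float:
    """NG86 synonymous divergence between two aligned coding sequences.

    Both sequences must be codon-aligned (equal length divisible by 3); gap
    or ambiguous codons and codons that are stops in either sequence are
    skipped.  The proportion of synonymous differences is corrected with the
    one-parameter (Jukes-Cantor) distance.

    Raises :class:`SaturationError` when the synonymous proportion reaches
    3/4 and :class:`InsufficientDataError` below ``min_codons`` comparable
    codons.
    """
    a = seq_a.upper().replace("U", "T")
    b = seq_b.upper().replace("U", "T")
    if len(a) != len(b) or len(a) % 3 != 0:
        raise ValueError("sequences must be codon-aligned (equal length, multiple of 3)")
    syn_sites = 0.0
    syn_diffs = 0.0
    n_codons = 0
    for i in range(0, len(a), 3):
        ca, cb = a[i:i + 3], b[i:i + 3]
        if ca not in _AA or cb not in _AA:  # gaps, ambiguity codes, stops
            continue
        path = _path_differences(ca, cb)
        if path is None:
            continue
        n_codons += 1
        syn_sites += 0.5 * (_SYN_SITES[ca] + _SYN_SITES[cb])
        syn_diffs += path[0]
    if n_codons < min_codons:
        raise InsufficientDataError(
            f"only {n_codons} comparable codons (<{min_codons})")
    ps = syn_diffs / syn_sites if syn_sites > 0 else 0.0
    if ps >= SATURATION:
        raise SaturationError(f"synonymous proportion {ps:.3f} >= 3/4")
    return -0.75 * math.log1p(-4.0 * ps / 3.0)


def ks_matrix_from_table(path_or_frame) -> dict[frozenset[str], float]:
    """Load an external per-pair Ks table (columns gene-a, gene-b, Ks)."""
    if isinstance(path_or_frame, pd.DataFrame):
        frame = path_or_frame
    else:
        frame = pd.read_csv(path_or_frame, sep="\t")
    cols = list(frame.columns[:3])
    out: dict[frozenset[str], float] = {}
    for a, b, ks in frame[cols].itertuples(index=False):
        out[frozenset((str(a), str(b)))] = float(ks)
    return out


# ---------------------------------------------------------------------------
# node Ks


def node_ks_from_tree(tree: GeneTree,
                      ks: Mapping[frozenset[str], float | None],
                      family_id: str | None = None) -> list[NodeKs]:
    """Assign a Ks value to every internal node of a gene-family tree.

    A node's value is the median of the pairwise Ks values between leaves of
    its left child and leaves of its right child; saturated pairs (``None``
    in ``ks``) are ignored and nodes with no unsaturated cross-pair are
    skipped.  This per-node assignment gives one age per duplication event
    instead of one per pair, which sharpens WGD peaks.
    """
    family = family_id or tree.name or "fam"
    records: list[NodeKs] = []
    counter = 0
    leafsets: dict[int, list[str]] = {}
    for node in tree.root.postorder():
        if node.is_leaf:
            leafsets[id(node)] = [node.label]
            continue
        left, right = node.children[0], node.children[1]
        leafsets[id(node)] = leafsets[id(left)] + leafsets[id(right)]
        counter += 1
        values = []
        for la in leafsets[id(left)]:
            for lb in leafsets[id(right)]:
                v = ks.get(frozenset((la, lb)))
                if v is not None and math.isfinite(v):
                    values.append(v)
        if not values:
            continue
        values.sort()
        n = len(values)
        med = values[n // 2] if n % 2 else 0.5 * (values[n // 2 - 1] + values[n // 2])
        records.append(NodeKs(family_id=family, node_id=f"node{counter}", ks=med))
    return records


# ---------------------------------------------------------------------------
# age-distribution TSV


def write_age_distribution(ages: AgeDistribution, path) -> None:
    """Write the DupPipe-style tab-delimited node-Ks table."""
    frame = pd.DataFrame(
        [(r.family_id, r.node_id, r.ks) for r in ages.records],
        columns=["family_id", "node_id", "Ks"],
    )
    frame.to_csv(path, sep="\t", index=False, float_format="%.8g")


def read_age_distribution(path, species: str | None = None) -> AgeDistribution:
    frame = pd.read_csv(path, sep="\t")
    records = [NodeKs(str(f), str(n), float(k))
               for f, n, k in frame.itertuples(index=False)]
    name = species or Path(str(path)).stem
    return AgeDistribution(species=name, records=records)
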