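"""Ortholog divergence and paralog-vs-ortholog WGD placement.

Orthologs between two transcriptomes are identified as reciprocal best
BLAST hits (RBH).  The Ks distribution of those ortholog pairs dates the
lineage split; comparing a WGD peak's median paralog Ks with the median
ortholog Ks brackets the duplication against the speciation: a peak younger
than the split happened after divergence, a peak older than the split is
shared by both lineages.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .core_io import Hit
from .errors import InsufficientDataError
from .wgd_detect import PeakCall

__all__ = [
    "OrthologPair",
    "DivergenceSummary",
    "PlacementCall",
    "reciprocal_best_hits",
    "ortholog_divergence",
    "place_wgd",
]


@dataclass(frozen=True)
class OrthologPair:
    gene_a: str
    gene_b: str
    ks: float | None = None


@dataclass(frozen=True)
class DivergenceSummary:
    species_pair: tuple[str, str]
    n_pairs: int
    mean_ks: float
    median_ks: float


@dataclass(frozen=True)
class PlacementCall:
    peak_median: float
    species_pair: tuple[str, str]
    ortholog_median: float
    verdict: str  # "shared" | "after-divergence" | "unresolved"


def _best_hits(hits: Iterable[Hit]) -> dict[str, str]:
    """Best subject per query by bitscore, then identity, then subject id."""
    best: dict[str, Hit] = {}
    for hit in hits:
        cur = best.get(hit.query)
        if cur is None:
            best[hit.query] = hit
            continue
        a = (hit.bitscore, hit.pct_identity)
        b = (cur.bitscore, cur.pct_identity)
        if a > b or (a == b and hit.subject < cur.subject):
            best[hit.query] = hit
    return {q: h.subject for q, h in best.items()}


def reciprocal_best_hits(hits_ab: Iterable[Hit],
                         hits_ba: Iterable[Hit]) -> list[OrthologPair]:
    """Reciprocal best hits from A-vs-B and B-vs-A hit tables."""
    best_ab = _best_hits(hits_ab)
    best_ba = _best_hits(hits_ba)
    pairs = [OrthologPair(a, b) for a, b in best_ab.items()
             if best_ba.get(b) == a]
    pairs.sort(key=lambda p: (p.gene_a, p.gene_b))
    return pairs


def ortholog_divergence(pairs: Sequence[OrthologPair],
                        species_pair: tuple[str, str] = ("A", "B"),
                        min_pairs: int = 20) -> DivergenceSummary:
    """Mean and median ortholog Ks over unsaturated pairs."""
    values = [p.ks for p in pairs if p.ks is not None]
    if len(values) < min_pairs:
        raise InsufficientDataError(
            f"{len(values)} ortholog pairs with Ks (<{min_pairs})")
    return DivergenceSummary(species_pair=species_pair, n_pairs=len(values),
                             mean_ks=statistics.fmean(values),
                             median_ks=statistics.median(values))


def place_wgd(peak: PeakCall | float, divergence: DivergenceSummary,
              margin: float = 0.0, ci_overlap: bool = False) -> PlacementCall:
    """Place a WGD peak relative to a lineage divergence.

    Paralog (peak) median younger than the ortholog median means the
    duplication post-dates the split (``after-divergence``); older means it
    is ``shared`` by both lineages; within ``margin`` (or, with
    ``ci_overlap``, when the peak's 95% CI contains the ortholog median) it
    is ``unresolved``.
    """
    if isinstance(peak, PeakCall):
        peak_median = peak.median_ks
        if ci_overlap and peak.ci[0] <= divergence.median_ks <= peak.ci[1]:
            return PlacementCall(peak_median, divergence.species_pair,
                                 divergence.median_ks, "unresolved")
    else:
        peak_median = float(peak)
    ortho = divergence.median_ks
    if peak_median < ortho - margin:
        verdict = "after-divergence"
    elif peak_median > ortho + margin:
        verdict = "shared"
    else:
        verdict = "unresolved"
    return PlacementCall(peak_median, divergence.species_pair, ortho, verdict)
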