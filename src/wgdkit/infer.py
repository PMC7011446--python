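"""Episode classification against null/positive simulations and the
total-evidence WGD caller.

An observed MAPS profile is compared node by node to each resampled null
simulation set with a one-sided Fisher exact test (observed shared
duplications greater than expected).  A node is a significant *burst* when
the test rejects at alpha in at least 95% of the null resamples.  A burst is
*WGD-consistent* when, against positive simulations carrying a WGD at that
node, the observed counts are not significantly lower in at least half of
the positive resamples.

Because duplication mapping is least reliable at the tips and root of the
species tree, results at N1 and Nk carry a low-confidence flag.

A WGD is only called from the weight of evidence across the Ks-plot,
ortholog-divergence and MAPS lines; Ks + ortholog support without MAPS
support is recorded as a significant burst of gene duplication, not a WGD.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd
from scipy import stats

from .maps_core import MapsProfile, OccupancyRule, SpeciesIndex, per_tree_node_counts
from .simulate import SimulationSet

__all__ = [
    "EpisodeTest",
    "TotalEvidenceCall",
    "resample_profiles",
    "fisher_vs_null",
    "fisher_vs_positive",
    "classify_episodes",
    "total_evidence",
    "episode_frame",
]

ALPHA = 0.01
NULL_SIG_FRACTION = 0.95       # fraction of null resamples that must reject
POSITIVE_CONSISTENT_FRACTION = 0.5


@dataclass
class EpisodeTest:
    node: str
    obs_dup: int
    obs_subtrees: int
    null_pvalues: list[float] = field(default_factory=list)
    frac_null_significant: float = 0.0
    positive_pvalues: list[float] = field(default_factory=list)
    frac_positive_consistent: float = float("nan")
    classification: str = "background"  # background | burst | WGD-consistent
    low_confidence: bool = False
    skipped: bool = False


@dataclass(frozen=True)
class TotalEvidenceCall:
    placement: str
    ks_peak: bool | None
    ortholog: str | None
    maps: str | None
    verdict: str  # "WGD" | "significant-burst" | "none"
    conflict: bool = False


# ---------------------------------------------------------------------------
# profiles from simulation sets


def resample_profiles(simset: SimulationSet,
                      rule: OccupancyRule = OccupancyRule()) -> list[MapsProfile]:
    """One MAPS profile per resample of the simulation set (per-tree counts
    are computed once and summed per subset)."""
    index = SpeciesIndex(simset.species)
    per_tree = [per_tree_node_counts(t, index, rule) for t in simset.trees]
    labels = index.node_labels
    profiles = []
    for idx in simset.resample_indices:
        prof = MapsProfile(node_order=labels,
                           n_subtrees={lab: 0 for lab in labels},
                           n_dup={lab: 0 for lab in labels})
        for i in idx:
            for lab, (n, d) in per_tree[i].items():
                prof.n_subtrees[lab] += n
                prof.n_dup[lab] += d
        profiles.append(prof)
    return profiles


# ---------------------------------------------------------------------------
# Fisher tests


def _fisher_one_sided(obs_dup: int, obs_total: int, sim_dup: int,
                      sim_total: int, alternative: str) -> float:
    table = [[obs_dup, obs_total - obs_dup], [sim_dup, sim_total - sim_dup]]
    return float(stats.fisher_exact(table, alternative=alternative).pvalue)


def fisher_vs_null(observed: MapsProfile, null_profiles: Sequence[MapsProfile],
                   alpha: float = ALPHA,
                   sig_fraction: float = NULL_SIG_FRACTION) -> dict[str, EpisodeTest]:
    """Per-node one-sided Fisher tests of the observed profile against every
    null resample; a node is a burst when p < alpha in >= ``sig_fraction``
    of the resamples."""
    tests: dict[str, EpisodeTest] = {}
    labels = observed.node_order
    for pos, node in enumerate(labels):
        obs_n = observed.n_subtrees.get(node, 0)
        obs_d = observed.n_dup.get(node, 0)
        test = EpisodeTest(node=node, obs_dup=obs_d, obs_subtrees=obs_n,
                           low_confidence=pos in (0, len(labels) - 1))
        if obs_n == 0:
            test.skipped = True
            tests[node] = test
            continue
        for prof in null_profiles:
            sim_n = prof.n_subtrees.get(node, 0)
            sim_d = prof.n_dup.get(node, 0)
            if sim_n == 0:
                continue
            test.null_pvalues.append(
                _fisher_one_sided(obs_d, obs_n, sim_d, sim_n, "greater"))
        if test.null_pvalues:
            sig = sum(p < alpha for p in test.null_pvalues)
            test.frac_null_significant = sig / len(test.null_pvalues)
            if test.frac_null_significant >= sig_fraction:
                test.classification = "burst"
        tests[node] = test
    return tests


def fisher_vs_positive(tests: Mapping[str, EpisodeTest],
                       positive_profiles: Mapping[str, Sequence[MapsProfile]],
                       alpha: float = ALPHA,
                       consistent_fraction: float = POSITIVE_CONSISTENT_FRACTION,
                       ) -> dict[str, EpisodeTest]:
    """Promote bursts to WGD-consistent when the observed counts are not
    significantly *lower* than positive simulations at that node (p >= alpha
    in >= ``consistent_fraction`` of the positive resamples)."""
    for node, test in tests.items():
        if test.classification != "burst" or node not in positive_profiles:
            continue
        for prof in positive_profiles[node]:
            sim_n = prof.n_subtrees.get(node, 0)
            sim_d = prof.n_dup.get(node, 0)
            if sim_n == 0:
                continue
            test.positive_pvalues.append(
                _fisher_one_sided(test.obs_dup, test.obs_subtrees,
                                  sim_d, sim_n, "less"))
        if test.positive_pvalues:
            ok = sum(p >= alpha for p in test.positive_pvalues)
            test.frac_positive_consistent = ok / len(test.positive_pvalues)
            if test.frac_positive_consistent >= consistent_fraction:
                test.classification = "WGD-consistent"
    return dict(tests)


def classify_episodes(observed: MapsProfile,
                      null_set: SimulationSet,
                      positive_sets: Mapping[str, SimulationSet] | None = None,
                      rule: OccupancyRule = OccupancyRule(),
                      alpha: float = ALPHA) -> dict[str, EpisodeTest]:
    """Full null + positive classification for an observed profile."""
    null_profiles = resample_profiles(null_set, rule)
    tests = fisher_vs_null(observed, null_profiles, alpha=alpha)
    if positive_sets:
        pos_profiles = {node: resample_profiles(s, rule)
                        for node, s in positive_sets.items()}
        tests = fisher_vs_positive(tests, pos_profiles, alpha=alpha)
    return tests


def episode_frame(tests: Mapping[str, EpisodeTest]) -> pd.DataFrame:
    rows = []
    for node, t in tests.items():
        rows.append((node, t.obs_dup, t.obs_subtrees,
                     round(t.frac_null_significant, 4),
                     round(t.frac_positive_consistent, 4)
                     if t.positive_pvalues else float("nan"),
                     t.classification,
                     "low" if t.low_confidence else "normal",
                     "skipped" if t.skipped else "ok"))
    return pd.DataFrame(rows, columns=[
        "node", "obs_dup", "obs_subtrees", "null_frac_significant",
        "positive_frac_consistent", "classification", "confidence", "status"])


# ---------------------------------------------------------------------------
# total evidence


def total_evidence(placement: str,
                   ks_peak: bool | None = None,
                   ortholog_verdicts: Sequence[str] | None = None,
                   maps_classification: str | None = None) -> TotalEvidenceCall:
    """Weigh the three evidence lines for one candidate WGD placement.

    A WGD verdict needs at least two supporting lines.  When Ks and
    ortholog placement support the event but a MAPS analysis was run and
    does not, the event is recorded as a ``significant-burst``.  Conflicting
    ortholog placements for the same peak void the call.
    """
    ortho_support: bool | None = None
    conflict = False
    ortho_summary: str | None = None
    if ortholog_verdicts:
        verdicts = set(ortholog_verdicts)
        ortho_summary = ",".join(sorted(verdicts))
        if "shared" in verdicts and "after-divergence" in verdicts:
            conflict = True
        ortho_support = "shared" in verdicts
    maps_support = (maps_classification == "WGD-consistent"
                    if maps_classification is not None else None)
    if conflict:
        return TotalEvidenceCall(placement, ks_peak, ortho_summary,
                                 maps_classification, "none", conflict=True)
    support = sum(bool(s) for s in (ks_peak, ortho_support, maps_support)
                  if s is not None)
    if ks_peak and ortho_support and maps_support is False:
        verdict = "significant-burst"
    elif support >= 2:
        verdict = "WGD"
    else:
        verdict = "none"
    return TotalEvidenceCall(placement, ks_peak, ortho_summary,
                             maps_classification, verdict)
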