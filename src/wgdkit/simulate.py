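"""Birth-death guest-gene-tree simulation and synthetic fixtures.

Gene families evolve inside the species tree under a linear birth-death
process: one ancestral lineage at the root, per-lineage gene birth rate
``birth`` and loss rate ``death`` per unit branch length, all lineages
splitting at every speciation.  A WGD is an instantaneous doubling of all
extant lineages at a chosen point on a species-tree branch, each new copy
surviving the duplication instant with retention probability ``r``.
Simulated sets are conditioned on at least one surviving copy per taxon by
rejection, matching the family filter applied to observed data.

The module also provides the inverse problem (maximum-likelihood birth/death
rate estimation from per-family gene counts, via the closed-form linear
birth-death transition probabilities combined by pruning) and the synthetic
Ks samples and hit tables used to exercise the Ks-plot side of the pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import optimize

from .core_io import GeneTree, Hit, Node, SpeciesTree, TaxonMap
from .dup_age import AgeDistribution, NodeKs
from .errors import InsufficientDataError, WgdkitError
from .maps_core import SpeciesIndex, validate_species_tree

__all__ = [
    "BirthDeathRates",
    "WgdEvent",
    "SimulationSet",
    "simulate_guest_tree",
    "build_null_set",
    "build_positive_set",
    "estimate_rates",
    "bd_transition_probs",
    "synth_ks_sample",
    "synth_hit_table",
    "ladder_species_tree",
]


@dataclass(frozen=True)
class BirthDeathRates:
    """Per-gene, per-unit-branch-length birth (duplication) and death rates."""

    birth: float
    death: float

    def __post_init__(self):
        if self.birth < 0 or self.death < 0:
            raise ValueError("rates must be non-negative")


@dataclass(frozen=True)
class WgdEvent:
    """A WGD on the stem branch of species-tree node ``node`` (N-label or
    taxon name), at ``position`` (fraction of the branch measured from the
    parent) with per-copy retention probability ``retention``."""

    node: str
    position: float = 0.5
    retention: float = 0.2

    def __post_init__(self):
        if not 0.0 <= self.retention <= 1.0:
            raise ValueError("retention must be in [0, 1]")
        if not 0.0 <= self.position <= 1.0:
            raise ValueError("position must be in [0, 1]")


@dataclass
class SimulationSet:
    """A reproducible collection of simulated gene trees with a resample
    plan (subsets drawn without replacement)."""

    trees: list[GeneTree]
    species: SpeciesTree
    rates: BirthDeathRates
    wgd_events: tuple[WgdEvent, ...]
    seed: int
    resample_indices: list[np.ndarray] = field(default_factory=list)
    n_rejected: int = 0

    def resamples(self) -> Iterable[list[GeneTree]]:
        for idx in self.resample_indices:
            yield [self.trees[i] for i in idx]


# ---------------------------------------------------------------------------
# guest-tree simulation


def ladder_species_tree(taxa: Sequence[str], branch_length: float = 1.0) -> SpeciesTree:
    """A pectinate species tree; ``taxa[0]``/``taxa[1]`` form the cherry and
    the last taxon is the outgroup.  All branches share one length."""
    if len(taxa) < 3:
        raise ValueError("need at least 3 taxa")
    node = Node(children=[Node(label=taxa[0], length=branch_length),
                          Node(label=taxa[1], length=branch_length)])
    node.length = branch_length
    depth = 2.0 * branch_length
    for i, taxon in enumerate(taxa[2:], start=1):
        node = Node(children=[node, Node(label=taxon, length=depth)])
        node.length = branch_length
        depth += branch_length
    node.length = 0.0
    return SpeciesTree(root=node, outgroup=taxa[-1])


class _GuestSimulator:
    def __init__(self, species: SpeciesTree, rates: BirthDeathRates,
                 wgd_events: Sequence[WgdEvent], rng: np.random.Generator):
        self.rng = rng
        self.rates = rates
        index = SpeciesIndex(species)
        self.root = species.root
        # resolve WGD node labels to species nodes
        by_label: dict[str, Node] = {}
        for node in self.root.postorder():
            by_label[index.label[id(node)]] = node
        self.events_by_node: dict[int, list[WgdEvent]] = {}
        for ev in wgd_events:
            if ev.node not in by_label:
                raise WgdkitError(f"unknown species-tree node {ev.node!r}")
            node = by_label[ev.node]
            self.events_by_node.setdefault(id(node), []).append(ev)
        for evs in self.events_by_node.values():
            evs.sort(key=lambda e: e.position)
        self.counters: dict[str, int] = {}

    def _leaf(self, taxon: str) -> Node:
        self.counters[taxon] = self.counters.get(taxon, 0) + 1
        return Node(label=f"{taxon}_{self.counters[taxon]}", length=0.0)

    def _join(self, a: Node | None, b: Node | None) -> Node | None:
        if a is not None and b is not None:
            return Node(length=0.0, children=[a, b])
        return a if a is not None else b

    def _at_node(self, sp: Node) -> Node | None:
        """One gene lineage sitting at species node ``sp`` (post-branch)."""
        if sp.is_leaf:
            return self._leaf(sp.label)
        left = self._enter_branch(sp.children[0])
        right = self._enter_branch(sp.children[1])
        return self._join(left, right)

    def _enter_branch(self, sp: Node) -> Node | None:
        events = self.events_by_node.get(id(sp), [])
        t = sp.length or 0.0
        return self._evolve(sp, 0.0, t, events, 0)

    def _evolve(self, sp: Node, s: float, t: float,
                events: Sequence[WgdEvent], ev_i: int) -> Node | None:
        """One lineage at offset ``s`` on the stem branch (length ``t``) of
        species node ``sp``; returns the surviving gene subtree or None."""
        birth, death = self.rates.birth, self.rates.death
        total = birth + death
        next_wgd = events[ev_i].position * t if ev_i < len(events) else math.inf
        wait = self.rng.exponential(1.0 / total) if total > 0 else math.inf
        if s + wait < min(next_wgd, t):
            if self.rng.random() < (birth / total):
                a = self._evolve(sp, s + wait, t, events, ev_i)
                b = self._evolve(sp, s + wait, t, events, ev_i)
                return self._join(a, b)
            return None  # loss
        if next_wgd <= t and next_wgd < s + wait:
            retained = self.rng.random() < events[ev_i].retention
            a = self._evolve(sp, next_wgd, t, events, ev_i + 1)
            if retained:
                b = self._evolve(sp, next_wgd, t, events, ev_i + 1)
                return self._join(a, b)
            return a
        return self._at_node(sp)

    def run(self) -> Node | None:
        self.counters = {}
        # root WGDs (the root has no stem branch) fire before the root split
        root_events = self.events_by_node.get(id(self.root), [])
        if self.root.length:
            return self._enter_branch(self.root)
        lineages = 1
        for ev in root_events:
            lineages += sum(self.rng.random() < ev.retention
                            for _ in range(lineages))
        subtrees = [self._at_node(self.root) for _ in range(lineages)]
        subtrees = [s for s in subtrees if s is not None]
        if not subtrees:
            return None
        acc = subtrees[0]
        for nxt in subtrees[1:]:
            acc = Node(length=0.0, children=[acc, nxt])
        return acc


def simulate_guest_tree(species: SpeciesTree, rates: BirthDeathRates,
                        wgd_events: Sequence[WgdEvent] = (),
                        seed: int | np.random.Generator | None = None,
                        condition: bool = True,
                        max_redraws: int = 10_000,
                        name: str = "sim") -> GeneTree | None:
    """Simulate one gene tree inside the species tree.

    With ``condition=True`` (the default) the draw is rejected and repeated
    until every taxon retains at least one gene copy, matching the family
    filter applied to observed collections; the number of rejected draws is
    recorded on the returned tree as ``n_rejected``.  With
    ``condition=False`` the raw draw is returned: taxa may be missing, a
    single-survivor family degenerates to a one-leaf tree, and full
    extinction yields ``None``.
    """
    rng = np.random.default_rng(seed)
    if not condition:
        sim = _GuestSimulator(species, rates, wgd_events, rng)
        root = sim.run()
        if root is None:
            return None
        return GeneTree(root=root, taxon_map=TaxonMap(), name=name)
    tree, attempts = _simulate_surviving(species, rates, wgd_events, rng,
                                         name=name, max_redraws=max_redraws)
    tree.n_rejected = attempts  # type: ignore[attr-defined]
    return tree


def _simulate_surviving(species: SpeciesTree, rates: BirthDeathRates,
                        wgd_events: Sequence[WgdEvent],
                        rng: np.random.Generator, name: str,
                        max_redraws: int = 10_000) -> tuple[GeneTree, int]:
    sim = _GuestSimulator(species, rates, wgd_events, rng)
    taxa = set(species.root.leaf_labels())
    tmap = TaxonMap()
    for attempt in range(max_redraws):
        root = sim.run()
        if root is None or len(root.leaves()) < 2:
            continue
        tree = GeneTree(root=root, taxon_map=tmap, name=name)
        if tree.leaf_taxa() == taxa:
            return tree, attempt
    raise WgdkitError(
        f"no surviving family in {max_redraws} draws; survival probability "
        "too low for these rates/retention")


def build_null_set(species: SpeciesTree, rates: BirthDeathRates,
                   n: int = 3000, subset: int = 1000, n_resamples: int = 100,
                   seed: int = 0) -> SimulationSet:
    """Null simulation set: ``n`` background-rate gene trees plus a plan of
    ``n_resamples`` subsets of ``subset`` trees drawn without replacement."""
    return _build_set(species, rates, (), n, subset, n_resamples, seed)


def build_positive_set(species: SpeciesTree, rates: BirthDeathRates,
                       wgd_node: str, retention: float = 0.2,
                       position: float = 0.5,
                       n: int = 3000, subset: int = 1000,
                       n_resamples: int = 100, seed: int = 0) -> SimulationSet:
    """Positive simulation set: as the null plus one WGD at ``wgd_node``."""
    event = WgdEvent(node=wgd_node, position=position, retention=retention)
    return _build_set(species, rates, (event,), n, subset, n_resamples, seed)


def _build_set(species, rates, events, n, subset, n_resamples, seed) -> SimulationSet:
    if subset > n:
        raise ValueError(f"subset ({subset}) exceeds pool size ({n})")
    rng = np.random.default_rng(seed)
    trees: list[GeneTree] = []
    rejected = 0
    for i in range(n):
        tree, attempts = _simulate_surviving(species, rates, events, rng,
                                             name=f"sim{i:05d}")
        trees.append(tree)
        rejected += attempts
    plan = [rng.choice(n, size=subset, replace=False)
            for _ in range(n_resamples)]
    return SimulationSet(trees=trees, species=species, rates=rates,
                         wgd_events=tuple(events), seed=seed,
                         resample_indices=plan, n_rejected=rejected)


# ---------------------------------------------------------------------------
# birth/death-rate estimation from gene counts


def bd_transition_probs(birth: float, death: float, t: float,
                        n_max: int) -> np.ndarray:
    """Matrix ``P[m, k] = P(N(t)=k | N(0)=m)`` for the linear birth-death
    process, ``m, k = 0..n_max`` (truncated), via the classical geometric
    form for one ancestor and convolution for several."""
    if t <= 0:
        return np.eye(n_max + 1)
    if abs(birth - death) < 1e-12:
        if birth == 0:
            return np.eye(n_max + 1)
        alpha = beta = birth * t / (1.0 + birth * t)
    else:
        g = math.exp((birth - death) * t)
        alpha = death * (g - 1.0) / (birth * g - death)
        beta = birth * alpha / death if death > 0 else \
            birth * (g - 1.0) / (birth * g - death)
    p1 = np.zeros(n_max + 1)
    p1[0] = alpha
    if beta < 1.0:
        k = np.arange(1, n_max + 1)
        p1[1:] = (1 - alpha) * (1 - beta) * beta ** (k - 1)
    probs = np.zeros((n_max + 1, n_max + 1))
    probs[0, 0] = 1.0
    probs[1] = p1
    for m in range(2, n_max + 1):
        probs[m] = np.convolve(probs[m - 1], p1)[: n_max + 1]
    return probs


def _count_patterns(counts: Sequence[Mapping[str, int]],
                    taxa: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    arr = np.array([[c.get(t, 0) for t in taxa] for c in counts], dtype=int)
    patterns, mult = np.unique(arr, axis=0, return_counts=True)
    return patterns, mult


def _loglik_counts(birth: float, death: float, species_root: Node,
                   patterns: np.ndarray, mult: np.ndarray,
                   taxa: Sequence[str], n_max: int) -> float:
    """Pruning log-likelihood of per-taxon count patterns, starting from one
    gene at the root and conditioning on >=1 surviving copy in every tip."""
    tindex = {t: i for i, t in enumerate(taxa)}
    matrices: dict[int, np.ndarray] = {}
    for node in species_root.postorder():
        if node is not species_root:
            matrices[id(node)] = bd_transition_probs(birth, death,
                                                     node.length or 0.0, n_max)

    def partials(node: Node) -> tuple[np.ndarray, np.ndarray]:
        """(L, S): L[f, n] = P(pattern below | n genes at node), and
        S[n] = P(every tip below has >=1 copy | n genes at node)."""
        if node.is_leaf:
            obs = patterns[:, tindex[node.label]]
            L = np.zeros((patterns.shape[0], n_max + 1))
            valid = obs <= n_max
            L[np.flatnonzero(valid), obs[valid]] = 1.0
            S = np.ones(n_max + 1)
            S[0] = 0.0
            return L, S
        L = np.ones((patterns.shape[0], n_max + 1))
        S = np.ones(n_max + 1)
        for child in node.children:
            cl, cs = partials(child)
            P = matrices[id(child)]
            L *= cl @ P.T
            S *= P @ cs
        return L, S

    L_root, S_root = partials(species_root)
    lik = L_root[:, 1]
    cond = S_root[1]
    if cond <= 0 or np.any(lik <= 0):
        return -np.inf
    return float((mult * (np.log(lik) - math.log(cond))).sum())


def estimate_rates(counts: Sequence[Mapping[str, int]],
                   species: SpeciesTree, constrain_equal: bool = False,
                   min_families: int = 50,
                   n_max: int | None = None) -> BirthDeathRates:
    """Maximum-likelihood birth/death rates from per-family gene counts.

    A single (birth, death) pair is shared across all branches; the
    likelihood starts from one gene at the root and is conditioned on every
    tip retaining at least one copy (matching the family filter).  Returns
    zero rates with no optimisation when every family has exactly one copy
    per taxon (no events is then the ML explanation).
    """
    if len(counts) < min_families:
        raise InsufficientDataError(
            f"{len(counts)} families (<{min_families})")
    taxa = sorted(species.root.leaf_labels())
    patterns, mult = _count_patterns(counts, taxa)
    max_count = int(patterns.max())
    if max_count <= 1 and patterns.min() == 1:
        rates = BirthDeathRates(0.0, 0.0)
        object.__setattr__(rates, "identifiable", False)  # advisory flag
        return rates
    if n_max is None:
        n_max = max(3 * max_count + 5, 12)
    total_len = sum((n.length or 0.0) for n in species.root.postorder())
    init = math.log(max(0.5 / max(total_len, 1e-9), 1e-6))

    if constrain_equal:
        def neg(params):
            r = math.exp(params[0])
            return -_loglik_counts(r, r, species.root, patterns, mult, taxa, n_max)
        res = optimize.minimize(neg, [init], method="Nelder-Mead",
                                options={"xatol": 1e-4, "fatol": 1e-6})
        r = math.exp(res.x[0])
        return BirthDeathRates(r, r)

    def neg(params):
        b, d = math.exp(params[0]), math.exp(params[1])
        return -_loglik_counts(b, d, species.root, patterns, mult, taxa, n_max)

    res = optimize.minimize(neg, [init, init], method="Nelder-Mead",
                            options={"xatol": 1e-4, "fatol": 1e-6})
    return BirthDeathRates(math.exp(res.x[0]), math.exp(res.x[1]))


def family_counts(trees: Iterable[GeneTree]) -> list[dict[str, int]]:
    """Per-family per-taxon gene copy counts from gene trees."""
    out = []
    for tree in trees:
        counts: dict[str, int] = {}
        for label in tree.root.leaf_labels():
            taxon = tree.taxon_of(label)
            counts[taxon] = counts.get(taxon, 0) + 1
        out.append(counts)
    return out


# ---------------------------------------------------------------------------
# synthetic Ks samples and hit tables


def synth_ks_sample(background_rate: float = 1.5,
                    peaks: Sequence[tuple[float, float, float]] = (),
                    n: int = 5000, ks_min: float = 0.01, ks_max: float = 2.0,
                    seed: int | np.random.Generator | None = 0,
                    species: str = "synthetic") -> AgeDistribution:
    """Synthetic age distribution: truncated-exponential background plus
    Gaussian peaks given as ``(mean, sd, weight)`` with total weight <= 1."""
    rng = np.random.default_rng(seed)
    weights = [w for _, _, w in peaks]
    if sum(weights) > 1.0 + 1e-9:
        raise ValueError("peak weights exceed 1")
    values = np.empty(0)
    if n > 0:
        comp = rng.choice(len(peaks) + 1, size=n,
                          p=[1.0 - sum(weights)] + weights)
        values = np.empty(n)
        bg = comp == 0
        # inverse-CDF truncated exponential background
        u = rng.random(int(bg.sum()))
        d = background_rate
        ea, eb = math.exp(-d * ks_min), math.exp(-d * ks_max)
        values[bg] = -np.log(ea - u * (ea - eb)) / d
        for i, (mean, sd, _) in enumerate(peaks, start=1):
            sel = comp == i
            draws = rng.normal(mean, sd, size=int(sel.sum()))
            while True:  # keep peak draws inside the window
                bad = (draws <= ks_min) | (draws > ks_max)
                if not bad.any():
                    break
                draws[bad] = rng.normal(mean, sd, size=int(bad.sum()))
            values[sel] = draws
    records = [NodeKs(family_id=f"fam{i:05d}", node_id="node1", ks=float(v))
               for i, v in enumerate(values)]
    meta = {"background_rate": background_rate, "peaks": list(peaks),
            "window": (ks_min, ks_max)}
    return AgeDistribution(species=species, records=records, metadata=meta)


def synth_hit_table(families: Sequence[Iterable[str]],
                    seed: int | np.random.Generator | None = 0) -> list[Hit]:
    """Hit table whose surviving duplicate pairs single-link back into
    exactly the requested families (each family a chain of passing hits)."""
    rng = np.random.default_rng(seed)
    hits: list[Hit] = []
    for fam in families:
        members = sorted(fam)
        for gene in members:  # self-hits, filtered downstream
            hits.append(Hit(gene, gene, 100.0, 500, 0.0, 1000.0))
        for a, b in zip(members, members[1:]):
            ident = float(rng.uniform(45.0, 95.0))
            length = int(rng.integers(310, 900))
            hits.append(Hit(a, b, round(ident, 1), length, 1e-30,
                            float(rng.uniform(200, 900))))
    return hits
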