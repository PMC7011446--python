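# Methods

This note documents the models, estimators and decision rules implemented
in `wgdkit`, the defaults and why they were chosen, what the synthetic-data
generator does and does not emulate, and the package's known limitations.

## Gene-age distributions (dup_age)

**Duplicate pairs and families.** Hits from all-vs-all similarity searches
become duplicate pairs when they show ≥40% identity over ≥300 bp
(configurable); self-hits are dropped and unordered pairs deduplicated
keeping the best identity. Families are the connected components of the
pair graph (single linkage). Thresholds that concern protein-guided frame
identification (30% over ≥150 sites for the best-hit protein pairing) are
carried as metadata only: `wgdkit` expects in-frame CDS input or
precomputed codon alignments and does not translate or frame-fix.

**Ks estimator.** Synonymous divergence is estimated by NG86 codon
counting. Per codon, the synonymous-site count is the fraction of the nine
single-nucleotide mutations that preserve the amino acid; mutations that
create a stop codon count as nonsynonymous. For codons differing at
several positions, synonymous/nonsynonymous differences are averaged over
all mutational orderings, excluding orderings that pass through a stop; a
codon pair whose orderings are all blocked, or that contains a gap,
ambiguity or stop codon, is skipped. The proportion of synonymous
differences is corrected with the one-parameter (Jukes–Cantor) distance,
`Ks = -3/4 ln(1 - 4/3 ps)`. Pairs with `ps ≥ 3/4` are reported as
*saturated* and excluded from age distributions rather than imputed; pairs
with fewer than 30 comparable codons raise an insufficient-data error.
Codon-model maximum-likelihood estimates (e.g. F3×4) differ numerically
from counting estimates; an external per-pair Ks TSV can therefore be
passed through unchanged wherever the internal estimator would be used.

**Node Ks.** Dating duplications per *node* of the family tree, rather than
per pair, avoids counting one event many times. Since no closed rule is
standard for summarising the cross-pair values at a node, the package uses
the **median** of all pairwise Ks values between the node's two child
clades (saturated pairs ignored; nodes with no unsaturated cross-pair are
skipped). The median is robust to residual saturated outliers; it always
lies within the range of the cross-pair values.

## Peak detection (wgd_detect)

**Null model.** The no-WGD expectation is constant duplication with
exponential paralog survival: a truncated exponential on the analysis
window `(0.01, ks_max]`, `ks_max ∈ {2, 5}`. The decay rate is fit by
maximum likelihood (the moment equation is solved by bracketed
root-finding; below rate 1e-6 the closed form is replaced by its uniform
limit to avoid catastrophic cancellation). At least 100 in-window values
are required.

**K-S gate.** Observed ages are compared to a simulated null sample
(default 10,000 draws, inverse-CDF, seeded) by the two-sample
Kolmogorov–Smirnov test with the asymptotic p-value. Mixture peaks are
promoted to WGD candidates only when this test rejects at α = 0.05 —
peak-shaped wiggles that a flexible mixture finds in a perfectly
null-shaped distribution are thereby discarded.

**Mixture model.** Gaussian mixtures on raw (untransformed) Ks, fit by a
hand-written EM with k-means++-style seeded restarts (default 10), K from 1
to 4 selected by BIC, tolerance 1e-6 on the log-likelihood, at most 500
iterations, a 1e-3 standard-deviation floor against singularities. The
per-iteration log-likelihood trace is stored and is non-decreasing (EM
guarantee; asserted in tests). Fitting on raw Ks matches the way mixture
overlays are usually drawn over Ks histograms; log-scale mixtures are out
of scope.

**Peak calling.** A component is a *peak* when its weight is ≥ 0.05 (to
suppress spurious micro-components) and the fitted mixture density has an
interior local maximum within one standard deviation of the component mean
— components that merely absorb the decaying background have no interior
mode of their own. The reported peak age is the median of the observations
assigned to the component by maximum posterior responsibility, with a
nonparametric bootstrap 95% CI (default 200 resamples) of that median.
Whether published "median Ks" values are component means or
responsibility medians is not standardised; the responsibility-median +
bootstrap convention is this package's documented choice. Peaks with
median Ks > 2 are never WGD candidates on their own (saturation risk) and
are flagged `needs-corroboration`.

## Ortholog divergence and placement (ortho_divergence)

Reciprocal best hits use bitscore, then percent identity, then
lexicographic subject id as the tie-break (the tie-break order is this
package's choice). The divergence summary is the mean and median Ks over
unsaturated ortholog pairs (≥20 required). Placement compares point
medians: peak median above the ortholog median ⇒ `shared`, below ⇒
`after-divergence`, within an optional `margin` (default 0) ⇒
`unresolved`; an alternative CI-overlap mode returns `unresolved` whenever
the peak's bootstrap CI contains the ortholog median. The verdict is
monotone in the ortholog median.

## MAPS (maps_core)

The species tree must be pectinate; internal nodes are numbered N1
(tip-most cherry ancestor) to Nk (root). Six to eight taxa are accepted
silently, other sizes with a warning. A gene-tree node is a duplication
under the **species-overlap** criterion (child clades share ≥1 taxon) and
maps to the species-tree MRCA of the union of child taxon sets (a terminal
branch when the union is one taxon). Species-overlap duplications are
exactly the *apparent* duplications of LCA reconciliation, which is the
independent oracle used in tests.

For node Ni with clade C and daughter lineages D1, D2, the counted
subtrees are the **maximal** gene-tree clades whose taxon set lies inside
C, touches both daughters, and contains at least `ceil(f·|C|)` distinct
taxa (default f = 0.45). A counted subtree is a shared duplication at Ni
when its root is a duplication mapped to Ni and both child clades
independently meet the same occupancy minimum. Counting only maximal
clades makes the per-node denominator well defined; a duplication nested
strictly inside a counted clade does not add a second subtree, so the
shared-duplication count can be below the raw event tally when events at
one node nest. Whether the original subtree filter demands full
topological concordance with the ladder rather than these taxon-set
conditions cannot be settled here; the taxon-set rule is this package's
operational definition. Raising f never increases either the denominator
or the numerator (monotone filtering), which is what damps the inflation
of mapped duplications towards the root in sparse gene trees.

Gene trees are assumed rooted; an unrooted tree with a designated outgroup
is rooted on the first outgroup leaf in sorted order. The family filter
keeps trees containing at least one copy of every analysis taxon.

## Simulation (simulate)

Gene families evolve inside the species tree as a linear birth–death
process: one lineage enters at the root, each lineage independently gains
(λ) or loses (μ) copies per unit branch length with exponential waiting
times, and all lineages split at every speciation. A WGD is an
instantaneous doubling of all extant lineages at a point on a branch
(default the midpoint — only the branch, not the position, is usually
known); each new copy survives the duplication instant with retention
probability r (default 0.2 in positive sets). Both the position and r are
exposed parameters because neither is identified by the downstream counts
alone. Simulated sets are conditioned on ≥1 surviving copy per taxon by
rejection (matching the family filter applied to observed data); rejection
counts are recorded so effective rates are auditable, and an unconditioned
mode exists for closed-form checks (E[copies] = e^{(λ−μ)t}).

Null sets default to 3,000 trees with 100 resamples of 1,000 drawn without
replacement; positive sets are the same with one WGD inserted. The tests
and the acceptance script run scaled-down versions of this design (600
trees, 20 resamples of 200, observed collections of 300; the desk-scale
problem sizes keep the full study design while remaining single-CPU
friendly).

**Rate estimation** is a simplified gene-count ML in the spirit of
WGDgc/Rabier et al.: a single (λ, μ) shared across branches, transition
probabilities from the classical geometric form for a linear birth–death
process (convolved for several ancestors, truncated at ~3× the largest
observed count), combined over the species tree by pruning, starting from
one gene at the root and conditioned on ≥1 copy at every tip. Optimisation
is Nelder–Mead on log rates. No rate heterogeneity across branches or
families is modelled. When every family has exactly one copy per taxon the
estimate is λ̂ = μ̂ = 0 without optimisation (no events is the ML
explanation, and the pair is not separately identifiable there). On 1,000
simulated families at λ = μ = 0.002 over a 6-taxon ladder (branch length
50) both rates are recovered to within a few percent.

**Synthetic Ks samples** are a truncated-exponential background (default
rate 1.5 per unit Ks, matching the fast decay of young paralog cohorts)
plus Gaussian peaks, drawn within the analysis window. They emulate the
shape of real age distributions but not their artefacts: no saturation
noise, no assembly-induced allelic peaks near Ks = 0, no rate variation
across genes. Passing the detection tests on these samples therefore shows
the statistical machinery is calibrated and powered under the stated
model, not that real transcriptomes are free of those artefacts.

## Episode classification and total evidence (infer, cli)

For each species-tree node, the observed (duplications, subtrees) counts
are tested one-sided ("observed greater") against each resampled null set
with Fisher's exact test; a node is a **burst** when p < α (= 0.01) in at
least 95% of resamples. Testing per resample and aggregating by a
significance fraction is this package's rule — pooling all null trees into
one table would ignore the resampling uncertainty the design creates. No
multiple-testing correction is applied across nodes (tests are reported
per node). A burst is **WGD-consistent** when, against positive sets
carrying a WGD at that node, the observed counts are *not* significantly
lower (p ≥ α) in at least half of the positive resamples; the 50%
threshold operationalises "statistically consistent with the positive
simulations". Tips and roots are tested but flagged low-confidence, since
gene-tree error inflates duplication mapping there.

The total-evidence caller requires at least two supporting lines (Ks peak,
ortholog placement `shared`, MAPS `WGD-consistent`) for a `WGD` verdict;
Ks + ortholog support with a MAPS analysis that ran and did not support
yields `significant-burst`; conflicting ortholog placements void the call.

## Numerical and interface choices

- Polytomies are resolved deterministically (children ordered by smallest
  leaf label, folded left), so duplication counts are reproducible.
- All randomness flows through numpy Generators seeded from a single seed;
  identical seeds give byte-identical output files.
- Gene ids map to taxa by prefix before a configurable delimiter
  (default `_`), or by an explicit two-column table; the MAPS-release
  reader accepts any two-column whitespace-delimited readme as that table
  (the release's exact readme format is not standardised — this is an
  assumption).
- Fisher exact tests, the K-S test and newick parsing are delegated to
  scipy/dendropy; the tests verify them against enumeration oracles where
  they are load-bearing.

## Limitations

- The Ks estimator is a counting method; systematic offsets relative to
  codon-ML values are expected at higher divergences (use the pass-through
  table for ML estimates).
- Incomplete lineage sorting, allopolyploidy and gene-tree estimation
  error are not simulated; the null model covers background birth–death
  only.
- The birth–death likelihood truncates copy numbers and shares one rate
  pair across branches.
- MAPS profiles require a pectinate species tree by design; non-ladder
  questions need a different tool.
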