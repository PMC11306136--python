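# Methods

## Seed-gene selection

Variant rows are retained when three conditions hold jointly: the trait
label equals one of the configured target traits (case-insensitive exact
match after trimming — substring matching would admit unrelated traits from
a controlled vocabulary), the consequence annotation is in the configured
set, and the association p-value is strictly below `p_max` (default
`1e-5`).  "Nonsense" is interpreted as the sequence-ontology term
`stop_gained`; `stop_lost` is excluded by default but the consequence set
is configurable.  Multi-gene mapped fields (e.g. `APOE - APOC1`) contribute
all listed genes; rows with an empty gene field are dropped with a warning
since an intergenic variant cannot anchor a network node.  Filtering is
idempotent and order-preserving.

## Interactome assembly

Each repository dialect is declared as a column map; edges are normalized
to unordered pairs, self-loops dropped, duplicates collapsed.  Confidence
filtering is strictly greater-than at the per-source thresholds (0.7 /
0.5 / 0.45).  BioGRID-style interactions carry no score and enter
unthresholded, keeping their physical/genetic type.  The expression rule
counts samples with TPM strictly above `min_tpm` (default 0) and requires
at least `ceil(min_fraction · n_samples)` of them; the ceiling is computed
with a `1e-9` guard so that an exact 80% boundary (192 of 240) is
*inclusive* rather than lost to float representation of `0.8 × 240`.
Merging unions provenance as `(source, kind, score)` tuples per pair, and
is invariant to the order of input lists.

## Mutual-information co-expression

The estimator is the plug-in MI on equal-frequency (quantile) bins with
`n_bins = floor(sqrt(n_samples))` by default (15 at n = 240) — the standard
bias/variance compromise for histogram MI.  Binning operates on ranks with
ties broken by stable original sample order, so any monotone transform of a
profile yields identical bins; a constant profile collapses to one bin with
zero entropy.  Entropies are in nats; the base only rescales MI and its
threshold jointly, so edge calls are base-invariant.  Entropy summation
runs over sorted bin counts, which makes `mi(a,b) == mi(b,a)` bitwise exact
(transposed contingency tables share the same count multiset).

The significance target `p < 1e-15` cannot be resolved by direct
permutation.  The null is built by pairing randomly chosen distinct genes
and independently permuting one profile (default `1e5` draws), then
`ln P(MI ≥ m) = a + b·m` is fitted by least squares over the top
`tail_fraction` (default 0.1) of null values and solved for the cutoff at
the target probability.  The exponential-tail form is exact when the null
survival is exponential and empirically adequate for binned-MI nulls, whose
upper tail is chi-square-like; extrapolation beyond `1/n_permutations` is
logged.  A non-negative fitted slope or a constant tail raises a
calibration error rather than producing a bogus cutoff.  Inference is
bipartite — seed × every other expressed gene — and no data-processing-
inequality pruning is applied: the only edge criterion is the calibrated
MI cutoff.  Edge scores are `1 − exp(−MI)`, a monotone map of MI into
(0, 1] comparable to the PPI confidence scales.

## Shortest-path subnetwork

For seeds S, one BFS per seed gives hop distances; an edge (u, v) lies on a
shortest s–t path iff `d(s,u) + 1 + d(v,t) = d(s,t)` in either orientation.
The union over all seed pairs is collected by this distance criterion in
O(|S|² · E) without enumerating paths, whose count can grow exponentially.
The search is unweighted by design — confidence scores never act as
weights.  Seed pairs in different components are skipped with a warning.
If the union is disconnected, the component with the most seeds is kept
(ties: larger node count, then lexicographically smallest member).  Only
edges on shortest paths are kept; induced edges between subnetwork nodes
that lie on no shortest path are excluded.

## Hubs

Degree and betweenness are computed on the extracted subnetwork, not the
parent interactome.  Betweenness uses the pair normalization
`2/((n−1)(n−2))` and is set to zero with a warning below three nodes.
"Most connected" means degree rank; betweenness is descriptive and only
breaks ties (then the gene symbol, making selection order-independent).
The hub count is `max(1, floor(fraction · n))` — floor, because the 1%
rule on a 4,383-node graph should yield 43, not the 44 of ceiling or
rounding — with a small epsilon guard against float fuzz in
`fraction · n`.

## Over-representation

Gene sets are restricted to the background universe before counting; sets
smaller than `min_set_size` (default 5) after restriction are excluded to
avoid degenerate one-gene calls.  The p-value is the upper hypergeometric
tail `P(X ≥ k)` (scipy), BH adjustment is pooled across all loaded
collections in one pass (statsmodels), and significance is `FDR < 0.05`
strictly.  The default universe is the node set of the assembled
interactome; `expressed` switches to all tissue-expressed genes.  Both
choices are defensible — enrichment against the interactome asks "is this
set over-represented among connected genes", against the expressed genome
"among tissue genes" — and reported FDRs depend on it, which is why the
universe is an explicit configuration knob.

## Synthetic fixture

The generator emulates the four real inputs at desk scale with exact
ground truth; defaults are the package's study conditions:

* **Expression** — 300 genes × 240 samples.  Module genes follow
  `x_g = loading · z_m + ε_g` on a log scale with a shared standard-normal
  latent factor per module and Gaussian noise, then exponentiation gives
  non-negative, right-skewed TPM-like values.  Default modules: two
  dependent modules of 12 genes (loading 0.95, noise SD 0.1) and one
  loading-0 module whose members are mutually independent by construction.
  10% of genes outside the modules are zeroed in >20% of samples to
  exercise the prevalence filter.
* **Catalog** — 60 rows, of which exactly `round(0.2 · 60) = 12` pass all
  three filters and map (some through multi-gene separator-delimited
  fields) to exactly the 6 seed genes; every failing row is constructed to
  fail a specific filter.  Seeds are placed round-robin across the
  dependent modules so that cross-module seed pairs have no direct
  co-expression edge and must route through the network.
* **PPI files** — uniform scores within per-source ranges straddling the
  thresholds; the BioGRID-style file is unscored with an interaction-type
  column and contains a star of physical interactions from one non-seed
  *bridge* gene to every seed.  This both guarantees that all seeds share
  one post-threshold component (so shortest paths exist) and plants a
  high-degree non-seed connector the hub stage should discover.
* **GMT** — planted sets take a configured fraction of members from the
  ordered seed neighborhood (seeds first, then bridge, then module
  partners), so a fraction of 1.0 provably covers the seeds; decoys are
  uniform draws.

All generators draw from fixed-offset substreams of one seed, and all
artifacts are byte-identical under equal seeds.

What the fixture does **not** emulate: realistic allele frequencies or LD,
GTEx covariates and batch structure, scale (hundreds of genes, not
~18,000 nodes), identifier harmonization across databases, or heavy-tailed
degree distributions of real interactomes.  Passing tests therefore
demonstrate correctness of the algorithms and conventions, not recovery of
any real-data result; headline numbers from real snapshots (subnetwork and
interactome sizes, specific enriched terms) are snapshot-dependent and out
of scope.

## Problem sizes and determinism

Default test/analysis sizes — 300 genes, 240 samples, `1e5` null
permutations, 100 decoy replicates — were chosen so a full run completes in
seconds while keeping every statistical check well-powered (e.g. the
exponential-tail fit at `1e5` draws recovers closed-form exponential
quantiles to ~1%).  Every stochastic component takes an explicit seed;
the pipeline writes byte-identical outputs across same-seed runs (the run
manifest additionally echoes the configured output directory, so manifests
from different directories differ in that field only).

## Known limitations

* The exponential tail is an extrapolation model; if the true null tail
  decays faster than exponential the cutoff is conservative, if slower it
  is liberal.  The calibration report (intercept, slope, tail fraction,
  extrapolation flag) is emitted so the fit can be audited.
* Bipartite MI inference never tests non-seed pairs, by design; the
  co-expression layer is seed-centric, not a full network reconstruction.
* The hypergeometric test treats genes as exchangeable; no correction for
  gene length, degree or expression level is applied.
* Identifier space is plain gene symbols; protein-accession mapping must
  happen upstream.
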