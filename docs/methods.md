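# Methods

## Networks

Graphs are undirected and simple. Node identity is the pair
`(node_class, identifier)` so a drug name can never collide with a gene
symbol; parallel edges collapse. Drugs with zero recorded targets are
excluded from graphs (they cannot form edges) but stay in the dataset.
Expansion admits a non-addictive drug iff it shares at least one target
with an addictive drug, and adds only its edges to addictive-drug
targets: the target side of the expanded network is identical to the
core network's. Expansion is therefore idempotent and monotone
(it never removes core nodes or edges), properties the test suite checks
directly.

Drug-centric ego networks additionally carry `drug_enzyme` and `ppi`
edge classes; a protein may appear in several roles (target, enzyme,
PPI endpoint) and is stored once.

## Topology

* **Degree**: incident edge count. In a bipartite drug–target network
  every edge touches exactly one drug, so the mean drug degree equals
  edges / drugs — a reconciliation identity the reports rely on.
* **Betweenness**: Brandes' algorithm via networkx, normalized by
  `(n−1)(n−2)/2` with `n` the *total* node count of the graph (not per
  component); pairs in different components contribute zero. Graphs with
  fewer than 3 nodes get all-zero centralities. The implementation is
  checked against an independent BFS path-counting oracle on random
  graphs up to 12 nodes.
* **Hubs and bridges**: a hub is a *drug* node with degree strictly
  greater than the cutoff (default 3); a bridge is *any* node with
  normalized betweenness strictly greater than the cutoff (default
  0.04). Both comparisons are strict. Hubs are restricted to drugs
  because the target side of an expanded network is degree-saturated by
  construction and its degrees do not follow a power law.
* **Candidate subnetwork**: retained drugs are hubs or bridges; retained
  targets are bridge targets plus targets adjacent to a retained drug
  (a convention — adjacency-only retention cannot be distinguished from
  target-hub retention using published counts alone). Isolated retained
  nodes are dropped. Candidates are ordered by degree desc, betweenness
  desc, then id, so output is fully reproducible.
* **Cutoff selection**: the defaults (3, 0.04) govern all analyses. An
  advisory `suggest_cutoff` fits a two-segment piecewise line to the
  log–log survival curve and returns the value at the least-squares
  breakpoint; it is exposed for exploration, never used implicitly.
* **Power-law diagnostic**: least-squares fit of log10(count) against
  log10(k) over observed degrees k ≥ 1; requires at least 3 distinct
  degrees. Reported as (slope, Pearson r); a heavy-tailed degree
  distribution shows slope < 0 with |r| ≥ 0.8.

## Statistics

* **Fisher's exact test**: scipy, with conventions pinned here. The
  two-sided p sums hypergeometric point probabilities not exceeding that
  of the observed table (the point-probability rule used by R and
  scipy). Tables with an empty margin return p = 1 (logged). The
  two-sided convention is verified against an exact rational-arithmetic
  enumeration oracle on random tables with N ≤ 60.

  On the reference nervous-system comparison (32/38 vs 203/407 drugs in
  ATC class N), the one-sided upper-tail p is 2.56 × 10⁻⁵ and the
  two-sided point-probability p is 3.16 × 10⁻⁵. Published accounts of
  this comparison quote both a one-sided-looking and a two-sided-looking
  value; our enumeration shows the one-sided value is exact at printed
  precision while the second printed value (3.0 × 10⁻⁵) is consistent
  with the two-sided test only up to loose rounding. The ATC screen
  defaults to two-sided (either direction of imbalance is interesting);
  the literature screen uses the upper tail, since only
  over-representation of drug–keyword co-occurrence is evidence of an
  addiction link.
* **Hypergeometric tail**: `P(X ≥ k)` via scipy's log-space survival
  function; stable at corpus-scale populations (~2 × 10⁷).
* **Multiple testing**: Benjamini–Hochberg step-up for enrichment
  (family = all sets tested), Bonferroni `min(1, m·p)` for the
  literature screen (family = rows actually tested, i.e. the candidate
  drugs, not the whole drug universe). Both adjustments are
  order-equivariant; rows violating count invariants are rejected with a
  logged report and do not enlarge the family.
* **Enrichment filters**: adjusted p < 0.01 AND overlap ≥ 5 genes. The
  default universe is every gene appearing in the gene-set collection;
  callers can override it. Because the universe choice used by online
  enrichment services is generally unstated, absolute enrichment
  p-values from such services are not comparison targets.

## Synthetic data

The generator produces data with the *statistical shape* the pipeline
assumes; it makes no attempt at realistic chemistry or text.

* **Drug degrees**: discrete truncated power law on {1..20},
  P(k) ∝ k^(−γ), γ = 2.2 by default, with an independent zero-target
  coin at p = 3/44 for addictive drugs (three of the 44 reference drugs
  have no target; the degree range 1–20 matches the reference data).
* **Category structure**: 44 addictive drugs split across six action
  categories with the reference sizes (12, 2, 1, 10, 6, 13); the 91
  addictive targets are partitioned into per-category blocks and each
  drug draws each target from its own block with probability 0.8
  (`category_cohesion`), else uniformly — so category clustering is
  recoverable but not trivial.
* **Pool drugs**: 1500 drugs drawing targets uniformly from the
  addictive universe plus a private gene pool twice its size; this
  yields both drugs that qualify for expansion and drugs that do not,
  roughly in the proportion seen in real drug–target data.
* **ATC letters**: ~90% of addictive drugs are coded, 85% of those in
  class N; pool drugs are 70% coded, 50% in class N — mirroring the
  strong nervous-system skew of addictive pharmacology.
* **Literature counts**: per-drug abstract counts are lognormal (median
  500); the keyword margin is fixed at 200 000 of a 21 508 439-abstract
  corpus. Null joint counts are hypergeometric given the margins, so
  the Fisher screen is *exactly* calibrated under the null. Planted
  drugs draw their joint count Poisson around `ratio × expected`
  (default ratio 10), clipped to the margins; ratio 1 reduces to the
  null rate.
* **Gene sets**: 50 sets over a 2000-gene universe containing the
  targets; null sets are uniform draws of size 10–100, planted sets
  (default 3) have 20 members of which 12 are target genes.
* **Randomness**: the three generators draw from independent streams
  derived from `(seed, stream-id)` seed sequences, so each can be called
  alone and still reproduce.

What passing tests on synthetic data do **not** show: real drug–target
annotations are biased and incomplete, real literature counts are not
independent across drugs (reviews, synonymy, negation), and real
pathway databases overlap heavily. Calibration and sensitivity results
here certify the *statistical machinery*, not performance on any real
database.

## Problem sizes

Default analyses run on 44 + 1500 drugs, 91 + 182 genes, 50 gene sets
and 94-drug literature tables; calibration suites use 1000 null
replicates (family-wise error) and 100 replicates (sensitivity), which
keep the full test suite under half a minute while leaving binomial
error on estimated rates at a few tenths of a percent.

## Known limitations

* The fixture of reference drugs records target *counts*, not target
  identities, so the real addictive network cannot be rebuilt from the
  package alone; published node/edge totals are verified as accounting
  identities instead.
* Internal tallies of the reference table disagree slightly between its
  per-record rows and derived summaries (e.g. the number of
  illicit-group drugs); the per-record table is treated as
  authoritative.
* The literature screen consumes a single union keyword count per drug;
  per-keyword breakdowns and negation handling are out of scope.
* Ego-network protein interactions are consumed as an input edge list;
  no interaction database retrieval is performed.
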