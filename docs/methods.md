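# Methods

## Model

For a GO term pair (GO₁, GO₂) the package models the number X of pool
members associated with both terms as hypergeometric: drawing the n members
associated with GO₂ from a pool of N of which K are associated with GO₁,

P(X ≤ k₀) = Σ_{k=0..k₀} C(K,k)·C(N−K, n−k) / C(N,n),

with the special case P(X=0) = C(N−K,n)/C(N,n). The *low* tail is reported:
a small value means the observed co-occurrence k₀ is depleted relative to
independence, i.e. the terms are functionally dissimilar in that species.
Classification uses a strict inequality — p_low < threshold (default 0.05)
→ `Dissimilar`, ties and everything above → `NotDissimilar` — and `NA` is
returned when a statistic cannot be computed at all (term unknown or
obsolete, term annotating no protein of the species, or an empty pool).
The statistic is symmetric in the two terms; internally the (K, n) arguments
are passed to the CDF in canonical order so the symmetry is exact even at
floating-point level.

### Pools, counting, and the direct/inherited distinction

Co-occurrence is only observable on entities that carry at least two
annotations, so the pool N deliberately excludes everything else:

- **AP mode** — proteins with ≥ 2 distinct **direct** annotations in the
  namespace under study; for a cross-ontology pair, proteins with ≥ 1 direct
  annotation in each of the two namespaces. Direct means an explicit row of
  the annotation file; inherited (propagated) terms never confer
  eligibility.
- **IP mode** — network edges whose endpoints **both** satisfy the same
  rule. The one-endpoint reading is implementable
  (`ip_both_endpoints_eligible=False`) but both-endpoints is the default:
  the eligibility requirement distributes most naturally over the two
  interacting proteins.

K, n and k are then counted over **propagated** annotations restricted to
the pool (direct ∪ every ancestor over `is_a` and `part_of`, the GO
Consortium's standard propagation set; `regulates`-family edges are
excluded and the relation set is configurable). Restricting to the pool
keeps K, n ≤ N, which the hypergeometric model requires. In IP mode an edge
counts in k when one endpoint carries GO₁ and an endpoint — possibly the
same one — carries GO₂; requiring the two terms on *distinct* endpoints is
available as `ip_distinct_endpoints=True`.

`part_of` edges that cross namespaces do not propagate annotations across
namespaces; cross-ontology relationships are expressed through the
cross-ontology pools instead, which keeps "one direct annotation in each
ontology" well defined. Obsolete terms are parsed and retained (so lookups
can distinguish obsolete from unknown) but excluded from propagation and
pools; querying one yields NA.

### Companion statistics

Jaccard (k/(K+n−k)) and Cohen's kappa are computed from the same pooled
2×2 membership table as the test — both = k, only-GO₁ = K−k, only-GO₂ =
n−k, neither = N−K−n+k — so every reported number refers to one universe.
Kappa is absent when chance agreement is exactly 1.

### Power

The observed counts define a two-binomial design: group sizes K and N−K
with alternative proportions p₁ = k/K and p₂ = (n−k)/(N−K). Each of
`n_sims` simulations (default 1000, binomial SE ≤ 0.0158) draws the two
counts, forms the 2×2 table and applies Fisher's exact test at level α;
power is the rejection fraction. The default is the **two-sided** test
(matching the R routine this mechanism mirrors, whose simulated test is the
two-sided `fisher.test`); one-sided alternatives are available, with
`less` corresponding to the depletion direction a dissimilar pair shows.
Two-sided p-values sum all table probabilities not exceeding the observed
one, with a 1e−7 relative tolerance guarding ties against rounding; the
implementation was checked against `scipy.stats.fisher_exact` on random
tables. The seed is an explicit argument everywhere — no hidden global
randomness — and identical seeds reproduce estimates bit-for-bit. A
degenerate design (p₁ = p₂ ∈ {0, 1}) reports its rejection fraction with a
`degenerate` flag.

Note that the exact test is conservative on small groups: its true size can
sit well below α, so "size ≈ level" statements are only meaningful for
large, balanced designs (the test suite uses K = N−K = 1000 at p = 0.5).

## Input policies

- **GAF 2.x** — all evidence codes retained (electronic annotations
  included); `NOT`-qualified rows dropped (they assert absence of function
  and would corrupt co-occurrence); duplicate (protein, term) pairs
  collapsed to the first row; isoform suffixes (`-1`, `-2`) folded into the
  parent accession; rows of other taxa skipped; malformed rows skipped with
  a logged count; zero usable rows for the configured taxon is a hard error
  (it almost always means the file and the configuration disagree about the
  species).
- **PSI-MITAB 2.5+** — interactors resolved through `uniprotkb:` cross
  references (records without one are dropped and counted); detection
  methods filtered against a whitelist of binary-capable methods
  (two-hybrid family, protein complementation family) — co-complex and
  affinity-purification methods are excluded because they do not establish
  direct binary contact. The whitelist is configurable, as is an optional
  interaction-type filter (direct/physical, off by default because older
  MITAB files type interactions unreliably). Self-interactions are
  discarded.
- **Redundancy mapping** — a two-column secondary→canonical TSV; edges are
  rewritten through it, the canonical protein inheriting the secondary
  one's interactions; rewrite-induced self-loops are dropped. A chained or
  cyclic mapping is a hard error. Producing this table (e.g. by ≥ 95%
  sequence-identity clustering) is outside the package's scope.

## The store

`build()` runs parse → propagate → filter → merge and persists a
deterministic TSV bundle (terms, ontology edges, direct annotations,
network edges; all sorted) plus `meta.json` with input digests, pool counts
and the full configuration snapshot; rebuilding from identical inputs
yields byte-identical tables (the timestamp lives only in `meta.json`).
Pair statistics are computed lazily at query time; the quadratic all-pairs
table is opt-in (`--all-pairs`) because real proteomes make it infeasible.
`summarize()` reports Dissimilar/NotDissimilar/NA fractions over a stated
universe: all unordered pairs of distinct non-obsolete terms that annotate
at least one protein, same- and cross-namespace; the two headline fractions
need not sum to one because NA pairs count only in the denominator.

## The fixture generator

`fixtures.generate(seed, out_dir)` emits a miniature species — by default
30 terms in three namespaces (with multi-parent nodes and a `part_of`
edge per namespace), 120 proteins and 300 interactions — chosen large
enough that planted signals are unambiguous at threshold 0.05 yet small
enough for exhaustive brute-force oracles. Structure planted:

- a **dissimilar** BP pair annotating two disjoint ~25-protein groups that
  share no interaction edges (AP: K = n = 25, k = 0 in a pool of ~115,
  ~5.4 expected; IP: k = 0 with ~17 expected);
- a **similar** BP pair co-annotating one group with lift ≥ 3× expectation;
- a module-structured network (dense within groups, bridges only to the
  unstructured remainder);
- a handful of proteins with a single direct BP term (outside the BP pool),
  one ontology term that annotates nothing (exercising NA), and one
  obsolete term;
- deliberate noise rows exercising every filter: NOT qualifiers, duplicate
  and isoform rows, off-taxon rows, an alt_id annotation, self-interactions,
  reversed duplicates from a second source database, non-whitelisted
  detection methods, records without UniProt cross-references, and
  secondary accessions resolved through the mapping file.

The accompanying ledger (JSON) records the ground truth — direct sets,
final edge list, pool sizes, planted counts — and is the oracle the test
suite compares pipeline output against. What the fixture does **not**
emulate: realistic annotation-depth or degree distributions, evidence-code
biases, and proteome-scale pool sizes; passing tests demonstrate
correctness of counting, filtering and classification mechanics, not the
numeric values any real species would produce.

## Numerical and design notes

- Hypergeometric tails come from `scipy.stats.hypergeom`; agreement with
  exact integer enumeration is asserted for every valid (N, K, n, k) with
  N ≤ 30 at 1e−12, and pmf normalisation at 1e−9.
- Querying a term together with its own ancestor is allowed and trivially
  yields k = n (every descendant-annotated protein inherits the ancestor).
- Querying a term against itself is rejected as a value error; a
  syntactically invalid GO id yields a per-row `Error` marker rather than a
  crash, keeping batch queries robust.
- Query result rows attach the power estimate only when a power seed is
  supplied; each row derives a sub-seed from the row index so results do
  not depend on how queries are batched.

## Known limitations

- The metrics inherit annotation bias: sparsely annotated species produce
  wide, noisy pools and many NA pairs.
- The IP pool treats every edge as one exchangeable trial; hubs violate
  exchangeability and can inflate K and n for broadly distributed terms.
- The detection-method whitelist is a flat MI-identifier set, not an
  ontology-aware closure over the PSI-MI hierarchy; callers wanting exact
  descendant closure should supply their own set.
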