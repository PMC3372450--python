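# Methods

## The model

A drug-target interactome is an undirected multigraph over two disjoint
identifier namespaces — drugs (knowledge-base ids, e.g. `DB00001`) and
genes/proteins (upper-case gene symbols) — with four edge relations:

* **DDI**: the candidate drug and a drug documented to interact adversely
  with it;
* **DT**: the candidate and a primary target, originally a UniProtKB
  accession, expressed as a gene symbol through the two-step map
  AC → Entrez Gene ID → symbol;
* **DG**: the candidate and a gene carrying pharmacokinetic (PK) or
  pharmacodynamic (PD) evidence in a pharmacogenomic source;
* **PPI**: an experimentally supported human protein-protein interaction
  with at least one endpoint among the candidate's targets or associated
  genes (first-neighbor recruitment of potential off-targets).

A node pair may carry several relations (a gene linked by both DT and DG
contributes two edges), but at most one edge per (pair, relation). Node
roles are single-valued; a gene that is both target and associated gene
gets the dedicated role `target_and_gene`, which outranks either single
role. DDI partners without a full drug record are kept as stub nodes
(edge conservation over strict referential integrity) and flagged.
An identifier appearing in both namespaces is a hard error, not a silent
coexistence.

## Ingestion and filtering

Every parser counts what it excludes; nothing is dropped silently.

* **Drug XML** (documented dialect): unknown elements are skipped with a
  log entry; duplicate ids, unknown status-group tokens and self-DDIs are
  validation errors. Status groups come from the five-token vocabulary
  {approved, experimental, nutraceutical, illicit, withdrawn},
  case-normalised.
* **PSI-MI TAB 2.5**: rows shorter than 15 columns are skipped into a
  row-level error report. The filter then excludes, in order and with
  per-reason counts: non-human taxa (default 9606 for both partners),
  non-experimental detection methods, interactors that fail either step of
  the identifier map, and self-interactions; surviving unordered
  duplicates collapse into one canonical edge (`symbol_a < symbol_b`) with
  the union of source databases. The accounting identity
  `raw rows = edges + Σ per-reason exclusions + collapsed duplicates`
  is asserted in tests. Because interaction sources rarely agree on which
  PSI-MI method terms count as "experimental", the vocabulary is
  configurable: by default anything passes except a deny-list of
  predicted/in-silico MI identifiers (MI:0063, MI:0064, MI:0085, MI:0362,
  MI:0363) and keywords ("predict", "in silico", "interolog",
  "inference"); an explicit allow-list can replace this.
* **Associations TSV**: evidence strings split on `/` into the {PK, PD}
  subset; rows with unknown tokens are rejected into a report. Gene
  symbols are upper-cased everywhere on ingest.
* **Identifier map**: a partial function by design; unmapped accessions
  are excluded from networks but always reported with their ids — silent
  identifier loss is the main integration bug class this package guards
  against.

Cross-source drug linking runs in two stages: explicit external-link
foreign ids first (conflicts are errors), then normalised-name equality
over names and synonyms for the remainder. The normaliser lower-cases,
collapses whitespace and strips one trailing salt/ester token from a
configurable list — a deterministic, testable substitute for
dictionary-based generic-name resolution, sufficient for name
reconciliation between sources. Names matching several drugs are reported
as ambiguous and never linked; stage-1 links are never overwritten.

## Network analysis

* **Degree** counts every incident edge regardless of relation; the
  handshake identity Σ deg = 2·|E| is asserted on every fixture.
* **Hubs**: visual "plateau" reading of a degree distribution is not an
  algorithm, so the default rule is deterministic: the threshold is the
  smallest degree `d` with at most `fraction · n` nodes (default 5%) at or
  above it, and every node at or above the threshold is a hub — ties
  included, so the hub set may exceed the fraction. If the rule leaves the
  set empty (all degrees equal), the maximum-degree nodes are the hubs.
  A mean + 2·SD rule is available for comparison.
* **Simplification** removes all drug nodes except the candidates, then —
  in a single pass, with degrees measured once on the drug-free graph —
  removes non-candidate nodes with at most one link. The single pass is
  the default because the reduction is described as one removal action;
  `iterate=True` repeats to a fixpoint and `drug_removal_first=False`
  flips the step order, since the original order is ambiguous.
  Candidates are never removed.
* **Modules**: connected components by default; greedy modularity
  communities optionally (clique percolation is deliberately out of
  scope — module structure is used descriptively, and both replacements
  are standard and dependency-light). Labels are assigned by each
  module's smallest node id, so they are deterministic.

## ATC classification and enrichment

ATC codes follow the positional grammar letter / 2 digits / letter /
letter / 2 digits (depths 1, 3, 4, 5, 7 characters); the first letter must
be one of the 14 WHO anatomical main groups. Grouping at level *L* counts
a multi-coded drug once per distinct level-*L* prefix; fractions are
reported over classified drugs (≥ 1 code), so with multi-coding they may
sum above 1 — documented rather than hidden.

Enrichment is over-representation only (upper tail): depletion is out of
scope. The background universe defaults to the union of all collection
members and can be overridden with an explicit gene list; the choice is
echoed in every report because the adjusted p-values depend on it. Genes
outside the background are dropped from the query and the sets before
counting. Sets with zero overlap are excluded from the Benjamini–Hochberg
adjustment by default — they cannot be significant and only inflate the
number of tests `m` — with a flag to include them. BH is the step-up
procedure `adj_(i) = min_{j≥i} p_(j)·m/j`, capped at 1, stable under ties,
implemented directly and cross-checked in tests against both a
definitional oracle and statsmodels.

## Synthetic data generator

The generator emulates the six inputs with a single seeded RNG and writes
a manifest of every expected downstream count, computed by independent
construction-time bookkeeping (naive scans, not the package's own code
paths). The default profile mirrors a well-characterised single-drug
interactome: 60 drugs, one candidate with 54 adverse-interaction partners,
26 targets and 51 associated genes (16 overlapping), a 300-protein /
800-edge PPI graph with a designated strictly-maximal hub (30% of edges
biased to it), and planted filter fodder — 20 self-interactions, 30
non-human rows, 25 predicted-only rows, 10 duplicate pairs, 10 rows with
unmappable accessions, 5% identifier-map holes, 5 invalid association
rows, 10 explicit + 5 name-based + 2 ambiguous drug links, and one
dangling DDI partner. The interacting drugs carry a nervous-system-heavy
ATC composition (41 of 54 in `N`, 6 in `J`; level 3: N05B 11, N05C 9,
N03A 7, N06A 5, N05A 4, N02A 3, N06B 1, N07X 1, J01A 4, J01C 2, A02B 3,
C07A 2, R06A 2), typical of an antipsychotic's adverse-interaction
profile. Ten 40-gene sets are written, one of which overlaps 20 of the
candidate's network genes so enrichment has a recoverable planted signal.

What the generator does **not** emulate: real drug nomenclature and
chemistry, scale-free PPI topology beyond the single hub bias,
literature-grade evidence annotations, or the size of production
knowledge bases (thousands of drugs, tens of thousands of interactions).
Passing tests therefore demonstrate the correctness of the integration,
filtering, network and statistical machinery under realistic *shape*, not
the scientific content of any real source snapshot; counts tied to
specific database releases are inherently version-dependent and are not
reproduction targets.

## Numerical and design choices

* Hypergeometric tails come from `scipy.stats.hypergeom.sf(k-1, N, K, n)`,
  clipped to [0, 1]; the test suite checks them against exact integer
  enumeration over every (N ≤ 60, K, n, k) to 1e-12.
* All tie-breaks are lexicographic (node ids, set names); sorting is
  stable; all file output uses UTF-8, `\n`, and sorted JSON keys, making
  end-to-end runs byte-reproducible for a fixed seed.
* Degenerate inputs: empty seed sets, empty networks, queries disjoint
  from the background, and modules without gene nodes all return empty
  results with warnings rather than errors; empty queries, unknown drug
  ids, vocabulary violations and namespace clashes are errors.
* SIF export writes one line per edge (isolated nodes are not
  representable), so line count equals edge count; GraphML is the
  lossless round-trip format (roles, relations, provenance); the TSV
  edge list carries edges and relations only.
* Test and acceptance problem sizes (the 60-drug / 300-protein default
  profile, 100 random builder instances up to 1000 edges, 500 BH vectors,
  a 1000-gene enrichment simulation with 200 null replicates) were chosen
  as the smallest scales at which every planted structure is
  distinguishable from noise; the full suite runs in a few seconds.

## Known limitations

* The name normaliser handles case, whitespace and one trailing salt
  token; it is not a medication-extraction system and will not reconcile
  brand names or misspellings.
* DDI edges are undirected and carry only description text; severity and
  direction are not modelled.
* Enrichment supports one collection and BH only; GO-style ontology
  structure and other multiple-testing methods are out of scope.
* The hub rule is a ranking convention, not an estimate of a power-law
  regime; no degree-exponent fitting is attempted.
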