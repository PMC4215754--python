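# Methods

## The pathway model

A KGML document is held as a `Pathway`: metadata (`name`, `org`,
`number`, `title`), an insertion-ordered mapping of `PathwayEntry`
objects keyed by entry id, and an ordered list of `PathwayRelation`
objects.  Invariants enforced at validation: entry ids unique; every
relation endpoint and every group component resolves to an entry; group
entries carry at least two components and non-group entries none;
graphics boxes have positive size.  Graphics coordinates follow the
KGML convention — integer box centers, top-left origin, y growing
downward.

Parsing targets the KGML 0.7.x element set.  Unknown attributes at any
level are preserved in opaque `extra` mappings and re-emitted on write,
which gives forward compatibility and carries this package's own
modification-tracking attributes (`added_by`, `reversed`,
`former_group`) through save/load cycles.  Exact duplicate relations —
observed in real KGML — are collapsed to one occurrence with a logged
warning rather than treated as errors.  `<reaction>` elements describe
compound chemistry in metabolic maps and are outside the
protein-interaction scope: they are skipped with a warning, so metabolic
maps still parse to their protein-relation subgraph.  Encoding is fixed
to UTF-8 both ways.  The writer emits attributes in a fixed order
(extras sorted by key), so two writes of the same pathway are
byte-identical; `parse_kgml(write_kgml(p)) == p` is a structural
identity tested across 100 generated pathways.

Only single-organism pathways are modelled; multi-organism and
ko-reference maps are untargeted.  One consequence of enforcing the
group-arity invariant strictly: a (rare, arguably malformed) real-world
group with a single component is rejected at validation rather than
silently passed through.

## Corrections

The three inconsistency classes each get a *detector* (pure,
exhaustive) and an *applier* that accepts only detector-flagged
candidates — the programmatic form of a semi-automatic review.
`correct_all(p, mode="report-only")` returns all candidates without
touching the pathway; `mode="auto"` applies everything in a fixed order:
PCP edges, then binding reversal, then group dissolution.  The order is
fixed so reports are reproducible, and group expansion runs last so the
first two operate on the authored topology.  Ties everywhere break by
ascending entry id.  Appliers never mutate their input.

**PCP.**  The detector enumerates every triple `(A, c, B)` with `A→c`
and `c→B` relations, `c` compound-type, `A ≠ B` gene-type — equivalent
to brute-force enumeration of length-2 paths through compounds, which is
exactly how the tests check it.  When a compound has several upstream
and downstream proteins, *all* pairs get a direct edge: this preserves
every signal path, at the cost of possibly over-connecting hubs.  The
new edge is `PPrel` with a `compound` subtype valued with the compound's
entry id plus the upstream relation's other subtypes; the original
protein-compound edges and the compound entry are kept, because the
correction is an overlay on the intact map, not a rewrite.  Existence of
the direct edge makes re-application a no-op.

**Binding direction.**  Which binding edges are "reversed" is
under-determined by the file format; this package pins a *dead-end
heuristic*: a `PPrel` binding/association edge is suspect when its
source has no other incoming relation while its target has another
outgoing one — i.e. the edge points from a source-less terminal into the
cascade.  The predicate is deliberately a single isolated function so an
alternative criterion (e.g. one using arrowhead glyph information, which
KGML does not expose) can replace it without touching the applier.
Reversed edges are stamped (`reversed="true"`) and stamped edges are
never re-flagged; likewise machine-added edges (`added_by=...`) are
excluded from detection.  Together these make `correct_all` idempotent,
which is a tested invariant.

**Groups.**  A group with components `e₁..e_k` and `m` incident
relations dissolves into `k(k−1)/2` pairwise binding/association edges
(the complex's internal cohesion) plus, for each incident relation, `k`
rewired copies targeting each component (inheriting type and subtypes);
the container is removed and components are annotated with
`former_group` so provenance survives tuning and export.  Relation
count therefore changes by exactly `k(k−1)/2 + mk − m`; collisions with
pre-existing relations are collapsed and logged as
`duplicate_relation_collapsed`.  Nested groups dissolve innermost-first,
with a dissolved inner group replaced by its components in any
container still listing it; cyclic nesting is a validation error.

Every mutation emits exactly one record; logs are one line per record —
ISO timestamp, kind, tab-separated `key=value` fields.

## Tuning

**Tissue-specific tuning.**  The survival rule is `expression ≥
threshold` (strictly-below values are pruned).  Thresholds are either
absolute or a percentile resolved by the **nearest-rank** definition —
the value at 1-based rank `ceil(p/100 · n)` of the sorted sample —
chosen over interpolating definitions because it is deterministic,
returns an observed value, and has no ambiguity at small n.  The
percentile's value set defaults to the chosen tissue's column
(`per_tissue`); computing it over the whole table (`whole_table`) is
equally defensible for cross-tissue comparability, so both are
implemented behind `TuningConfig.percentile_scope` with `per_tissue` the
default.  Genes absent from the expression table are treated as below
threshold, with a per-gene warning: absence of evidence must not
silently count as expression.  A `keep_missing` flag overrides this for
sparse tables.  An entry survives iff at least one member gene does;
non-gene entries always survive; a group entry whose components drop
below two is removed.  The input is cloned and output ids are freshly
assigned (1..n), with relation endpoints, group components and
compound-subtype id references remapped consistently.

**PPI drill-down.**  Gene entries expand to one node per member gene;
for a parent relation between gene entries, a member pair survives iff
the scored-interaction table holds a record for the unordered pair with
score ≥ the threshold and at least one accepted evidence source.  PPI
evidence is undirected, so the surviving edge inherits its *direction*
from the pathway and only its *existence* from the interaction record.
Relations touching non-gene entries (compounds, maps) fan out to all
members unfiltered, since physical-interaction evidence is undefined
there.  Nodes for the same gene arising from duplicated entries merge
into one (union of incident edges; graphics from the lowest original
entry id, a deterministic, order-independent choice), and gene nodes
with no remaining edge are removed.  Paralogs *within* one entry are
never connected to each other: members of a paralog box are
alternatives, not interactors, so intra-entry pairs are not edge
candidates.  Scores are kept in [0, 1]; a table whose maximum exceeds 1
is assumed to use the 0–1000 integer convention and rescaled by 1/1000
with a logged notice.

`tune_full` is tissue tuning followed by drill-down with concatenated
reports; a silent gene is thus excluded even when PPI-supported.
Tested invariants: tuned gene sets are subsets of the input's and nest
monotonically under threshold sweeps; enlarging the source set never
shrinks the edge set; every drill-down gene edge is witnessed by a
parent relation and a qualifying interaction record; inputs are never
mutated.

## Synthetic fixtures

The generators exist to give every detector and tuner a planted ground
truth; they emulate the *structure* of real inputs, not their
statistics.

`make_synthetic_pathway` builds, from one seeded `random.Random`
stream: core gene entries (default 30, 1–3 genes each, ids `hsa:1001`
up); compound entries; background `PPrel` relations (default 40) with
non-binding subtypes only; then the plants — PCP chains (one dedicated
compound each, exactly one edge in and out, so detection is
unambiguous), mis-directed binding edges (a fresh source-less terminal
pointing at a node with background out-edges, satisfying the dead-end
heuristic by construction), groups with fresh components and 1–2
incident edges, and duplicated entries (same gene list at a shifted map
position, wired to one neighbor).  Plants are disjoint: no relation
participates in two inconsistencies, so counts are exact.  The default
plant counts (3 PCP, 7 reversed bindings, 2 groups) mirror the shape of
a realistic signaling map's inconsistency load.  Infeasible recipes
(more PCP motifs than compounds, reversed bindings with no cascade, ...)
raise with the offending count named.

`make_expression_table` plants per-tissue silent sets
(`round(fraction · n)` genes, default fraction ≈ 0.1): silent values lie
strictly below, expressed values at or above, the column's 25th
nearest-rank percentile, with enough expressed values pinned at the
floor that the percentile lands exactly on it — so the standard
25-percentile threshold separates the classes with no edge cases.  This
clean separation is impossible once the silent count reaches the
percentile rank (the rank-th value would itself be silent); such
fractions are rejected rather than generating ambiguous truth.  A
`forced_silent` hook plants scenario genes (e.g. a hub silent in exactly
one tissue) while guaranteeing their expression elsewhere.

`make_ppi_table` samples a fraction of all gene pairs, assigns each a
score from a small set of tiers and a non-empty random source subset,
and records the planted score per pair — so the supported edge set at
any threshold is known exactly.

What passing these tests does *not* show: robustness to the full
heterogeneity of real KGML (vendor quirks beyond duplicated relations
and unknown attributes), to noisy near-threshold expression values, or
to the biological plausibility of any particular pruning — the fixtures
validate graph logic, not biology.

## Numerical and interface choices

* Percentiles: nearest-rank, no interpolation; empty value sets are
  errors, percentile 0 the minimum and 100 the maximum.
* Survival comparisons use `>=` against the threshold on both the
  expression and the PPI side.
* Entry `name` attributes are space-separated KEGG id lists, split on
  parse and re-joined with single spaces on write.
* Relation identity for duplicate collapsing is
  `(entry1, entry2, type, sorted subtypes)`.
* CLI exit codes: 0 success, 1 input/validation error, 2 transport
  failure, 3 pathway not found.  Option precedence: flag > flat-YAML
  config file > default.
* Problem sizes in the test and acceptance runs — pathways of roughly
  10–60 entries, 100 round-trip seeds, 20-seed scenario and
  monotonicity sweeps with 5 threshold values — are chosen as the
  smallest sizes at which every planted mechanism (fan-outs, merges,
  nested subsets) actually exercises multiple instances per run.

## Known limitations

* The binding-direction heuristic is a topological proxy; without
  arrowhead information some genuinely reversed edges (both endpoints
  well-connected) are invisible to it, and the package makes no claim of
  completeness there — hence the report-only mode and the swappable
  predicate.
* Metabolic `<reaction>` semantics are not modelled at all.
* The REST fetch does no caching or rate limiting; it is meant for
  retrieving individual pathways interactively, consistent with KEGG's
  academic-use terms.
* Strict group-arity validation rejects single-component groups (see
  above).
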