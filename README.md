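# keggtuner

Parse, correct, and context-tune KEGG KGML pathway maps.

KEGG pathway maps are distributed as KGML — XML documents whose
`<entry>` elements are nodes (paralogous-gene groups, compounds, linked
maps, protein complexes) and whose `<relation>` elements are edges
refined by `<subtype>` labels (activation, inhibition,
binding/association, ...).  The maps are drawn for human readers, which
leaves three systematic obstacles for automated network analysis:

1. **Protein-compound-protein (PCP) chains.**  A protein interaction
   mediated by a small compound appears only as protein → compound →
   protein; the direct protein-protein edge is missing.
2. **Mis-directed binding edges.**  Some binding/association relations
   point against the signal flow, from a source-less terminal node into
   the cascade.
3. **Group nodes and abstraction.**  Complexes are containers without
   pairwise edges; every entry bundles paralogs as if all were present;
   every gene is assumed expressed in every tissue.

`keggtuner` is a library (plus a thin CLI) for working through those
obstacles:

* **kgml** — dataclass pathway model, validating parser, deterministic
  KGML writer, single-pathway REST fetch (academic use), SIF edge-list
  export.  `parse_kgml(write_kgml(p)) == p` holds structurally.
* **corrections** — exhaustive detectors plus appliers for the three
  inconsistency classes, chained by `correct_all`.  For each PCP triple
  `(A, c, B)` a `PPrel` edge `A → B` is added carrying a `compound`
  subtype valued with `c`'s entry id (originals retained).  A binding
  edge `u → v` is flagged as reversed when `u` has no other incoming and
  `v` has another outgoing relation.  A group with components
  `e₁..e_k` and `m` incident relations dissolves into `k(k−1)/2`
  pairwise binding edges plus `m·k` rewired edges, changing the relation
  count by exactly `k(k−1)/2 + mk − m`.  Every mutation emits one log
  record; the pass is idempotent and supports a report-only mode.
* **tuning** — tissue-specific pruning (a gene survives iff its
  expression in the chosen tissue is ≥ a threshold, typically the 25th
  nearest-rank percentile; an entry survives iff a member gene does) and
  PPI drill-down (entries expand to single-gene nodes; a gene-gene edge
  survives iff a scored physical-interaction record ≥ the confidence
  threshold, e.g. 0.8, from chosen evidence sources supports the pair;
  duplicates merge, isolated nodes go).
* **fixtures** — deterministic generators for synthetic pathways,
  expression tables and scored PPI tables with *planted, counted* motifs,
  so every operation has a ground-truth oracle without any download.

## Worked example

```python
from keggtuner import FixtureSpec, correct_all, make_synthetic_pathway

pathway, truth = make_synthetic_pathway(
    FixtureSpec(n_pcp_motifs=3, n_reversed_bindings=7, n_groups=2, seed=42))
corrected, report = correct_all(pathway, mode="auto")
print(report.counts)
```

prints

```
{'pcp_edge_added': 3, 'binding_reversed': 7, 'group_processed': 2}
```

— the correction pass recovered exactly the planted inconsistencies: 3
compound-mediated chains each gained a direct protein-protein edge, 7
dead-end binding edges were re-directed with the signal flow, and 2
complexes were dissolved into pairwise-bound components.  The input had
50 entries and 57 relations; the output has 48 entries (the two group
containers are gone) and 68 relations (3 PCP edges plus the group
expansions).  Each change is one line in the correction log.

The `examples/` directory holds one short script per capability
(`correct_pathway.py`, `tissue_tuning.py`, `ppi_drilldown.py`,
`roundtrip_and_export.py`); each builds a small input, runs the method
and explains its output.

The same workflow from a shell:

```sh
keggtuner make-fixtures --out-dir fx --seed 42
keggtuner correct fx/pathway.xml -o corrected.xml --log run.log
keggtuner tune corrected.xml -o tuned.xml \
    --expression fx/expression.tsv --tissue T1 \
    --ppi fx/ppi.tsv --score-threshold 0.8
keggtuner export tuned.xml -o tuned.sif
```

Expression tables are tab-delimited (`gene`, then one column per
tissue, gene ids in KEGG namespace such as `hsa:3932`); PPI tables are
tab-delimited `gene_a  gene_b  score  sources` with scores in [0, 1]
(0–1000-convention inputs are detected and rescaled) and sources drawn
from GRID, DIP, KEGG, MINT, PDB.

## Scope

Signaling pathways are the target; metabolic `<reaction>` elements
(compound-chemistry networks) are outside the protein-interaction model
and are skipped with a warning.  Rendering, visual styles and BioPAX
export are out of scope.  No expression or interaction data ship with
the package: tuning is data-source-agnostic by file contract.  KEGG REST
retrieval is for individual academic use only (see
https://www.kegg.jp/kegg/legal.html); there is deliberately no bulk
download command.
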