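"""PPI drill-down: expand paralog entries and keep only physically
supported gene pairs.

A 3-gene paralog box is duplicated at two map positions; the scored
interaction table supports only the first member toward each neighbor at
confidence 0.9 (a second member only at 0.5).  At threshold 0.8 the
duplicates merge into a single node carrying both edges and the
unsupported paralogs vanish.
"""

from keggtuner import (
    PPITable, Pathway, PathwayEntry, PathwayRelation, Subtype,
    TuningConfig, drill_down_ppi,
)

p = Pathway(name="path:demo", org="demo", number="1", title="drill-down demo")
p.add_entry(PathwayEntry(id=1, names=["hsa:n1"], type="gene"))
p.add_entry(PathwayEntry(id=2, names=["hsa:v1", "hsa:v2", "hsa:v3"], type="gene"))
p.add_entry(PathwayEntry(id=3, names=["hsa:v1", "hsa:v2", "hsa:v3"], type="gene"))
p.add_entry(PathwayEntry(id=4, names=["hsa:n2"], type="gene"))
p.relations.append(PathwayRelation(1, 2, "PPrel", [Subtype("activation", "-->")]))
p.relations.append(PathwayRelation(3, 4, "PPrel", [Subtype("activation", "-->")]))

ppi = PPITable([
    ("hsa:n1", "hsa:v1", 0.9, {"GRID"}),
    ("hsa:v1", "hsa:n2", 0.9, {"MINT"}),
    ("hsa:n1", "hsa:v2", 0.5, {"GRID"}),
    ("hsa:v3", "hsa:n2", 0.5, {"PDB"}),
])

out, report = drill_down_ppi(p, ppi, TuningConfig(ppi_score_threshold=0.8))
print("surviving genes:", sorted(out.gene_ids()))
for r in out.relations:
    print(f"  {out.entries[r.entry1].names[0]} -> {out.entries[r.entry2].names[0]}")
print("report:", report.counts)

# hsa:v1 appears once (duplicates merged) and carries both parent edges;
# hsa:v2/hsa:v3, supported only below threshold, are removed as isolated.
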