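"""Computer-assisted correction of KGML inconsistencies.

KEGG KGML files, drawn for human-readable maps, carry systematic quirks
that break automated network analysis:

* **Protein-compound-protein (PCP) chains** — a protein interaction that
  is mediated by a small compound appears only as two edges through the
  compound node; the direct protein-protein edge is missing.
* **Reversed binding directions** — some binding/association edges point
  against the signal flow (from a source-less terminal node into the
  cascade).
* **Group nodes** — protein complexes are drawn as container entries whose
  component proteins carry no explicit pairwise edges.

Each correction is exposed as a detector (pure, exhaustive) plus an
applier that only accepts detector-flagged candidates — the programmatic
equivalent of a semi-automatic review — and :func:`correct_all` chains
them in a fixed order.  Every mutation emits one
:class:`~keggtuner.report.Record`; appliers never mutate their input
pathway.

Relations created or re-directed here are stamped with tracking
attributes (``added_by``, ``reversed``) that survive KGML round-trips;
detectors skip stamped relations, which makes the whole correction pass
idempotent.
"""

from __future__ import annotations

from .kgml import KGMLValidationError, Pathway, PathwayRelation, Subtype
from .report import CorrectionReport

#: Tracking attribute set on machine-added relations.
ADDED_BY_ATTR = "added_by"
#: Tracking attribute set on relations whose direction was reversed.
REVERSED_ATTR = "reversed"
#: Entry annotation recording dissolved-group membership.
FORMER_GROUP_ATTR = "former_group"

BINDING = "binding/association"


def detect_pcp_motifs(pathway: Pathway):
    """Enumerate every protein-compound-protein chain.

    Returns sorted triples ``(upstream_id, compound_id, downstream_id)``
    such that a relation upstream→compound and a relation
    compound→downstream exist, the middle entry is compound-type, the ends
    are distinct gene-type entries.  Exhaustive: equivalent to brute-force
    enumeration of length-2 paths through compound entries.
    """
    pathway.validate()
    triples = []
    for comp in pathway.entries.values():
        if not comp.is_compound:
            continue
        ups = [
            r.entry1
            for r in pathway.relations_to(comp.id)
            if pathway.entries[r.entry1].is_gene
        ]
        downs = [
            r.entry2
            for r in pathway.relations_from(comp.id)
            if pathway.entries[r.entry2].is_gene
        ]
        for a in ups:
            for b in downs:
                if a != b:
                    triples.append((a, comp.id, b))
    return sorted(set(triples))


def _pcp_edge_exists(pathway: Pathway, a: int, b: int, compound_id: int) -> bool:
    for r in pathway.relations:
        if (
            r.entry1 == a
            and r.entry2 == b
            and r.type == "PPrel"
            and any(s.name == "compound" and s.value == str(compound_id)
                    for s in r.subtypes)
        ):
            return True
    return False


def apply_pcp_correction(pathway: Pathway, motifs):
    """Add one direct protein-protein edge per PCP motif.

    For each ``(a, c, b)`` a ``PPrel`` relation a→b is appended carrying a
    ``compound`` subtype whose value is the mediating compound's entry id,
    plus any other subtypes of the original a→c relation.  The original
    protein-compound edges and the compound entry are retained: the
    correction overlays the missing edge on the intact map.  Idempotent —
    a motif whose direct edge already exists adds nothing.
    """
    detected = set(detect_pcp_motifs(pathway))
    bad = [m for m in motifs if tuple(m) not in detected]
    if bad:
        raise ValueError(f"motifs not present in pathway: {bad}")

    out = pathway.copy()
    report = CorrectionReport()
    for a, c, b in sorted(tuple(m) for m in motifs):
        if _pcp_edge_exists(out, a, b, c):
            continue
        upstream_rel = next(
            r for r in out.relations if r.entry1 == a and r.entry2 == c
        )
        subtypes = [Subtype("compound", str(c))] + [
            Subtype(s.name, s.value)
            for s in upstream_rel.subtypes
            if s.name != "compound"
        ]
        out.relations.append(
            PathwayRelation(a, b, "PPrel", subtypes, {ADDED_BY_ATTR: "pcp"})
        )
        report.add(
            "pcp_edge_added",
            upstream=a, compound=c, downstream=b,
            subtypes=",".join(s.name for s in subtypes),
        )
    return out, report


def detect_suspect_bindings(pathway: Pathway):
    """Flag binding/association edges whose direction contradicts signal flow.

    The dead-end heuristic: a ``PPrel`` binding edge is suspect when its
    source has no other incoming relation while its target has at least one
    other outgoing relation — the edge points from a source-less terminal
    into the cascade, so the authored direction is most likely reversed.
    This predicate is deliberately isolated so alternative criteria (e.g.
    arrowhead glyph information) can replace it.  Machine-added and
    already-reversed relations are never flagged.
    """
    pathway.validate()
    suspects = []
    for rel in pathway.relations:
        if rel.type != "PPrel" or not rel.has_subtype(BINDING):
            continue
        if ADDED_BY_ATTR in rel.extra or REVERSED_ATTR in rel.extra:
            continue
        has_other_incoming = any(
            r is not rel and r.entry2 == rel.entry1 for r in pathway.relations
        )
        has_other_outgoing = any(
            r is not rel and r.entry1 == rel.entry2 for r in pathway.relations
        )
        if not has_other_incoming and has_other_outgoing:
            suspects.append(rel)
    return suspects


def apply_binding_reversal(pathway: Pathway, relations):
    """Swap the endpoints of detector-flagged binding relations.

    Only relations in the current suspect set may be reversed (the
    semi-automatic contract).  Subtypes are unchanged, the relation count
    is preserved, and each reversed relation is stamped so it is not
    re-flagged by a later pass.
    """
    suspects = detect_suspect_bindings(pathway)
    positions = []
    for rel in relations:
        matched = [i for i, r in enumerate(pathway.relations) if r is rel]
        if not matched or not any(rel is s for s in suspects):
            raise ValueError(
                f"relation {getattr(rel, 'entry1', '?')}->"
                f"{getattr(rel, 'entry2', '?')} is not a flagged candidate"
            )
        positions.append(matched[0])

    out = pathway.copy()
    report = CorrectionReport()
    for pos in positions:
        rel = out.relations[pos]
        before = (rel.entry1, rel.entry2)
        rel.entry1, rel.entry2 = rel.entry2, rel.entry1
        rel.extra[REVERSED_ATTR] = "true"
        report.add(
            "binding_reversed",
            entry1_before=before[0], entry2_before=before[1],
            entry1_after=rel.entry1, entry2_after=rel.entry2,
        )
    return out, report


def _group_order(pathway: Pathway):
    """Groups sorted innermost-first (components before containers),
    ties broken by ascending entry id.  Cyclic nesting is an error."""
    groups = {e.id: e for e in pathway.entries.values() if e.is_group}
    order, done = [], set()

    def visit(gid, stack):
        if gid in done:
            return
        if gid in stack:
            raise KGMLValidationError(
                f"cyclic group component references involving entry {gid}"
            )
        stack.add(gid)
        for comp in sorted(groups[gid].components):
            if comp in groups:
                visit(comp, stack)
        stack.discard(gid)
        done.add(gid)
        order.append(gid)

    for gid in sorted(groups):
        visit(gid, set())
    return order


def process_group_nodes(pathway: Pathway):
    """Dissolve every group (complex) entry into its components.

    For a group with components ``e1..ek``: all ``k(k-1)/2`` unordered
    component pairs gain an undirected binding/association edge; every
    relation incident to the group is rewired to each component (inheriting
    type and subtypes); the group entry is removed and each component is
    annotated with its former membership.  Nested groups are dissolved
    innermost-first.
    """
    pathway.validate()
    out = pathway.copy()
    report = CorrectionReport()

    for gid in _group_order(out):
        group = out.entries[gid]
        comps = sorted(group.components)
        existing_keys = {r.key() for r in out.relations}

        n_pairs = 0
        for i, a in enumerate(comps):
            for b in comps[i + 1:]:
                rel = PathwayRelation(
                    a, b, "PPrel", [Subtype(BINDING, "---")],
                    {ADDED_BY_ATTR: "group_expansion"},
                )
                if rel.key() in existing_keys:
                    report.add("duplicate_relation_collapsed",
                               entry1=a, entry2=b, type="PPrel")
                    continue
                existing_keys.add(rel.key())
                out.relations.append(rel)
                n_pairs += 1

        incident = [r for r in out.relations
                    if r.entry1 == gid or r.entry2 == gid]
        n_rewired = 0
        for r in incident:
            for comp in comps:
                e1 = comp if r.entry1 == gid else r.entry1
                e2 = comp if r.entry2 == gid else r.entry2
                new = PathwayRelation(
                    e1, e2, r.type,
                    [Subtype(s.name, s.value) for s in r.subtypes],
                    dict(r.extra),
                )
                if new.key() in existing_keys:
                    report.add("duplicate_relation_collapsed",
                               entry1=e1, entry2=e2, type=r.type)
                    continue
                existing_keys.add(new.key())
                out.relations.append(new)
                n_rewired += 1
        incident_ids = {id(r) for r in incident}
        out.relations = [r for r in out.relations if id(r) not in incident_ids]

        for comp in comps:
            entry = out.entries[comp]
            prior = entry.extra.get(FORMER_GROUP_ATTR, "")
            entry.extra[FORMER_GROUP_ATTR] = (
                f"{prior},{gid}" if prior else str(gid)
            )
        del out.entries[gid]
        # a dissolved nested group is replaced by its components in any
        # container that still lists it
        for other in out.entries.values():
            if other.is_group and gid in other.components:
                other.components = [c for c in other.components if c != gid]
                other.components.extend(c for c in comps
                                        if c not in other.components)
        report.add(
            "group_processed",
            group=gid, components=",".join(str(c) for c in comps),
            pair_relations=n_pairs, rewired_relations=n_rewired,
            removed_relations=len(incident),
        )

    out.validate()
    return out, report


def correct_all(pathway: Pathway, mode: str = "auto"):
    """Run the full correction pass: PCP edges, binding reversal, group
    dissolution — in that fixed order, on all detected candidates.

    ``mode="auto"`` applies every correction; ``mode="report-only"``
    mutates nothing and returns the candidate set as records (the
    computer-assisted contract: review first, then apply a selection via
    the individual ``apply_*`` functions).
    """
    if mode not in ("auto", "report-only"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "report-only":
        report = CorrectionReport()
        for a, c, b in detect_pcp_motifs(pathway):
            report.add("pcp_edge_added", upstream=a, compound=c, downstream=b,
                       proposed=True)
        for rel in detect_suspect_bindings(pathway):
            report.add("binding_reversed", entry1_before=rel.entry1,
                       entry2_before=rel.entry2, proposed=True)
        for e in pathway.entries.values():
            if e.is_group:
                report.add("group_processed", group=e.id,
                           components=",".join(str(c) for c in e.components),
                           proposed=True)
        return pathway.copy(), report

    out, report = apply_pcp_correction(pathway, detect_pcp_motifs(pathway))
    out, rev_report = apply_binding_reversal(out, detect_suspect_bindings(out))
    report.extend(rev_report)
    out, group_report = process_group_nodes(out)
    report.extend(group_report)
    return out, report
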