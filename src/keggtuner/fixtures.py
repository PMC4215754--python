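"""Deterministic synthetic fixtures with planted, counted motifs.

Every correction and tuning operation in this package has a ground-truth
oracle: the generators below build KGML pathways, expression tables and
scored-interaction tables whose inconsistencies and context structure are
*planted* — protein-compound-protein chains, mis-directed binding edges,
group (complex) nodes, duplicated paralog entries, per-tissue silent gene
sets, score-tiered interaction support — and return a
:class:`FixtureTruth` recording exactly what was planted.  Detectors and
tuners can then be checked against the truth without any download.

Planted motifs are disjoint (a relation participates in at most one
planted inconsistency) so the counts are unambiguous, and every generator
is driven by a single seeded pseudo-random stream: the same seed yields
byte-identical artifacts.
"""

from __future__ import annotations

import itertools
import math
import random
from dataclasses import dataclass, field

from .kgml import Graphics, Pathway, PathwayEntry, PathwayRelation, Subtype
from .tuning import ExpressionTable, PPITable

import pandas as pd

_BACKGROUND_SUBTYPES = ("activation", "inhibition", "phosphorylation",
                        "expression")
_SUBTYPE_VALUES = {"activation": "-->", "inhibition": "--|",
                   "phosphorylation": "+p", "expression": "-->",
                   "binding/association": "---"}


class InfeasibleFixtureError(ValueError):
    """The requested plant counts cannot be realized."""


@dataclass
class FixtureSpec:
    """Recipe for a synthetic pathway.

    ``n_gene_entries`` counts the core gene entries used for background
    wiring and motif anchors; reversed-binding terminal entries and group
    component entries are created in addition, keeping every planted
    motif disjoint.
    """

    n_gene_entries: int = 30
    genes_per_entry_range: tuple = (1, 3)
    n_compound_entries: int = 5
    n_relations: int = 40
    n_pcp_motifs: int = 3
    n_reversed_bindings: int = 7
    n_groups: int = 2
    group_size_range: tuple = (2, 3)
    n_duplicated_entries: int = 1
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_gene_entries", "n_compound_entries", "n_relations",
                     "n_pcp_motifs", "n_reversed_bindings", "n_groups",
                     "n_duplicated_entries"):
            if getattr(self, name) < 0:
                raise InfeasibleFixtureError(f"{name} must be >= 0")
        if self.n_pcp_motifs > self.n_compound_entries:
            raise InfeasibleFixtureError(
                f"n_pcp_motifs={self.n_pcp_motifs} exceeds "
                f"n_compound_entries={self.n_compound_entries}: each motif "
                "needs a dedicated compound entry"
            )
        if self.n_pcp_motifs > 0 and self.n_gene_entries < 2:
            raise InfeasibleFixtureError(
                "PCP motifs need at least 2 core gene entries"
            )
        if self.n_reversed_bindings > 0 and (
            self.n_relations < 1 or self.n_gene_entries < 2
        ):
            raise InfeasibleFixtureError(
                "reversed bindings need at least 1 background relation "
                "(a cascade for the mis-directed edge to point into)"
            )
        if self.n_relations > 0 and self.n_gene_entries < 2:
            raise InfeasibleFixtureError(
                "background relations need at least 2 core gene entries"
            )
        if self.n_groups > 0 and self.group_size_range[0] < 2:
            raise InfeasibleFixtureError("groups need at least 2 components")
        if self.n_duplicated_entries > self.n_gene_entries:
            raise InfeasibleFixtureError(
                "cannot duplicate more entries than exist"
            )


@dataclass
class FixtureTruth:
    """Exactly what a generator planted, for use as a test oracle."""

    pcp_triples: list = field(default_factory=list)
    reversed_bindings: list = field(default_factory=list)
    group_components: dict = field(default_factory=dict)
    group_incident_counts: dict = field(default_factory=dict)
    duplicated_gene_ids: list = field(default_factory=list)
    duplicate_entry_pairs: list = field(default_factory=list)
    n_entries: int = 0
    n_relations: int = 0
    silent_genes: dict = field(default_factory=dict)
    supported_pairs: dict = field(default_factory=dict)
    score_by_pair: dict = field(default_factory=dict)

    def pairs_at_or_above(self, threshold: float):
        """Unordered interaction pairs with planted score >= threshold."""
        return {p for p, s in self.score_by_pair.items() if s >= threshold}


def _gene_entry(eid: int, genes, rng: random.Random) -> PathwayEntry:
    return PathwayEntry(
        id=eid, names=list(genes), type="gene",
        graphics=Graphics(
            label=genes[0].split(":", 1)[-1],
            x=40 + 60 * (eid % 12), y=40 + 40 * (eid // 12),
            width=46, height=17, bgcolor="#BFFFBF",
        ),
    )


def make_synthetic_pathway(spec: FixtureSpec):
    """Build a pathway with planted inconsistencies and its truth record.

    Background relations carry only non-binding subtypes among core gene
    entries, so the binding-direction detector sees exactly the planted
    mis-directed edges; each planted compound mediates exactly one
    protein-compound-protein chain, so the PCP detector recovers exactly
    the planted triples.
    """
    spec.validate()
    rng = random.Random(spec.seed)
    truth = FixtureTruth()
    pathway = Pathway(
        name=f"path:syn{spec.seed:05d}", org="syn", number=f"{spec.seed:05d}",
        title=f"Synthetic signaling pathway (seed {spec.seed})",
    )

    next_id = itertools.count(1)
    next_gene = itertools.count(1001)

    core = []
    for _ in range(spec.n_gene_entries):
        n_genes = rng.randint(*spec.genes_per_entry_range)
        genes = [f"hsa:{next(next_gene)}" for _ in range(n_genes)]
        entry = _gene_entry(next(next_id), genes, rng)
        pathway.add_entry(entry)
        core.append(entry)

    compounds = []
    for i in range(spec.n_compound_entries):
        entry = PathwayEntry(
            id=next(next_id), names=[f"cpd:C{10001 + i:05d}"], type="compound",
            graphics=Graphics(label=f"C{10001 + i:05d}", x=500, y=40 + 30 * i,
                              width=8, height=8, shape="circle"),
        )
        pathway.add_entry(entry)
        compounds.append(entry)

    # background wiring: directed non-binding PPrel edges among core entries
    existing_keys = set()
    n_background = 0
    attempts = 0
    while n_background < spec.n_relations and attempts < 50 * max(spec.n_relations, 1):
        attempts += 1
        a, b = rng.sample(core, 2)
        subtype = rng.choice(_BACKGROUND_SUBTYPES)
        rel = PathwayRelation(
            a.id, b.id, "PPrel",
            [Subtype(subtype, _SUBTYPE_VALUES[subtype])],
        )
        if rel.key() in existing_keys:
            continue
        existing_keys.add(rel.key())
        pathway.relations.append(rel)
        n_background += 1
    if n_background < spec.n_relations:
        raise InfeasibleFixtureError(
            f"could not place {spec.n_relations} distinct background "
            f"relations among {spec.n_gene_entries} gene entries"
        )

    # PCP chains: one dedicated compound per motif, exactly one edge in and
    # one edge out of each planted compound
    for i in range(spec.n_pcp_motifs):
        upstream, downstream = rng.sample(core, 2)
        compound = compounds[i]
        pathway.relations.append(PathwayRelation(
            upstream.id, compound.id, "PCrel",
            [Subtype("activation", "-->")],
        ))
        pathway.relations.append(PathwayRelation(
            compound.id, downstream.id, "PCrel",
            [Subtype("activation", "-->")],
        ))
        truth.pcp_triples.append((upstream.id, compound.id, downstream.id))
    truth.pcp_triples.sort()

    # mis-directed binding edges: fresh source-less terminal -> cascade node
    cascade_ids = {r.entry1 for r in pathway.relations
                   if r.type == "PPrel"}
    cascade = [e for e in core if e.id in cascade_ids]
    if spec.n_reversed_bindings > 0 and not cascade:
        raise InfeasibleFixtureError(
            "no cascade node with an outgoing relation is available for "
            "planting reversed bindings"
        )
    for _ in range(spec.n_reversed_bindings):
        terminal = _gene_entry(next(next_id), [f"hsa:{next(next_gene)}"], rng)
        pathway.add_entry(terminal)
        target = rng.choice(cascade)
        pathway.relations.append(PathwayRelation(
            terminal.id, target.id, "PPrel",
            [Subtype("binding/association", "---")],
        ))
        truth.reversed_bindings.append((terminal.id, target.id))

    # group (complex) nodes with fresh components and planted incident edges
    for _ in range(spec.n_groups):
        k = rng.randint(*spec.group_size_range)
        members = []
        for _ in range(k):
            member = _gene_entry(next(next_id), [f"hsa:{next(next_gene)}"], rng)
            pathway.add_entry(member)
            members.append(member.id)
        group = PathwayEntry(
            id=next(next_id), names=["undefined"], type="group",
            graphics=Graphics(label="", shape="rectangle", width=92, height=34),
            components=members,
        )
        pathway.add_entry(group)
        m = rng.randint(1, 2)
        for _ in range(m):
            upstream = rng.choice(core)
            rel = PathwayRelation(
                upstream.id, group.id, "PPrel",
                [Subtype("activation", "-->")],
            )
            if rel.key() in existing_keys:
                continue
            existing_keys.add(rel.key())
            pathway.relations.append(rel)
        truth.group_components[group.id] = sorted(members)
        truth.group_incident_counts[group.id] = len(
            [r for r in pathway.relations
             if r.entry1 == group.id or r.entry2 == group.id]
        )

    # duplicated entries: same gene list drawn at a second map position
    dup_candidates = [e for e in core]
    for i in range(spec.n_duplicated_entries):
        original = dup_candidates[i % len(dup_candidates)]
        dup = PathwayEntry(
            id=next(next_id), names=list(original.names), type="gene",
            graphics=Graphics(
                label=original.graphics.label,
                x=original.graphics.x + 300, y=original.graphics.y + 120,
                width=46, height=17, bgcolor="#BFFFBF",
            ),
        )
        pathway.add_entry(dup)
        neighbor = rng.choice([e for e in core if e.id != original.id])
        pathway.relations.append(PathwayRelation(
            dup.id, neighbor.id, "PPrel",
            [Subtype("activation", "-->")],
        ))
        truth.duplicated_gene_ids.extend(original.names)
        truth.duplicate_entry_pairs.append((original.id, dup.id))

    truth.n_entries = len(pathway.entries)
    truth.n_relations = len(pathway.relations)
    pathway.validate()
    return pathway, truth


def make_expression_table(genes, tissues, silent_fraction_per_tissue,
                          seed: int = 0, forced_silent=None):
    """Build an expression table with per-tissue planted silent genes.

    Per tissue, ``round(fraction * n_genes)`` genes are silent (values
    strictly below the table's 25th nearest-rank percentile) and the rest
    expressed (values at or above it), so tuning at the standard
    25-percentile threshold separates the classes exactly.  Clean
    separation requires the silent count to stay below ``ceil(0.25 * n)``;
    an infeasible fraction raises.

    ``silent_fraction_per_tissue`` may be one fraction for all tissues or
    a ``{tissue: fraction}`` mapping.  ``forced_silent`` optionally maps a
    tissue to genes that must be in its silent set (for planting scenarios
    such as a hub silent in one tissue only); genes forced silent in any
    tissue are excluded from the random silent draw of every other tissue,
    so a forced-silent gene is guaranteed expressed elsewhere.
    """
    genes = list(genes)
    tissues = list(tissues)
    if not genes:
        raise ValueError("gene list is empty")
    if not tissues:
        raise ValueError("tissue list is empty")
    if not isinstance(silent_fraction_per_tissue, dict):
        silent_fraction_per_tissue = {
            t: float(silent_fraction_per_tissue) for t in tissues
        }
    forced_silent = {t: set(v) for t, v in (forced_silent or {}).items()}
    all_forced = set().union(*forced_silent.values()) if forced_silent else set()
    unknown = all_forced - set(genes)
    if unknown:
        raise ValueError(f"forced-silent genes not in gene list: {sorted(unknown)}")
    rng = random.Random(seed)
    truth = FixtureTruth()
    n = len(genes)
    rank25 = math.ceil(0.25 * n)

    columns = {}
    for tissue in tissues:
        frac = silent_fraction_per_tissue.get(tissue, 0.0)
        if not 0.0 <= frac <= 1.0:
            raise ValueError(f"silent fraction {frac} outside [0, 1]")
        forced = forced_silent.get(tissue, set())
        n_silent = max(round(frac * n), len(forced))
        if n_silent >= rank25 and n_silent > 0:
            raise InfeasibleFixtureError(
                f"{n_silent} silent genes of {n} in tissue {tissue!r} would "
                f"put the 25th nearest-rank percentile (rank {rank25}) inside "
                "the silent class; silent and expressed values could not be "
                "cleanly separated by that threshold"
            )
        drawable = [g for g in genes if g not in all_forced]
        silent = set(forced)
        if n_silent > len(silent):
            silent |= set(rng.sample(drawable, n_silent - len(silent)))
        truth.silent_genes[tissue] = silent
        # enough expressed genes pinned at the floor value that the 25th
        # nearest-rank percentile lands exactly on the floor
        n_pinned = max(0, rank25 - n_silent)
        expressed = [g for g in genes if g not in silent]
        pinned = set(expressed[:n_pinned])
        values = {}
        for g in genes:
            if g in silent:
                values[g] = round(rng.uniform(0.5, 20.0), 3)
            elif g in pinned:
                values[g] = 100.0
            else:
                values[g] = round(rng.uniform(100.0, 1000.0), 3)
        columns[tissue] = values

    frame = pd.DataFrame(
        {t: [columns[t][g] for g in genes] for t in tissues}, index=genes
    )
    frame.index.name = "gene"
    return ExpressionTable(frame), truth


def make_ppi_table(genes, supported_pair_fraction: float = 0.3,
                   score_tiers=(0.5, 0.9), sources=("GRID", "MINT", "KEGG"),
                   seed: int = 0):
    """Build a scored interaction table over a gene universe.

    A ``supported_pair_fraction`` of all unordered gene pairs receive a
    record; each record's score is drawn from ``score_tiers`` and its
    evidence labels form a random non-empty subset of ``sources``.  The
    truth records the planted score per pair, queryable at any threshold
    via :meth:`FixtureTruth.pairs_at_or_above`.
    """
    genes = sorted(set(genes))
    if not genes:
        raise ValueError("gene list is empty")
    if not 0.0 <= supported_pair_fraction <= 1.0:
        raise ValueError("supported_pair_fraction outside [0, 1]")
    if any(not 0.0 <= t <= 1.0 for t in score_tiers):
        raise ValueError("score tiers must lie in [0, 1]")
    sources = sorted(sources)
    rng = random.Random(seed)
    truth = FixtureTruth()

    all_pairs = list(itertools.combinations(genes, 2))
    n_supported = round(supported_pair_fraction * len(all_pairs))
    supported = rng.sample(all_pairs, n_supported)

    interactions = []
    for a, b in supported:
        score = rng.choice(list(score_tiers))
        n_src = rng.randint(1, len(sources))
        src = frozenset(rng.sample(sources, n_src))
        interactions.append((a, b, score, src))
        truth.score_by_pair[frozenset((a, b))] = score
    for tier in score_tiers:
        truth.supported_pairs[tier] = truth.pairs_at_or_above(tier)
    return PPITable(interactions), truth
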