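"""Biological-context-specific pathway tuning.

Two orthogonal refinements turn a generic KEGG pathway into a variant
specific to one biological context:

* **Tissue-specific tuning** prunes genes whose expression in a chosen
  tissue or cell type falls below a threshold (an absolute value, or a
  nearest-rank percentile of the expression table).  A multi-gene entry
  survives as long as at least one member gene is expressed; entries with
  no expressed gene are removed together with their incident edges.
  Non-gene entries (compounds, linked maps) are always preserved.

* **PPI drill-down** expands each paralog-group entry into single-gene
  nodes and keeps a gene-gene edge only where a physical-interaction
  record at or above a confidence score, from chosen evidence sources,
  supports that specific pair.  Duplicated single-gene nodes are merged
  and isolated gene nodes removed.

Both operations are pure: the input pathway is cloned, and the output
carries freshly assigned entry identifiers.
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kgml import Graphics, Pathway, PathwayEntry, PathwayRelation, Subtype
from .report import TuningReport

logger = logging.getLogger(__name__)

#: Evidence databases the scored-interaction table may cite.
PPI_SOURCES = frozenset({"GRID", "DIP", "KEGG", "MINT", "PDB"})


class ExpressionTable:
    """Gene-by-tissue expression matrix backed by a pandas DataFrame.

    Rows are gene ids in the pathway's namespace (e.g. ``hsa:3932``),
    columns are tissue/cell-type names, values are non-negative floats;
    NaN marks a missing measurement.
    """

    def __init__(self, frame: pd.DataFrame):
        if frame.empty:
            raise ValueError("expression table is empty")
        dup = frame.index[frame.index.duplicated()].unique().tolist()
        if dup:
            raise ValueError(f"duplicate gene rows: {', '.join(map(str, dup))}")
        self.frame = frame.apply(pd.to_numeric, errors="coerce")

    @property
    def genes(self):
        return list(self.frame.index)

    @property
    def tissues(self):
        return list(self.frame.columns)

    def value(self, gene: str, tissue: str):
        """Expression of ``gene`` in ``tissue``; None when absent/missing."""
        if gene not in self.frame.index or tissue not in self.frame.columns:
            return None
        v = self.frame.at[gene, tissue]
        return None if pd.isna(v) else float(v)

    def column_values(self, tissue: str) -> np.ndarray:
        return self.frame[tissue].dropna().to_numpy(dtype=float)

    def all_values(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float).ravel()

    def to_tsv(self) -> str:
        buf = io.StringIO()
        self.frame.to_csv(buf, sep="\t", index_label="gene")
        return buf.getvalue()


def read_expression_table(source) -> ExpressionTable:
    """Read a tab-delimited expression table.

    Expected layout: header ``gene<TAB>tissue1<TAB>...``, one row per
    gene.  ``source`` may be a path, file-like object, or the text itself.
    Non-numeric cells become missing values.
    """
    if isinstance(source, str) and "\t" in source:
        source = io.StringIO(source)
    try:
        frame = pd.read_csv(source, sep="\t", index_col=0)
    except pd.errors.EmptyDataError as exc:
        raise ValueError("expression table is empty") from exc
    return ExpressionTable(frame)


def write_expression_table(table: ExpressionTable, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(table.to_tsv())


@dataclass(frozen=True)
class PPIRecord:
    score: float
    sources: frozenset


class PPITable:
    """Undirected scored gene-gene physical interactions.

    Scores live in [0, 1] (a STRING-style combined confidence adjusted
    for the probability of a random observation).  An input whose scores
    exceed 1 is assumed to use the 0-999/1000 integer convention and is
    rescaled by 1/1000 (logged).  At most one record per unordered pair.
    """

    def __init__(self, interactions):
        records = {}
        max_score = 0.0
        raw = []
        for gene_a, gene_b, score, sources in interactions:
            if gene_a == gene_b:
                raise ValueError(f"self-interaction for {gene_a}")
            pair = frozenset((gene_a, gene_b))
            if pair in records:
                raise ValueError(
                    f"duplicate interaction record for pair {sorted(pair)}"
                )
            records[pair] = None
            sources = frozenset(sources)
            unknown = sources - PPI_SOURCES
            if unknown:
                logger.warning("unknown PPI sources %s kept verbatim",
                               sorted(unknown))
            raw.append((pair, float(score), sources))
            max_score = max(max_score, float(score))

        scale = 1000.0 if max_score > 1.0 else 1.0
        if scale != 1.0:
            logger.warning(
                "PPI scores exceed 1 (max %.1f); assuming 0-1000 convention "
                "and rescaling by 1/1000", max_score,
            )
        self.records = {}
        for pair, score, sources in raw:
            score = score / scale
            if not 0.0 <= score <= 1.0:
                raise ValueError(f"score {score} outside [0, 1] for {sorted(pair)}")
            self.records[pair] = PPIRecord(score, sources)

    def __len__(self):
        return len(self.records)

    def supports(self, gene_a: str, gene_b: str,
                 score_threshold: float, sources) -> bool:
        """True when the unordered pair has a record with score at or above
        the threshold citing at least one of the requested sources."""
        rec = self.records.get(frozenset((gene_a, gene_b)))
        return (
            rec is not None
            and rec.score >= score_threshold
            and bool(rec.sources & frozenset(sources))
        )

    def to_tsv(self) -> str:
        lines = ["gene_a\tgene_b\tscore\tsources"]
        for pair in sorted(self.records, key=sorted):
            a, b = sorted(pair)
            rec = self.records[pair]
            lines.append(
                f"{a}\t{b}\t{rec.score:g}\t{','.join(sorted(rec.sources))}"
            )
        return "\n".join(lines) + "\n"


def read_ppi_table(source) -> PPITable:
    """Read a tab-delimited scored interaction table
    (``gene_a  gene_b  score  sources`` with comma-separated sources)."""
    if isinstance(source, str) and "\t" in source:
        source = io.StringIO(source)
    frame = pd.read_csv(source, sep="\t")
    required = {"gene_a", "gene_b", "score", "sources"}
    if not required.issubset(frame.columns):
        raise ValueError(
            f"PPI table must have columns {sorted(required)}, "
            f"got {list(frame.columns)}"
        )
    interactions = [
        (row.gene_a, row.gene_b, row.score,
         frozenset(str(row.sources).split(",")))
        for row in frame.itertuples()
    ]
    return PPITable(interactions)


def write_ppi_table(table: PPITable, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(table.to_tsv())


@dataclass
class TuningConfig:
    """Parameters of a tuning run.

    tissue : column of the expression table to tune against.
    threshold_mode : ``percentile`` (default; value in [0, 100], resolved
        by the nearest-rank rule) or ``absolute``.
    percentile_scope : ``per_tissue`` (percentile of the chosen tissue's
        values; default) or ``whole_table`` (percentile over every value).
    ppi_score_threshold : minimum interaction confidence in [0, 1]
        (0.8 is a common stringent choice).
    ppi_sources : evidence databases accepted during drill-down.
    keep_missing : retain genes absent from the expression table instead
        of treating absence as silence.
    """

    tissue: str = ""
    threshold_mode: str = "percentile"
    threshold_value: float = 25.0
    percentile_scope: str = "per_tissue"
    ppi_score_threshold: float = 0.8
    ppi_sources: frozenset = field(default_factory=lambda: PPI_SOURCES)
    keep_missing: bool = False

    def __post_init__(self):
        if self.threshold_mode not in ("percentile", "absolute"):
            raise ValueError(f"unknown threshold mode {self.threshold_mode!r}")
        if self.threshold_mode == "percentile" and not (
            0.0 <= self.threshold_value <= 100.0
        ):
            raise ValueError("percentile must lie in [0, 100]")
        if self.percentile_scope not in ("per_tissue", "whole_table"):
            raise ValueError(f"unknown percentile scope {self.percentile_scope!r}")
        if not 0.0 <= self.ppi_score_threshold <= 1.0:
            raise ValueError("PPI score threshold must lie in [0, 1]")
        self.ppi_sources = frozenset(self.ppi_sources)


def nearest_rank_percentile(values, percentile: float) -> float:
    """Nearest-rank percentile: the value at 1-based rank
    ``ceil(p/100 * n)`` of the sorted sample (rank clamped to [1, n]).
    Deterministic, no interpolation."""
    vals = np.sort(np.asarray(values, dtype=float))
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise ValueError("cannot take a percentile of an empty value set")
    rank = math.ceil(percentile / 100.0 * vals.size)
    rank = min(max(rank, 1), vals.size)
    return float(vals[rank - 1])


def compute_threshold(table: ExpressionTable, config: TuningConfig) -> float:
    """Resolve the survival threshold for a tuning run.

    In absolute mode, the configured value itself.  In percentile mode,
    the nearest-rank percentile of the chosen tissue's column
    (``per_tissue``) or of every value in the table (``whole_table``),
    ignoring missing values.
    """
    if config.threshold_mode == "absolute":
        return float(config.threshold_value)
    if config.percentile_scope == "per_tissue":
        if config.tissue not in table.tissues:
            raise ValueError(
                f"tissue {config.tissue!r} not in table; "
                f"available: {', '.join(table.tissues)}"
            )
        values = table.column_values(config.tissue)
    else:
        values = table.all_values()
        values = values[~np.isnan(values)]
    return nearest_rank_percentile(values, config.threshold_value)


def _renumber(pathway: Pathway) -> Pathway:
    """Assign fresh consecutive entry ids (1..n, stored order), remapping
    relation endpoints, group components and compound-subtype values."""
    mapping = {old: i + 1 for i, old in enumerate(pathway.entries.keys())}
    out = Pathway(
        name=pathway.name, org=pathway.org, number=pathway.number,
        title=pathway.title, image=pathway.image, link=pathway.link,
        extra=dict(pathway.extra),
    )
    for old_id, entry in pathway.entries.items():
        clone = PathwayEntry(
            id=mapping[old_id], names=list(entry.names), type=entry.type,
            link=entry.link, graphics=entry.graphics,
            components=[mapping[c] for c in entry.components if c in mapping],
            extra=dict(entry.extra),
        )
        out.add_entry(clone)
    for r in pathway.relations:
        subtypes = []
        for s in r.subtypes:
            value = s.value
            if s.name in ("compound", "hidden compound") and value.isdigit():
                old = int(value)
                if old in mapping:
                    value = str(mapping[old])
            subtypes.append(Subtype(s.name, value))
        out.relations.append(
            PathwayRelation(mapping[r.entry1], mapping[r.entry2], r.type,
                            subtypes, dict(r.extra))
        )
    return out


def tune_tissue(pathway: Pathway, table: ExpressionTable,
                config: TuningConfig):
    """Prune the pathway to genes expressed in one tissue.

    The pathway is cloned (the input is never modified).  Each gene
    entry's member list is filtered to genes whose expression in
    ``config.tissue`` is at or above the resolved threshold; entries left
    with no member are removed along with their incident relations.
    Genes absent from the table count as silent (with a logged warning)
    unless ``config.keep_missing`` is set.  Non-gene entries always
    survive.  Output entry ids are freshly assigned.
    """
    pathway.validate()
    if config.tissue not in table.tissues:
        raise ValueError(
            f"tissue {config.tissue!r} not in table; "
            f"available: {', '.join(table.tissues)}"
        )
    threshold = compute_threshold(table, config)
    report = TuningReport()
    out = pathway.copy()
    out.extra["tuned_tissue"] = config.tissue

    removed_entry_ids = []
    for entry in list(out.entries.values()):
        if not entry.is_gene:
            continue
        surviving = []
        for gene in entry.names:
            value = table.value(gene, config.tissue)
            if value is None:
                if config.keep_missing:
                    surviving.append(gene)
                else:
                    logger.warning(
                        "gene %s absent from expression table; treated as "
                        "below threshold", gene,
                    )
                    report.add("gene_removed", gene=gene, entry=entry.id,
                               reason="missing")
            elif value >= threshold:
                surviving.append(gene)
            else:
                report.add("gene_removed", gene=gene, entry=entry.id,
                           reason=f"expression {value:g} < {threshold:g}")
        if surviving:
            entry.names = surviving
        else:
            removed_entry_ids.append(entry.id)

    removed = set(removed_entry_ids)
    for eid in removed_entry_ids:
        report.add("entry_removed", entry=eid,
                   names=" ".join(pathway.entries[eid].names)
                   if eid in pathway.entries else "")
        del out.entries[eid]
    out.relations = [
        r for r in out.relations
        if r.entry1 not in removed and r.entry2 not in removed
    ]
    # groups that lost components below the minimum arity cannot stand
    for entry in list(out.entries.values()):
        if entry.is_group:
            entry.components = [c for c in entry.components if c not in removed]
            if len(entry.components) < 2:
                report.add("entry_removed", entry=entry.id, names="group")
                del out.entries[entry.id]
                out.relations = [
                    r for r in out.relations
                    if r.entry1 != entry.id and r.entry2 != entry.id
                ]

    out = _renumber(out)
    out.validate()
    return out, report


def drill_down_ppi(pathway: Pathway, ppi: PPITable, config: TuningConfig):
    """Expand paralog entries into single-gene nodes filtered by PPI.

    Steps: (1) every gene entry becomes one node per member gene, copying
    the parent's attributes; (2) an edge between two gene nodes is kept
    only when the scored-interaction table supports that unordered pair at
    ``config.ppi_score_threshold`` from ``config.ppi_sources``, the edge
    direction and attributes inherited from the parent relation; (3)
    relations touching non-gene entries fan out to all members unfiltered
    (PPI evidence is undefined for compounds and maps); (4) nodes for the
    same gene arising from duplicated entries are merged, keeping the
    graphics of the lowest original entry id; (5) gene nodes left with no
    incident relation are removed.  Output ids are freshly assigned.
    """
    pathway.validate()
    if not config.ppi_sources:
        raise ValueError("PPI source set is empty")
    report = TuningReport()

    # final node key: ("gene", gene_id) for expanded members,
    # ("entry", old_id) for non-gene entries
    node_for_entry = {}
    gene_parents = {}
    for entry in pathway.entries.values():
        if entry.is_gene:
            keys = [("gene", g) for g in entry.names]
            node_for_entry[entry.id] = keys
            for g in entry.names:
                gene_parents.setdefault(g, []).append(entry.id)
            if len(entry.names) > 1:
                report.add("entry_expanded", entry=entry.id,
                           genes=" ".join(entry.names))
        else:
            node_for_entry[entry.id] = [("entry", entry.id)]
    for gene, parents in gene_parents.items():
        if len(parents) > 1:
            report.add("entries_merged", gene=gene,
                       entries=",".join(str(p) for p in sorted(parents)))

    # group entries whose components are gene entries lose those components
    # during expansion; a group left with < 2 components cannot survive, and
    # edges to it must not count toward node incidence
    dropped = set()
    changed = True
    while changed:
        changed = False
        for entry in pathway.entries.values():
            if not entry.is_group or entry.id in dropped:
                continue
            kept = [
                c for c in entry.components
                if c not in dropped and not pathway.entries[c].is_gene
            ]
            if len(kept) < 2:
                dropped.add(entry.id)
                changed = True

    edges = []
    seen_edges = set()
    for r in pathway.relations:
        if r.entry1 in dropped or r.entry2 in dropped:
            continue
        e1 = pathway.entries[r.entry1]
        e2 = pathway.entries[r.entry2]
        both_gene = e1.is_gene and e2.is_gene
        for u in node_for_entry[r.entry1]:
            for v in node_for_entry[r.entry2]:
                if u == v:
                    continue
                if both_gene and not ppi.supports(
                    u[1], v[1], config.ppi_score_threshold, config.ppi_sources
                ):
                    continue
                key = (u, v, r.type,
                       tuple(sorted(s.key() for s in r.subtypes)))
                if key in seen_edges:
                    continue
                seen_edges.add(key)
                edges.append((u, v, r))

    incident = set()
    for u, v, _ in edges:
        incident.add(u)
        incident.add(v)

    out = Pathway(
        name=pathway.name, org=pathway.org, number=pathway.number,
        title=pathway.title, image=pathway.image, link=pathway.link,
        extra=dict(pathway.extra),
    )
    out.extra["ppi_tuned"] = "true"

    new_entries = {}
    emitted_genes = set()
    for entry in pathway.entries.values():
        if entry.is_gene:
            for gene in entry.names:
                key = ("gene", gene)
                if gene in emitted_genes:
                    continue
                if key not in incident:
                    report.add("isolated_removed", gene=gene, entry=entry.id)
                    emitted_genes.add(gene)
                    continue
                emitted_genes.add(gene)
                rep_parent = min(gene_parents[gene])
                graphics = pathway.entries[rep_parent].graphics
                clone = PathwayEntry(
                    id=0, names=[gene], type="gene", link=entry.link,
                    graphics=Graphics(
                        label=gene.split(":", 1)[-1], x=graphics.x,
                        y=graphics.y, width=graphics.width,
                        height=graphics.height, shape=graphics.shape,
                        fgcolor=graphics.fgcolor, bgcolor=graphics.bgcolor,
                        extra=dict(graphics.extra),
                    ),
                    extra=dict(pathway.entries[rep_parent].extra),
                )
                new_entries[key] = clone
        else:
            if entry.id in dropped:
                continue
            clone = PathwayEntry(
                id=0, names=list(entry.names), type=entry.type,
                link=entry.link, graphics=entry.graphics,
                components=list(entry.components), extra=dict(entry.extra),
            )
            new_entries[("entry", entry.id)] = clone

    old_to_key = {}
    for next_id, (key, entry) in enumerate(new_entries.items(), start=1):
        entry.id = next_id
        if key[0] == "entry":
            old_to_key[key[1]] = next_id
        out.add_entry(entry)

    # group components / compound subtype values still reference old entry
    # ids; remap survivors, drop the rest
    for entry in list(out.entries.values()):
        if entry.is_group:
            entry.components = [
                old_to_key[c] for c in entry.components if c in old_to_key
            ]
            if len(entry.components) < 2:
                del out.entries[entry.id]

    for u, v, r in edges:
        if u not in new_entries or v not in new_entries:
            continue
        if (new_entries[u].id not in out.entries
                or new_entries[v].id not in out.entries):
            continue
        subtypes = []
        for s in r.subtypes:
            value = s.value
            if (s.name in ("compound", "hidden compound") and value.isdigit()
                    and int(value) in old_to_key):
                value = str(old_to_key[int(value)])
            subtypes.append(Subtype(s.name, value))
        out.relations.append(
            PathwayRelation(new_entries[u].id, new_entries[v].id, r.type,
                            subtypes, dict(r.extra))
        )

    out.validate()
    return out, report


def tune_full(pathway: Pathway, table: ExpressionTable, ppi: PPITable,
              config: TuningConfig):
    """Tissue-specific tuning followed by PPI drill-down: the fine-tuned
    network in which every component occurs in the same biological
    context.  Reports are concatenated."""
    tissue_tuned, report = tune_tissue(pathway, table, config)
    out, ppi_report = drill_down_ppi(tissue_tuned, ppi, config)
    report.extend(ppi_report)
    return out, report
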