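"""Tissue-specific tuning and PPI drill-down, checked against hand-applied
rules, brute-force pair filtering, and fixture ground truth."""

import logging

import pandas as pd
import pytest

from keggtuner import (
    ExpressionTable,
    FixtureSpec,
    PPITable,
    PPI_SOURCES,
    Pathway,
    PathwayEntry,
    PathwayRelation,
    Subtype,
    TuningConfig,
    compute_threshold,
    drill_down_ppi,
    make_expression_table,
    make_ppi_table,
    make_synthetic_pathway,
    nearest_rank_percentile,
    read_expression_table,
    read_ppi_table,
    tune_full,
    tune_tissue,
    write_expression_table,
)


def build(entries, relations):
    p = Pathway(name="path:t", org="t", number="1", title="t")
    for eid, names, etype in entries:
        p.add_entry(PathwayEntry(id=eid, names=names, type=etype))
    for e1, e2, rtype in relations:
        p.relations.append(
            PathwayRelation(e1, e2, rtype, [Subtype("activation", "-->")])
        )
    return p


def table_from(rows, tissues):
    frame = pd.DataFrame({t: [r[1][i] for r in rows]
                          for i, t in enumerate(tissues)},
                         index=[r[0] for r in rows])
    return ExpressionTable(frame)


class TestExpressionTable:
    def test_read_toy_table(self):
        text = "gene\tT1\tT2\nhsa:1\t5\t7\nhsa:2\t1\t3\n"
        table = read_expression_table(text)
        assert table.genes == ["hsa:1", "hsa:2"]
        assert table.tissues == ["T1", "T2"]
        assert table.value("hsa:2", "T2") == 3.0

    def test_blank_cell_is_missing(self):
        text = "gene\tT1\tT2\nhsa:1\t\t7\nhsa:2\t1\t3\n"
        table = read_expression_table(text)
        assert table.value("hsa:1", "T1") is None
        assert table.value("hsa:1", "T2") == 7.0

    def test_non_numeric_cell_is_missing(self):
        table = read_expression_table("gene\tT1\nhsa:1\tnope\nhsa:2\t4\n")
        assert table.value("hsa:1", "T1") is None

    def test_duplicate_gene_rows_rejected(self):
        with pytest.raises(ValueError, match="hsa:1"):
            read_expression_table("gene\tT1\nhsa:1\t5\nhsa:1\t6\n")

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            read_expression_table("gene\tT1\n")

    def test_round_trip_through_disk(self, tmp_path):
        table, _ = make_expression_table(
            [f"hsa:{i}" for i in range(1, 21)], ["T1", "T2"], 0.1, seed=7
        )
        path = tmp_path / "expr.tsv"
        write_expression_table(table, path)
        again = read_expression_table(str(path))
        pd.testing.assert_frame_equal(table.frame, again.frame,
                                      check_names=False)


class TestThreshold:
    def test_nearest_rank_hand_computed(self):
        # rank = ceil(25/100 * 4) = 1 -> smallest value
        assert nearest_rank_percentile([1, 2, 3, 4], 25) == 1

    def test_percentile_100_is_max(self):
        assert nearest_rank_percentile([1, 2, 3, 4], 100) == 4

    def test_percentile_0_is_min(self):
        assert nearest_rank_percentile([4, 3, 2, 1], 0) == 1

    def test_empty_values_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            nearest_rank_percentile([], 25)

    def test_scope_selects_value_set(self):
        table = table_from([("g1", (1, 100)), ("g2", (2, 200)),
                            ("g3", (3, 300)), ("g4", (4, 400))], ["T1", "T2"])
        per_tissue = TuningConfig(tissue="T2", threshold_value=25)
        assert compute_threshold(table, per_tissue) == 100
        whole = TuningConfig(tissue="T2", threshold_value=25,
                             percentile_scope="whole_table")
        assert compute_threshold(table, whole) == 2  # rank ceil(.25*8)=2

    def test_absolute_mode_passthrough(self):
        table = table_from([("g1", (1,))], ["T1"])
        cfg = TuningConfig(tissue="T1", threshold_mode="absolute",
                           threshold_value=17.5)
        assert compute_threshold(table, cfg) == 17.5


class TestTissueTuning:
    def test_entry_keeps_only_expressed_genes(self):
        p = build([(1, ["hsa:1", "hsa:2"], "gene")], [])
        table = table_from([("hsa:1", (10,)), ("hsa:2", (2,))], ["T"])
        cfg = TuningConfig(tissue="T", threshold_mode="absolute",
                           threshold_value=5)
        out, report = tune_tissue(p, table, cfg)
        assert [e.names for e in out.entries.values()] == [["hsa:1"]]
        assert report.count("gene_removed") == 1

    def test_entry_with_no_expressed_gene_removed_with_edges(self):
        p = build([(1, ["hsa:1"], "gene"), (2, ["hsa:2"], "gene")],
                  [(1, 2, "PPrel")])
        table = table_from([("hsa:1", (10,)), ("hsa:2", (1,))], ["T"])
        cfg = TuningConfig(tissue="T", threshold_mode="absolute",
                           threshold_value=5)
        out, report = tune_tissue(p, table, cfg)
        assert len(out.entries) == 1
        assert out.relations == []
        assert report.count("entry_removed") == 1

    def test_threshold_at_min_removes_nothing(self):
        p = build([(1, ["hsa:1"], "gene"), (2, ["hsa:2"], "gene")],
                  [(1, 2, "PPrel")])
        table = table_from([("hsa:1", (10,)), ("hsa:2", (2,))], ["T"])
        cfg = TuningConfig(tissue="T", threshold_mode="absolute",
                           threshold_value=2)
        out, _ = tune_tissue(p, table, cfg)
        assert out.gene_ids() == p.gene_ids()

    def test_non_gene_entries_preserved(self):
        p = build([(1, ["hsa:1"], "gene"), (2, ["cpd:C1"], "compound"),
                   (3, ["path:x"], "map")], [])
        table = table_from([("hsa:1", (0.1,))], ["T"])
        cfg = TuningConfig(tissue="T", threshold_mode="absolute",
                           threshold_value=5)
        out, _ = tune_tissue(p, table, cfg)
        assert {e.names[0] for e in out.entries.values()} == {"cpd:C1", "path:x"}

    def test_silent_hub_absent_only_in_silent_tissue(self):
        # one hub whose only gene is silent in T2 but expressed in T1
        p = build(
            [(1, ["hsa:1"], "gene"), (2, ["hsa:99"], "gene"),
             (3, ["hsa:3"], "gene")],
            [(1, 2, "PPrel"), (2, 3, "PPrel")],
        )
        table = table_from(
            [("hsa:1", (50, 50)), ("hsa:99", (50, 1)), ("hsa:3", (50, 50))],
            ["T1", "T2"],
        )
        cfg = dict(threshold_mode="absolute", threshold_value=10)
        in_t1, _ = tune_tissue(p, table, TuningConfig(tissue="T1", **cfg))
        in_t2, _ = tune_tissue(p, table, TuningConfig(tissue="T2", **cfg))
        assert "hsa:99" in in_t1.gene_ids()
        assert "hsa:99" not in in_t2.gene_ids()
        assert in_t2.relations == []  # hub loss disconnects the cascade

    def test_missing_gene_silent_by_default_kept_on_flag(self, caplog):
        p = build([(1, ["hsa:1"], "gene")], [])
        table = table_from([("hsa:2", (10,))], ["T"])
        cfg = TuningConfig(tissue="T", threshold_mode="absolute",
                           threshold_value=5)
        with caplog.at_level(logging.WARNING):
            out, _ = tune_tissue(p, table, cfg)
        assert len(out.entries) == 0
        assert any("absent" in rec.message for rec in caplog.records)
        keep = TuningConfig(tissue="T", threshold_mode="absolute",
                            threshold_value=5, keep_missing=True)
        out, _ = tune_tissue(p, table, keep)
        assert len(out.entries) == 1

    def test_unknown_tissue_names_available(self):
        p = build([(1, ["hsa:1"], "gene")], [])
        table = table_from([("hsa:1", (10,))], ["Liver"])
        with pytest.raises(ValueError, match="Liver"):
            tune_tissue(p, table, TuningConfig(tissue="Brain"))

    def test_input_not_mutated_and_ids_fresh(self):
        pathway, _ = make_synthetic_pathway(FixtureSpec(seed=3))
        genes = sorted(pathway.gene_ids())
        table, _ = make_expression_table(genes, ["T1"], 0.1, seed=3)
        before = pathway.copy()
        out, _ = tune_tissue(pathway, table, TuningConfig(tissue="T1"))
        assert pathway == before
        assert list(out.entries) == list(range(1, len(out.entries) + 1))

    def test_removed_entries_match_fixture_truth(self):
        pathway, _ = make_synthetic_pathway(
            FixtureSpec(seed=13, n_groups=0)
        )
        genes = sorted(pathway.gene_ids())
        table, truth = make_expression_table(genes, ["T1"], 0.1, seed=13)
        out, report = tune_tissue(pathway, table, TuningConfig(tissue="T1"))
        removed = {r.details["gene"] for r in report.records
                   if r.kind == "gene_removed"}
        assert removed == truth.silent_genes["T1"]
        assert out.gene_ids() == set(genes) - truth.silent_genes["T1"]


class TestPPITable:
    def test_read_table(self):
        text = ("gene_a\tgene_b\tscore\tsources\n"
                "hsa:1\thsa:2\t0.9\tGRID,MINT\n"
                "hsa:2\thsa:3\t0.4\tPDB\n")
        ppi = read_ppi_table(text)
        assert len(ppi) == 2
        assert ppi.supports("hsa:2", "hsa:1", 0.8, {"GRID"})
        assert not ppi.supports("hsa:2", "hsa:1", 0.8, {"PDB"})
        assert not ppi.supports("hsa:2", "hsa:3", 0.8, {"PDB"})

    def test_string_style_scores_rescaled(self, caplog):
        with caplog.at_level(logging.WARNING):
            ppi = PPITable([("a", "b", 900, {"GRID"}),
                            ("b", "c", 400, {"MINT"})])
        assert ppi.supports("a", "b", 0.8, {"GRID"})
        assert not ppi.supports("b", "c", 0.8, {"MINT"})
        assert any("1/1000" in rec.message for rec in caplog.records)

    def test_duplicate_pair_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            PPITable([("a", "b", 0.5, {"GRID"}), ("b", "a", 0.6, {"MINT"})])

    def test_self_interaction_rejected(self):
        with pytest.raises(ValueError, match="self"):
            PPITable([("a", "a", 0.5, {"GRID"})])


class TestDrillDown:
    def test_pair_filter_single_relation(self):
        p = build([(1, ["a", "b"], "gene"), (2, ["c"], "gene")],
                  [(1, 2, "PPrel")])
        ppi = PPITable([("a", "c", 0.9, {"GRID"}), ("b", "c", 0.5, {"GRID"})])
        out, report = drill_down_ppi(p, ppi, TuningConfig())
        kept = {(out.entries[r.entry1].names[0], out.entries[r.entry2].names[0])
                for r in out.relations}
        assert kept == {("a", "c")}
        assert out.gene_ids() == {"a", "c"}  # b isolated, removed
        assert report.count("isolated_removed") == 1

    def test_direction_inherited_from_pathway(self):
        p = build([(1, ["a"], "gene"), (2, ["b"], "gene")], [(2, 1, "PPrel")])
        ppi = PPITable([("a", "b", 0.9, {"GRID"})])
        out, _ = drill_down_ppi(p, ppi, TuningConfig())
        (rel,) = out.relations
        assert out.entries[rel.entry1].names == ["b"]
        assert out.entries[rel.entry2].names == ["a"]

    def test_edges_to_non_gene_entries_unfiltered(self):
        p = build([(1, ["a", "b"], "gene"), (2, ["cpd:C1"], "compound")],
                  [(1, 2, "PCrel")])
        ppi = PPITable([("a", "b", 0.1, {"GRID"})])
        out, _ = drill_down_ppi(p, ppi, TuningConfig())
        kept = {(out.entries[r.entry1].names[0], out.entries[r.entry2].names[0])
                for r in out.relations}
        assert kept == {("a", "cpd:C1"), ("b", "cpd:C1")}

    def test_duplicated_paralog_entry_merges_to_one(self):
        # a 3-gene paralog box duplicated at two map positions; PPI links
        # only v1 to both neighbors -> one merged v1 node with both edges
        p = build(
            [(1, ["n1"], "gene"), (2, ["v1", "v2", "v3"], "gene"),
             (3, ["v1", "v2", "v3"], "gene"), (4, ["n2"], "gene")],
            [(1, 2, "PPrel"), (3, 4, "PPrel")],
        )
        ppi = PPITable([("n1", "v1", 0.9, {"GRID"}),
                        ("v1", "n2", 0.9, {"MINT"}),
                        ("n1", "v2", 0.5, {"GRID"}),
                        ("v3", "n2", 0.5, {"GRID"})])
        out, report = drill_down_ppi(p, ppi, TuningConfig())
        assert out.gene_ids() == {"n1", "v1", "n2"}
        v1_entries = [e for e in out.entries.values() if e.names == ["v1"]]
        assert len(v1_entries) == 1
        v1 = v1_entries[0]
        incident = [r for r in out.relations
                    if v1.id in (r.entry1, r.entry2)]
        assert len(incident) == 2
        assert report.count("entries_merged") >= 1

    def test_merge_keeps_lowest_entry_graphics(self):
        p = build([(1, ["g"], "gene"), (5, ["g"], "gene"),
                   (2, ["h"], "gene")], [(1, 2, "PPrel"), (5, 2, "PPrel")])
        p.entries[1].graphics.x, p.entries[5].graphics.x = 111, 555
        ppi = PPITable([("g", "h", 0.9, {"GRID"})])
        out, _ = drill_down_ppi(p, ppi, TuningConfig())
        g_entry = next(e for e in out.entries.values() if e.names == ["g"])
        assert g_entry.graphics.x == 111

    def test_threshold_zero_complete_ppi_counting_oracle(self):
        pathway, _ = make_synthetic_pathway(
            FixtureSpec(seed=8, n_pcp_motifs=0, n_reversed_bindings=0,
                        n_groups=0, n_duplicated_entries=0, n_relations=15,
                        n_gene_entries=10)
        )
        genes = sorted(pathway.gene_ids())
        ppi, _ = make_ppi_table(genes, 1.0, (0.6,), seed=8)
        cfg = TuningConfig(ppi_score_threshold=0.0)
        out, _ = drill_down_ppi(pathway, ppi, cfg)
        expected = 0
        for r in pathway.relations:
            n1, n2 = pathway.entries[r.entry1], pathway.entries[r.entry2]
            if n1.is_gene and n2.is_gene:
                shared = len(set(n1.names) & set(n2.names))
                expected += len(n1.names) * len(n2.names) - shared
        gene_gene = [r for r in out.relations
                     if out.entries[r.entry1].is_gene
                     and out.entries[r.entry2].is_gene]
        assert len(gene_gene) == expected

    def test_every_edge_witnessed_by_parent_and_ppi(self):
        pathway, _ = make_synthetic_pathway(FixtureSpec(seed=21))
        genes = sorted(pathway.gene_ids())
        ppi, _ = make_ppi_table(genes, 0.4, (0.5, 0.9), seed=21)
        cfg = TuningConfig(ppi_score_threshold=0.8)
        out, _ = drill_down_ppi(pathway, ppi, cfg)
        parent_pairs = set()
        for r in pathway.relations:
            n1, n2 = pathway.entries[r.entry1], pathway.entries[r.entry2]
            if n1.is_gene and n2.is_gene:
                for u in n1.names:
                    for v in n2.names:
                        parent_pairs.add((u, v))
        for r in out.relations:
            e1, e2 = out.entries[r.entry1], out.entries[r.entry2]
            if e1.is_gene and e2.is_gene:
                pair = (e1.names[0], e2.names[0])
                assert pair in parent_pairs
                assert ppi.supports(pair[0], pair[1], 0.8, PPI_SOURCES)

    def test_no_isolated_gene_entries_in_output(self):
        pathway, _ = make_synthetic_pathway(FixtureSpec(seed=33))
        ppi, _ = make_ppi_table(sorted(pathway.gene_ids()), 0.2, (0.9,),
                                seed=33)
        out, _ = drill_down_ppi(pathway, ppi, TuningConfig())
        incident = set()
        for r in out.relations:
            incident.update((r.entry1, r.entry2))
        for e in out.entries.values():
            if e.is_gene:
                assert e.id in incident

    def test_empty_source_set_rejected(self):
        p = build([(1, ["a"], "gene")], [])
        ppi = PPITable([("a", "b", 0.5, {"GRID"})])
        with pytest.raises(ValueError, match="empty"):
            drill_down_ppi(p, ppi, TuningConfig(ppi_sources=frozenset()))

    def test_disjoint_sources_yield_no_gene_edges(self):
        p = build([(1, ["a"], "gene"), (2, ["b"], "gene")], [(1, 2, "PPrel")])
        ppi = PPITable([("a", "b", 0.9, {"MINT"})])
        out, _ = drill_down_ppi(p, ppi, TuningConfig(
            ppi_sources=frozenset({"PDB"})))
        assert out.relations == []


class TestTuneFull:
    def _inputs(self, seed=17):
        pathway, _ = make_synthetic_pathway(FixtureSpec(seed=seed))
        genes = sorted(pathway.gene_ids())
        table, etruth = make_expression_table(genes, ["T1"], 0.1, seed=seed)
        ppi, _ = make_ppi_table(genes, 0.5, (0.5, 0.9), seed=seed)
        return pathway, table, ppi, etruth

    def test_equals_manual_composition(self):
        pathway, table, ppi, _ = self._inputs()
        cfg = TuningConfig(tissue="T1")
        combined, _ = tune_full(pathway, table, ppi, cfg)
        step1, _ = tune_tissue(pathway, table, cfg)
        step2, _ = drill_down_ppi(step1, ppi, cfg)
        assert combined == step2

    def test_silent_gene_excluded_even_with_ppi_support(self):
        p = build([(1, ["a", "s"], "gene"), (2, ["b"], "gene")],
                  [(1, 2, "PPrel")])
        table = table_from([("a", (50,)), ("s", (1,)), ("b", (50,))], ["T"])
        ppi = PPITable([("s", "b", 0.95, {"GRID"}), ("a", "b", 0.95, {"GRID"})])
        cfg = TuningConfig(tissue="T", threshold_mode="absolute",
                           threshold_value=10)
        out, _ = tune_full(p, table, ppi, cfg)
        assert "s" not in out.gene_ids()
        assert out.gene_ids() == {"a", "b"}

    def test_permissive_thresholds_preserve_gene_set(self):
        pathway, _ = make_synthetic_pathway(
            FixtureSpec(seed=19, n_groups=0, n_duplicated_entries=0)
        )
        genes = sorted(pathway.gene_ids())
        table, _ = make_expression_table(genes, ["T1"], 0.0, seed=19)
        ppi, _ = make_ppi_table(genes, 1.0, (0.9,), seed=19)
        cfg = TuningConfig(tissue="T1", ppi_score_threshold=0.0)
        out, _ = tune_full(pathway, table, ppi, cfg)
        connected = set()
        for r in pathway.relations:
            for eid in (r.entry1, r.entry2):
                entry = pathway.entries[eid]
                if entry.is_gene:
                    connected.update(entry.names)
        assert out.gene_ids() == connected


class TestMonotonicity:
    @pytest.mark.parametrize("seed", [2, 4])
    def test_tissue_threshold_nesting(self, seed):
        pathway, _ = make_synthetic_pathway(FixtureSpec(seed=seed, n_groups=0))
        genes = sorted(pathway.gene_ids())
        table, _ = make_expression_table(genes, ["T1"], 0.1, seed=seed)
        previous = None
        for pct in (0, 25, 50, 75, 100):
            cfg = TuningConfig(tissue="T1", threshold_value=pct)
            out, _ = tune_tissue(pathway, table, cfg)
            current = out.gene_ids()
            if previous is not None:
                assert current <= previous
            previous = current

    @pytest.mark.parametrize("seed", [2, 4])
    def test_ppi_score_threshold_nesting(self, seed):
        pathway, _ = make_synthetic_pathway(FixtureSpec(seed=seed))
        genes = sorted(pathway.gene_ids())
        ppi, _ = make_ppi_table(genes, 0.6, (0.2, 0.5, 0.9), seed=seed)

        def gene_edges(threshold):
            out, _ = drill_down_ppi(
                pathway, ppi, TuningConfig(ppi_score_threshold=threshold))
            return {(out.entries[r.entry1].names[0],
                     out.entries[r.entry2].names[0])
                    for r in out.relations
                    if out.entries[r.entry1].is_gene
                    and out.entries[r.entry2].is_gene}

        previous = None
        for thr in (0.0, 0.25, 0.5, 0.75, 1.0):
            current = gene_edges(thr)
            if previous is not None:
                assert current <= previous
            previous = current

    def test_enlarging_sources_never_shrinks_edges(self):
        pathway, _ = make_synthetic_pathway(FixtureSpec(seed=6))
        genes = sorted(pathway.gene_ids())
        ppi, _ = make_ppi_table(genes, 0.6, (0.9,),
                                sources=("GRID", "MINT", "PDB"), seed=6)

        def n_edges(sources):
            out, _ = drill_down_ppi(pathway, ppi, TuningConfig(
                ppi_score_threshold=0.8, ppi_sources=frozenset(sources)))
            return len(out.relations)

        assert n_edges({"GRID"}) <= n_edges({"GRID", "MINT"}) \
            <= n_edges({"GRID", "MINT", "PDB"})
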