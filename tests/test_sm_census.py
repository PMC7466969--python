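import logging

import dendropy
import numpy as np
import pandas as pd
import pytest

from hgtcensus import reference, sm_census as sm
from hgtcensus.io_formats import DomainHit


class TestMerge:
    def _tables(self):
        anti = pd.DataFrame(
            [
                {"gene_id": "g1", "genome_id": "G", "sm_class": "NRPS"},
                {"gene_id": "g2", "genome_id": "G", "sm_class": "PKS"},
                {"gene_id": "g3", "genome_id": "G", "sm_class": "TC"},
            ]
        )
        smurf = pd.DataFrame(
            [
                {"gene_id": "g1", "genome_id": "G", "sm_class": "NRPS"},
                {"gene_id": "g2", "genome_id": "G", "sm_class": "PKS-like"},  # conflict
                {"gene_id": "g4", "genome_id": "G", "sm_class": "NRPS-like"},
                {"gene_id": "g5", "genome_id": "G", "sm_class": "DMAT"},
            ]
        )
        return anti, smurf

    def test_union_sources_and_conflict(self, caplog):
        anti, smurf = self._tables()
        with caplog.at_level(logging.WARNING):
            merged = {g.gene_id: g for g in sm.merge_sm_predictions(anti, smurf)}
        assert len(merged) == 5
        assert merged["g1"].source == "both"
        assert merged["g4"].source == "smurf"  # SMURF-only genes are retained
        assert merged["g2"].sm_class == "PKS" and merged["g2"].source == "both"
        assert "conflict" in caplog.text

    def test_unknown_class_rejected(self):
        bad = pd.DataFrame([{"gene_id": "g", "genome_id": "G", "sm_class": "laccase"}])
        with pytest.raises(ValueError, match="NRPS"):
            sm.merge_sm_predictions(bad, bad.iloc[:0])


class TestCensusTables:
    def test_pooled_counts_match_published_table(self):
        ledger = reference.build_census_ledger()
        table = sm.tabulate_sm_counts(ledger)
        row = table.loc["B. meristosporus CBS 931.73"]
        assert (
            row["Total SM"], row["NRPS/NRPS-like"], row["PKS/PKS-like"],
            row["NRPS-PKS hybrids"], row["TC"],
        ) == (44, 30, 4, 0, 10)
        expected = reference.load_sm_core_counts()
        for isolate in expected.index:
            assert table.loc[isolate, "Total SM"] == expected.loc[isolate, "total_sm"]

    def test_empty_ledger(self):
        assert sm.tabulate_sm_counts([]).empty

    def test_totals_conserved(self):
        ledger = reference.build_census_ledger()
        table = sm.tabulate_sm_counts(ledger)
        pools = ["NRPS/NRPS-like", "PKS/PKS-like", "NRPS-PKS hybrids", "TC"]
        assert (table[pools].sum(axis=1) == table["Total SM"]).all()

    def test_crosstab_reproduces_consistent_published_cells(self):
        ledger = reference.build_census_ledger()
        crosstab, non_sm = sm.crosstab_hgt(ledger, reference.hgt_gene_ids())
        assert non_sm == []
        b8920 = "B. heterosporus B8920"
        assert crosstab.loc[b8920, ("NRPS/NRPS-like", "hgt")] == 7
        assert crosstab.loc[b8920, ("NRPS/NRPS-like", "total")] == 18
        assert crosstab.loc[b8920, ("Total SM", "hgt")] == 7
        b9252 = "B. meristosporus B9252"
        assert crosstab.loc[b9252, ("Total SM", "hgt")] == 12
        assert crosstab.loc[b9252, ("NRPS/NRPS-like", "hgt")] == 9
        assert crosstab.loc[b9252, ("PKS/PKS-like", "hgt")] == 1
        assert crosstab.loc[b9252, ("TC", "hgt")] == 2
        # numerators never exceed denominators; class cells sum to the total
        for genome in crosstab.index:
            total = 0
            for pool in ("NRPS/NRPS-like", "PKS/PKS-like", "NRPS-PKS hybrids", "TC"):
                assert crosstab.loc[genome, (pool, "hgt")] <= crosstab.loc[genome, (pool, "total")]
                total += crosstab.loc[genome, (pool, "hgt")]
            assert total == crosstab.loc[genome, ("Total SM", "hgt")]

    def test_crosstab_percent_recomputed(self):
        # the printed "2/6 (1.4%)" cell is inconsistent; counts govern
        ledger = reference.build_census_ledger()
        crosstab, _ = sm.crosstab_hgt(ledger, reference.hgt_gene_ids())
        pct = crosstab.loc["B. meristosporus B9252", ("TC", "percent")]
        assert pct == pytest.approx(100 * 2 / 6)
        formatted = sm.format_crosstab(crosstab)
        assert formatted.loc["B. meristosporus B9252", "TC"] == "2/6 (33%)"

    def test_empty_hgt_set(self):
        ledger = reference.build_census_ledger()
        crosstab, _ = sm.crosstab_hgt(ledger, set())
        assert (crosstab.xs("hgt", axis=1, level=1) == 0).all().all()

    def test_non_sm_hgt_bucket(self):
        ledger = reference.build_census_ledger()
        _, non_sm = sm.crosstab_hgt(ledger, {"not_an_sm_gene"})
        assert non_sm == ["not_an_sm_gene"]


class TestCladeAssignment:
    def _tree(self, newick):
        return dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)

    def test_query_inside_reference_mrca(self):
        tree = self._tree("((rA1,(rA2,q1)),(rB1,rB2));")
        defs = [sm.CladeDefinition("A", frozenset({"rA1", "rA2"}))]
        assert sm.assign_clades(tree, defs, ["q1"]) == {"q1": "A"}

    def test_query_outside_every_clade_unassigned(self):
        tree = self._tree("(((rA1,rA2),q1),(rB1,rB2));")
        defs = [
            sm.CladeDefinition("A", frozenset({"rA1", "rA2"})),
            sm.CladeDefinition("B", frozenset({"rB1", "rB2"})),
        ]
        assert sm.assign_clades(tree, defs, ["q1"])["q1"] == "unassigned"

    def test_smallest_containing_clade_wins(self):
        tree = self._tree("((((rA1,(rA2,q1)),rC1),(rB1,rB2)),out);")
        defs = [
            sm.CladeDefinition("big", frozenset({"rC1", "rB1"})),
            sm.CladeDefinition("small", frozenset({"rA1", "rA2"})),
        ]
        assert sm.assign_clades(tree, defs, ["q1"])["q1"] == "small"

    def test_missing_reference_tip_named(self):
        tree = self._tree("((a,b),(c,d));")
        defs = [sm.CladeDefinition("X", frozenset({"a", "ghost"}))]
        with pytest.raises(ValueError, match="ghost"):
            sm.assign_clades(tree, defs, ["c"])

    def test_tip_order_permutation_invariant(self):
        defs = [
            sm.CladeDefinition("A", frozenset({"rA1", "rA2"})),
            sm.CladeDefinition("B", frozenset({"rB1", "rB2"})),
        ]
        variants = [
            "((rA1,(rA2,q1)),((rB1,rB2),out));",
            "(((q1,rA2),rA1),((rB2,rB1),out));",
            "((out,(rB1,rB2)),((rA2,q1),rA1));",
        ]
        results = [
            sm.assign_clades(self._tree(v), defs, ["q1"], outgroup_tips=["out"])
            for v in variants
        ]
        assert all(r == {"q1": "A"} for r in results)

    def test_rerooting_along_outgroup_edge_invariant(self):
        defs = [sm.CladeDefinition("B", frozenset({"rB1", "rB2"}))]
        rooted_variants = [
            "(((rA1,rA2),((rB1,rB2),q1)),out);",
            "(out,((rA1,rA2),((rB2,rB1),q1)));",
        ]
        for v in rooted_variants:
            got = sm.assign_clades(self._tree(v), defs, ["q1"], outgroup_tips=["out"])
            assert got == {"q1": "unassigned"}

    def test_abundance_matrix_row_sums(self):
        assignments = {"q1": "X", "q2": "X", "q3": "unassigned", "q4": "Y"}
        genome_of = {"q1": "G1", "q2": "G1", "q3": "G1", "q4": "G2"}
        mat = sm.clade_abundance_matrix(assignments, genome_of)
        assert mat.loc["G1", "X"] == 2 and mat.loc["G1", "unassigned"] == 1
        counts = pd.Series(genome_of).value_counts()
        assert (mat.sum(axis=1) == counts[mat.index]).all()

    def test_empty_assignment(self):
        assert sm.clade_abundance_matrix({}, {}).empty


class TestDomains:
    def test_architecture_fractions(self):
        hits = [
            DomainHit("p", "A", (100, 300), 50.0),
            DomainHit("p", "A", (500, 700), 60.0),
        ]
        layout = sm.domain_architecture(1000, hits)
        assert [(d["start_frac"], d["end_frac"]) for d in layout] == [
            (0.1, 0.3), (0.5, 0.7),
        ]

    def test_full_length_domain(self):
        (d,) = sm.domain_architecture(200, [DomainHit("p", "A", (0, 200), 10.0)])
        assert (d["start_frac"], d["end_frac"]) == (0.0, 1.0)

    def test_tetramodular_layout_ordered(self):
        hits = [
            DomainHit("p", "A-domain", (s, s + 150), 40.0 + s / 100)
            for s in (1300, 100, 900, 500)
        ]
        layout = sm.domain_architecture(1600, hits)
        assert len(layout) == 4
        starts = [d["start_frac"] for d in layout]
        assert starts == sorted(starts)

    def test_overlap_keeps_higher_score(self, caplog):
        hits = [
            DomainHit("p", "A", (100, 300), 80.0),
            DomainHit("p", "A", (250, 400), 30.0),
        ]
        with caplog.at_level(logging.WARNING):
            layout = sm.domain_architecture(500, hits)
        assert len(layout) == 1 and layout[0]["score"] == 80.0
        assert "overlap" in caplog.text

    def test_presence_matrix(self):
        hits = [
            DomainHit("g1", "KS", (0, 100), 50.0),
            DomainHit("g1", "AT", (150, 250), 50.0),
            DomainHit("g3", "KS", (0, 100), 50.0),
            DomainHit("g3", "KR", (120, 200), 50.0),
            DomainHit("g3", "PP", (300, 350), 50.0),
            DomainHit("g4", "AT", (0, 80), 50.0),
        ]
        mat = sm.domain_presence_matrix(["g1", "g2", "g3", "g4", "g5"], hits)
        assert mat.loc["g1"].tolist() == [True, True, False, False, False]
        assert not mat.loc["g2"].any()
        assert mat.loc["g3", ["KS", "KR", "PP"]].all() and not mat.loc["g3", "AT"]
        assert mat.values.sum() == 6


class TestExpression:
    def test_tpm_arithmetic(self):
        tpm = sm.tpm_normalize(
            pd.Series({"a": 10, "b": 10}), pd.Series({"a": 1000, "b": 2000})
        )
        assert tpm["a"] == pytest.approx(666666.67, abs=0.01)
        assert tpm["b"] == pytest.approx(333333.33, abs=0.01)

    def test_single_expressed_gene(self):
        tpm = sm.tpm_normalize(
            pd.Series({"a": 5, "b": 0}), pd.Series({"a": 500, "b": 900})
        )
        assert tpm["a"] == pytest.approx(1e6)

    def test_sum_is_one_million(self):
        rng = np.random.default_rng(13)
        counts = pd.Series(rng.integers(0, 1000, size=100).astype(float))
        lengths = pd.Series(rng.integers(200, 5000, size=100).astype(float))
        total = sm.tpm_normalize(counts, lengths).sum()
        assert total == pytest.approx(1e6, rel=1e-6)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            sm.tpm_normalize(pd.Series({"a": 0.0}), pd.Series({"a": 100.0}))

    def test_report_flags_and_ranks(self, caplog):
        tpm = pd.Series({"sm1": 74.03, "sm2": 0.0, "hk1": 10.0, "hk2": 30.0, "x": 5.0})
        ledger = [
            sm.SmCoreGene("sm1", "G", "NRPS"),
            sm.SmCoreGene("sm2", "G", "TC"),
        ]
        with caplog.at_level(logging.WARNING):
            report = sm.expression_report(tpm, ledger, ["hk1", "hk2", "missing_hk"])
        report = report.set_index("gene_id")
        assert report.loc["sm1", "expressed_at_housekeeping_level"]
        assert not report.loc["sm2", "expressed_at_housekeeping_level"]
        # ranks follow descending-TPM sort order
        order = tpm.sort_values(ascending=False).index.tolist()
        assert report.loc["sm1", "rank"] == order.index("sm1") + 1
        assert "missing_hk" in caplog.text

    def test_no_housekeeping_present_rejected(self):
        with pytest.raises(ValueError):
            sm.expression_report(
                pd.Series({"a": 1.0}), [sm.SmCoreGene("a", "G", "TC")], ["nope"]
            )
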