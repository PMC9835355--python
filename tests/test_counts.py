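import pandas as pd
import pytest

from commscope.counts import (AnnotationTable, CountTable, UNASSIGNED,
                              assign_contig_taxonomy, bin_counts,
                              contig_consistency, ec_taxon_distribution,
                              filter_low_counts, merge_tables, parse_lineage)


def make_annotation(rows, samples=("s1",)):
    """rows: (gene, contig, genus, ec, ko, counts per sample)."""
    recs = []
    for gene, contig, genus, ec, ko, *cts in rows:
        rec = {"gene_id": gene, "contig_id": contig, "ec": ec, "ko": ko}
        for rank in ("phylum", "class", "order", "family", "genus", "species"):
            rec[f"tax_{rank}"] = ""
        rec["tax_genus"] = genus
        rec.update(dict(zip(samples, cts)))
        recs.append(rec)
    return AnnotationTable(df=pd.DataFrame(recs), samples=list(samples))


def make_design(samples, treatment="T"):
    return pd.DataFrame(
        {"treatment": [treatment] * len(samples),
         "replicate": [str(i + 1) for i in range(len(samples))]},
        index=pd.Index(samples, name="sample"),
    )


class TestContigTaxonomy:
    def test_majority_rule(self):
        t = make_annotation([
            ("g1", "c1", "X", "", "", 0),
            ("g2", "c1", "X", "", "", 0),
            ("g3", "c1", "Y", "", "", 0),
        ])
        assert assign_contig_taxonomy(t, "genus") == {"c1": "X"}

    def test_single_annotated_gene(self):
        t = make_annotation([("g1", "c1", "Z", "", "", 0)])
        assert assign_contig_taxonomy(t, "genus") == {"c1": "Z"}

    def test_tie_breaks_lexicographically_and_is_row_order_invariant(self):
        rows = [("g1", "c1", "Y", "", "", 0), ("g2", "c1", "X", "", "", 0)]
        for order in (rows, rows[::-1]):
            t = make_annotation(order)
            assert assign_contig_taxonomy(t, "genus") == {"c1": "X"}

    def test_unannotated_contig_maps_to_unassigned(self):
        t = make_annotation([("g1", "c1", "", "", "", 0)])
        assert assign_contig_taxonomy(t, "genus") == {"c1": UNASSIGNED}

    def test_consistency_statistic(self):
        t = make_annotation([
            ("g1", "c1", "X", "", "", 0), ("g2", "c1", "X", "", "", 0),
            ("g3", "c2", "X", "", "", 0), ("g4", "c2", "Y", "", "", 0),
        ])
        assert contig_consistency(t, "genus") == 0.5

    def test_unsupported_rank_rejected(self):
        t = make_annotation([("g1", "c1", "X", "", "", 0)])
        with pytest.raises(ValueError, match="rank"):
            assign_contig_taxonomy(t, "kingdom")


class TestBinning:
    def test_counts_are_additive_under_the_ec_key(self):
        t = make_annotation([
            ("g1", "c1", "X", "e1", "", 2),
            ("g2", "c1", "X", "e1", "", 3),
            ("g3", "c2", "Y", "e2", "", 5),
        ])
        ct = bin_counts(t, "EC", make_design(["s1"]))
        assert ct.matrix.loc["e1", "s1"] == 5
        assert ct.matrix.loc["e2", "s1"] == 5

    def test_missing_key_rows_pool_into_unassigned_conserving_mass(self):
        t = make_annotation([
            ("g1", "c1", "X", "e1", "", 2),
            ("g2", "c1", "X", "e1", "", 3),
            ("g3", "c2", "Y", "e2", "ko3", 5),
        ])
        ct = bin_counts(t, "KO", make_design(["s1"]))
        assert ct.matrix.loc["ko3", "s1"] == 5
        assert ct.matrix.loc[UNASSIGNED, "s1"] == 5
        assert ct.matrix["s1"].sum() == t.df["s1"].sum()

    def test_binning_is_row_order_invariant(self):
        rows = [("g1", "c1", "X", "e1", "", 2), ("g2", "c2", "Y", "e2", "", 7)]
        a = bin_counts(make_annotation(rows), "EC", make_design(["s1"]))
        b = bin_counts(make_annotation(rows[::-1]), "EC", make_design(["s1"]))
        pd.testing.assert_frame_equal(a.matrix, b.matrix)

    def test_taxon_binning_via_contig_majority(self):
        t = make_annotation([
            ("g1", "c1", "X", "", "", 4),
            ("g2", "c1", "X", "", "", 1),
            ("g3", "c1", "Y", "", "", 1),
        ])
        ct = bin_counts(t, "taxon", make_design(["s1"]), rank="genus",
                        use_contig_taxonomy=True)
        assert ct.matrix.loc["X", "s1"] == 6  # whole contig inherits X

    def test_unknown_key_scheme_rejected(self):
        t = make_annotation([("g1", "c1", "X", "", "", 0)])
        with pytest.raises(ValueError, match="key_scheme"):
            bin_counts(t, "pfam", make_design(["s1"]))


class TestMergeAndFilter:
    def _table(self, samples, features_counts, treatment):
        mat = pd.DataFrame(features_counts, columns=samples)
        mat.index.name = "feature"
        return CountTable("EC", mat, make_design(samples, treatment))

    def test_merge_unions_features_and_fills_zeros(self):
        a = self._table(["s1"], {"s1": {"e1": 3}}, "T")
        b = self._table(["s2"], {"s2": {"e2": 4}}, "C")
        merged = merge_tables([a, b])
        assert merged.matrix.loc["e1", "s2"] == 0
        assert merged.matrix.loc["e2", "s1"] == 0
        assert merged.matrix.to_numpy().sum() == 7

    def test_merge_single_table_is_identity(self):
        a = self._table(["s1"], {"s1": {"e1": 3}}, "T")
        pd.testing.assert_frame_equal(merge_tables([a]).matrix, a.matrix)

    def test_duplicate_sample_ids_rejected(self):
        a = self._table(["s1"], {"s1": {"e1": 3}}, "T")
        with pytest.raises(ValueError, match="duplicate"):
            merge_tables([a, a])

    def test_low_count_filter(self):
        a = self._table(["s1"], {"s1": {"e1": 60, "e2": 10}}, "T")
        assert list(filter_low_counts(a, 50).matrix.index) == ["e1"]


def test_ec_taxon_distribution_sums_reads_per_taxon(default_synth):
    _, _, _, table, _ = default_synth
    dist = ec_taxon_distribution(table, "genus")
    assert set(dist.columns) == {"ec", "taxon", "sample", "count"}
    # total EC-annotated reads are conserved
    annotated = table.df[table.df["ec"].astype(bool)]
    assert dist["count"].sum() == annotated[table.samples].to_numpy().sum()


def test_lineage_parser_handles_partial_lineages():
    assert parse_lineage("genus:G01;order:O01") == {"genus": "G01", "order": "O01"}
    assert parse_lineage("") == {}
    assert parse_lineage(float("nan")) == {}
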