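"""OTU table I/O, rarefaction, alpha diversity, Venn partitions, group tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from wormnet.community import (GroupComparison, OtuTable, OtuTableError,
                               SampleMetadata, alpha_diversity, depth_report,
                               group_compare, group_label, normalize_lineage,
                               rarefy, read_otu_table, round_half_up,
                               venn_partition, write_otu_table)


class TestOtuTableIO:
    def test_round_trip_identity(self, small_table, tmp_path):
        path = tmp_path / "table.tsv"
        write_otu_table(small_table, path)
        back = read_otu_table(path)
        assert back.otu_ids == small_table.otu_ids
        assert back.sample_ids == small_table.sample_ids
        assert np.array_equal(back.counts, small_table.counts)
        assert back.lineages == small_table.lineages

    def test_negative_cell_names_offender(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("#OTU_ID\ts1\ts2\nO1\t3\t-4\n")
        with pytest.raises(OtuTableError, match="O1.*s2"):
            read_otu_table(path)

    def test_non_integer_cell_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("#OTU_ID\ts1\nO1\t2.5\n")
        with pytest.raises(OtuTableError, match="non-integer"):
            read_otu_table(path)

    def test_missing_taxonomy_column_gives_empty_ranks(self, tmp_path):
        path = tmp_path / "plain.tsv"
        path.write_text("#OTU_ID\ts1\nO1\t3\n")
        table = read_otu_table(path)
        assert table.lineages == [";" * 6]

    @pytest.mark.parametrize("raw,expected", [
        ("Bacteria;Proteobacteria", "Bacteria;Proteobacteria;;;;;"),
        ("", ";;;;;;"),
        ("a;b;c;d;e;f;g;h", "a;b;c;d;e;f;g"),
        ("a; b ;c", "a;b;c;;;;"),
    ])
    def test_lineage_normalized_to_seven_ranks(self, raw, expected):
        assert normalize_lineage(raw) == expected
        assert normalize_lineage(raw).count(";") == 6

    def test_duplicate_ids_rejected(self):
        with pytest.raises(OtuTableError, match="duplicate"):
            OtuTable(otu_ids=["A", "A"], sample_ids=["s"],
                     counts=np.array([[1], [2]]))


class TestRarefy:
    def test_column_sums_exactly_at_depth(self, small_table):
        rare = rarefy(small_table, depth=3, seed=1)
        assert (rare.counts.sum(axis=0) == 3).all()
        assert (rare.counts <= small_table.counts).all()

    def test_exhaustive_draw_returns_column_unchanged(self):
        table = OtuTable(otu_ids=["A", "B"], sample_ids=["s1"],
                         counts=np.array([[4], [6]]))
        rare = rarefy(table, depth=10, seed=0)
        assert np.array_equal(rare.counts, table.counts)

    def test_same_seed_identical(self, small_table):
        a = rarefy(small_table, 3, seed=9)
        b = rarefy(small_table, 3, seed=9)
        assert np.array_equal(a.counts, b.counts)

    def test_depth_above_total_lists_offenders(self, small_table):
        with pytest.raises(ValueError, match="s2"):
            rarefy(small_table, depth=11, seed=0)

    def test_hypergeometric_expectation(self):
        # 50/50 OTU: mean rarefied proportion over many seeds stays at 0.5
        table = OtuTable(otu_ids=["A", "B"], sample_ids=["s"],
                         counts=np.array([[500], [500]]))
        props = [rarefy(table, 100, seed=s).counts[0, 0] / 100
                 for s in range(1000)]
        n, big_n = 100, 1000
        sd_one = np.sqrt(0.25 / n * (big_n - n) / (big_n - 1))
        assert abs(np.mean(props) - 0.5) < 3 * sd_one / np.sqrt(len(props))


class TestAlphaDiversity:
    @staticmethod
    def _table(counts):
        arr = np.asarray(counts)[:, None]
        return OtuTable(otu_ids=[f"O{i}" for i in range(arr.shape[0])],
                        sample_ids=["s"], counts=arr)

    def test_uniform_composition(self):
        res = alpha_diversity(self._table([10, 10, 10, 10]))
        row = res.loc["s"]
        assert row["shannon"] == pytest.approx(np.log(4), abs=1e-12)
        assert row["evenness"] == pytest.approx(1.0, abs=1e-12)
        assert row["richness"] == 4

    def test_chao1_with_singletons_and_doubletons(self):
        # F1 = 2, F2 = 1 -> chao1 = 4 + 4/2 = 6
        res = alpha_diversity(self._table([1, 1, 2, 3]))
        assert res.loc["s", "chao1"] == pytest.approx(6.0, abs=1e-12)

    def test_single_taxon_sample(self):
        res = alpha_diversity(self._table([42]))
        row = res.loc["s"]
        assert row["shannon"] == 0.0
        assert row["chao1"] == 1.0
        assert np.isnan(row["evenness"])

    def test_zero_rows_change_nothing(self):
        a = alpha_diversity(self._table([5, 3, 2]))
        b = alpha_diversity(self._table([5, 3, 2, 0, 0]))
        for col in ("shannon", "chao1", "evenness"):
            assert a.loc["s", col] == pytest.approx(b.loc["s", col], abs=1e-12)
        assert a.loc["s", "richness"] == b.loc["s", "richness"]

    def test_chao1_equals_richness_without_singletons(self):
        res = alpha_diversity(self._table([4, 2, 3, 5]))
        assert res.loc["s", "chao1"] == res.loc["s", "richness"]

    def test_all_zero_sample_rejected(self):
        table = OtuTable(otu_ids=["A"], sample_ids=["s1", "s2"],
                         counts=np.array([[3, 0]]))
        with pytest.raises(ValueError, match="all-zero"):
            alpha_diversity(table)

    def test_unequal_depths_warn(self):
        table = OtuTable(otu_ids=["A", "B"], sample_ids=["s1", "s2"],
                         counts=np.array([[3, 9], [4, 2]]))
        with pytest.warns(UserWarning, match="depth"):
            alpha_diversity(table)

    def test_matches_scikit_bio(self):
        skbio_alpha = pytest.importorskip("skbio.diversity.alpha")
        counts = np.array([5, 1, 1, 2, 9, 3])
        res = alpha_diversity(self._table(counts)).loc["s"]
        assert res["shannon"] == pytest.approx(
            float(skbio_alpha.shannon(counts, base=np.e)), abs=1e-10)
        assert res["chao1"] == pytest.approx(
            float(skbio_alpha.chao1(counts, bias_corrected=False)), abs=1e-10)
        assert res["evenness"] == pytest.approx(
            float(skbio_alpha.pielou_e(counts)), abs=1e-10)


class TestVenn:
    @staticmethod
    def _bundle(counts_a, counts_b):
        n = len(counts_a)
        table = OtuTable(
            otu_ids=[f"O{i}" for i in range(n)],
            sample_ids=["HMs_1", "HMs_2", "HMe_1", "HMe_2"],
            counts=np.column_stack([counts_a, counts_a, counts_b, counts_b]),
        )
        meta = SampleMetadata(pd.DataFrame({
            "sample_id": table.sample_ids,
            "habitat": ["soil", "soil", "gut", "gut"],
            "treatment": "HM",
        }))
        return table, meta

    def test_identical_groups_share_everything(self):
        table, meta = self._bundle([1, 2, 3], [4, 5, 6])
        part = venn_partition(table, meta, "HMs", "HMe")
        assert part.shared_pct_reported == 100.0
        assert not part.unique_a and not part.unique_b

    def test_disjoint_groups_share_nothing(self):
        table, meta = self._bundle([1, 1, 0, 0], [0, 0, 1, 1])
        part = venn_partition(table, meta, "HMs", "HMe")
        assert part.shared_pct == 0.0
        assert len(part.unique_a) == 2 and len(part.unique_b) == 2

    def test_partition_is_exact_and_symmetric(self):
        table, meta = self._bundle([1, 1, 0, 3, 0], [0, 1, 2, 3, 0])
        ab = venn_partition(table, meta, "HMs", "HMe")
        ba = venn_partition(table, meta, "HMe", "HMs")
        assert ab.shared == ba.shared
        assert ab.unique_a == ba.unique_b and ab.unique_b == ba.unique_a
        union = ab.shared | ab.unique_a | ab.unique_b
        assert len(union) == ab.union_size == 4  # O4 absent everywhere

    def test_unknown_group_label(self):
        table, meta = self._bundle([1], [1])
        with pytest.raises(KeyError):
            venn_partition(table, meta, "HMs", "nope")


def test_round_half_up_matches_reported_style():
    assert round_half_up(15.688, 1) == 15.7
    assert round_half_up(7.85, 1) == 7.9  # half goes up, unlike bankers'
    assert round_half_up(24201.9167, 0) == 24202


def test_group_label_derivation():
    assert group_label("soil", "HM") == "HMs"
    assert group_label("gut", "HML") == "HMLe"
    with pytest.raises(ValueError):
        group_label("water", "HM")


class TestDepthReport:
    def test_per_habitat_means(self, four_group_meta):
        # soil columns sum to 4x6000, gut to 4x9001 -> means 6000 / 9001
        sids = four_group_meta.sample_ids
        soil = four_group_meta.df["habitat"] == "soil"
        counts = np.array([[6000 if soil[s] else 9001 for s in sids]])
        table = OtuTable(otu_ids=["O1"], sample_ids=sids, counts=counts)
        rep = depth_report(table, four_group_meta)
        assert rep.loc["soil", "mean_reads"] == 6000
        assert rep.loc["gut", "mean_reads"] == 9001
        assert rep.loc["soil", "total_reads"] == 24000


class TestGroupCompare:
    def test_identical_values_yield_no_difference(self, four_group_meta):
        values = pd.Series(1.0, index=four_group_meta.sample_ids)
        res = group_compare(values, four_group_meta)
        assert res.anova_p == 1.0
        assert set(res.letters.values()) == {"a"}

    def test_large_effect_group_gets_distinct_letter(self):
        rng = np.random.default_rng(5)
        rows, values = [], {}
        for g, mean in (("HM", 0.0), ("HML", 0.0), ("X", 5.0)):
            for r in range(4):
                sid = f"{g}_{r}"
                rows.append({"sample_id": sid, "habitat": "soil", "treatment": g})
                values[sid] = mean + 0.1 * rng.standard_normal()
        meta = SampleMetadata(pd.DataFrame(rows))
        res = group_compare(pd.Series(values), meta, by="treatment")
        assert isinstance(res, GroupComparison)
        assert res.letters["X"] != res.letters["HM"]
        assert res.letters["HM"] == res.letters["HML"]

    def test_tukey_matches_statsmodels(self):
        smstats = pytest.importorskip("statsmodels.stats.multicomp")
        rng = np.random.default_rng(1)
        vals = np.concatenate([rng.normal(0, 1, 5), rng.normal(1, 1, 6),
                               rng.normal(3, 1, 4)])
        labels = ["a"] * 5 + ["b"] * 6 + ["c"] * 4
        meta = SampleMetadata(pd.DataFrame({
            "sample_id": [f"s{i}" for i in range(15)],
            "habitat": "soil", "treatment": labels}))
        ours = group_compare(pd.Series(vals, index=meta.sample_ids), meta,
                             by="treatment")
        ref = smstats.pairwise_tukeyhsd(vals, labels)
        assert np.allclose(ours.tukey["p_adj"].to_numpy(), ref.pvalues, atol=1e-9)

    def test_single_sample_group_rejected(self):
        meta = SampleMetadata(pd.DataFrame({
            "sample_id": ["x1", "x2", "y1"], "habitat": "soil",
            "treatment": ["A", "A", "B"]}))
        with pytest.raises(ValueError, match="fewer than 2"):
            group_compare(pd.Series([1.0, 2.0, 3.0], index=meta.sample_ids),
                          meta, by="treatment")


@settings(max_examples=30, deadline=None)
@given(st.lists(st.integers(min_value=0, max_value=50), min_size=2, max_size=8)
       .filter(lambda c: sum(c) >= 5),
       st.integers(min_value=0, max_value=2**31 - 1))
def test_rarefaction_conserves_and_never_inflates(counts, seed):
    table = OtuTable(otu_ids=[f"O{i}" for i in range(len(counts))],
                     sample_ids=["s"], counts=np.asarray(counts)[:, None])
    rare = rarefy(table, 5, seed=seed)
    assert rare.counts.sum() == 5
    assert (rare.counts[:, 0] <= np.asarray(counts)).all()
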