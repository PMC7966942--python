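"""OTU table I/O, rarefaction, filtering, summaries, compositions."""

import numpy as np
import pandas as pd
import pytest

from rarecohort import (
    DataError,
    OtuTable,
    aggregate_composition,
    classify_taxa,
    CohortThresholds,
    compare_compositions,
    rarefy,
    read_otu_table,
    remove_singletons,
    summarize_taxa,
    write_otu_table,
)
from conftest import random_table


class TestReadWrite:
    def test_parse_classic_layout_with_taxonomy(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text(
            "otu\tS1\tS2\ttaxonomy\n"
            "t1\t3\t0\tBacteria;Proteobacteria;Betaproteobacteria\n"
            "t2\t1\t2\tBacteria;Bacteroidetes\n"
            "t3\t0\t5\tBacteria\n"
        )
        table = read_otu_table(path)
        assert table.n_samples == 2 and table.n_taxa == 3
        assert table.counts.loc["S2", "t3"] == 5
        assert all(len(v) <= 7 for v in table.taxonomy.values())
        assert table.taxonomy["t1"][2] == "Betaproteobacteria"

    def test_duplicate_taxon_id_error_names_id(self, tmp_path):
        path = tmp_path / "dup.tsv"
        path.write_text("otu\tS1\nt1\t3\nt1\t4\n")
        with pytest.raises(DataError, match="t1"):
            read_otu_table(path)

    def test_unparseable_count_is_error(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("otu\tS1\nt1\tthree\n")
        with pytest.raises(DataError):
            read_otu_table(path)

    def test_metadata_mismatch_error(self, tmp_path, tiny_table):
        write_otu_table(tiny_table, tmp_path / "t.tsv")
        (tmp_path / "m.tsv").write_text(
            "sample_id\tdate\nS1\t2005-05-01\nS9\t2005-07-01\nS3\t2005-09-01\n"
        )
        with pytest.raises(DataError, match="S9"):
            read_otu_table(tmp_path / "t.tsv", tmp_path / "m.tsv")

    def test_round_trip_lossless(self, tmp_path, rng):
        counts = pd.DataFrame(
            rng.poisson(5, size=(12, 50)),
            index=[f"S{i}" for i in range(12)],
            columns=[f"T{j}" for j in range(50)],
        )
        tax = {f"T{j}": ("Bacteria", f"Phylum{j % 5}") for j in range(50)}
        table = OtuTable(counts, taxonomy=tax)
        write_otu_table(table, tmp_path / "t.tsv")
        back = read_otu_table(tmp_path / "t.tsv")
        pd.testing.assert_frame_equal(back.counts, counts, check_dtype=False)
        assert back.taxonomy == tax

    def test_dates_round_trip(self, tmp_path, tiny_table):
        write_otu_table(tiny_table, tmp_path / "t.tsv", tmp_path / "m.tsv")
        back = read_otu_table(tmp_path / "t.tsv", tmp_path / "m.tsv")
        assert back.sample_dates == tiny_table.sample_dates


class TestValidation:
    def test_negative_counts_rejected(self):
        with pytest.raises(DataError, match="non-negative"):
            OtuTable(pd.DataFrame([[1, -2]], index=["S1"], columns=["a", "b"]))

    def test_non_integer_counts_rejected(self):
        with pytest.raises(DataError, match="integer"):
            OtuTable(pd.DataFrame([[1.5, 2.0]], index=["S1"],
                                  columns=["a", "b"]))

    def test_missing_date_rejected(self, tiny_table):
        import datetime
        with pytest.raises(DataError, match="S3"):
            OtuTable(tiny_table.counts,
                     sample_dates={"S1": datetime.date(2020, 1, 1),
                                   "S2": datetime.date(2020, 2, 1)})


class TestRarefy:
    def test_study_design_grand_total(self, rng):
        # 12 samples each above 2,988 reads subsampled to equal depth
        counts = pd.DataFrame(
            rng.multinomial(4000, np.ones(200) / 200, size=12),
            index=[f"S{i}" for i in range(12)],
            columns=[f"T{j}" for j in range(200)],
        )
        out = rarefy(OtuTable(counts), 2988, seed=7)
        assert out.grand_total == 35856
        assert (out.sample_totals == 2988).all()

    def test_depth_equal_to_total_is_identity(self, tiny_table):
        depth = int(tiny_table.sample_totals.min())
        sub = tiny_table.subset_samples(
            tiny_table.sample_totals.index[tiny_table.sample_totals == depth]
        )
        out = rarefy(sub, depth, seed=0)
        pd.testing.assert_frame_equal(out.counts, sub.counts)

    def test_counts_never_exceed_input(self, rng):
        table = random_table(rng, 5, 40)
        keep = table.sample_totals >= 20
        out = rarefy(table, 20, seed=3)
        assert (out.counts.le(table.counts.loc[out.sample_ids])).all().all()

    def test_hypergeometric_mean(self):
        # counts (5,5), depth 4: retained count of taxon A has mean 2
        table = OtuTable(pd.DataFrame([[5, 5]], index=["S1"],
                                      columns=["a", "b"]))
        draws = np.array(
            [rarefy(table, 4, seed=s).counts.iloc[0, 0] for s in range(2000)]
        )
        # exact multivariate hypergeometric moments for one margin
        var = 4 * 0.5 * 0.5 * (10 - 4) / (10 - 1)
        se = np.sqrt(var / draws.size)
        assert abs(draws.mean() - 2.0) < 3 * se

    def test_below_depth_sample_dropped(self):
        counts = pd.DataFrame([[6, 6], [2, 3], [8, 4]],
                              index=["S1", "S2", "S3"], columns=["a", "b"])
        out = rarefy(OtuTable(counts), 10, seed=0)
        assert out.sample_ids == ["S1", "S3"]

    def test_errors(self, tiny_table):
        with pytest.raises(DataError):
            rarefy(tiny_table, 0, seed=0)
        with pytest.raises(DataError):
            rarefy(tiny_table, 10_000, seed=0)

    def test_deterministic_given_seed(self, rng):
        table = random_table(rng, 4, 30)
        a = rarefy(table, 15, seed=42)
        b = rarefy(table, 15, seed=42)
        pd.testing.assert_frame_equal(a.counts, b.counts)


class TestRemoveSingletons:
    def test_definition(self):
        counts = pd.DataFrame([[1, 2, 0], [0, 0, 1]], index=["S1", "S2"],
                              columns=["one", "two", "other_one"])
        out = remove_singletons(OtuTable(counts))
        assert out.taxon_ids == ["two"]

    def test_identity_when_no_singletons(self, tiny_table):
        out = remove_singletons(tiny_table)
        pd.testing.assert_frame_equal(out.counts, tiny_table.counts)

    def test_matches_brute_force_and_idempotent(self, rng):
        table = random_table(rng, 4, 200, lam=0.2)
        out = remove_singletons(table)
        expected = [t for t in table.taxon_ids
                    if table.counts[t].sum() != 1]
        assert out.taxon_ids == expected
        again = remove_singletons(out)
        pd.testing.assert_frame_equal(again.counts, out.counts)


class TestSummarize:
    def test_full_presence_and_absence(self, tiny_table):
        s = summarize_taxa(tiny_table)
        assert s.loc["otuD", "occurrence"] == 3
        assert s.loc["otuD", "occurrence_freq"] == 1.0
        counts = tiny_table.counts.copy()
        counts["ghost"] = 0
        s2 = summarize_taxa(OtuTable(counts))
        assert s2.loc["ghost", "occurrence"] == 0
        assert s2.loc["ghost", "mean_rel_abund"] == 0.0

    def test_matches_per_taxon_loop(self, rng):
        table = random_table(rng, 7, 40)
        s = summarize_taxa(table)
        for taxon in table.taxon_ids:
            col = table.counts[taxon]
            props = col / table.sample_totals
            assert s.loc[taxon, "total_count"] == col.sum()
            assert s.loc[taxon, "mean_rel_abund"] == pytest.approx(props.mean())
            assert s.loc[taxon, "occurrence"] == int((col > 0).sum())

    def test_rel_abund_sums_to_one(self, standard_table):
        s = summarize_taxa(standard_table)
        assert s["mean_rel_abund"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_zero_total_sample_error(self):
        counts = pd.DataFrame([[0, 0], [1, 2]], index=["S1", "S2"],
                              columns=["a", "b"])
        with pytest.raises(DataError, match="S1"):
            summarize_taxa(OtuTable(counts))


class TestComposition:
    @staticmethod
    def _partition(table):
        return classify_taxa(summarize_taxa(table),
                             CohortThresholds(0.5, 1, 2))

    def test_single_phylum_carries_cohort_share(self):
        counts = pd.DataFrame([[4, 6], [2, 8]], index=["S1", "S2"],
                              columns=["a", "b"])
        tax = {"a": ("Bacteria", "Bacteroidetes"),
               "b": ("Bacteria", "Bacteroidetes")}
        table = OtuTable(counts, taxonomy=tax)
        comp = aggregate_composition(table, self._partition(table), "phylum")
        # one rank value holds the whole cohort share in every sample
        assert (comp.data["Bacteroidetes"] == comp.data.sum(axis=1)).all()

    def test_conservation_per_cohort_sample(self, tiny_table):
        part = self._partition(tiny_table)
        comp = aggregate_composition(tiny_table, part, "phylum")
        rel = tiny_table.relative_abundance()
        for (cohort, sample), row in comp.data.iterrows():
            cohort_share = rel.loc[sample, part.taxa(cohort)].sum()
            assert row.sum() == pytest.approx(cohort_share, abs=1e-9)

    def test_proteobacteria_split_to_class(self, tiny_table):
        comp = aggregate_composition(tiny_table, self._partition(tiny_table),
                                     "phylum")
        assert "Betaproteobacteria" in comp.data.columns
        assert "unclassified_Proteobacteria" in comp.data.columns
        assert "Proteobacteria" not in comp.data.columns

    def test_matches_brute_force_groupby(self, rng):
        table = random_table(rng, 5, 40, lam=3.0)
        phyla = [f"P{j % 6}" for j in range(40)]
        tax = {t: ("Bacteria", phyla[j]) for j, t in enumerate(table.taxon_ids)}
        table = OtuTable(table.counts, taxonomy=tax)
        part = self._partition(table)
        comp = aggregate_composition(table, part, "phylum")
        rel = table.relative_abundance()
        for cohort in comp.cohorts:
            taxa = part.taxa(cohort)
            for sample in table.sample_ids:
                for phylum in set(phyla):
                    expect = sum(
                        rel.loc[sample, t] for t in taxa
                        if tax[t][1] == phylum
                    )
                    got = comp.data.loc[(cohort, sample)].get(phylum, 0.0)
                    assert got == pytest.approx(expect, abs=1e-12)

    def test_requires_taxonomy(self, rng):
        table = random_table(rng, 4, 10)
        with pytest.raises(DataError, match="taxonomy"):
            aggregate_composition(table, self._partition(table), "phylum")


class TestCompareCompositions:
    def _comp(self, data, rank="phylum"):
        from rarecohort.core_table import CompositionTable
        return CompositionTable(rank, data)

    def test_identical_tables_give_p_one(self, tiny_table):
        part = TestComposition._partition(tiny_table)
        comp = aggregate_composition(tiny_table, part, "phylum")
        a = comp.for_cohort(comp.cohorts[0])
        res = compare_compositions(a, a)
        assert np.allclose(res["p"], 1.0, atol=1e-9)
        assert res.attrs["corrected"] is False

    def test_large_shift_detected(self, rng):
        idx_a = pd.MultiIndex.from_product([["x"], [f"S{i}" for i in range(6)]])
        idx_b = pd.MultiIndex.from_product([["y"], [f"S{i}" for i in range(6)]])
        base = rng.uniform(0.1, 0.2, size=6)
        a = self._comp(pd.DataFrame({"Bacteroidetes": base}, index=idx_a))
        b = self._comp(pd.DataFrame({"Bacteroidetes": base + 0.5}, index=idx_b))
        res = compare_compositions(a, b)
        assert res.loc["Bacteroidetes", "p"] < 0.01

    def test_welch_formula_on_toy(self):
        xa = np.array([0.1, 0.2, 0.3])
        xb = np.array([0.4, 0.45, 0.5])
        idx_a = pd.MultiIndex.from_product([["x"], ["S1", "S2", "S3"]])
        idx_b = pd.MultiIndex.from_product([["y"], ["S1", "S2", "S3"]])
        a = self._comp(pd.DataFrame({"v": xa}, index=idx_a))
        b = self._comp(pd.DataFrame({"v": xb}, index=idx_b))
        res = compare_compositions(a, b)
        # hand-computed Welch statistic
        va, vb = xa.var(ddof=1) / 3, xb.var(ddof=1) / 3
        t_hand = (xa.mean() - xb.mean()) / np.sqrt(va + vb)
        assert res.loc["v", "t"] == pytest.approx(t_hand, rel=1e-12)
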