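import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from bsaqtl.germplasm import (
    anova_duncan,
    assignments,
    ddct,
    define_haplotypes,
    duncan_critical_range,
    frequency_breakdown,
    group_heights,
    single_marker_test,
)
from bsaqtl.simdata import make_panel_fixture, make_qpcr_fixture

PANEL_SIZES = [39, 6, 8, 21, 21, 53]
PANEL_MEANS = [210.97, 155.60, 137.23, 174.18, 191.06, 201.92]


@pytest.fixture(scope="module")
def panel():
    return make_panel_fixture(
        seed=11, group_sizes=PANEL_SIZES, group_means=PANEL_MEANS, sd=12.0
    )


class TestDefineHaplotypes:
    def test_partition_sizes(self, panel):
        groups = define_haplotypes(panel)
        assert len(groups) == 6
        assert sorted(g.n for g in groups) == sorted(PANEL_SIZES)
        assert sum(g.n for g in groups) == 148

    def test_labels_ordered_by_descending_mean(self, panel):
        groups = define_haplotypes(panel)
        assert [g.label for g in groups] == [f"Hap{i}" for i in range(1, 7)]
        means = [g.overall_mean for g in groups]
        assert means == sorted(means, reverse=True)

    def test_single_group_when_identical(self):
        panel = make_panel_fixture(seed=1, group_sizes=[10], group_means=[150.0],
                                   sd=5.0)
        assert len(define_haplotypes(panel)) == 1

    def test_combinatorial_bound_four_biallelic_sites(self, rng):
        # alleles drawn from 2 letters per site: at most 16 distinct groups
        strings = ["".join(rng.choice(["A", "T"], size=4)) for _ in range(500)]
        panel = pd.DataFrame(
            {
                "accession": [f"a{i}" for i in range(500)],
                "alleles": strings,
                "height_2024": rng.normal(150, 10, size=500),
            }
        )
        assert len(define_haplotypes(panel)) <= 16

    def test_incomplete_strings_excluded(self):
        panel = pd.DataFrame(
            {
                "accession": ["a1", "a2", "a3"],
                "alleles": ["ACGT", "AC-T", "ACGT"],
                "height_2024": [100.0, 110.0, 120.0],
            }
        )
        groups = define_haplotypes(panel)
        assert sum(g.n for g in groups) == 2

    def test_empty_panel_rejected(self):
        with pytest.raises(ValueError):
            define_haplotypes(pd.DataFrame(columns=["accession", "alleles",
                                                    "height_2024"]))

    def test_assignments_cover_members(self, panel):
        groups = define_haplotypes(panel)
        label_of = assignments(groups)
        assert len(label_of) == 148


class TestDuncan:
    def test_critical_values_match_published_tables(self):
        # studentized-range quantiles q_{0.05}(p, df) from standard tables
        published = {(2, 20): 2.950, (3, 20): 3.578, (4, 20): 3.958,
                     (2, 10): 3.151}
        for (p, df), q_tab in published.items():
            q = sps.studentized_range.ppf(0.95, p, df)
            assert q == pytest.approx(q_tab, abs=2e-3)
        # at p=2 Duncan's protection level equals alpha, so the critical
        # range with unit scale reduces to the plain table quantile
        assert duncan_critical_range(
            2, 20, ms_error=1.0, n_harmonic=1.0, alpha=0.05
        ) == pytest.approx(2.950, abs=2e-3)

    def test_two_group_reduction_matches_lsd(self, rng):
        # with k=2 Duncan's range equals Fisher's LSD (equal n), so the
        # significance decisions must coincide across random datasets
        agreements = 0
        for rep in range(60):
            shift = rng.uniform(0.0, 3.0)
            a = rng.normal(0.0, 1.0, size=8)
            b = rng.normal(shift, 1.0, size=8)
            res = anova_duncan({"A": a, "B": b}, alpha=0.05)
            duncan_sig = res.letters["A"] != res.letters["B"] and not (
                set(res.letters["A"]) & set(res.letters["B"])
            )
            t_crit = sps.t.ppf(0.975, res.df_error)
            lsd = t_crit * np.sqrt(res.ms_error * (1 / 8 + 1 / 8))
            lsd_sig = abs(a.mean() - b.mean()) > lsd
            assert duncan_sig == lsd_sig
            agreements += 1
        assert agreements == 60

    def test_identical_means_share_a_letter(self):
        base = np.array([10.0, 12.0, 14.0])
        res = anova_duncan({"A": base, "B": base, "C": base})
        letters = set(res.letters.values())
        assert len(letters) == 1

    def test_separated_groups_get_distinct_letters(self):
        # power sanity check: >= 6 sd separation, n >= 6 per group
        hits = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            a = rng.normal(0.0, 1.0, size=6)
            b = rng.normal(6.0, 1.0, size=6)
            res = anova_duncan({"A": a, "B": b})
            if not set(res.letters["A"]) & set(res.letters["B"]):
                hits += 1
        assert hits >= 38  # >= 95%

    def test_singleton_groups_excluded(self):
        res = anova_duncan({"A": [1.0, 2.0], "B": [5.0, 6.0], "C": [3.0]})
        assert res.excluded == ["C"]
        assert "C" not in res.letters

    def test_too_few_groups_rejected(self):
        with pytest.raises(ValueError):
            anova_duncan({"A": [1.0, 2.0], "B": [3.0]})

    def test_letter_display_is_transitively_consistent(self, rng):
        # sharing a letter is an interval property on the descending-mean
        # order: if i and j share one, everything between shares it too
        for rep in range(25):
            data = {
                f"G{i}": rng.normal(rng.uniform(0, 4), 1.0, size=6)
                for i in range(5)
            }
            res = anova_duncan(data)
            order = list(res.means)
            for letter in set("".join(res.letters.values())):
                idx = [i for i, lab in enumerate(order)
                       if letter in res.letters[lab]]
                assert idx == list(range(min(idx), max(idx) + 1))

    def test_panel_fixture_extreme_groups_differ(self, panel):
        groups = define_haplotypes(panel)
        res = anova_duncan(group_heights(panel, groups))
        assert res.p_value < 1e-6
        # tallest and shortest fixture groups must not share a letter
        assert not set(res.letters["Hap1"]) & set(res.letters["Hap6"])

    def test_group_heights_by_year(self, panel):
        groups = define_haplotypes(panel)
        by_year = group_heights(panel, groups, year=2024)
        overall = group_heights(panel, groups)
        assert set(by_year) == set(overall)
        res = anova_duncan(by_year)
        assert res.p_value < 1e-6


class TestSingleMarkerTest:
    def test_type_one_error_calibration(self):
        rejections = 0
        n_reps = 200
        for seed in range(n_reps):
            rng = np.random.default_rng([seed, 7])
            alleles = np.where(rng.random(148) < 0.5, "T", "C")
            panel = pd.DataFrame(
                {
                    "accession": [f"a{i}" for i in range(148)],
                    "alleles": ["".join(x) for x in
                                np.char.add(alleles, "AAA")],
                    "height_2024": rng.normal(180, 20, size=148),
                }
            )
            res = single_marker_test(panel, 0, year=2024)
            if res.status == "ok" and res.p < 0.05:
                rejections += 1
        rate = rejections / n_reps
        assert 0.01 <= rate <= 0.10  # ~3 binomial SDs around 0.05

    def test_power_with_large_shift(self):
        # +20 cm shift, sd 10, n=30/group: noncentrality ~7.7, so p < 0.001
        # essentially always (closed-form power > 0.9999)
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng([seed, 9])
            heights = np.concatenate(
                [rng.normal(160, 10, 30), rng.normal(180, 10, 30)]
            )
            panel = pd.DataFrame(
                {
                    "accession": [f"a{i}" for i in range(60)],
                    "alleles": ["CAAA"] * 30 + ["TAAA"] * 30,
                    "height_2024": heights,
                }
            )
            res = single_marker_test(panel, 0, year=2024)
            if res.p < 0.001:
                hits += 1
        assert hits >= 48  # >= 95%

    def test_monomorphic_site_not_testable(self, panel):
        sub = panel[panel["alleles"] == panel["alleles"].iloc[0]]
        res = single_marker_test(sub, 0, year=2024)
        assert res.status == "monomorphic"

    def test_degenerate_zero_variance(self):
        panel = pd.DataFrame(
            {
                "accession": ["a1", "a2", "a3", "a4"],
                "alleles": ["C", "C", "T", "T"],
                "height_2024": [100.0, 100.0, 100.0, 100.0],
            }
        )
        res = single_marker_test(panel, 0, year=2024)
        assert res.status == "degenerate"
        assert np.isnan(res.p)

    def test_reports_group_means(self):
        panel = pd.DataFrame(
            {
                "accession": ["a1", "a2", "a3", "a4"],
                "alleles": ["C", "C", "T", "T"],
                "height_2024": [100.0, 110.0, 150.0, 160.0],
            }
        )
        res = single_marker_test(panel, 0, year=2024)
        assert (res.allele_a, res.allele_b) == ("C", "T")
        assert res.mean_a == 105.0 and res.mean_b == 155.0


class TestFrequencyBreakdown:
    def test_six_of_ninety_two_rounds_to_six_point_five(self):
        # 6/92 = 6.52% -> 6.5% after rounding
        panel = pd.DataFrame(
            {
                "accession": [f"a{i}" for i in range(92)],
                "alleles": ["AAAA"] * 6 + ["TTTT"] * 86,
                "market_class": ["confection"] * 92,
                "height_2024": np.linspace(100, 200, 92),
            }
        )
        groups = define_haplotypes(panel)
        table = frequency_breakdown(panel, groups, by="market_class")
        small = next(g.label for g in groups if g.n == 6)
        assert table.loc["confection", small] == 6.5

    def test_single_accession_stratum(self):
        panel = pd.DataFrame(
            {
                "accession": ["a1"],
                "alleles": ["AAAA"],
                "market_class": ["oilseed"],
                "height_2024": [100.0],
            }
        )
        groups = define_haplotypes(panel)
        table = frequency_breakdown(panel, groups, by="market_class")
        assert table.loc["oilseed", "Hap1"] == 100.0

    def test_rows_sum_to_hundred(self, panel):
        groups = define_haplotypes(panel)
        for by in ("market_class", "region"):
            table = frequency_breakdown(panel, groups, by=by)
            assert np.allclose(table.sum(axis=1), 100.0)

    def test_invariant_to_input_order(self, panel):
        groups = define_haplotypes(panel)
        a = frequency_breakdown(panel, groups, by="region")
        shuffled = panel.sample(frac=1.0, random_state=3)
        b = frequency_breakdown(shuffled, groups, by="region")
        pd.testing.assert_frame_equal(a, b)

    def test_unknown_stratum_column_rejected(self, panel):
        groups = define_haplotypes(panel)
        with pytest.raises(ValueError):
            frequency_breakdown(panel, groups, by="flavor")


class TestDdct:
    def _table(self, dcts_by_line, gene="g1"):
        rows = []
        for line, dcts in dcts_by_line.items():
            for i, dct in enumerate(dcts):
                rows.append(
                    {
                        "line": line, "gene": gene, "bio_rep": i + 1,
                        "ct_target": 20.0 + dct, "ct_reference": 20.0,
                    }
                )
        return pd.DataFrame(rows)

    def test_reference_group_mean_is_exactly_one(self):
        table = self._table({"ref": [5.0, 5.0, 5.0], "other": [4.0, 4.0, 4.0]})
        res = ddct(table, "ref")
        ref_rows = res.per_replicate[res.per_replicate["group"] == "ref"]
        assert (ref_rows["rel_expr"] == 1.0).all()

    def test_one_cycle_below_reference_doubles(self):
        table = self._table({"ref": [5.0, 5.0], "other": [4.0, 4.0]})
        res = ddct(table, "ref")
        other = res.summary[res.summary["line"] == "other"]
        assert other["fold_change"].iloc[0] == pytest.approx(2.0)

    def test_hand_arithmetic_geometric_mean(self):
        # dCt {5,6,7} against reference mean 6: expressions {2,1,0.5},
        # fold change (geometric mean) exactly 1.0
        table = self._table({"ref": [6.0, 6.0], "other": [5.0, 6.0, 7.0]})
        res = ddct(table, "ref")
        other_reps = res.per_replicate[res.per_replicate["group"] == "other"]
        assert sorted(other_reps["rel_expr"]) == [0.5, 1.0, 2.0]
        row = res.summary[res.summary["line"] == "other"].iloc[0]
        assert row["fold_change"] == pytest.approx(1.0)
        assert row["mean_rel_expr"] == pytest.approx(3.5 / 3)

    def test_technical_replicates_averaged_first(self):
        rows = []
        for tech, ct in ((1, 24.0), (2, 26.0)):  # mean target Ct 25
            rows.append({"line": "ref", "gene": "g", "bio_rep": 1,
                         "tech_rep": tech, "ct_target": ct,
                         "ct_reference": 20.0})
        rows.append({"line": "ref", "gene": "g", "bio_rep": 2, "tech_rep": 1,
                     "ct_target": 25.0, "ct_reference": 20.0})
        res = ddct(pd.DataFrame(rows), "ref")
        assert np.allclose(res.per_replicate["dct"], 5.0)
        assert np.allclose(res.per_replicate["rel_expr"], 1.0)

    def test_missing_reference_ct_excluded(self, caplog):
        table = self._table({"ref": [5.0, 5.0], "other": [4.0, 4.0]})
        table.loc[0, "ct_reference"] = np.nan
        with caplog.at_level("INFO"):
            res = ddct(table, "ref")
        assert len(res.per_replicate) == 3

    def test_fixture_recovers_fold_difference(self):
        table = make_qpcr_fixture(seed=5, log2_fold=2.0, ct_sd=0.05)
        res = ddct(table, "dwarf")
        tall = res.summary[res.summary["line"] == "tall"].iloc[0]
        assert tall["fold_change"] == pytest.approx(4.0, rel=0.2)
        assert tall["p"] < 0.01

    def test_absent_reference_group_rejected(self):
        table = self._table({"a": [1.0, 2.0]})
        with pytest.raises(ValueError):
            ddct(table, "zzz")
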