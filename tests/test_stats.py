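import random

import numpy as np
import pandas as pd
import pytest

from pncattr import (
    CategoryPercentRow,
    category_table,
    chisq_vs_majority,
    crosstab_to_percent_row,
    frequency_crosstab,
    paired_t,
    pattern_rollup,
    visit_summary,
)
from oracles import oracle_chi2_2x2, oracle_paired_t


class TestVisitSummary:
    def test_episode_level_mean(self, small_cohort):
        _, result = small_cohort
        df = visit_summary(result.classifications, result.all_profiles)
        ep = df[df.level == "pregnancy"].iloc[0]
        expected = np.mean([c.n_total for c in result.classifications])
        assert ep.mean_visits == pytest.approx(expected)
        strata_cols = [c for c in df.columns if c.startswith("pct_")]
        assert ep[strata_cols].sum() == pytest.approx(100.0)

    def test_provider_level_rows(self, small_cohort):
        _, result = small_cohort
        df = visit_summary(result.classifications, result.all_profiles)
        pr = df[df.level == "pregnancy_provider"].iloc[0]
        assert pr.n == len(result.all_profiles)
        assert pr.mean_visits <= df[df.level == "pregnancy"].iloc[0].mean_visits


class TestCategoryTable:
    def test_planted_composition_recovered(self, small_cohort):
        cohort, result = small_cohort
        table = category_table(result.classifications, result.profiles_by_episode)
        vals = dict(zip(table.measure, table.value))
        labels = {
            l.episode_id: l.planted_regime
            for l in cohort.labels
            if l.episode_id in result.profiles_by_episode
        }
        n = len(labels)
        assert vals["pct_Only"] == pytest.approx(
            100 * sum(r == "only" for r in labels.values()) / n
        )
        multplur_regimes = {
            "multplur_initial", "multplur_final", "multplur_initialfinal",
            "dispersal", "other_dominant",
        }
        assert vals["pct_MultPlur"] == pytest.approx(
            100 * sum(r in multplur_regimes for r in labels.values()) / n
        )
        # episode-level category percentages partition the cohort
        assert (
            vals["pct_Only"] + vals["pct_Majority"] + vals["pct_Plurality"]
            + vals["pct_MultPlur"]
        ) == pytest.approx(100.0)

    def test_tied_maximum_distribution(self, small_cohort):
        _, result = small_cohort
        table = category_table(result.classifications, result.profiles_by_episode)
        vals = dict(zip(table.measure, table.value))
        tied = {k: v for k, v in vals.items() if k.startswith("pct_tied_max_")}
        assert sum(tied.values()) == pytest.approx(100.0)


class TestFrequencyCrosstab:
    def test_cells_sum_to_hundred(self, small_cohort):
        _, result = small_cohort
        xtab = frequency_crosstab(result.classifications, result.profiles_by_episode)
        all_row = xtab[xtab.stratum == "all"].iloc[0]
        assert all_row.All_providers == pytest.approx(100.0)
        by_strata = xtab[xtab.stratum != "all"].All_providers.sum()
        assert by_strata == pytest.approx(100.0)

    def test_single_visit_stratum_is_all_only(self, small_cohort):
        _, result = small_cohort
        xtab = frequency_crosstab(result.classifications, result.profiles_by_episode)
        row = xtab[xtab.stratum == "=1"].iloc[0]
        assert row.Only == pytest.approx(row.All_providers)
        assert row.Dispersal == 0.0


class TestPatternRollup:
    ROW = CategoryPercentRow(
        only=28.40, majority=19.55, plurality=33.49,
        multplur_initial=7.31, multplur_final=3.06,
    )

    def test_cumulative_frequency_patterns(self):
        r = pattern_rollup(self.ROW)
        assert round(r.p2, 2) == 47.95
        assert round(r.p3, 2) == 81.44

    def test_sequence_patterns(self):
        r = pattern_rollup(self.ROW)
        assert round(r.p4, 2) == 88.75
        assert round(r.p6, 2) == 91.81

    def test_all_zero_row(self):
        r = pattern_rollup(CategoryPercentRow(0, 0, 0, 0, 0))
        assert all(v == 0 for v in r.as_dict().values())

    def test_inconsistent_row_rejected(self):
        with pytest.raises(ValueError, match="exceeds 100"):
            pattern_rollup(CategoryPercentRow(60, 30, 20, 5, 5))

    def test_monotone_on_generated_cohort(self, small_cohort):
        from pncattr import frequency_crosstab

        _, result = small_cohort
        xtab = frequency_crosstab(result.classifications, result.profiles_by_episode)
        r = pattern_rollup(crosstab_to_percent_row(xtab)).as_dict()
        assert r[1] <= r[2] <= r[3] <= r[4] <= r[6] <= 100 + 1e-9
        assert r[3] <= r[5] <= r[6]


class TestChiSquare:
    def _counts(self, a, b, c, d):
        return pd.DataFrame(
            {"X": [a, b], "Majority": [c, d]}, index=["s1", "rest"]
        )

    def test_homogeneous_table(self):
        chi2, p = chisq_vs_majority(self._counts(10, 10, 10, 10), "s1", "X")
        assert chi2 == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_hand_formula_value(self):
        chi2, _ = chisq_vs_majority(self._counts(20, 10, 10, 20), "s1", "X")
        assert chi2 == pytest.approx(oracle_chi2_2x2(20, 10, 10, 20), abs=1e-9)
        assert chi2 == pytest.approx(20 / 3, abs=1e-9)

    def test_transpose_symmetry(self):
        chi2a, _ = chisq_vs_majority(self._counts(7, 3, 4, 9), "s1", "X")
        chi2b, _ = chisq_vs_majority(self._counts(7, 4, 3, 9), "s1", "X")
        assert chi2a == pytest.approx(chi2b, abs=1e-12)

    def test_agrees_with_textbook_formula_on_random_tables(self):
        rng = random.Random(17)
        for _ in range(100):
            a, b, c, d = (rng.randint(1, 200) for _ in range(4))
            chi2, _ = chisq_vs_majority(self._counts(a, b, c, d), "s1", "X")
            assert chi2 == pytest.approx(oracle_chi2_2x2(a, b, c, d), abs=1e-9)

    def test_majority_vs_itself_rejected(self):
        with pytest.raises(ValueError):
            chisq_vs_majority(self._counts(1, 1, 1, 1), "s1", "Majority")

    def test_zero_marginal_flagged(self):
        with pytest.raises(ValueError, match="marginal"):
            chisq_vs_majority(self._counts(0, 0, 10, 10), "s1", "X")


class TestPairedT:
    def test_closed_form(self):
        r = paired_t([1, 2, 3])
        assert r.mean_diff == pytest.approx(2.0)
        assert r.t == pytest.approx(2 / (1 / 3**0.5), abs=1e-12)
        assert r.df == 2

    def test_agrees_with_oracle_on_random_inputs(self):
        rng = random.Random(23)
        for _ in range(100):
            d = [rng.gauss(0, 1) for _ in range(rng.randint(3, 40))]
            r = paired_t(d)
            t_o, df_o = oracle_paired_t(d)
            assert r.t == pytest.approx(t_o, abs=1e-9)
            assert r.df == df_o

    def test_antisymmetry(self):
        d = [0.5, -1.2, 2.2, 0.1]
        r1, r2 = paired_t(d), paired_t([-x for x in d])
        assert r1.t == pytest.approx(-r2.t)
        assert r1.p == pytest.approx(r2.p)

    def test_all_zero_degenerate(self):
        r = paired_t([0.0, 0.0, 0.0])
        assert r.degenerate and r.t == 0.0 and r.mean_diff == 0.0

    def test_ci_covers_mean(self):
        r = paired_t([1.0, 2.0, 3.0, 4.0])
        assert r.ci_low < r.mean_diff < r.ci_high
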