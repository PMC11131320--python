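import datetime as dt
import random

import pytest

from pncattr import (
    Category,
    MultPlurSubtype,
    PncVisit,
    classify_episode,
    compute_coc,
    compute_fractions,
    freq_stratum,
    select_predominant,
)
from conftest import make_visits
from oracles import oracle_categories, oracle_coc, oracle_subtype


def classify_layout(layout):
    profiles, cls = classify_episode(make_visits(layout))
    return {p.sspi.split("|")[0]: p for p in profiles}, cls


class TestFractions:
    def test_counts_and_fractions(self):
        by, _ = classify_layout("AAAAABBC")
        assert by["A"].n_visits == 5 and by["A"].fraction == pytest.approx(0.625)
        assert by["B"].fraction == pytest.approx(0.25)
        assert by["C"].fraction == pytest.approx(0.125)

    def test_sole_provider_fraction_one(self):
        by, _ = classify_layout("AAAAAAAA")
        assert by["A"].fraction == 1.0

    def test_fractions_sum_to_one(self):
        profiles = compute_fractions(make_visits("AABBCCDE"))
        assert sum(p.fraction for p in profiles) == pytest.approx(1.0, abs=1e-9)


class TestCoc:
    @pytest.mark.parametrize(
        "counts,expected",
        [([1, 1, 1], 0.0), ([3], 1.0), ([2, 1], 1 / 3), ([1], 1.0)],
    )
    def test_known_values(self, counts, expected):
        assert compute_coc(counts) == pytest.approx(expected, abs=1e-12)

    def test_matches_exact_fraction_oracle(self):
        rng = random.Random(5)
        for _ in range(300):
            counts = [rng.randint(1, 6) for _ in range(rng.randint(1, 6))]
            assert compute_coc(counts) == pytest.approx(
                float(oracle_coc(counts)), abs=1e-12
            )


class TestCategories:
    def test_majority_and_others(self):
        by, _ = classify_layout("AAAAABBC")
        assert by["A"].category is Category.MAJORITY
        assert by["B"].category is Category.OTHER
        assert by["C"].category is Category.OTHER

    def test_unique_max_at_most_half_is_plurality(self):
        by, _ = classify_layout("AAAABBBCCC")  # A 4/10 unique max
        assert by["A"].category is Category.PLURALITY

    def test_exact_half_two_providers_is_multplur_not_majority(self):
        by, _ = classify_layout("AABB")
        assert by["A"].category is Category.MULTPLUR
        assert by["B"].category is Category.MULTPLUR

    def test_tied_max_is_multplur(self):
        by, _ = classify_layout("AAABBBCC")
        assert by["A"].category is Category.MULTPLUR
        assert by["C"].category is Category.OTHER

    def test_sole_provider_is_only(self):
        by, _ = classify_layout("A")
        assert by["A"].category is Category.ONLY

    def test_random_episodes_match_definitional_oracle(self):
        rng = random.Random(99)
        for _ in range(2000):
            n_prov = rng.randint(1, 6)
            counts = {}
            total = 0
            for j in range(n_prov):
                c = rng.randint(1, max(1, (20 - total) // max(1, n_prov - j)))
                counts[chr(65 + j)] = c
                total += c
            layout = "".join(k * v for k, v in counts.items())
            layout = "".join(rng.sample(layout, len(layout)))
            by, _ = classify_layout(layout)
            expected = oracle_categories(counts)
            got = {k: p.category.value for k, p in by.items()}
            assert got == expected


class TestSubtypes:
    def test_initial_final_when_holding_both_endpoints(self):
        by, _ = classify_layout("ABBA")
        assert by["A"].multplur_subtype is MultPlurSubtype.INITIAL_FINAL
        assert by["B"].multplur_subtype is MultPlurSubtype.NEITHER

    def test_initial_only(self):
        by, _ = classify_layout("ABAB")
        assert by["A"].multplur_subtype is MultPlurSubtype.INITIAL
        assert by["B"].multplur_subtype is MultPlurSubtype.FINAL

    def test_dispersal_episode_subtypes(self):
        by, cls = classify_layout("ABC")
        assert cls.dispersal
        assert by["A"].multplur_subtype is MultPlurSubtype.INITIAL
        assert by["B"].multplur_subtype is MultPlurSubtype.NEITHER
        assert by["C"].multplur_subtype is MultPlurSubtype.FINAL

    def test_non_multplur_is_na(self):
        by, _ = classify_layout("AAB")
        assert by["A"].multplur_subtype is MultPlurSubtype.NA

    def test_matches_subtype_oracle(self):
        for layout in ("ABBA", "ABAB", "BABA", "CABAB", "CAABBD"):
            by, _ = classify_layout(layout)
            for key, p in by.items():
                assert p.multplur_subtype.value == oracle_subtype(
                    p.category.value, p.has_first, p.has_last
                )


class TestDispersal:
    @pytest.mark.parametrize(
        "layout,expected", [("ABC", True), ("A", False), ("AABC", False), ("AB", True)]
    )
    def test_definition(self, layout, expected):
        _, cls = classify_layout(layout)
        assert cls.dispersal is expected

    def test_dispersal_iff_coc_zero(self):
        for layout in ("ABC", "AB", "AABC", "AABB", "A", "ABCD"):
            _, cls = classify_layout(layout)
            assert cls.dispersal == (cls.coc_index == 0.0 and cls.n_total >= 2)


class TestSelectPredominant:
    def test_majority_identified_from_pattern_two(self):
        by, cls = classify_layout("AAAB")
        assert cls.predominant_by_pattern[1] is None
        assert cls.predominant_by_pattern[2] == "A|16"

    def test_plurality_needs_pattern_three(self):
        _, cls = classify_layout("AABC")
        assert cls.predominant_by_pattern[2] is None
        assert cls.predominant_by_pattern[3] == "A|16"

    def test_multplur_endpoint_patterns(self):
        # A, B tied; A first, B last
        _, cls = classify_layout("ABAB")
        assert cls.predominant_by_pattern[3] is None
        assert cls.predominant_by_pattern[4] == "A|16"
        assert cls.predominant_by_pattern[5] == "B|16"
        assert cls.predominant_by_pattern[6] == "A|16"  # initial priority

    def test_final_only_multplur(self):
        _, cls = classify_layout("CABAB")  # first visit by non-tied C
        assert cls.predominant_by_pattern[4] is None
        assert cls.predominant_by_pattern[5] == "B|16"
        assert cls.predominant_by_pattern[6] == "B|16"

    def test_dispersal_returns_none_for_all_patterns(self):
        _, cls = classify_layout("ABC")
        assert all(v is None for v in cls.predominant_by_pattern.values())

    def test_unknown_pattern_rejected(self):
        profiles = compute_fractions(make_visits("AAB"))
        with pytest.raises(ValueError):
            select_predominant(profiles, 7)

    def test_same_day_tie_broken_deterministically(self):
        # two tied MultPlur providers sharing the first date: lexicographic SSPI
        visits = make_visits("AB") + make_visits("BA", start=dt.date(2017, 1, 1))
        visits = [
            PncVisit(v.episode_id, v.sspi, v.specialty_group, v.visit_date, i + 1)
            for i, v in enumerate(visits)
        ]
        profiles, cls = classify_episode(visits)
        assert cls.predominant_by_pattern[6] == "A|16"


class TestNesting:
    def test_identified_sets_monotone(self, small_cohort):
        _, result = small_cohort
        for c in result.classifications:
            ident = {k: c.predominant_by_pattern[k] is not None for k in range(1, 7)}
            for a, b in [(1, 2), (2, 3), (3, 4), (4, 6), (3, 5), (5, 6)]:
                assert not (ident[a] and not ident[b]), (
                    f"pattern {a} identified but {b} did not for {c.episode_id}"
                )

    def test_at_most_one_predominant(self, small_cohort):
        _, result = small_cohort
        for c in result.classifications:
            for v in c.predominant_by_pattern.values():
                assert v is None or isinstance(v, str)


class TestFreqStratum:
    @pytest.mark.parametrize(
        "n,expected",
        [(1, "=1"), (2, "2-8"), (8, "2-8"), (9, "9-14"), (14, "9-14"), (15, ">14")],
    )
    def test_boundaries(self, n, expected):
        assert freq_stratum(n) == expected
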