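"""Cohort summary tables and the statistical comparisons.

Builds the standard reporting surface for a classified cohort: visit-count
summaries at the pregnancy and pregnancy-provider level, the category
percentage table, the frequency-by-category crosstab, the cumulative pattern
rollup, the category-vs-Majority chi-square screens, and a paired t utility
for the travel-distance comparison.

Percentages are kept at full precision internally and rounded only at report
serialization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .types import Category, EpisodeClassification, MultPlurSubtype, ProviderEpisodeProfile

__all__ = [
    "CategoryPercentRow",
    "PatternRollup",
    "episode_label",
    "visit_summary",
    "category_table",
    "frequency_crosstab",
    "crosstab_to_percent_row",
    "pattern_rollup",
    "chisq_vs_majority",
    "paired_t",
    "PairedTResult",
]

CROSSTAB_COLUMNS = [
    "Only",
    "Majority",
    "Plurality",
    "MultPlur_Initial",
    "MultPlur_Final",
    "MultPlur_InitialFinal",
    "Dispersal",
    "NoPredominant",
]


@dataclass
class CategoryPercentRow:
    """Episode percentages (0-100) by identified category.

    By reporting convention the ``multplur_initial`` entry contains the
    InitialFinal episodes as well (an InitialFinal provider holds the first
    visit), so the rollup adds disjoint quantities.
    """

    only: float
    majority: float
    plurality: float
    multplur_initial: float
    multplur_final: float
    multplur_initialfinal: float = 0.0
    dispersal: float = 0.0


@dataclass
class PatternRollup:
    """Cumulative percent of episodes with an identified predominant
    provider under each pattern."""

    p1: float
    p2: float
    p3: float
    p4: float
    p5: float
    p6: float

    def as_dict(self) -> dict[int, float]:
        return {i: getattr(self, f"p{i}") for i in range(1, 7)}


def episode_label(
    classification: EpisodeClassification,
    profiles: list[ProviderEpisodeProfile],
) -> str:
    """Mutually exclusive episode-level category under pattern-6 attribution.

    Only/Majority/Plurality episodes keep that label; dispersal episodes are
    ``Dispersal``; a MultPlur episode takes the subtype of its selected
    pattern-6 provider; an episode whose tied providers hold neither endpoint
    is ``NoPredominant``.
    """
    if classification.dispersal:
        return "Dispersal"
    by_sspi = {p.sspi: p for p in profiles}
    for p in profiles:
        if p.category in (Category.ONLY, Category.MAJORITY, Category.PLURALITY):
            return p.category.value
    chosen = classification.predominant_by_pattern.get(6)
    if chosen is None:
        return "NoPredominant"
    sub = by_sspi[chosen].multplur_subtype
    return {
        MultPlurSubtype.INITIAL: "MultPlur_Initial",
        MultPlurSubtype.FINAL: "MultPlur_Final",
        MultPlurSubtype.INITIAL_FINAL: "MultPlur_InitialFinal",
    }[sub]


def visit_summary(
    classifications: list[EpisodeClassification],
    profiles: list[ProviderEpisodeProfile],
    bounds: Sequence[int] = (1, 8, 14),
) -> pd.DataFrame:
    """Visit-count N/mean/SD and stratum percentages at the pregnancy and the
    pregnancy-provider level."""
    if not classifications:
        raise ValueError("empty cohort")
    from .classify import freq_stratum

    ep = np.array([c.n_total for c in classifications], dtype=float)
    pr = np.array([p.n_visits for p in profiles], dtype=float)
    strata = [f"={bounds[0]}", f"{bounds[0] + 1}-{bounds[1]}",
              f"{bounds[1] + 1}-{bounds[2]}", f">{bounds[2]}"]
    rows = []
    for label, arr in (("pregnancy", ep), ("pregnancy_provider", pr)):
        labels = [freq_stratum(int(v), bounds) for v in arr]
        pct = {s: 100.0 * labels.count(s) / len(labels) for s in strata}
        rows.append(
            {
                "level": label,
                "n": len(arr),
                "mean_visits": arr.mean(),
                "sd_visits": arr.std(ddof=1) if len(arr) > 1 else 0.0,
                **{f"pct_{s}": pct[s] for s in strata},
            }
        )
    return pd.DataFrame(rows)


def category_table(
    classifications: list[EpisodeClassification],
    profiles_by_episode: dict[str, list[ProviderEpisodeProfile]],
) -> pd.DataFrame:
    """Category percentage table: mean providers per episode, percent of
    episodes by Only/Majority/Plurality/MultPlur, MultPlur subtype percent,
    and the distribution of the number of tied-maximum providers."""
    n = len(classifications)
    if n == 0:
        raise ValueError("empty cohort")
    rows = [("mean_providers", sum(c.n_providers for c in classifications) / n)]

    def pct(count: int) -> float:
        return 100.0 * count / n

    cat_count = {c: 0 for c in ("Only", "Majority", "Plurality", "MultPlur")}
    sub_count = {s: 0 for s in ("Dispersal", "Initial", "Final", "InitialFinal")}
    tied_count: dict[int, int] = {}
    for c in classifications:
        profs = profiles_by_episode[c.episode_id]
        max_n = max(p.n_visits for p in profs)
        tied = sum(1 for p in profs if p.n_visits == max_n)
        tied_count[tied] = tied_count.get(tied, 0) + 1
        top_cat = next(p.category for p in profs if p.n_visits == max_n)
        if top_cat is Category.MULTPLUR:
            cat_count["MultPlur"] += 1
            if c.dispersal:
                sub_count["Dispersal"] += 1
            subs = {p.multplur_subtype for p in profs if p.category is Category.MULTPLUR}
            if MultPlurSubtype.INITIAL_FINAL in subs:
                sub_count["InitialFinal"] += 1
            if MultPlurSubtype.INITIAL in subs:
                sub_count["Initial"] += 1
            if MultPlurSubtype.FINAL in subs:
                sub_count["Final"] += 1
        else:
            cat_count[top_cat.value] += 1
    rows += [(f"pct_{k}", pct(v)) for k, v in cat_count.items()]
    rows += [(f"pct_MultPlur_{k}", pct(v)) for k, v in sub_count.items()]
    rows += [
        (f"pct_tied_max_{k}", pct(tied_count.get(k, 0)))
        for k in range(1, max(tied_count) + 1)
    ]
    return pd.DataFrame(rows, columns=["measure", "value"])


def frequency_crosstab(
    classifications: list[EpisodeClassification],
    profiles_by_episode: dict[str, list[ProviderEpisodeProfile]],
) -> pd.DataFrame:
    """Percent of all episodes in each (frequency stratum x category) cell,
    under pattern-6 attribution; cells over all strata and categories sum to
    100 up to rounding.  Rows are strata plus an all-frequency row."""
    n = len(classifications)
    if n == 0:
        raise ValueError("empty cohort")
    strata = sorted({c.freq_stratum for c in classifications})
    cells: dict[tuple[str, str], int] = {}
    for c in classifications:
        lab = episode_label(c, profiles_by_episode[c.episode_id])
        cells[(c.freq_stratum, lab)] = cells.get((c.freq_stratum, lab), 0) + 1
    rows = []
    for s in ["all"] + strata:
        row: dict[str, float] = {"stratum": s}
        for col in CROSSTAB_COLUMNS:
            if s == "all":
                cnt = sum(v for (st, lab), v in cells.items() if lab == col)
            else:
                cnt = cells.get((s, col), 0)
            row[col] = 100.0 * cnt / n
        row["All_providers"] = sum(row[c] for c in CROSSTAB_COLUMNS)
        rows.append(row)
    return pd.DataFrame(rows, columns=["stratum", "All_providers", *CROSSTAB_COLUMNS])


def crosstab_to_percent_row(crosstab: pd.DataFrame) -> CategoryPercentRow:
    """All-frequency crosstab row -> rollup input, with InitialFinal folded
    into the Initial column (its provider holds the first visit)."""
    row = crosstab.loc[crosstab["stratum"] == "all"].iloc[0]
    return CategoryPercentRow(
        only=row["Only"],
        majority=row["Majority"],
        plurality=row["Plurality"],
        multplur_initial=row["MultPlur_Initial"] + row["MultPlur_InitialFinal"],
        multplur_final=row["MultPlur_Final"],
        multplur_initialfinal=row["MultPlur_InitialFinal"],
        dispersal=row["Dispersal"],
    )


def pattern_rollup(row: CategoryPercentRow, tol: float = 1e-9) -> PatternRollup:
    """Cumulative identified-predominant percent under patterns 1-6.

    p1 = Only; p2 = p1 + Majority; p3 = p2 + Plurality;
    p4 = p3 + MultPlur_Initial; p5 = p3 + MultPlur_Final;
    p6 = p3 + MultPlur_Initial + MultPlur_Final.
    """
    p1 = row.only
    p2 = p1 + row.majority
    p3 = p2 + row.plurality
    p4 = p3 + row.multplur_initial
    p5 = p3 + row.multplur_final
    p6 = p3 + row.multplur_initial + row.multplur_final
    rollup = PatternRollup(p1, p2, p3, p4, p5, p6)
    if any(v > 100.0 + tol for v in rollup.as_dict().values()):
        raise ValueError(f"inconsistent category row: rollup exceeds 100%: {rollup}")
    return rollup


def chisq_vs_majority(
    counts: pd.DataFrame, stratum: str, category: str
) -> tuple[float, float]:
    """Pearson chi-square (df = 1, no continuity correction) comparing a
    category against the Majority reference across one stratum vs the rest.

    ``counts`` is a stratum x category table of episode counts.  The 2x2
    table is [[n(cat, s), n(cat, rest)], [n(Majority, s), n(Majority, rest)]].
    A zero marginal leaves the statistic undefined (ValueError).
    """
    if category == "Majority":
        raise ValueError("category must differ from the Majority reference")
    a = counts.loc[stratum, category]
    b = counts[category].sum() - a
    c = counts.loc[stratum, "Majority"]
    d = counts["Majority"].sum() - c
    table = np.array([[a, b], [c, d]], dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError(f"zero marginal in 2x2 table for {category!r} x {stratum!r}")
    chi2, p, dof, _ = sps.chi2_contingency(table, correction=False)
    assert dof == 1
    return float(chi2), float(p)


@dataclass
class PairedTResult:
    mean_diff: float
    ci_low: float
    ci_high: float
    t: float
    df: int
    p: float
    degenerate: bool = False


def paired_t(differences: Sequence[float], alpha: float = 0.05) -> PairedTResult:
    """Two-sided paired t-test on a vector of paired differences, with a
    (1 - alpha) confidence interval for the mean difference.

    Zero sample variance is flagged degenerate (t set to 0 by convention
    when the mean is also 0, infinite otherwise).
    """
    d = np.asarray(differences, dtype=float)
    d = d[~np.isnan(d)]
    if d.size < 2:
        raise ValueError("paired t-test needs >= 2 non-missing differences")
    n = d.size
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    df = n - 1
    tcrit = float(sps.t.ppf(1 - alpha / 2, df))
    if sd == 0.0:
        t_stat = 0.0 if mean == 0.0 else math.copysign(math.inf, mean)
        p = 1.0 if mean == 0.0 else 0.0
        return PairedTResult(mean, mean, mean, t_stat, df, p, degenerate=True)
    se = sd / math.sqrt(n)
    t_stat, p = sps.ttest_1samp(d, 0.0)
    return PairedTResult(
        mean, mean - tcrit * se, mean + tcrit * se, float(t_stat), df, float(p)
    )
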