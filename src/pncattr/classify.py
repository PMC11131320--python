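"""Predominant-provider classification — the core attribution algorithm.

Each provider within a pregnancy episode is categorized by its share of the
episode's prenatal visits:

* **Only** — the sole provider (fraction 100%).
* **Majority** — strictly more than half the visits, with ≥ 2 providers.
* **Plurality** — the unique largest fraction, at most 50%.
* **MultPlur** — two or more providers tied at the largest fraction; sequence
  information then distinguishes the one giving the first visit (*Initial*),
  the last visit (*Final*), both (*InitialFinal*), or neither.
* **Other** — any provider below the maximum fraction.

A fraction of exactly one half shared by two providers is MultPlur, not
Majority: majority requires strictly more than half.

Visit concentration is summarized by the Bice–Boxerman continuity-of-care
index ``COC = (Σ n_i² − N) / (N (N − 1))``, which is 1 for a single provider
and 0 exactly when every visit is with a different provider.  That fully
dispersed case (provider count = visit count ≥ 2) carries no usable sequence
signal, so no predominant provider is attributed to it under any pattern.

Six nested identification patterns select the predominant provider:
1 Only; 2 + Majority; 3 + Plurality; 4 + MultPlur holding the first visit;
5 + MultPlur holding the last visit; 6 + MultPlur holding first or last, with
priority to the first-visit holder (prenatal-care adequacy indices weight
initiation heavily, hence the Initial priority).
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

from .types import (
    Category,
    EpisodeClassification,
    MultPlurSubtype,
    PncVisit,
    ProviderEpisodeProfile,
)
from .visits import first_last_flags

__all__ = [
    "compute_fractions",
    "compute_coc",
    "assign_category",
    "assign_multplur_subtype",
    "detect_dispersal",
    "select_predominant",
    "freq_stratum",
    "classify_episode",
    "PATTERNS",
]

logger = logging.getLogger(__name__)

PATTERNS = (1, 2, 3, 4, 5, 6)


def compute_fractions(visits: list[PncVisit]) -> list[ProviderEpisodeProfile]:
    """One profile per distinct SSPI: visit count, fraction, sequence flags."""
    if not visits:
        raise ValueError("episode has no visits")
    n_total = len(visits)
    flags = first_last_flags(visits)
    counts: dict[str, int] = {}
    first_date: dict[str, object] = {}
    group: dict[str, str] = {}
    for v in visits:
        counts[v.sspi] = counts.get(v.sspi, 0) + 1
        if v.sspi not in first_date or v.visit_date < first_date[v.sspi]:
            first_date[v.sspi] = v.visit_date
        group[v.sspi] = v.specialty_group
    episode_id = visits[0].episode_id
    return [
        ProviderEpisodeProfile(
            episode_id=episode_id,
            sspi=sspi,
            n_visits=n,
            fraction=n / n_total,
            has_first=flags[sspi][0],
            has_last=flags[sspi][1],
            specialty_group=group[sspi],
            first_visit_date=first_date[sspi],
        )
        for sspi, n in sorted(counts.items())
    ]


def compute_coc(counts: Sequence[int]) -> float:
    """Bice–Boxerman continuity-of-care index for per-provider visit counts.

    ``(Σ n_i² − N) / (N (N − 1))`` with ``N = Σ n_i``; defined as 1 when
    N = 1 (a single visit is perfectly concentrated).
    """
    if any(c < 1 for c in counts) or not counts:
        raise ValueError("counts must be positive integers")
    n_total = sum(counts)
    if n_total == 1:
        return 1.0
    return (sum(c * c for c in counts) - n_total) / (n_total * (n_total - 1))


def assign_category(profiles: list[ProviderEpisodeProfile]) -> None:
    """Set ``category`` on every profile of one episode, in place."""
    if len(profiles) == 1:
        profiles[0].category = Category.ONLY
        return
    max_n = max(p.n_visits for p in profiles)
    top = [p for p in profiles if p.n_visits == max_n]
    for p in profiles:
        if p.n_visits < max_n:
            p.category = Category.OTHER
        elif len(top) > 1:
            p.category = Category.MULTPLUR
        elif p.fraction > 0.5:
            p.category = Category.MAJORITY
        else:
            p.category = Category.PLURALITY


def assign_multplur_subtype(profiles: list[ProviderEpisodeProfile]) -> None:
    """Set the sequence subtype on MultPlur profiles, in place; others NA."""
    for p in profiles:
        if p.category is not Category.MULTPLUR:
            p.multplur_subtype = MultPlurSubtype.NA
        elif p.has_first and p.has_last:
            p.multplur_subtype = MultPlurSubtype.INITIAL_FINAL
        elif p.has_first:
            p.multplur_subtype = MultPlurSubtype.INITIAL
        elif p.has_last:
            p.multplur_subtype = MultPlurSubtype.FINAL
        else:
            p.multplur_subtype = MultPlurSubtype.NEITHER


def detect_dispersal(n_providers: int, n_total: int) -> bool:
    """Fully dispersed: every visit with a different provider (and ≥ 2)."""
    return n_providers == n_total and n_total >= 2


def _pick(cands: list[ProviderEpisodeProfile]) -> Optional[str]:
    """Deterministic residual tie-break: earliest first visit, then SSPI."""
    if not cands:
        return None
    if len(cands) > 1:
        logger.info(
            "episode %s: tie among %d candidates broken by visit date/SSPI",
            cands[0].episode_id,
            len(cands),
        )
    best = min(cands, key=lambda p: (p.first_visit_date, p.sspi))
    return best.sspi


def select_predominant(
    profiles: list[ProviderEpisodeProfile], pattern: int
) -> Optional[str]:
    """The predominant provider's SSPI under one identification pattern.

    Patterns 1-3 use frequency categories only; 4-6 extend to tied-plurality
    providers via sequence flags.  Fully dispersed episodes return ``None``
    under every pattern.  At most one SSPI is ever returned.
    """
    if pattern not in PATTERNS:
        raise ValueError(f"unknown pattern {pattern!r}; expected 1..6")
    by_cat: dict[Category, list[ProviderEpisodeProfile]] = {}
    for p in profiles:
        by_cat.setdefault(p.category, []).append(p)

    for cat in (Category.ONLY, Category.MAJORITY, Category.PLURALITY)[
        : {1: 1, 2: 2}.get(pattern, 3)
    ]:
        got = by_cat.get(cat)
        if got:
            return got[0].sspi  # these categories are unique by construction

    if pattern <= 3:
        return None

    multplur = by_cat.get(Category.MULTPLUR, [])
    n_total = sum(p.n_visits for p in profiles)
    if detect_dispersal(len(profiles), n_total):
        return None
    if pattern == 4:
        return _pick([p for p in multplur if p.has_first])
    if pattern == 5:
        return _pick([p for p in multplur if p.has_last])
    # pattern 6: first-visit holder takes priority over last-visit holder
    return _pick([p for p in multplur if p.has_first]) or _pick(
        [p for p in multplur if p.has_last]
    )


def freq_stratum(n_total: int, bounds: Sequence[int] = (1, 8, 14)) -> str:
    """Visit-count stratum label: "=1", "2-8", "9-14" or ">14" (default cuts)."""
    if n_total < 1:
        raise ValueError("visit count must be >= 1")
    b1, b2, b3 = bounds
    if n_total <= b1:
        return f"={b1}"
    if n_total <= b2:
        return f"{b1 + 1}-{b2}"
    if n_total <= b3:
        return f"{b2 + 1}-{b3}"
    return f">{b3}"


def classify_episode(
    visits: list[PncVisit], bounds: Sequence[int] = (1, 8, 14)
) -> tuple[list[ProviderEpisodeProfile], EpisodeClassification]:
    """Run the full per-episode algorithm: profiles plus episode summary."""
    profiles = compute_fractions(visits)
    assign_category(profiles)
    assign_multplur_subtype(profiles)
    n_total = len(visits)
    counts = [p.n_visits for p in profiles]
    classification = EpisodeClassification(
        episode_id=profiles[0].episode_id,
        n_total=n_total,
        n_providers=len(profiles),
        coc_index=compute_coc(counts),
        dispersal=detect_dispersal(len(profiles), n_total),
        freq_stratum=freq_stratum(n_total, bounds),
        predominant_by_pattern={
            k: select_predominant(profiles, k) for k in PATTERNS
        },
    )
    return profiles, classification
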