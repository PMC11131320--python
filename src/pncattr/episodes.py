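"""Pregnancy episode construction and cohort filtering.

Each delivery record anchors one episode whose claim window runs from
``delivery_month - (gestational_age - 1)`` through the delivery month,
inclusive — all arithmetic at month granularity, matching the precision at
which claims data typically releases dates.  Episodes are kept in the analytic
cohort only if the member was continuously enrolled across the whole window
(a claims gap would otherwise masquerade as a care gap).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .config import CodeConfig
from .types import ClaimRecord, DeliveryRecord, EnrollmentSpan, Month, PregnancyEpisode

__all__ = [
    "build_episodes",
    "check_continuous_enrollment",
    "assign_claims_to_episode",
    "EpisodeBuildReport",
]


@dataclass
class EpisodeBuildReport:
    """Deliveries rejected during episode construction, with reasons."""

    rejected: list[tuple[str, str]] = field(default_factory=list)


def build_episodes(
    deliveries: list[DeliveryRecord], config: CodeConfig
) -> tuple[list[PregnancyEpisode], EpisodeBuildReport]:
    """Construct one episode per delivery record.

    Gestational age defaults to ``config.default_gestation_months`` when the
    record carries none; ages outside [1, 12] are rejected with a report.
    When one member has overlapping windows, the later delivery wins the
    contested months: the earlier episode's window is truncated to end before
    the later window begins (with a warning).
    """
    report = EpisodeBuildReport()
    episodes: list[PregnancyEpisode] = []
    for d in deliveries:
        ga = d.gestational_age_months or config.default_gestation_months
        if not 1 <= ga <= 12:
            report.rejected.append((d.birth_id, f"gestational age {ga} out of [1, 12]"))
            continue
        start = d.delivery_month - (ga - 1)
        episodes.append(
            PregnancyEpisode(
                episode_id=f"E-{d.birth_id}",
                member_id=d.member_id,
                delivery_month=d.delivery_month,
                window_start=start,
                window_end=d.delivery_month,
            )
        )

    # resolve overlapping windows per member: later delivery keeps its months
    by_member: dict[str, list[PregnancyEpisode]] = {}
    for e in episodes:
        by_member.setdefault(e.member_id, []).append(e)
    for member, eps in by_member.items():
        eps.sort(key=lambda e: (e.delivery_month, e.episode_id))
        for earlier, later in zip(eps, eps[1:]):
            if earlier.window_end >= later.window_start:
                warnings.warn(
                    f"overlapping pregnancy windows for member {member}; "
                    f"truncating {earlier.episode_id} before {later.window_start}",
                    stacklevel=2,
                )
                earlier.window_end = later.window_start - 1
    return episodes, report


def check_continuous_enrollment(
    episode: PregnancyEpisode, spans: list[EnrollmentSpan]
) -> bool:
    """True iff every month of the gestational window is covered by the spans.

    Adjacent or overlapping spans union; no spans means not enrolled.
    """
    own = [s for s in spans if s.member_id == episode.member_id]
    m = episode.window_start
    while m <= episode.window_end:
        if not any(s.covers(m) for s in own):
            return False
        m = m + 1
    return True


def assign_claims_to_episode(
    episode: PregnancyEpisode, claims: list[ClaimRecord]
) -> list[ClaimRecord]:
    """Exactly the member's claims whose service month falls in the window."""
    return [
        c
        for c in claims
        if c.member_id == episode.member_id and episode.in_window(Month.of(c.service_date))
    ]
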