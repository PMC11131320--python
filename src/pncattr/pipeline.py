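"""End-to-end orchestration: claims tables in, classified cohort out.

Implements the cohort filter funnel — all claims → in-window claims →
prenatal-care claims → deduplicated visits — and keeps an episode in the
analytic cohort only when its member is continuously enrolled for the whole
gestational window and at least one prenatal visit remains.  Stage counts are
recorded so cohort attrition stays auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .classify import classify_episode
from .config import CodeConfig
from .episodes import (
    assign_claims_to_episode,
    build_episodes,
    check_continuous_enrollment,
)
from .types import (
    ClaimRecord,
    DeliveryRecord,
    EnrollmentSpan,
    EpisodeClassification,
    PncVisit,
    PregnancyEpisode,
    ProviderEpisodeProfile,
)
from .visits import dedupe_to_visits, is_pnc_claim

__all__ = ["PipelineResult", "run_cohort"]


@dataclass
class PipelineResult:
    """Everything downstream reporting needs, plus the attrition funnel."""

    episodes: list[PregnancyEpisode]
    kept_episode_ids: list[str]
    exclusion_reasons: dict[str, str]
    visits_by_episode: dict[str, list[PncVisit]]
    profiles_by_episode: dict[str, list[ProviderEpisodeProfile]]
    classifications: list[EpisodeClassification]
    stage_counts: dict[str, int] = field(default_factory=dict)

    @property
    def all_profiles(self) -> list[ProviderEpisodeProfile]:
        return [p for profs in self.profiles_by_episode.values() for p in profs]

    def visited_sspis(self) -> dict[str, list[str]]:
        return {
            eid: sorted({v.sspi for v in visits})
            for eid, visits in self.visits_by_episode.items()
        }

    def classification_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.classifications:
            rows.append(
                {
                    "episode_id": c.episode_id,
                    "n_total": c.n_total,
                    "n_providers": c.n_providers,
                    "coc_index": c.coc_index,
                    "dispersal": c.dispersal,
                    "freq_stratum": c.freq_stratum,
                    **{
                        f"pattern_{k}": v or ""
                        for k, v in sorted(c.predominant_by_pattern.items())
                    },
                }
            )
        return pd.DataFrame(rows)

    def profile_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "episode_id": p.episode_id,
                    "sspi": p.sspi,
                    "specialty_group": p.specialty_group,
                    "n_visits": p.n_visits,
                    "fraction": p.fraction,
                    "has_first": p.has_first,
                    "has_last": p.has_last,
                    "category": p.category.value,
                    "multplur_subtype": p.multplur_subtype.value,
                }
                for p in self.all_profiles
            ]
        )

    def visit_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "episode_id": v.episode_id,
                    "sspi": v.sspi,
                    "specialty_group": v.specialty_group,
                    "visit_date": v.visit_date.isoformat(),
                    "seq_index": v.seq_index,
                }
                for visits in self.visits_by_episode.values()
                for v in visits
            ]
        )


def run_cohort(
    claims: list[ClaimRecord],
    enrollment: list[EnrollmentSpan],
    deliveries: list[DeliveryRecord],
    config: Optional[CodeConfig] = None,
) -> PipelineResult:
    """Run the full attribution pipeline on in-memory tables."""
    config = config or CodeConfig()
    episodes, _ = build_episodes(deliveries, config)

    claims_by_member: dict[str, list[ClaimRecord]] = {}
    for c in claims:
        claims_by_member.setdefault(c.member_id, []).append(c)
    spans_by_member: dict[str, list[EnrollmentSpan]] = {}
    for s in enrollment:
        spans_by_member.setdefault(s.member_id, []).append(s)

    kept: list[str] = []
    reasons: dict[str, str] = {}
    visits_by_episode: dict[str, list[PncVisit]] = {}
    profiles_by_episode: dict[str, list[ProviderEpisodeProfile]] = {}
    classifications: list[EpisodeClassification] = []
    n_in_window = n_pnc = n_visits = 0

    for ep in episodes:
        member_claims = claims_by_member.get(ep.member_id, [])
        in_window = assign_claims_to_episode(ep, member_claims)
        n_in_window += len(in_window)
        pnc = [c for c in in_window if is_pnc_claim(c, config)]
        n_pnc += len(pnc)
        ep.continuously_enrolled = check_continuous_enrollment(
            ep, spans_by_member.get(ep.member_id, [])
        )
        if not ep.continuously_enrolled:
            reasons[ep.episode_id] = "not_enrolled"
            continue
        if not pnc:
            reasons[ep.episode_id] = "no_pnc"
            continue
        visits = dedupe_to_visits(ep, pnc, config)
        n_visits += len(visits)
        profiles, classification = classify_episode(
            visits, config.frequency_strata_bounds
        )
        kept.append(ep.episode_id)
        visits_by_episode[ep.episode_id] = visits
        profiles_by_episode[ep.episode_id] = profiles
        classifications.append(classification)

    return PipelineResult(
        episodes=episodes,
        kept_episode_ids=kept,
        exclusion_reasons=reasons,
        visits_by_episode=visits_by_episode,
        profiles_by_episode=profiles_by_episode,
        classifications=classifications,
        stage_counts={
            "claims_total": len(claims),
            "claims_in_window": n_in_window,
            "claims_pnc": n_pnc,
            "pnc_visits": n_visits,
            "episodes_total": len(episodes),
            "episodes_kept": len(kept),
        },
    )
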