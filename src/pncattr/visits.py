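"""Prenatal-care visit identification and claim-to-visit collapsing.

A claim counts as prenatal care when its procedure code or primary-diagnosis
prefix is in the configured lists AND its provider specialty is in the
included universe.  Because one billing identifier can be shared by different
professionals, providers are keyed by the specialty-specified provider
identifier (SSPI): ``provider_id`` joined with ``specialty_code``.

Billing commonly splits one encounter into several claim lines, so claims
collapse to visits on the key ``(sspi, service_date)``: one provider, one day,
one visit.
"""

from __future__ import annotations

from .config import CodeConfig
from .types import ClaimRecord, PncVisit, PregnancyEpisode

__all__ = [
    "SSPI_DELIMITER",
    "is_pnc_claim",
    "make_sspi",
    "split_sspi",
    "dedupe_to_visits",
    "first_last_flags",
]

SSPI_DELIMITER = "|"


def is_pnc_claim(claim: ClaimRecord, config: CodeConfig) -> bool:
    """Whether an in-window claim is a prenatal-care service."""
    if claim.specialty_code not in config.included_specialties:
        return False
    if claim.procedure_code and claim.procedure_code in config.pnc_procedure_codes:
        return True
    return any(claim.primary_dx.startswith(p) for p in config.pnc_dx_prefixes)


def make_sspi(provider_id: str, specialty_code: str) -> str:
    """Specialty-specified provider identifier: injective ``id|specialty``."""
    if not provider_id or not specialty_code:
        raise ValueError("provider_id and specialty_code must be non-empty")
    if SSPI_DELIMITER in provider_id:
        raise ValueError(
            f"provider_id contains reserved delimiter {SSPI_DELIMITER!r}: {provider_id!r}"
        )
    return f"{provider_id}{SSPI_DELIMITER}{specialty_code}"


def split_sspi(sspi: str) -> tuple[str, str]:
    provider_id, _, specialty = sspi.partition(SSPI_DELIMITER)
    return provider_id, specialty


def dedupe_to_visits(
    episode: PregnancyEpisode, pnc_claims: list[ClaimRecord], config: CodeConfig
) -> list[PncVisit]:
    """Collapse PNC claims to visits: one per distinct ``(sspi, date)``.

    Visits are sorted by ``(visit_date, sspi)`` and given dense sequence
    indices 1..n; same-date visits to different providers get distinct stable
    indices in SSPI order.
    """
    keys = {
        (make_sspi(c.provider_id, c.specialty_code), c.service_date): c.specialty_code
        for c in pnc_claims
    }
    ordered = sorted(keys.items(), key=lambda kv: (kv[0][1], kv[0][0]))
    return [
        PncVisit(
            episode_id=episode.episode_id,
            sspi=sspi,
            specialty_group=config.group_of(spec),
            visit_date=date,
            seq_index=i,
        )
        for i, ((sspi, date), spec) in enumerate(ordered, start=1)
    ]


def first_last_flags(visits: list[PncVisit]) -> dict[str, tuple[bool, bool]]:
    """Per-SSPI (has_first, has_last) flags for one episode's visits.

    Every provider with a visit on the earliest date has_first; every provider
    with a visit on the latest date has_last.  Date ties flag all tied
    providers — resolution is deferred to the pattern tie-breaks.
    """
    if not visits:
        raise ValueError("first_last_flags requires a non-empty visit list")
    first_date = min(v.visit_date for v in visits)
    last_date = max(v.visit_date for v in visits)
    flags: dict[str, tuple[bool, bool]] = {}
    for v in visits:
        f, l = flags.get(v.sspi, (False, False))
        flags[v.sspi] = (f or v.visit_date == first_date, l or v.visit_date == last_date)
    return flags
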