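"""Seeded generator of labelled synthetic claims cohorts.

Each generated pregnancy episode is *planted* into one utilization regime —
exclusive provider, majority, unique plurality, the three tied-plurality
sequence variants, full dispersal, or a no-predominant layout — with visit
counts drawn from configurable frequency strata.  The layouts guarantee the
intended classification by construction, so the generator's ground-truth
labels serve as an exact oracle for the attribution algorithm.

Default mixes emulate the composition observed in a large state Medicaid
pregnancy cohort (roughly 28% exclusive, 20% majority, 33% plurality, 10%
tied-plurality with usable sequence information, 7% dispersed, 1%
unidentifiable; strata 6/49/40/5% across visit-count bins).  The generator
reproduces only the structural features the algorithm consumes — visit
counts, provider sharing, dates, specialties, zips — not real billing
distributions.

Randomness is hierarchical: one global seed feeds a per-episode stream keyed
by episode index, so enlarging a cohort never reshuffles existing episodes.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from numpy.random import Generator, SeedSequence, default_rng
from pydantic import BaseModel, Field, model_validator

from .config import CodeConfig
from .types import (
    ClaimRecord,
    DeliveryRecord,
    EnrollmentSpan,
    Month,
    ZipGazetteerEntry,
)
from .visits import make_sspi

__all__ = [
    "ScenarioConfig",
    "NoiseConfig",
    "GroundTruthLabel",
    "GeneratedCohort",
    "generate_cohort",
    "perturb_noise",
    "REGIMES",
]

REGIMES = (
    "only",
    "majority",
    "plurality",
    "multplur_initial",
    "multplur_final",
    "multplur_initialfinal",
    "dispersal",
    "other_dominant",
)

#: Smallest visit count at which each regime's layout is constructible.
_MIN_VISITS = {
    "only": 1,
    "majority": 3,
    "plurality": 4,
    "multplur_initial": 4,
    "multplur_initialfinal": 4,
    "multplur_final": 5,
    "dispersal": 2,
    "other_dominant": 6,
}

_DEFAULT_REGIME_MIX = {
    "only": 0.2840,
    "majority": 0.1955,
    "plurality": 0.3349,
    "multplur_initial": 0.0589,
    "multplur_final": 0.0305,
    "multplur_initialfinal": 0.0142,
    "dispersal": 0.0712,
    "other_dominant": 0.0108,
}

_DEFAULT_STRATUM_WEIGHTS = {"=1": 0.0618, "2-8": 0.4899, "9-14": 0.4022, ">14": 0.0462}

_DEFAULT_SPECIALTY_MIX = {
    "obgyn": 0.45,
    "primary_care": 0.20,
    "organization": 0.15,
    "nurse_practitioner": 0.08,
    "midwife": 0.05,
    "other": 0.05,
    "missing": 0.02,
}

_GROUP_CODES = {
    "midwife": ["06"],
    "primary_care": ["12", "14", "19", "78"],
    "obgyn": ["16", "26", "27"],
    "organization": ["50", "97"],
    "nurse_practitioner": ["86"],
    "other": ["02", "10", "40", "48", "57", "94", "95", "PA"],
    "missing": ["missing"],
}


class ScenarioConfig(BaseModel):
    """Composition and scale of one synthetic cohort."""

    n_episodes: int = 1000
    regime_mix: dict[str, float] = Field(default_factory=lambda: dict(_DEFAULT_REGIME_MIX))
    stratum_weights: dict[str, float] = Field(
        default_factory=lambda: dict(_DEFAULT_STRATUM_WEIGHTS)
    )
    specialty_mix: dict[str, float] = Field(
        default_factory=lambda: dict(_DEFAULT_SPECIALTY_MIX)
    )
    max_visits: int = 20
    provider_pool_size: int = 200
    zip_pool_size: int = 30
    n_out_of_state_zips: int = 3
    #: coordinate box (south, north, west, east) — defaults roughly coastal-
    #: plain southeastern US
    lat_range: tuple[float, float] = (32.0, 35.2)
    lon_range: tuple[float, float] = (-83.4, -78.5)
    enrollment_gap_rate: float = 0.1
    out_of_state_residence_rate: float = 0.05
    gestation_months: int = 9
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "ScenarioConfig":
        if self.n_episodes < 1:
            raise ValueError("n_episodes must be >= 1")
        unknown = set(self.regime_mix) - set(REGIMES)
        if unknown:
            raise ValueError(f"unknown regimes: {sorted(unknown)}")
        if abs(sum(self.regime_mix.values()) - 1.0) > 1e-9:
            raise ValueError("regime_mix proportions must sum to 1")
        for name, p in {**self.regime_mix, **self.stratum_weights}.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"proportion out of [0,1] for {name!r}: {p}")
        if not 0.0 <= self.enrollment_gap_rate <= 1.0:
            raise ValueError("enrollment_gap_rate must be a probability")
        if self.max_visits < 15:
            raise ValueError("max_visits must cover the >14 stratum (>= 15)")
        return self


class NoiseConfig(BaseModel):
    """Rates of filterable perturbations added on top of a clean cohort.

    Every perturbation is designed to be removed by the pipeline's window,
    code or specialty filters, so ground-truth labels stay valid.
    """

    duplicate_claim_rate: float = 0.0
    out_of_window_rate: float = 0.0
    non_pnc_rate: float = 0.0
    missing_specialty_rate: float = 0.5  # share of noise claims with blank specialty
    excluded_specialty_code: str = "99"


@dataclass
class GroundTruthLabel:
    episode_id: str
    planted_regime: str
    planted_predominant_sspi: Optional[str]
    planted_n_visits: int
    planted_n_providers: int
    continuously_enrolled: bool = True


@dataclass
class GeneratedCohort:
    """All tables one run of the pipeline consumes, plus ground truth."""

    claims: list[ClaimRecord]
    enrollment: list[EnrollmentSpan]
    deliveries: list[DeliveryRecord]
    gazetteer: dict[str, ZipGazetteerEntry]
    labels: list[GroundTruthLabel]
    provider_zips: dict[str, str] = field(default_factory=dict)
    residence_zips: dict[str, str] = field(default_factory=dict)
    config: Optional[ScenarioConfig] = None


def _stratum_range(label: str, max_visits: int) -> tuple[int, int]:
    return {"=1": (1, 1), "2-8": (2, 8), "9-14": (9, 14), ">14": (15, max_visits)}[label]


def _draw_n_visits(rng: Generator, regime: str, cfg: ScenarioConfig) -> int:
    """Visit count: stratum by weight, uniform within, respecting the
    regime's feasibility floor."""
    lo_req = _MIN_VISITS[regime]
    allowed = {
        s: w
        for s, w in cfg.stratum_weights.items()
        if w > 0 and _stratum_range(s, cfg.max_visits)[1] >= lo_req
    }
    if not allowed:
        raise ValueError(
            f"infeasible scenario: regime {regime!r} needs >= {lo_req} visits but "
            f"no stratum with positive weight allows that"
        )
    names = sorted(allowed)
    w = np.array([allowed[s] for s in names])
    s = names[rng.choice(len(names), p=w / w.sum())]
    lo, hi = _stratum_range(s, cfg.max_visits)
    return int(rng.integers(max(lo, lo_req), hi + 1))


def _tied_layout(
    rng: Generator, regime: str, n: int
) -> tuple[list[int], int]:
    """Per-provider date-index assignment for one episode.

    Returns (assignment, predominant_index): ``assignment[j]`` is the
    provider index owning the j-th earliest visit date; ``predominant_index``
    is the provider the pattern-6 rule must select, or -1 for none.
    Provider 0 is "A", 1 is "B", higher indices are fillers.
    """
    if regime == "only":
        return [0] * n, 0
    if regime == "dispersal":
        return list(range(n)), -1

    if regime in ("majority", "plurality"):
        # provider 0 takes a visits; everyone else stays strictly below a,
        # which makes the maximum unique in both regimes
        a = n // 2 + (1 if regime == "majority" else 0)
        counts = [a]
        rest = n - a
        while rest > 0:
            take = min(a - 1, rest)
            counts.append(take)
            rest -= take
        assignment = np.repeat(np.arange(len(counts)), counts)
        rng.shuffle(assignment)
        return assignment.tolist(), 0

    # tied-plurality layouts: providers 0 ("A") and 1 ("B") share the max m
    m = min(max(2, n // 3), n // 2)
    slots = [-1] * n  # -1 = unassigned date slot
    middle = list(range(1, n - 1))
    rng.shuffle(middle)

    def take_middle(k: int) -> list[int]:
        return [middle.pop() for _ in range(k)]

    if regime == "multplur_initial":
        slots[0] = 0
        for j in take_middle(m - 1):
            slots[j] = 0
        slots[n - 1] = 1
        for j in take_middle(m - 1):
            slots[j] = 1
        pred = 0
    elif regime == "multplur_final":
        m = min(m, (n - 1) // 2)
        slots[0] = 2  # a filler holds the first visit
        slots[n - 1] = 1
        for j in take_middle(m - 1):
            slots[j] = 1
        for j in take_middle(m):
            slots[j] = 0  # "A" is tied but holds neither endpoint
        pred = 1
    elif regime == "multplur_initialfinal":
        m = min(m, n // 2)
        slots[0] = 0
        slots[n - 1] = 0
        for j in take_middle(m - 2):
            slots[j] = 0
        for j in take_middle(m):
            slots[j] = 1
        pred = 0
    elif regime == "other_dominant":
        m = min(m, (n - 2) // 2)
        slots[0] = 2
        slots[n - 1] = 3
        for j in take_middle(m):
            slots[j] = 0
        for j in take_middle(m):
            slots[j] = 1
        pred = -1
    else:  # pragma: no cover
        raise ValueError(f"unknown regime {regime!r}")

    # unassigned middle dates go to distinct single-visit fillers
    next_filler = max(slots) + 1
    for j in range(n):
        if slots[j] == -1:
            slots[j] = next_filler
            next_filler += 1
    return slots, pred


def _build_provider_pool(rng: Generator, cfg: ScenarioConfig) -> list[tuple[str, str]]:
    """(provider_id, specialty_code) pool with specialties drawn by group mix."""
    groups = sorted(g for g, w in cfg.specialty_mix.items() if w > 0)
    w = np.array([cfg.specialty_mix[g] for g in groups])
    pool = []
    for i in range(cfg.provider_pool_size):
        g = groups[rng.choice(len(groups), p=w / w.sum())]
        codes = _GROUP_CODES[g]
        spec = codes[rng.integers(len(codes))]
        pool.append((f"P{i:04d}", spec))
    return pool


def _build_gazetteer(rng: Generator, cfg: ScenarioConfig) -> dict[str, ZipGazetteerEntry]:
    out: dict[str, ZipGazetteerEntry] = {}
    lat0, lat1 = cfg.lat_range
    lon0, lon1 = cfg.lon_range
    for i in range(cfg.zip_pool_size):
        out_of_state = i >= cfg.zip_pool_size - cfg.n_out_of_state_zips
        lat = float(rng.uniform(lat0, lat1)) + (3.0 if out_of_state else 0.0)
        lon = float(rng.uniform(lon0, lon1))
        area = float(np.exp(rng.normal(3.0, 0.6)))  # ~20 sq mi typical
        out[f"29{i:03d}"] = ZipGazetteerEntry(
            zip=f"29{i:03d}",
            centroid_lat=lat,
            centroid_lon=lon,
            land_area=area,
            in_state=not out_of_state,
        )
    return out


def _pnc_codes(rng: Generator, code_config: CodeConfig) -> tuple[str, str]:
    """(primary_dx, procedure_code) that qualify as prenatal care."""
    if rng.random() < 0.7:
        prefix = sorted(code_config.pnc_dx_prefixes)[
            rng.integers(len(code_config.pnc_dx_prefixes))
        ]
        return f"{prefix}.{rng.integers(0, 99):02d}", ""
    proc = sorted(code_config.pnc_procedure_codes)[
        rng.integers(len(code_config.pnc_procedure_codes))
    ]
    return "R99", proc  # dx deliberately non-qualifying; procedure carries it


def generate_cohort(
    config: ScenarioConfig, code_config: Optional[CodeConfig] = None
) -> GeneratedCohort:
    """Generate a labelled cohort; deterministic for a fixed seed."""
    code_config = code_config or CodeConfig()
    global_rng = default_rng(SeedSequence([config.seed, 0]))
    gazetteer = _build_gazetteer(global_rng, config)
    pool = _build_provider_pool(global_rng, config)
    in_state_zips = sorted(z for z, e in gazetteer.items() if e.in_state)
    all_zips = sorted(gazetteer)
    provider_zips = {
        make_sspi(pid, spec): in_state_zips[int(global_rng.integers(len(in_state_zips)))]
        if global_rng.random() > 0.05
        else all_zips[int(global_rng.integers(len(all_zips)))]
        for pid, spec in pool
    }

    regimes = sorted(config.regime_mix)
    mix = np.array([config.regime_mix[r] for r in regimes])
    mix = mix / mix.sum()

    claims: list[ClaimRecord] = []
    enrollment: list[EnrollmentSpan] = []
    deliveries: list[DeliveryRecord] = []
    labels: list[GroundTruthLabel] = []
    residence_zips: dict[str, str] = {}

    for i in range(config.n_episodes):
        rng = default_rng(SeedSequence([config.seed, 1, i]))
        regime = regimes[rng.choice(len(regimes), p=mix)]
        n = _draw_n_visits(rng, regime, config)
        assignment, pred_idx = _tied_layout(rng, regime, n)
        n_providers = max(assignment) + 1

        member_id = f"M{i:05d}"
        birth_id = f"B{i:05d}"
        episode_id = f"E-{birth_id}"
        delivery = Month(2016, 1) + int(rng.integers(0, 30))
        window_start = delivery - (config.gestation_months - 1)
        deliveries.append(
            DeliveryRecord(birth_id, member_id, delivery, config.gestation_months)
        )

        # distinct visit dates across the gestational window, sorted
        first_day = window_start.first_day()
        span_days = ((delivery + 1).first_day() - first_day).days
        offsets = np.sort(rng.choice(span_days, size=n, replace=False))
        dates = [first_day + _dt.timedelta(days=int(o)) for o in offsets]

        # distinct providers for this episode, sampled from the shared pool
        chosen = rng.choice(len(pool), size=n_providers, replace=False)
        providers = [pool[int(j)] for j in chosen]
        sspis = [make_sspi(pid, spec) for pid, spec in providers]

        for j, (date, prov_idx) in enumerate(zip(dates, assignment)):
            pid, spec = providers[prov_idx]
            dx, proc = _pnc_codes(rng, code_config)
            claims.append(
                ClaimRecord(
                    claim_id=f"C{i:05d}-{j:02d}",
                    member_id=member_id,
                    provider_id=pid,
                    specialty_code=spec,
                    service_date=date,
                    primary_dx=dx,
                    procedure_code=proc,
                    claim_class="office",
                )
            )

        gap = (
            rng.random() < config.enrollment_gap_rate and config.gestation_months >= 2
        )
        pad_pre, pad_post = int(rng.integers(0, 4)), int(rng.integers(0, 4))
        if gap:
            # punch a one-month hole inside the window
            hole = window_start + int(rng.integers(0, config.gestation_months - 1))
            if hole - 1 >= window_start - pad_pre:
                enrollment.append(
                    EnrollmentSpan(member_id, window_start - pad_pre, hole - 1)
                )
            enrollment.append(EnrollmentSpan(member_id, hole + 1, delivery + pad_post))
        else:
            enrollment.append(
                EnrollmentSpan(member_id, window_start - pad_pre, delivery + pad_post)
            )

        if rng.random() < config.out_of_state_residence_rate:
            residence_zips[episode_id] = all_zips[int(rng.integers(len(all_zips)))]
        else:
            residence_zips[episode_id] = in_state_zips[
                int(rng.integers(len(in_state_zips)))
            ]

        labels.append(
            GroundTruthLabel(
                episode_id=episode_id,
                planted_regime=regime,
                planted_predominant_sspi=sspis[pred_idx] if pred_idx >= 0 else None,
                planted_n_visits=n,
                planted_n_providers=n_providers,
                continuously_enrolled=not gap,
            )
        )

    return GeneratedCohort(
        claims=claims,
        enrollment=enrollment,
        deliveries=deliveries,
        gazetteer=gazetteer,
        labels=labels,
        provider_zips=provider_zips,
        residence_zips=residence_zips,
        config=config,
    )


def perturb_noise(cohort: GeneratedCohort, noise: NoiseConfig) -> GeneratedCohort:
    """Add filterable noise claims; ground-truth labels remain valid.

    Duplicate lines collapse in visit deduplication; out-of-window claims are
    dropped by the gestational window; non-prenatal claims (including those
    with blank or excluded specialties) are dropped by the code/specialty
    filter.
    """
    cfg = cohort.config or ScenarioConfig()
    rng = default_rng(SeedSequence([cfg.seed, 2]))
    by_member: dict[str, list[ClaimRecord]] = {}
    for c in cohort.claims:
        by_member.setdefault(c.member_id, []).append(c)
    extra: list[ClaimRecord] = []
    serial = 0
    for member, mclaims in sorted(by_member.items()):
        for c in mclaims:
            if rng.random() < noise.duplicate_claim_rate:
                extra.append(
                    ClaimRecord(
                        claim_id=f"N{serial:06d}",
                        member_id=c.member_id,
                        provider_id=c.provider_id,
                        specialty_code=c.specialty_code,
                        service_date=c.service_date,
                        primary_dx=c.primary_dx,
                        procedure_code=c.procedure_code,
                        claim_class=c.claim_class,
                    )
                )
                serial += 1
            if rng.random() < noise.out_of_window_rate:
                early = c.service_date.replace(day=1) - _dt.timedelta(days=400)
                extra.append(
                    ClaimRecord(
                        claim_id=f"N{serial:06d}",
                        member_id=c.member_id,
                        provider_id=c.provider_id,
                        specialty_code=c.specialty_code,
                        service_date=early,
                        primary_dx=c.primary_dx,
                        procedure_code=c.procedure_code,
                        claim_class="office",
                    )
                )
                serial += 1
            if rng.random() < noise.non_pnc_rate:
                blank = rng.random() < noise.missing_specialty_rate
                extra.append(
                    ClaimRecord(
                        claim_id=f"N{serial:06d}",
                        member_id=c.member_id,
                        provider_id=c.provider_id,
                        specialty_code=(
                            "missing" if blank else noise.excluded_specialty_code
                        ),
                        # unrelated acute-care diagnosis; never matches the
                        # prenatal code lists
                        primary_dx="J06.9",
                        procedure_code="",
                        service_date=c.service_date,
                        claim_class="office",
                    )
                )
                serial += 1
    return GeneratedCohort(
        claims=cohort.claims + extra,
        enrollment=cohort.enrollment,
        deliveries=cohort.deliveries,
        gazetteer=cohort.gazetteer,
        labels=cohort.labels,
        provider_zips=cohort.provider_zips,
        residence_zips=cohort.residence_zips,
        config=cohort.config,
    )
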