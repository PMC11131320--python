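"""Core domain records for claims-based prenatal-care provider attribution.

All tabular inputs and intermediate products of the pipeline are plain
dataclasses; month-precision calendar arithmetic is handled by :class:`Month`.
Claims data commonly releases service dates at month precision only, so every
date-bearing record tracks whether its day component was imputed.
"""

from __future__ import annotations

import datetime as _dt
import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

__all__ = [
    "Month",
    "ClaimRecord",
    "EnrollmentSpan",
    "DeliveryRecord",
    "ZipGazetteerEntry",
    "PregnancyEpisode",
    "PncVisit",
    "ProviderEpisodeProfile",
    "EpisodeClassification",
    "Category",
    "MultPlurSubtype",
    "MISSING_SPECIALTY",
    "IMPUTED_DAY",
    "parse_service_date",
]

#: Sentinel for claims whose provider specialty field is blank/unknown.
MISSING_SPECIALTY = "missing"

#: Day used when a service date arrives at month precision.
IMPUTED_DAY = 15

_YM_RE = re.compile(r"^(\d{4})-(\d{2})$")


@dataclass(frozen=True, order=True)
class Month:
    """A calendar month (year-month), the unit of gestational-window arithmetic.

    Supports ``month + k`` / ``month - k`` (integer months), subtraction of two
    months (number of months between them), and total ordering.
    """

    year: int
    month: int

    def __post_init__(self) -> None:
        if not 1 <= self.month <= 12:
            raise ValueError(f"month out of range: {self.month}")

    @classmethod
    def parse(cls, text: str) -> "Month":
        m = _YM_RE.match(text.strip())
        if not m:
            raise ValueError(f"not a YYYY-MM month: {text!r}")
        return cls(int(m.group(1)), int(m.group(2)))

    @classmethod
    def of(cls, d: _dt.date) -> "Month":
        return cls(d.year, d.month)

    def _index(self) -> int:
        return self.year * 12 + (self.month - 1)

    def __add__(self, k: int) -> "Month":
        i = self._index() + k
        return Month(i // 12, i % 12 + 1)

    def __sub__(self, other):
        if isinstance(other, Month):
            return self._index() - other._index()
        return self + (-other)

    def first_day(self) -> _dt.date:
        return _dt.date(self.year, self.month, 1)

    def __str__(self) -> str:
        return f"{self.year:04d}-{self.month:02d}"


def parse_service_date(text: str) -> tuple[_dt.date, bool]:
    """Parse ``YYYY-MM-DD`` or month-precision ``YYYY-MM``.

    Month-precision dates get day ``15`` so that within-episode sequence logic
    operates on a total order; the returned flag records the imputation.

    Returns
    -------
    (date, day_imputed)
    """
    text = text.strip()
    if _YM_RE.match(text):
        ym = Month.parse(text)
        return _dt.date(ym.year, ym.month, IMPUTED_DAY), True
    return _dt.date.fromisoformat(text), False


class Category(str, Enum):
    """Per-provider visit-share category within one pregnancy episode."""

    ONLY = "Only"
    MAJORITY = "Majority"
    PLURALITY = "Plurality"
    MULTPLUR = "MultPlur"
    OTHER = "Other"


class MultPlurSubtype(str, Enum):
    """Sequence subtype of a tied-plurality (MultPlur) provider."""

    INITIAL = "Initial"
    FINAL = "Final"
    INITIAL_FINAL = "InitialFinal"
    NEITHER = "Neither"
    NA = "NA"


@dataclass
class ClaimRecord:
    """One billed service line — the raw input unit."""

    claim_id: str
    member_id: str
    provider_id: str
    specialty_code: str
    service_date: _dt.date
    primary_dx: str
    procedure_code: str = ""
    claim_class: str = "office"
    day_imputed: bool = False


@dataclass
class EnrollmentSpan:
    """An inclusive month range of insurance coverage for one member."""

    member_id: str
    start_month: Month
    end_month: Month

    def __post_init__(self) -> None:
        if self.start_month > self.end_month:
            raise ValueError(
                f"span start {self.start_month} after end {self.end_month}"
            )

    def covers(self, m: Month) -> bool:
        return self.start_month <= m <= self.end_month


@dataclass
class DeliveryRecord:
    """One live birth; the anchor from which a pregnancy episode is dated."""

    birth_id: str
    member_id: str
    delivery_month: Month
    gestational_age_months: Optional[int] = None

    def __post_init__(self) -> None:
        g = self.gestational_age_months
        if g is not None and not 1 <= g <= 12:
            raise ValueError(f"gestational age out of [1, 12]: {g}")


@dataclass
class ZipGazetteerEntry:
    """Zip-code centroid coordinates and land area (square miles)."""

    zip: str
    centroid_lat: float
    centroid_lon: float
    land_area: float
    in_state: bool = True

    def __post_init__(self) -> None:
        if self.land_area <= 0:
            raise ValueError(f"land area must be positive: {self.land_area}")
        if abs(self.centroid_lat) > 90 or abs(self.centroid_lon) > 180:
            raise ValueError("coordinates out of range")


@dataclass
class PregnancyEpisode:
    """One pregnancy: a gestational claim window ending at the delivery month.

    ``window_start = delivery_month - (gestational_age_months - 1)`` and
    ``window_end = delivery_month``, both inclusive.
    """

    episode_id: str
    member_id: str
    delivery_month: Month
    window_start: Month
    window_end: Month
    continuously_enrolled: bool = False

    def in_window(self, m: Month) -> bool:
        return self.window_start <= m <= self.window_end


@dataclass
class PncVisit:
    """One deduplicated prenatal visit: episode x provider (SSPI) x date."""

    episode_id: str
    sspi: str
    specialty_group: str
    visit_date: _dt.date
    seq_index: int


@dataclass
class ProviderEpisodeProfile:
    """Per episode-provider visit count, fraction and sequence flags.

    ``fraction = n_visits / n_total`` for the episode; ``has_first`` /
    ``has_last`` mark providers seen on the episode's earliest / latest visit
    date (several providers may share a date, so several may carry a flag).
    """

    episode_id: str
    sspi: str
    n_visits: int
    fraction: float
    has_first: bool
    has_last: bool
    specialty_group: str = ""
    first_visit_date: Optional[_dt.date] = None
    category: Category = Category.OTHER
    multplur_subtype: MultPlurSubtype = MultPlurSubtype.NA


@dataclass
class EpisodeClassification:
    """Episode-level outcome: concentration, dispersal, stratum and the
    predominant provider under each identification pattern (1-6)."""

    episode_id: str
    n_total: int
    n_providers: int
    coc_index: float
    dispersal: bool
    freq_stratum: str
    predominant_by_pattern: dict[int, Optional[str]] = field(default_factory=dict)
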