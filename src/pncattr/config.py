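"""Code-list configuration: which claims count as prenatal care.

The claim-selection code lists (diagnosis prefixes, procedure codes) used by
the original Medicaid analysis are not public; the defaults below are
documented, commonly used pregnancy-supervision and antepartum-care codes and
are explicitly *non-authoritative placeholders* — every study should supply
its own lists.  The specialty universe and grouping, by contrast, follow the
published assignment exactly.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, Field, model_validator

from .types import MISSING_SPECIALTY

__all__ = ["CodeConfig", "load_config", "DEFAULT_SPECIALTY_GROUPS"]

#: Specialty code -> group label. Midwife 06; primary care 12/14/19/78;
#: OB-GYN 16/26/27; organization 50 (FQHC) / 97 (RHC); nurse practitioner 86;
#: the low-volume specialties 02/10/40/48/57/94/95 and physician assistants
#: (PA) are retained under "other"; blank specialty maps to "missing".
DEFAULT_SPECIALTY_GROUPS: dict[str, str] = {
    "06": "midwife",
    "12": "primary_care",
    "14": "primary_care",
    "19": "primary_care",
    "78": "primary_care",
    "16": "obgyn",
    "26": "obgyn",
    "27": "obgyn",
    "50": "organization",
    "97": "organization",
    "86": "nurse_practitioner",
    "02": "other",
    "10": "other",
    "40": "other",
    "48": "other",
    "57": "other",
    "94": "other",
    "95": "other",
    "PA": "other",
    MISSING_SPECIALTY: "missing",
}

# Placeholder prenatal-care identification lists (supervision-of-pregnancy
# diagnosis prefixes, ICD-9 and ICD-10-CM; global/antepartum and prenatal
# visit procedure codes). Replace with study-specific lists in production.
_DEFAULT_DX_PREFIXES = frozenset({"Z34", "O09", "V22", "V23"})
_DEFAULT_PROCEDURE_CODES = frozenset(
    {
        "59400", "59510", "59610", "59618",  # global obstetric packages
        "59425", "59426",                      # antepartum care only
        "0500F", "0501F", "0502F",             # prenatal visit category II
        "H1000", "H1001", "H1002", "H1003", "H1004",  # HCPCS prenatal
        "T1015",                               # clinic visit (FQHC/RHC)
    }
)

_VALID_GROUPS = {
    "midwife",
    "primary_care",
    "obgyn",
    "organization",
    "nurse_practitioner",
    "other",
    "missing",
}


class CodeConfig(BaseModel):
    """Validated configuration of code lists, specialty groups and cut points."""

    pnc_dx_prefixes: set[str] = Field(default_factory=lambda: set(_DEFAULT_DX_PREFIXES))
    pnc_procedure_codes: set[str] = Field(
        default_factory=lambda: set(_DEFAULT_PROCEDURE_CODES)
    )
    included_specialties: set[str] = Field(
        default_factory=lambda: set(DEFAULT_SPECIALTY_GROUPS)
    )
    specialty_groups: dict[str, str] = Field(
        default_factory=lambda: dict(DEFAULT_SPECIALTY_GROUPS)
    )
    default_gestation_months: int = 9
    #: Upper edges of the visit-count strata =1 / 2-8 / 9-14 / >14.
    frequency_strata_bounds: tuple[int, int, int] = (1, 8, 14)

    @model_validator(mode="after")
    def _check(self) -> "CodeConfig":
        if not 1 <= self.default_gestation_months <= 12:
            raise ValueError("default_gestation_months must be in [1, 12]")
        b = self.frequency_strata_bounds
        if list(b) != sorted(b) or len(set(b)) != 3:
            raise ValueError("frequency_strata_bounds must be strictly increasing")
        unknown = set(self.specialty_groups) - self.included_specialties
        if unknown:
            raise ValueError(
                f"specialty_groups contains codes outside the specialty "
                f"universe: {sorted(unknown)}"
            )
        ungrouped = self.included_specialties - set(self.specialty_groups)
        if ungrouped:
            raise ValueError(
                f"included specialties without a group: {sorted(ungrouped)}"
            )
        bad = set(self.specialty_groups.values()) - _VALID_GROUPS
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        return self

    def group_of(self, specialty_code: str) -> str:
        return self.specialty_groups.get(specialty_code, "missing")


def load_config(path: Optional[str | Path] = None) -> CodeConfig:
    """Load a :class:`CodeConfig` from a YAML/JSON document.

    Omitted fields take the documented defaults; ``None`` or an empty document
    yields the full default configuration.
    """
    if path is None:
        return CodeConfig()
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        return CodeConfig()
    if not isinstance(raw, dict):
        raise ValueError(f"config document must be a mapping, got {type(raw).__name__}")
    return CodeConfig(**raw)
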