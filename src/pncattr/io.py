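"""Readers and writers for the pipeline's delimited-text tables.

All inputs and outputs are UTF-8 comma-separated tables with a header row.
Readers validate schemas up front and reject malformed rows with a row-indexed
report rather than failing the whole file.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .config import CodeConfig
from .types import (
    MISSING_SPECIALTY,
    ClaimRecord,
    DeliveryRecord,
    EnrollmentSpan,
    Month,
    ZipGazetteerEntry,
    parse_service_date,
)

__all__ = [
    "SchemaError",
    "RowReport",
    "read_claims",
    "read_enrollment",
    "read_deliveries",
    "read_gazetteer",
    "write_claims",
    "write_enrollment",
    "write_deliveries",
    "write_gazetteer",
    "write_table",
    "write_manifest",
]


class SchemaError(ValueError):
    """Input file does not match the documented schema."""


@dataclasses.dataclass
class RowReport:
    """Rows rejected during a read, with 0-based row indices and reasons."""

    rejected: list[tuple[int, str]] = dataclasses.field(default_factory=list)

    def add(self, row: int, reason: str) -> None:
        self.rejected.append((row, reason))


CLAIMS_COLUMNS = [
    "claim_id",
    "member_id",
    "provider_id",
    "specialty_code",
    "service_date",
    "primary_dx",
    "procedure_code",
    "claim_class",
]


def _load(path: str | Path, required: Sequence[str], label: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{label} file {path} missing columns: {missing}")
    if df.empty:
        warnings.warn(f"{label} file {path} has no data rows", stacklevel=3)
    return df


def read_claims(
    path: str | Path, config: CodeConfig | None = None
) -> tuple[list[ClaimRecord], RowReport]:
    """Read a claims table; rows with unparseable dates are rejected, not fatal.

    A blank specialty becomes the ``missing`` sentinel. Specialty codes outside
    the configured universe are kept verbatim (the prenatal-care filter drops
    them later); only dates can reject a row here.
    """
    df = _load(path, CLAIMS_COLUMNS[:6], "claims")
    report = RowReport()
    records: list[ClaimRecord] = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            date, imputed = parse_service_date(row.service_date)
        except ValueError as exc:
            report.add(i, f"bad service_date: {exc}")
            continue
        cid = row.claim_id
        if cid in seen:
            report.add(i, f"duplicate claim_id {cid!r}")
            continue
        seen.add(cid)
        spec = row.specialty_code.strip() or MISSING_SPECIALTY
        records.append(
            ClaimRecord(
                claim_id=cid,
                member_id=row.member_id,
                provider_id=row.provider_id,
                specialty_code=spec,
                service_date=date,
                primary_dx=row.primary_dx,
                procedure_code=getattr(row, "procedure_code", ""),
                claim_class=getattr(row, "claim_class", "office") or "office",
                day_imputed=imputed,
            )
        )
    return records, report


def read_enrollment(path: str | Path) -> list[EnrollmentSpan]:
    df = _load(path, ["member_id", "start_month", "end_month"], "enrollment")
    return [
        EnrollmentSpan(r.member_id, Month.parse(r.start_month), Month.parse(r.end_month))
        for r in df.itertuples(index=False)
    ]


def read_deliveries(path: str | Path) -> list[DeliveryRecord]:
    df = _load(path, ["birth_id", "member_id", "delivery_month"], "deliveries")
    out = []
    for r in df.itertuples(index=False):
        ga = getattr(r, "gestational_age_months", "")
        out.append(
            DeliveryRecord(
                birth_id=r.birth_id,
                member_id=r.member_id,
                delivery_month=Month.parse(r.delivery_month),
                gestational_age_months=int(ga) if str(ga).strip() else None,
            )
        )
    return out


def read_gazetteer(path: str | Path) -> dict[str, ZipGazetteerEntry]:
    df = _load(
        path, ["zip", "centroid_lat", "centroid_lon", "land_area_sqmi"], "gazetteer"
    )
    out: dict[str, ZipGazetteerEntry] = {}
    for r in df.itertuples(index=False):
        e = ZipGazetteerEntry(
            zip=r.zip,
            centroid_lat=float(r.centroid_lat),
            centroid_lon=float(r.centroid_lon),
            land_area=float(r.land_area_sqmi),
            in_state=str(getattr(r, "in_state", "true")).strip().lower()
            in ("true", "1", "yes"),
        )
        out[e.zip] = e
    return out


def _claims_frame(claims: Iterable[ClaimRecord]) -> pd.DataFrame:
    rows = []
    for c in claims:
        d = dataclasses.asdict(c)
        # month-precision round-trip: an imputed day is written back as YYYY-MM
        d["service_date"] = (
            f"{c.service_date.year:04d}-{c.service_date.month:02d}"
            if c.day_imputed
            else c.service_date.isoformat()
        )
        del d["day_imputed"]
        d["specialty_code"] = "" if c.specialty_code == MISSING_SPECIALTY else c.specialty_code
        rows.append(d)
    return pd.DataFrame(rows, columns=CLAIMS_COLUMNS)


def write_claims(claims: Iterable[ClaimRecord], path: str | Path) -> None:
    _claims_frame(claims).to_csv(path, index=False)


def write_enrollment(spans: Iterable[EnrollmentSpan], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"member_id": s.member_id, "start_month": str(s.start_month), "end_month": str(s.end_month)}
            for s in spans
        ],
        columns=["member_id", "start_month", "end_month"],
    ).to_csv(path, index=False)


def write_deliveries(deliveries: Iterable[DeliveryRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "birth_id": d.birth_id,
                "member_id": d.member_id,
                "delivery_month": str(d.delivery_month),
                "gestational_age_months": (
                    "" if d.gestational_age_months is None else d.gestational_age_months
                ),
            }
            for d in deliveries
        ],
        columns=["birth_id", "member_id", "delivery_month", "gestational_age_months"],
    ).to_csv(path, index=False)


def write_gazetteer(entries: Iterable[ZipGazetteerEntry], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "zip": e.zip,
                "centroid_lat": e.centroid_lat,
                "centroid_lon": e.centroid_lon,
                "land_area_sqmi": e.land_area,
                "in_state": str(e.in_state).lower(),
            }
            for e in entries
        ],
        columns=["zip", "centroid_lat", "centroid_lon", "land_area_sqmi", "in_state"],
    ).to_csv(path, index=False)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Serialize a report table; percentages round to 2 decimals here only."""
    out = df.copy()
    for col in out.columns:
        if out[col].dtype.kind == "f":
            out[col] = out[col].round(4)
    out.to_csv(path, index=False)


def write_manifest(
    path: str | Path,
    *,
    config: CodeConfig,
    seed: int | None,
    inputs: dict[str, str],
    stage_counts: dict[str, int],
) -> dict:
    """Write the run manifest: config digest, seed, inputs, filter-funnel counts."""
    def _canon(obj):
        if isinstance(obj, (set, frozenset)):
            return sorted(obj)
        if isinstance(obj, dict):
            return {k: _canon(v) for k, v in sorted(obj.items())}
        if isinstance(obj, (list, tuple)):
            return [_canon(v) for v in obj]
        return obj

    digest = hashlib.sha256(
        json.dumps(_canon(config.model_dump()), sort_keys=True).encode()
    ).hexdigest()[:16]
    manifest = {
        "config_digest": digest,
        "seed": seed,
        "inputs": inputs,
        "stage_counts": stage_counts,
    }
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
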