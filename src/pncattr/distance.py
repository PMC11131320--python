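"""Travel-distance application: nearest vs. predominant provider.

Distances are zip-centroid to zip-centroid great-circle (haversine) miles,
with mean Earth radius 3958.8 mi.  When residence and provider share a zip,
the within-zip distance is approximated by the radius of a circle of equal
land area, ``r = sqrt(area / pi)`` — zero would understate travel inside
large rural zips.  Road-network routing is out of scope; great-circle
distances systematically undershoot driving distance but preserve ordering
and sign for the nearest-vs-predominant comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Mapping, Optional

import pandas as pd

from .stats import PairedTResult, paired_t
from .types import EpisodeClassification, ZipGazetteerEntry

__all__ = [
    "EARTH_RADIUS_MILES",
    "haversine_miles",
    "centroid_distance",
    "nearest_provider",
    "DistancePair",
    "compare_distances",
    "DistanceComparison",
]

EARTH_RADIUS_MILES = 3958.8

Scope = Literal["visited", "all_cohort_providers"]


def haversine_miles(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance between two (lat, lon) points, in miles."""
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    dphi = phi2 - phi1
    dlam = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlam / 2) ** 2
    return 2 * EARTH_RADIUS_MILES * math.asin(min(1.0, math.sqrt(a)))


def centroid_distance(
    zip_a: str, zip_b: str, gazetteer: Mapping[str, ZipGazetteerEntry]
) -> float:
    """Centroid-to-centroid miles; same-zip pairs use the equal-area radius."""
    try:
        a, b = gazetteer[zip_a], gazetteer[zip_b]
    except KeyError as exc:
        raise KeyError(f"zip not in gazetteer: {exc.args[0]!r}") from None
    if zip_a == zip_b:
        return math.sqrt(a.land_area / math.pi)
    return haversine_miles(a.centroid_lat, a.centroid_lon, b.centroid_lat, b.centroid_lon)


def nearest_provider(
    candidate_zips: Mapping[str, str],
    residence_zip: str,
    gazetteer: Mapping[str, ZipGazetteerEntry],
) -> tuple[str, float]:
    """Minimum-distance provider among candidates (SSPI -> billing zip).

    Candidates with unknown zips are skipped; distance ties break
    lexicographically on SSPI.  Raises if no candidate has a known zip.
    """
    best: Optional[tuple[float, str]] = None
    for sspi in sorted(candidate_zips):
        z = candidate_zips[sspi]
        if z not in gazetteer:
            continue
        d = centroid_distance(residence_zip, z, gazetteer)
        if best is None or d < best[0]:
            best = (d, sspi)
    if best is None:
        raise ValueError("no candidate provider with a known zip")
    return best[1], best[0]


@dataclass
class DistancePair:
    """Per-episode nearest vs. predominant distances (miles)."""

    episode_id: str
    predominant_sspi: str
    predominant_distance: float
    nearest_sspi: str
    nearest_distance: float
    included: bool


@dataclass
class DistanceComparison:
    pairs: list[DistancePair]
    n_included: int
    n_excluded: int
    mean_nearest: float
    mean_predominant: float
    test: PairedTResult

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(p) for p in self.pairs])


def compare_distances(
    classifications: list[EpisodeClassification],
    visited_by_episode: Mapping[str, list[str]],
    provider_zips: Mapping[str, str],
    residence_zips: Mapping[str, str],
    gazetteer: Mapping[str, ZipGazetteerEntry],
    pattern: int = 6,
    scope: Scope = "visited",
    in_state_only: bool = True,
) -> DistanceComparison:
    """Paired comparison of nearest vs. predominant provider distance.

    Includes only episodes with an identified predominant provider under
    ``pattern`` and (optionally) an in-state residence and provider zips.
    With ``scope="visited"`` the nearest provider is chosen among the
    episode's own providers, so nearest <= predominant for every included
    episode and the mean difference (nearest - predominant) is <= 0 by
    construction; ``scope="all_cohort_providers"`` searches every provider
    that appears in the cohort.
    """

    def _in_state(z: str) -> bool:
        return z in gazetteer and gazetteer[z].in_state

    all_candidates = dict(provider_zips)
    pairs: list[DistancePair] = []
    diffs: list[float] = []
    n_excluded = 0
    for c in classifications:
        pred = c.predominant_by_pattern.get(pattern)
        res = residence_zips.get(c.episode_id, "")
        usable = (
            pred is not None
            and pred in provider_zips
            and res in gazetteer
            and (not in_state_only or (_in_state(res) and _in_state(provider_zips[pred])))
        )
        if not usable:
            n_excluded += 1
            continue
        if scope == "visited":
            cands = {s: provider_zips[s] for s in visited_by_episode[c.episode_id] if s in provider_zips}
        else:
            cands = all_candidates
        if in_state_only:
            cands = {s: z for s, z in cands.items() if _in_state(z)}
        pred_d = centroid_distance(res, provider_zips[pred], gazetteer)
        near_sspi, near_d = nearest_provider(cands, res, gazetteer)
        pairs.append(DistancePair(c.episode_id, pred, pred_d, near_sspi, near_d, True))
        diffs.append(near_d - pred_d)
    if len(diffs) < 2:
        raise ValueError("fewer than 2 usable episode pairs for the paired t-test")
    test = paired_t(diffs)
    return DistanceComparison(
        pairs=pairs,
        n_included=len(pairs),
        n_excluded=n_excluded,
        mean_nearest=sum(p.nearest_distance for p in pairs) / len(pairs),
        mean_predominant=sum(p.predominant_distance for p in pairs) / len(pairs),
        test=test,
    )
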