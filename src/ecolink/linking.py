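"""The three methods for assigning provider quality scores to individuals.

* **Exact match** — each individual gets the scores of the specific provider
  they stated using; always evaluated against the full facility census, which
  is the study's best available "truth".
* **Euclidean nearest** — each individual is linked to the closest provider, as
  the crow flies, within the provider category (managing authority x level of
  care) they reported.
* **Administrative unit** — each individual gets the caseload-weighted mean
  score of all providers of the reported category within their district.

Whenever a source cannot be linked (an unrecalled or unenumerated provider, or
a category absent from the district or the sampled facility set), the fallback
assigns the average score for the reported category over the facility set in
use, degrading to the census-wide category average when even that is empty.
Unskilled sources (pharmacies, community health workers) never link; an
individual whose only sources are unskilled counts as receiving no skilled
care.  The few sick-child episodes with several skilled sources receive the
unweighted mean of the per-source scores.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from ecolink.region_model import (
    CareEpisode,
    ClusterRecord,
    FacilityRecord,
    ProviderCategory,
    RegionDataset,
)

EARTH_RADIUS_KM = 6371.0088  # mean Earth radius; fixed for reproducibility

METHODS = ("exact", "euclidean", "admin")
INDICATORS = ("structural", "process")


def distance_km(a: tuple[float, float], b: tuple[float, float]) -> float:
    """Great-circle (haversine) distance in km between (lon, lat) points."""
    lon1, lat1 = a
    lon2, lat2 = b
    for lat in (lat1, lat2):
        if not -90.0 <= lat <= 90.0:
            raise ValueError(f"latitude {lat} outside [-90, 90]")
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    dphi = phi2 - phi1
    dlam = math.radians(lon2 - lon1)
    h = math.sin(dphi / 2.0) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlam / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(h)))


@dataclass
class LinkResult:
    """Scores assigned to one episode by one linking method, with provenance."""

    episode_id: str
    method: str
    structural: float | None
    process: float | None
    linked_facilities: list[str] = field(default_factory=list)
    fallback_used: bool = False
    skilled_care: bool = True


class FallbackError(ValueError):
    """No facility of the category exists in either the set or the census."""


def _weighted_mean_scores(
    facilities: Sequence[FacilityRecord], service_area: str
) -> tuple[float, float]:
    """Caseload-weighted mean (structural, process); unweighted if volumes sum to 0.

    Facilities are summed in facility-id order so the result is identical for
    any ordering of the same facility set (a sampled set that happens to equal
    the census must reproduce census scores bit-for-bit).
    """
    facilities = sorted(facilities, key=lambda f: f.facility_id)
    total = sum(f.caseload[service_area] for f in facilities)
    if total > 0:
        weights = [f.caseload[service_area] / total for f in facilities]
    else:
        weights = [1.0 / len(facilities)] * len(facilities)
    structural = sum(w * f.structural_score[service_area] for w, f in zip(weights, facilities))
    process = sum(w * f.process_score[service_area] for w, f in zip(weights, facilities))
    return structural, process


def fallback_score(
    category: ProviderCategory,
    facilities: Sequence[FacilityRecord],
    service_area: str,
    census: Sequence[FacilityRecord] | None = None,
    caseload_weighted: bool = True,
) -> tuple[float, float]:
    """Average score for a reported provider category over a facility set.

    Falls back to the census-wide category mean when the category is entirely
    absent from the set (possible after sampling).
    """
    members = [f for f in facilities if f.skilled and f.category == category]
    if not members and census is not None:
        members = [f for f in census if f.skilled and f.category == category]
    if not members:
        raise FallbackError(f"no facility of category {category} in facility set or census")
    if caseload_weighted:
        return _weighted_mean_scores(members, service_area)
    members = sorted(members, key=lambda f: f.facility_id)
    structural = sum(f.structural_score[service_area] for f in members) / len(members)
    process = sum(f.process_score[service_area] for f in members) / len(members)
    return structural, process


def combine_multi_source(scores: Sequence[tuple[float, float]]) -> tuple[float, float]:
    """Unweighted mean of per-source (structural, process) score pairs."""
    if not scores:
        raise ValueError("combine_multi_source requires at least one skilled source score")
    n = len(scores)
    return (sum(s for s, _ in scores) / n, sum(p for _, p in scores) / n)


def _finish(
    episode: CareEpisode,
    method: str,
    per_source: list[tuple[tuple[float, float], str | None, bool]],
) -> LinkResult:
    """Assemble a LinkResult from (scores, facility_id, fallback) per skilled source."""
    if not per_source:
        return LinkResult(
            episode_id=episode.episode_id,
            method=method,
            structural=None,
            process=None,
            skilled_care=False,
        )
    structural, process = combine_multi_source([scores for scores, _, _ in per_source])
    fallback = any(fb for _, _, fb in per_source)
    linked = [] if fallback else [fid for _, fid, _ in per_source if fid is not None]
    return LinkResult(
        episode_id=episode.episode_id,
        method=method,
        structural=structural,
        process=process,
        linked_facilities=linked,
        fallback_used=fallback,
        skilled_care=True,
    )


def exact_match_link(
    episode: CareEpisode,
    census: Sequence[FacilityRecord],
    service_area: str | None = None,
    census_index: dict[str, FacilityRecord] | None = None,
) -> LinkResult:
    """Link each skilled source to the specific stated provider, with fallback.

    Exact matching always runs against the full census, never a sample: the
    facility assessment enumerated (nearly) every provider, so the stated
    source is known whenever the respondent could recall it.
    """
    area = service_area or episode.service_area
    index = census_index if census_index is not None else {f.facility_id: f for f in census}
    per_source = []
    for source in episode.sources:
        if not source.skilled:
            continue
        fid = source.stated_facility_id
        facility = index.get(fid) if fid is not None else None
        if facility is not None and facility.skilled:
            scores = (facility.structural_score[area], facility.process_score[area])
            per_source.append((scores, facility.facility_id, False))
        else:
            scores = fallback_score(source.category, census, area)
            per_source.append((scores, None, True))
    return _finish(episode, "exact", per_source)


def euclidean_link(
    episode: CareEpisode,
    cluster: ClusterRecord,
    facilities: Sequence[FacilityRecord],
    service_area: str | None = None,
    census: Sequence[FacilityRecord] | None = None,
) -> LinkResult:
    """Link each skilled source to the nearest facility of the reported category.

    Distance is great-circle from the episode's cluster centroid; equidistant
    candidates are broken by smallest facility id.
    """
    area = service_area or episode.service_area
    origin = (cluster.longitude, cluster.latitude)
    per_source = []
    for source in episode.sources:
        if not source.skilled:
            continue
        candidates = [f for f in facilities if f.skilled and f.category == source.category]
        if candidates:
            best = min(
                candidates,
                key=lambda f: (distance_km(origin, (f.longitude, f.latitude)), f.facility_id),
            )
            scores = (best.structural_score[area], best.process_score[area])
            per_source.append((scores, best.facility_id, False))
        else:
            scores = fallback_score(source.category, facilities, area, census=census)
            per_source.append((scores, None, True))
    return _finish(episode, "euclidean", per_source)


def admin_link(
    episode: CareEpisode,
    cluster: ClusterRecord,
    facilities: Sequence[FacilityRecord],
    service_area: str | None = None,
    census: Sequence[FacilityRecord] | None = None,
) -> LinkResult:
    """Assign the caseload-weighted mean score of the district x category set.

    Zero total caseload degrades to the unweighted mean; a district without any
    facility of the reported category (common after sampling) takes the
    fallback average over the whole facility set in use.
    """
    area = service_area or episode.service_area
    per_source = []
    for source in episode.sources:
        if not source.skilled:
            continue
        members = [
            f
            for f in facilities
            if f.skilled and f.category == source.category and f.district == cluster.district
        ]
        if members:
            scores = _weighted_mean_scores(members, area)
            per_source.append((scores, None, False))
        else:
            scores = fallback_score(source.category, facilities, area, census=census)
            per_source.append((scores, None, True))
    return _finish(episode, "admin", per_source)


def link_episodes(
    region: RegionDataset,
    method: str,
    facilities: Sequence[FacilityRecord] | None = None,
    service_area: str | None = None,
    episodes: Iterable[CareEpisode] | None = None,
) -> list[LinkResult]:
    """Apply one linking method to every episode (optionally one service area).

    ``facilities`` selects the facility set for the ecological methods (a
    sampled subset or, by default, the census); exact matching ignores it and
    always uses the census.
    """
    if method not in METHODS:
        raise ValueError(f"unknown linking method {method!r}")
    census = region.facilities
    fset = list(facilities) if facilities is not None else census
    clusters = region.cluster_index()
    census_index = region.facility_index()
    if episodes is None:
        episodes = (
            region.episodes_for(service_area) if service_area is not None else region.episodes
        )

    # Ecological links are a pure function of (cluster or district, category,
    # service area); memoising them makes the sampled-grid runs cheap.
    cache: dict[tuple, tuple[tuple[float, float], str | None, bool]] = {}

    def resolve(episode: CareEpisode, source) -> tuple[tuple[float, float], str | None, bool]:
        area = episode.service_area
        cluster = clusters[episode.cluster_id]
        if method == "euclidean":
            key = ("euclidean", cluster.cluster_id, source.category, area)
        else:
            key = ("admin", cluster.district, source.category, area)
        if key in cache:
            return cache[key]
        probe = CareEpisode(
            episode_id="_probe", cluster_id=cluster.cluster_id, service_area=area,
            sources=[type(source)(category=source.category)],
        )
        if method == "euclidean":
            res = euclidean_link(probe, cluster, fset, census=census)
        else:
            res = admin_link(probe, cluster, fset, census=census)
        value = (
            (res.structural, res.process),
            res.linked_facilities[0] if res.linked_facilities else None,
            res.fallback_used,
        )
        cache[key] = value
        return value

    results = []
    for episode in episodes:
        if method == "exact":
            results.append(exact_match_link(episode, census, census_index=census_index))
        else:
            per_source = [resolve(episode, s) for s in episode.sources if s.skilled]
            results.append(_finish(episode, method, per_source))
    return results
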