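"""Shared data model for regions and its delimited-text / GeoJSON persistence.

A region bundles three tables:

* a facility census (one row per provider, with managing authority, level of
  care, district, WGS84 location, per-service caseload and quality scores),
* household-survey clusters (centroid, district, survey weight), and
* care episodes (one individual in need of sick-child or delivery care, with
  the sources of care they reported).

The on-disk layout is plain CSV (UTF-8, header row) plus an RFC 7946 GeoJSON
point layer for mapping.  The column dictionary is fixed and documented in
``docs/methods.md``; unknown extra columns are preserved on read but ignored.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

SERVICE_AREAS = ("sick_child", "delivery")


class ManagingAuthority(str, Enum):
    PUBLIC = "public"
    PRIVATE = "private"
    RELIGIOUS = "religious"
    NGO = "ngo"


class FacilityLevel(str, Enum):
    FIRST_LEVEL = "first_level"
    REFERRAL = "referral"


@dataclass(frozen=True, order=True)
class ProviderCategory:
    """Managing authority x level of care; the key that restricts all linking."""

    authority: str
    level: str

    def __post_init__(self) -> None:
        ManagingAuthority(self.authority)
        FacilityLevel(self.level)

    def __str__(self) -> str:
        return f"{self.authority}_{self.level}"

    @classmethod
    def parse(cls, token: str) -> "ProviderCategory":
        authority, _, level = token.partition("_")
        return cls(authority, level)


@dataclass
class FacilityRecord:
    """One provider in the census.

    Caseloads are annual service volumes; structural and process scores are
    bounded in [0, 1] per service area.  Pharmacies and community health
    workers, when present in user data, carry ``skilled=False`` and never enter
    facility linking.
    """

    facility_id: str
    category: ProviderCategory
    district: str
    longitude: float
    latitude: float
    caseload: dict[str, float]
    structural_score: dict[str, float]
    process_score: dict[str, float]
    skilled: bool = True

    def score(self, indicator: str, service_area: str) -> float:
        table = self.structural_score if indicator == "structural" else self.process_score
        return table[service_area]


@dataclass
class ClusterRecord:
    """A household-survey cluster: the PSU of the design-based variance."""

    cluster_id: str
    longitude: float
    latitude: float
    district: str
    weight: float = 1.0


@dataclass
class CareSource:
    """One reported source of care.

    ``category is None`` tags an unskilled source (pharmacy / community health
    worker); those sources never link to a facility.  ``stated_facility_id`` is
    the specific provider named by the respondent, if recalled and enumerated;
    ``unresolvable`` flags a stated id absent from the facility table.
    """

    category: ProviderCategory | None
    stated_facility_id: str | None = None
    unresolvable: bool = False

    @property
    def skilled(self) -> bool:
        return self.category is not None


@dataclass
class CareEpisode:
    """One individual in need of care (a delivery or a sick-child illness).

    An empty ``sources`` list means no care was sought.  Delivery episodes have
    at most one source; sick-child episodes may have several.
    """

    episode_id: str
    cluster_id: str
    service_area: str
    sources: list[CareSource] = field(default_factory=list)
    weight: float = 1.0
    in_need: bool = True

    @property
    def sought_skilled_care(self) -> bool:
        return any(s.skilled for s in self.sources)


@dataclass
class RegionDataset:
    facilities: list[FacilityRecord]
    clusters: list[ClusterRecord]
    episodes: list[CareEpisode]
    metadata: dict = field(default_factory=dict)

    def facility_index(self) -> dict[str, FacilityRecord]:
        return {f.facility_id: f for f in self.facilities}

    def cluster_index(self) -> dict[str, ClusterRecord]:
        return {c.cluster_id: c for c in self.clusters}

    def episodes_for(self, service_area: str) -> list[CareEpisode]:
        return [e for e in self.episodes if e.service_area == service_area]

    def resolve_sources(self) -> None:
        """Flag stated facility ids that the facility table does not contain."""
        known = set(self.facility_index())
        for episode in self.episodes:
            for source in episode.sources:
                if source.stated_facility_id is not None:
                    source.unresolvable = source.stated_facility_id not in known


class SchemaError(ValueError):
    """A required column is missing or malformed."""


class RegionValidationError(ValueError):
    """A record violates a data-model invariant."""


@dataclass
class Finding:
    """One invariant violation located at a specific record."""

    table: str
    record_id: str
    message: str

    def __str__(self) -> str:
        return f"{self.table}[{self.record_id}]: {self.message}"


FACILITY_COLUMNS = [
    "facility_id",
    "authority",
    "level",
    "district",
    "longitude",
    "latitude",
    "skilled",
    "caseload_sick_child",
    "caseload_delivery",
    "structural_sick_child",
    "structural_delivery",
    "process_sick_child",
    "process_delivery",
]
CLUSTER_COLUMNS = ["cluster_id", "longitude", "latitude", "district", "weight"]
EPISODE_COLUMNS = ["episode_id", "cluster_id", "service_area", "weight", "sources"]

_UNSKILLED_TOKEN = "unskilled"


def _encode_source(source: CareSource) -> str:
    if source.category is None:
        return f"{_UNSKILLED_TOKEN}||"
    fid = source.stated_facility_id or ""
    return f"{source.category.authority}|{source.category.level}|{fid}"


def _decode_source(token: str) -> CareSource:
    parts = token.split("|")
    if len(parts) != 3:
        raise SchemaError(f"malformed source token {token!r}")
    head, level, fid = parts
    if head == _UNSKILLED_TOKEN:
        return CareSource(category=None)
    return CareSource(category=ProviderCategory(head, level), stated_facility_id=fid or None)


def encode_sources(sources: Iterable[CareSource]) -> str:
    return ";".join(_encode_source(s) for s in sources)


def decode_sources(cell: str) -> list[CareSource]:
    if not cell:
        return []
    return [_decode_source(tok) for tok in cell.split(";")]


def _require_columns(frame: pd.DataFrame, required: list[str], table: str) -> None:
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SchemaError(f"{table} table is missing required column(s): {', '.join(missing)}")


def read_region(
    facility_path: str | Path, cluster_path: str | Path, episode_path: str | Path
) -> RegionDataset:
    """Read and validate a region from its three delimited-text tables.

    Unresolvable stated facility ids are retained and flagged, never dropped:
    the exact-match fallback rule depends on them.
    """
    fac_frame = pd.read_csv(
        facility_path,
        dtype={"facility_id": str, "district": str},
        float_precision="round_trip",
    )
    clu_frame = pd.read_csv(
        cluster_path,
        dtype={"cluster_id": str, "district": str},
        float_precision="round_trip",
    )
    epi_frame = pd.read_csv(
        episode_path,
        dtype={"episode_id": str, "cluster_id": str},
        float_precision="round_trip",
        keep_default_na=False,
        na_values=[],
    )
    _require_columns(fac_frame, FACILITY_COLUMNS, "facility")
    _require_columns(clu_frame, CLUSTER_COLUMNS, "cluster")
    _require_columns(epi_frame, EPISODE_COLUMNS, "episode")

    facilities = [
        FacilityRecord(
            facility_id=row.facility_id,
            category=ProviderCategory(row.authority, row.level),
            district=row.district,
            longitude=float(row.longitude),
            latitude=float(row.latitude),
            caseload={
                "sick_child": float(row.caseload_sick_child),
                "delivery": float(row.caseload_delivery),
            },
            structural_score={
                "sick_child": float(row.structural_sick_child),
                "delivery": float(row.structural_delivery),
            },
            process_score={
                "sick_child": float(row.process_sick_child),
                "delivery": float(row.process_delivery),
            },
            skilled=bool(row.skilled),
        )
        for row in fac_frame.itertuples()
    ]
    clusters = [
        ClusterRecord(
            cluster_id=row.cluster_id,
            longitude=float(row.longitude),
            latitude=float(row.latitude),
            district=row.district,
            weight=float(row.weight),
        )
        for row in clu_frame.itertuples()
    ]
    episodes = [
        CareEpisode(
            episode_id=row.episode_id,
            cluster_id=row.cluster_id,
            service_area=row.service_area,
            weight=float(row.weight),
            sources=decode_sources(str(row.sources)),
        )
        for row in epi_frame.itertuples()
    ]
    region = RegionDataset(facilities=facilities, clusters=clusters, episodes=episodes)
    region.resolve_sources()
    findings = validate_region(region, check_resolution=False)
    if findings:
        raise RegionValidationError("; ".join(str(f) for f in findings))
    return region


def facilities_frame(facilities: Iterable[FacilityRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "facility_id": f.facility_id,
            "authority": f.category.authority,
            "level": f.category.level,
            "district": f.district,
            "longitude": f.longitude,
            "latitude": f.latitude,
            "skilled": f.skilled,
            "caseload_sick_child": f.caseload["sick_child"],
            "caseload_delivery": f.caseload["delivery"],
            "structural_sick_child": f.structural_score["sick_child"],
            "structural_delivery": f.structural_score["delivery"],
            "process_sick_child": f.process_score["sick_child"],
            "process_delivery": f.process_score["delivery"],
        }
        for f in facilities
    )


def _fmt_float(x) -> str:
    # shortest representation that parses back to the identical float
    return str(float(x))


def write_region(region: RegionDataset, directory: str | Path) -> set[Path]:
    """Write the three CSV tables plus a GeoJSON point layer.

    ``read_region`` of the written files reproduces the region exactly (floats
    are printed at full round-trip precision).
    """
    if not region.facilities:
        raise RegionValidationError("a region must contain at least one facility")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    fac_path = directory / "facilities.csv"
    clu_path = directory / "clusters.csv"
    epi_path = directory / "episodes.csv"
    geo_path = directory / "region.geojson"

    facilities_frame(region.facilities).to_csv(fac_path, index=False, float_format=_fmt_float)
    pd.DataFrame(
        {
            "cluster_id": c.cluster_id,
            "longitude": c.longitude,
            "latitude": c.latitude,
            "district": c.district,
            "weight": c.weight,
        }
        for c in region.clusters
    ).to_csv(clu_path, index=False, float_format=_fmt_float)
    pd.DataFrame(
        {
            "episode_id": e.episode_id,
            "cluster_id": e.cluster_id,
            "service_area": e.service_area,
            "weight": e.weight,
            "sources": encode_sources(e.sources),
        }
        for e in region.episodes
    ).to_csv(epi_path, index=False, float_format=_fmt_float)

    features = [
        {
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [f.longitude, f.latitude]},
            "properties": {
                "kind": "facility",
                "id": f.facility_id,
                "category": str(f.category),
                "district": f.district,
            },
        }
        for f in region.facilities
    ] + [
        {
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [c.longitude, c.latitude]},
            "properties": {"kind": "cluster", "id": c.cluster_id, "district": c.district},
        }
        for c in region.clusters
    ]
    geo_path.write_text(
        json.dumps({"type": "FeatureCollection", "features": features}, indent=1)
    )
    return {fac_path, clu_path, epi_path, geo_path}


def _finite(x: float) -> bool:
    return isinstance(x, (int, float)) and math.isfinite(x)


def validate_region(region: RegionDataset, check_resolution: bool = True) -> list[Finding]:
    """Check every data-model invariant; return one finding per violation."""
    findings: list[Finding] = []
    seen_fids: set[str] = set()
    for f in region.facilities:
        if f.facility_id in seen_fids:
            findings.append(Finding("facility", f.facility_id, "duplicate facility_id"))
        seen_fids.add(f.facility_id)
        if not (_finite(f.latitude) and -90.0 <= f.latitude <= 90.0):
            findings.append(Finding("facility", f.facility_id, "latitude outside [-90, 90]"))
        if not (_finite(f.longitude) and -180.0 <= f.longitude <= 180.0):
            findings.append(Finding("facility", f.facility_id, "longitude outside [-180, 180]"))
        for area in SERVICE_AREAS:
            for name, table in (
                ("structural", f.structural_score),
                ("process", f.process_score),
            ):
                value = table.get(area)
                if value is None or not _finite(value) or not 0.0 <= value <= 1.0:
                    findings.append(
                        Finding(
                            "facility",
                            f.facility_id,
                            f"{name} score for {area} outside [0, 1]: {value}",
                        )
                    )
            load = f.caseload.get(area)
            if load is None or not _finite(load) or load < 0:
                findings.append(
                    Finding("facility", f.facility_id, f"negative caseload for {area}: {load}")
                )

    seen_cids: set[str] = set()
    for c in region.clusters:
        if c.cluster_id in seen_cids:
            findings.append(Finding("cluster", c.cluster_id, "duplicate cluster_id"))
        seen_cids.add(c.cluster_id)
        if not (_finite(c.weight) and c.weight > 0):
            findings.append(Finding("cluster", c.cluster_id, "non-positive weight"))
        if not (_finite(c.latitude) and -90.0 <= c.latitude <= 90.0):
            findings.append(Finding("cluster", c.cluster_id, "latitude outside [-90, 90]"))

    known_fids = set(seen_fids)
    seen_eids: set[str] = set()
    for e in region.episodes:
        if e.episode_id in seen_eids:
            findings.append(Finding("episode", e.episode_id, "duplicate episode_id"))
        seen_eids.add(e.episode_id)
        if e.service_area not in SERVICE_AREAS:
            findings.append(
                Finding("episode", e.episode_id, f"unknown service_area {e.service_area!r}")
            )
        if e.cluster_id not in seen_cids:
            findings.append(
                Finding("episode", e.episode_id, f"cluster_id {e.cluster_id!r} does not resolve")
            )
        if not (_finite(e.weight) and e.weight > 0):
            findings.append(Finding("episode", e.episode_id, "non-positive weight"))
        if e.service_area == "delivery" and len(e.sources) > 1:
            findings.append(Finding("episode", e.episode_id, "delivery episode has >1 source"))
        if check_resolution:
            for source in e.sources:
                fid = source.stated_facility_id
                if fid is not None and fid not in known_fids and not source.unresolvable:
                    findings.append(
                        Finding(
                            "episode",
                            e.episode_id,
                            f"stated facility id {fid!r} neither resolves nor is flagged",
                        )
                    )
    return findings


def category_counts(facilities: Iterable[FacilityRecord]) -> Mapping[ProviderCategory, int]:
    counts: dict[ProviderCategory, int] = {}
    for f in facilities:
        counts[f.category] = counts.get(f.category, 0) + 1
    return counts
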