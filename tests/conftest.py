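"""Shared fixtures: a hand-built miniature region and seeded synthetic regions."""

import pytest

from ecolink.region_model import (
    CareEpisode,
    CareSource,
    ClusterRecord,
    FacilityRecord,
    ProviderCategory,
    RegionDataset,
)
from ecolink.synthetic_region import GeneratorConfig, generate_region

PUB1 = ProviderCategory("public", "first_level")
PRIV1 = ProviderCategory("private", "first_level")
PUBREF = ProviderCategory("public", "referral")


def _facility(fid, category, district, lon, lat, caseload, structural, process):
    return FacilityRecord(
        facility_id=fid,
        category=category,
        district=district,
        longitude=lon,
        latitude=lat,
        caseload={"sick_child": caseload, "delivery": caseload},
        structural_score={"sick_child": structural, "delivery": structural},
        process_score={"sick_child": process, "delivery": process},
    )


@pytest.fixture
def tiny_region() -> RegionDataset:
    """Four facilities, two clusters, seven episodes with every linking case.

    Hand-checkable expectations:
    - public first-level fallback (caseload-weighted over F1 w=100 and F2
      w=300): structural (100*0.6 + 300*0.2)/400 = 0.3, process
      (100*0.4 + 300*0.8)/400 = 0.7.
    - nearest public first-level facility from both clusters is F1.
    - district D2 has no public first-level facility, so admin linking from
      cluster C2 falls back to the region-wide category average.
    """
    facilities = [
        _facility("F1", PUB1, "D1", 0.0, 0.0, 100.0, 0.6, 0.4),
        _facility("F2", PUB1, "D1", 0.0, 0.05, 300.0, 0.2, 0.8),
        _facility("F3", PRIV1, "D2", 0.5, 0.0, 50.0, 0.9, 0.1),
        _facility("F4", PUBREF, "D1", 0.0, 0.5, 500.0, 0.95, 0.9),
    ]
    clusters = [
        ClusterRecord("C1", 0.0, 0.0, "D1", weight=1.0),
        ClusterRecord("C2", 0.5, 0.0, "D2", weight=1.0),
    ]
    episodes = [
        CareEpisode("E1", "C1", "delivery", [CareSource(PUB1, "F1")]),
        CareEpisode("E2", "C1", "delivery", [CareSource(PUB1, "GHOST")]),
        CareEpisode("E3", "C2", "delivery", []),
        CareEpisode("E4", "C1", "sick_child", [CareSource(PUB1, "F2"), CareSource(None)]),
        CareEpisode("E5", "C2", "sick_child", [CareSource(PRIV1, "F3")]),
        CareEpisode("E6", "C1", "sick_child", []),
        CareEpisode("E7", "C2", "sick_child", [CareSource(PUB1, "F1"), CareSource(PRIV1, "F3")]),
    ]
    region = RegionDataset(facilities=facilities, clusters=clusters, episodes=episodes)
    region.resolve_sources()
    return region


@pytest.fixture(scope="session")
def default_region() -> RegionDataset:
    """The study-sized synthetic region under the default configuration."""
    return generate_region(GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def preference_region() -> RegionDataset:
    """A region generated with quality-preferring, volume-correlated care-seeking."""
    return generate_region(
        GeneratorConfig(seed=11, quality_preference=4.0, caseload_quality_beta=3.0)
    )
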