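"""SPA-style facility sampling and the two quality-score simulations.

Facility assessments such as the SPA sample first-level facilities and keep a
census of referral facilities.  ``draw_facility_sample`` reproduces that
design: all referral facilities enter every draw, and the nominal sample size
n is a without-replacement random sample of first-level facilities, by default
allocated proportionally across two managing-authority strata (public versus
private/religious/NGO) with largest-remainder rounding.

Two perturbation schemes replace the census quality scores to probe settings
with more score variability than the original data:

* **random** — every structural and process score is redrawn uniformly on
  [0, 1], holding locations, categories, caseloads and care-seeking fixed;
* **preferential** — scores are shifted by +/- delta (default 15 percentage
  points) to emulate preferential care-seeking from higher-quality providers:
  facilities used by at least the utilization threshold (1 sick-child or 2
  delivery respondents) move up; unused facilities within 10 km of a household
  cluster move down; unused remote facilities move up or down according to
  whether they score above or below their category median.  Scores clamp to
  [0, 1].
"""

from __future__ import annotations

import math
from copy import deepcopy
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from ecolink.linking import distance_km
from ecolink.region_model import (
    CareEpisode,
    ClusterRecord,
    FacilityRecord,
    RegionDataset,
    SERVICE_AREAS,
)

_Z95 = 1.959963984540054


@dataclass
class SampleDesign:
    """Design of the facility-sampling experiment."""

    sample_sizes: list[int] = field(default_factory=lambda: [65, 90, 130])
    n_draws: int = 20
    stratify_by_authority: bool = True
    seed: int = 0


@dataclass
class QualitySimConfig:
    """Parameters of the quality-score simulations."""

    mode: str = "original"  # original | random | preferential
    delta: float = 0.15
    distance_threshold_km: float = 10.0
    min_users_sick_child: int = 1
    min_users_delivery: int = 2
    seed: int = 0

    def validate(self) -> None:
        if self.mode not in ("original", "random", "preferential"):
            raise ValueError(f"unknown quality simulation mode {self.mode!r}")
        if not 0.0 < self.delta < 1.0:
            raise ValueError("delta must lie in (0, 1)")
        if self.distance_threshold_km <= 0:
            raise ValueError("distance threshold must be positive")

    def min_users(self, service_area: str) -> int:
        return self.min_users_sick_child if service_area == "sick_child" else self.min_users_delivery


def spa_sample_size(
    n_frame: int, precision: float, p: float = 0.5, confidence: float = 0.95
) -> int:
    """Margin-of-error sample size with finite-population correction.

    n0 = z^2 p (1-p) / precision^2 ; n = ceil(n0 / (1 + (n0 - 1) / N)).
    """
    if not 0.0 < precision < 1.0:
        raise ValueError("precision must lie in (0, 1)")
    if n_frame <= 0:
        raise ValueError("frame size must be positive")
    if confidence != 0.95:
        raise ValueError("only the conventional 95% level is supported")
    n0 = _Z95**2 * p * (1.0 - p) / precision**2
    return max(1, math.ceil(n0 / (1.0 + (n0 - 1.0) / n_frame)))


def _stratum_of(facility: FacilityRecord) -> str:
    # two managing-authority strata among first-level facilities
    return "public" if facility.category.authority == "public" else "nonpublic"


def _largest_remainder(targets: dict[str, float], total: int) -> dict[str, int]:
    floors = {k: int(math.floor(v)) for k, v in targets.items()}
    shortfall = total - sum(floors.values())
    by_remainder = sorted(targets, key=lambda k: (-(targets[k] - floors[k]), k))
    for k in by_remainder[:shortfall]:
        floors[k] += 1
    return floors


def draw_seed(master_seed: int, size: int, draw_index: int) -> np.random.Generator:
    """Independent, reproducible stream for one (sample size, draw) cell."""
    return np.random.default_rng(np.random.SeedSequence([master_seed, size, draw_index]))


def draw_facility_sample(
    census: Sequence[FacilityRecord], n: int, design: SampleDesign, draw_index: int
) -> list[FacilityRecord]:
    """All referral facilities plus a random sample of n first-level facilities."""
    referral = [f for f in census if f.category.level == "referral"]
    first_level = [f for f in census if f.category.level == "first_level"]
    if n > len(first_level):
        raise ValueError(f"sample size {n} exceeds {len(first_level)} first-level facilities")
    rng = draw_seed(design.seed, n, draw_index)
    if design.stratify_by_authority:
        strata: dict[str, list[FacilityRecord]] = {}
        for f in first_level:
            strata.setdefault(_stratum_of(f), []).append(f)
        shares = {k: n * len(v) / len(first_level) for k, v in strata.items()}
        allocation = _largest_remainder(shares, n)
        chosen: list[FacilityRecord] = []
        for key in sorted(strata):
            members = strata[key]
            take = min(allocation[key], len(members))
            idx = rng.choice(len(members), size=take, replace=False)
            chosen.extend(members[i] for i in sorted(idx))
    else:
        idx = rng.choice(len(first_level), size=n, replace=False)
        chosen = [first_level[i] for i in sorted(idx)]
    return referral + chosen


def assign_random_quality(
    census: Sequence[FacilityRecord], rng: np.random.Generator
) -> list[FacilityRecord]:
    """Replace every quality score by an independent Uniform[0, 1] draw."""
    rescored = []
    for f in census:
        g = deepcopy(f)
        for area in SERVICE_AREAS:
            g.structural_score[area] = float(rng.random())
            g.process_score[area] = float(rng.random())
        rescored.append(g)
    return rescored


def facility_utilization(
    census: Sequence[FacilityRecord], episodes: Iterable[CareEpisode]
) -> dict[str, dict[str, int]]:
    """Distinct episodes per service area whose resolvable stated source is the facility."""
    known = {f.facility_id for f in census}
    counts = {fid: {area: 0 for area in SERVICE_AREAS} for fid in known}
    for episode in episodes:
        stated = {
            s.stated_facility_id
            for s in episode.sources
            if s.stated_facility_id is not None and not s.unresolvable
        }
        for fid in stated:
            if fid in known:
                counts[fid][episode.service_area] += 1
    return counts


def min_cluster_distance(
    facility: FacilityRecord, clusters: Sequence[ClusterRecord]
) -> float:
    """Minimum great-circle distance (km) from the facility to any cluster centroid."""
    if not clusters:
        raise ValueError("at least one cluster is required")
    return min(
        distance_km(
            (facility.longitude, facility.latitude), (c.longitude, c.latitude)
        )
        for c in clusters
    )


def _category_medians(
    census: Sequence[FacilityRecord], service_area: str
) -> dict[tuple[str, str], float]:
    """Pre-shift score median per (category, indicator)."""
    medians: dict[tuple[str, str], float] = {}
    by_cat: dict[str, list[FacilityRecord]] = {}
    for f in census:
        by_cat.setdefault(str(f.category), []).append(f)
    for cat, members in by_cat.items():
        for indicator in ("structural", "process"):
            values = [f.score(indicator, service_area) for f in members]
            medians[(cat, indicator)] = float(np.median(values))
    return medians


def apply_preferential_rules(
    census: Sequence[FacilityRecord],
    episodes: Iterable[CareEpisode],
    clusters: Sequence[ClusterRecord],
    config: QualitySimConfig,
    service_area: str,
    utilization: dict[str, dict[str, int]] | None = None,
    in_place: bool = False,
) -> tuple[list[FacilityRecord], dict[str, int]]:
    """Shift one service area's scores per the preferential care-seeking rules.

    Returns the re-scored census and a diagnostic tally of facilities shifted
    up versus down (the rules were designed to roughly balance the two so
    that neither ecological method is inherently advantaged).
    """
    config.validate()
    if utilization is None:
        utilization = facility_utilization(census, episodes)
    medians = _category_medians(census, service_area)
    threshold = config.min_users(service_area)
    tally = {"up": 0, "down": 0}
    out = []
    for f in census:
        g = f if in_place else deepcopy(f)
        users = utilization.get(f.facility_id, {}).get(service_area, 0)
        near = None  # computed lazily: distance only matters for unused facilities
        for indicator in ("structural", "process"):
            old = f.score(indicator, service_area)
            if users >= threshold:
                shift = config.delta
            else:
                if near is None:
                    near = min_cluster_distance(f, clusters) <= config.distance_threshold_km
                if near:
                    shift = -config.delta
                else:
                    median = medians[(str(f.category), indicator)]
                    # ties at the median shift upward (documented convention)
                    shift = config.delta if old >= median else -config.delta
            new = min(1.0, max(0.0, old + shift))
            table = g.structural_score if indicator == "structural" else g.process_score
            table[service_area] = new
            tally["up" if shift > 0 else "down"] += 1
        out.append(g)
    return out, tally


def apply_quality_simulation(
    region: RegionDataset, config: QualitySimConfig
) -> tuple[list[FacilityRecord], dict]:
    """Re-score the census per the configured mode; returns (census, diagnostics)."""
    config.validate()
    if config.mode == "original":
        return list(region.facilities), {}
    if config.mode == "random":
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 104729]))
        return assign_random_quality(region.facilities, rng), {}
    rescored = [deepcopy(f) for f in region.facilities]
    utilization = facility_utilization(region.facilities, region.episodes)
    diagnostics = {}
    for area in SERVICE_AREAS:
        rescored, tally = apply_preferential_rules(
            rescored,
            region.episodes,
            region.clusters,
            config,
            area,
            utilization=utilization,
            in_place=True,
        )
        diagnostics[area] = tally
    return rescored, diagnostics
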