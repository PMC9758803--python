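"""Synthetic regions with the statistical structure of a linking study.

The generator emulates a regional household survey plus facility census of the
kind used to estimate effective coverage in sub-Saharan settings: 44 household
clusters, 392 delivery and 183 sick-child episodes, and a census of 144 public
first-level, 43 private/religious first-level and 7 referral facilities, with
care-source probabilities calibrated to the observed mix (65.2% facility
delivery with 46.0% at public first-level facilities; 43.2% sick-child
care-seeking with 27.0% at public first-level facilities and 8.2% at
pharmacies).

Because the underlying study observes care-seeking rather than modelling it, a
choice model is needed here and is an explicit convention of this package: a
respondent first draws a source *category* (facility category, unskilled
provider, or none) from a multinomial, and then — for facility categories — a
specific facility with probability proportional to

    caseload * exp(-d / distance_decay_km) * exp(quality_preference * process)

a gravity kernel in great-circle distance d from the cluster centroid.  The
probability of seeking any care varies between clusters (a Beta profile with
intra-class correlation ``care_seeking_icc``, mean pinned at the configured
rate), reproducing the large design effects real cluster surveys show.  With
``quality_preference = 0`` (the default) choice is independent of quality;
positive values make respondents bypass nearer, lower-quality providers, the
mechanism the preferential-care-seeking scenario requires.

Quality scores are Beta-distributed, reparameterized by (mean, sd) per
provider category, with structural and process scores coupled through a
Gaussian copula.  Facilities cluster around a few town centres so that
nearest-facility linking is non-trivial; clusters are uniform over the region.
A configurable fraction of stated sources is blanked to emulate respondents
who could not recall the specific provider.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
from scipy.stats import beta as beta_dist
from scipy.stats import norm

from ecolink.linking import distance_km
from ecolink.region_model import (
    CareEpisode,
    CareSource,
    ClusterRecord,
    FacilityRecord,
    ProviderCategory,
    RegionDataset,
    SERVICE_AREAS,
)

# anchor of the local km frame (approximately northern Cote d'Ivoire)
ORIGIN_LON = -6.0
ORIGIN_LAT = 9.0
_KM_PER_DEG_LAT = 110.574
_KM_PER_DEG_LON = 111.320 * math.cos(math.radians(ORIGIN_LAT))

UNSKILLED = "unskilled"
NO_CARE = "none"


class ConfigError(ValueError):
    pass


def _default_facility_counts() -> dict[str, int]:
    # census composition: 144 public first-level, 43 private/religious
    # first-level, 7 referral (5 public, 2 private)
    return {
        "public_first_level": 144,
        "private_first_level": 22,
        "religious_first_level": 21,
        "public_referral": 5,
        "private_referral": 2,
    }


def _default_category_mix() -> dict[str, dict[str, float]]:
    # Facility-total and leading-category probabilities are calibrated to the
    # observed care-source mix; the split of the remaining facility mass
    # follows the observed ordering (public referral, then private first-level)
    # and is a generator convention.
    return {
        "delivery": {
            NO_CARE: 0.348,
            "public_first_level": 0.460,
            "public_referral": 0.110,
            "private_first_level": 0.050,
            "religious_first_level": 0.032,
        },
        "sick_child": {
            NO_CARE: 0.568,
            "public_first_level": 0.270,
            UNSKILLED: 0.082,
            "public_referral": 0.030,
            "private_first_level": 0.030,
            "religious_first_level": 0.020,
        },
    }


def _default_quality_means() -> dict[str, float]:
    # referral facilities score higher than first-level on average
    return {
        "public_first_level": 0.55,
        "private_first_level": 0.60,
        "religious_first_level": 0.60,
        "public_referral": 0.78,
        "private_referral": 0.78,
    }


@dataclass
class GeneratorConfig:
    n_clusters: int = 44
    n_deliveries: int = 392
    n_sick_children: int = 183
    facility_counts: dict[str, int] = field(default_factory=_default_facility_counts)
    region_extent_km: float = 150.0
    n_towns: int = 6
    town_scatter_km: float = 8.0
    n_districts: int = 9
    category_mix: dict[str, dict[str, float]] = field(default_factory=_default_category_mix)
    quality_means: dict[str, float] = field(default_factory=_default_quality_means)
    quality_sds: float | dict[str, float] = 0.07
    structural_process_corr: float = 0.6
    distance_decay_km: float = 15.0
    quality_preference: float = 0.0
    caseload_quality_beta: float = 0.0  # >0 couples caseload to process quality
    caseload_log_mean: float = math.log(250.0)
    caseload_log_sd: float = 0.8
    p_second_source_sick_child: float = 0.05
    care_seeking_icc: float = 0.55  # within-cluster correlation of care-seeking
    unlinkable_fraction: float = 0.07
    seed: int = 0

    def validate(self) -> None:
        for area, mix in self.category_mix.items():
            if area not in SERVICE_AREAS:
                raise ConfigError(f"unknown service area {area!r} in category_mix")
            total = sum(mix.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigError(f"category_mix[{area!r}] sums to {total}, not 1")
            for key, p in mix.items():
                if not 0.0 <= p <= 1.0:
                    raise ConfigError(f"probability {key}={p} outside [0, 1]")
                if key not in (NO_CARE, UNSKILLED) and key not in self.facility_counts:
                    raise ConfigError(f"category {key!r} has no facilities configured")
        if not 0.0 <= self.unlinkable_fraction < 1.0:
            raise ConfigError("unlinkable_fraction must lie in [0, 1)")
        if not 0.0 <= self.care_seeking_icc < 1.0:
            raise ConfigError("care_seeking_icc must lie in [0, 1)")
        for name in ("n_clusters", "n_deliveries", "n_sick_children", "n_districts", "n_towns"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        for mean in self.quality_means.values():
            if not 0.0 < mean < 1.0:
                raise ConfigError("quality means must lie strictly inside (0, 1)")

    def sd_for(self, category: str) -> float:
        if isinstance(self.quality_sds, Mapping):
            return float(self.quality_sds.get(category, 0.07))
        return float(self.quality_sds)

    def to_metadata(self) -> dict:
        return asdict(self)


def _km_to_lonlat(x_km: float, y_km: float) -> tuple[float, float]:
    return ORIGIN_LON + x_km / _KM_PER_DEG_LON, ORIGIN_LAT + y_km / _KM_PER_DEG_LAT


def _district_of(x_km: float, y_km: float, extent_km: float, n_districts: int) -> str:
    """Deterministic spatial partition of the extent into a near-square grid."""
    cols = math.ceil(math.sqrt(n_districts))
    rows = math.ceil(n_districts / cols)
    col = min(cols - 1, int(x_km / extent_km * cols))
    row = min(rows - 1, int(y_km / extent_km * rows))
    index = min(n_districts - 1, row * cols + col)
    return f"D{index:02d}"


def _beta_params(mean: float, sd: float) -> tuple[float, float]:
    """Moment inversion for Beta(a, b); sd is capped below the feasible bound."""
    cap = 0.95 * math.sqrt(mean * (1.0 - mean))
    sd = min(sd, cap)
    nu = mean * (1.0 - mean) / (sd * sd) - 1.0
    return mean * nu, (1.0 - mean) * nu


def _draw_score_pair(
    mean: float, sd: float, corr: float, rng: np.random.Generator
) -> tuple[float, float]:
    """Correlated (structural, process) scores via a Gaussian copula on Beta margins."""
    if sd <= 0.0:
        return mean, mean
    a, b = _beta_params(mean, sd)
    z1 = rng.standard_normal()
    z2 = corr * z1 + math.sqrt(max(0.0, 1.0 - corr * corr)) * rng.standard_normal()
    u1, u2 = norm.cdf(z1), norm.cdf(z2)
    s = float(beta_dist.ppf(u1, a, b))
    p = float(beta_dist.ppf(u2, a, b))
    return min(1.0, max(0.0, s)), min(1.0, max(0.0, p))


def cluster_seek_propensities(
    p_seek: float, n_clusters: int, icc: float, rng: np.random.Generator
) -> np.ndarray:
    """Per-cluster probabilities of seeking any care, with mean held at p_seek.

    Household surveys show strong between-cluster heterogeneity in care-seeking
    (the design effect implied by published regional CIs is well above 1).  The
    propensities follow the quantile profile of a Beta distribution whose
    intra-class correlation is ``icc`` — evaluated at fixed mid-quantiles and
    randomly permuted over clusters — so the region-wide care-seeking rate
    stays pinned at its configured value while clusters differ realistically.
    """
    if icc <= 0.0 or p_seek in (0.0, 1.0):
        return np.full(n_clusters, p_seek)
    kappa = (1.0 - icc) / icc
    grid = (np.arange(n_clusters) + 0.5) / n_clusters
    values = beta_dist.ppf(grid, p_seek * kappa, (1.0 - p_seek) * kappa)
    values *= p_seek / values.mean()  # undo the tiny quantile-average offset
    return rng.permutation(np.clip(values, 0.0, 1.0))


def sample_source_category(
    service_area: str, category_mix: Mapping[str, Mapping[str, float]], rng: np.random.Generator
) -> str:
    """Draw a source-category token ('none', 'unskilled', or a facility category)."""
    mix = category_mix[service_area]
    keys = sorted(mix)
    probs = np.array([mix[k] for k in keys], dtype=float)
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ConfigError(f"category_mix[{service_area!r}] does not sum to 1")
    return keys[int(rng.choice(len(keys), p=probs / probs.sum()))]


def sample_specific_provider(
    cluster: ClusterRecord,
    category: ProviderCategory,
    facilities: list[FacilityRecord],
    distance_decay_km: float,
    quality_preference: float,
    service_area: str,
    rng: np.random.Generator,
) -> str:
    """Gravity-model facility choice within a category.

    Probability proportional to caseload * exp(-d/decay) * exp(pref * process),
    d the great-circle distance from the cluster centroid.
    """
    candidates = [f for f in facilities if f.category == category]
    if not candidates:
        raise ValueError(f"no facility of category {category} to choose from")
    weights = np.array(
        [
            max(f.caseload[service_area], 1e-9)
            * math.exp(
                -distance_km(
                    (cluster.longitude, cluster.latitude), (f.longitude, f.latitude)
                )
                / distance_decay_km
            )
            * math.exp(quality_preference * f.process_score[service_area])
            for f in candidates
        ]
    )
    probs = weights / weights.sum()
    return candidates[int(rng.choice(len(candidates), p=probs))].facility_id


def apply_unlinkable_mask(
    region: RegionDataset, fraction: float, rng: np.random.Generator
) -> RegionDataset:
    """Blank stated facility ids for an expected fraction of care-seeking episodes.

    Emulates respondents who could not recall (or whose provider was not
    enumerated); the reported category is retained, so masked episodes take
    the fallback path under exact-match linking.  Mutates in place.
    """
    if not 0.0 <= fraction < 1.0:
        raise ConfigError("fraction must lie in [0, 1)")
    for episode in region.episodes:
        if not any(s.stated_facility_id is not None for s in episode.sources):
            continue
        if rng.random() < fraction:
            for source in episode.sources:
                source.stated_facility_id = None
    region.resolve_sources()
    return region


def _place_facilities(
    config: GeneratorConfig, towns: np.ndarray, rng: np.random.Generator
) -> list[FacilityRecord]:
    extent = config.region_extent_km
    facilities = []
    serial = 0
    for cat_token in sorted(config.facility_counts):
        count = config.facility_counts[cat_token]
        category = ProviderCategory.parse(cat_token)
        mean = config.quality_means[cat_token]
        sd = config.sd_for(cat_token)
        for _ in range(count):
            # mild clustering around towns keeps nearest-facility linking
            # non-trivial; a quarter of facilities are fully dispersed
            if rng.random() < 0.25:
                x, y = rng.uniform(0.0, extent, size=2)
            else:
                tx, ty = towns[int(rng.integers(len(towns)))]
                x = float(np.clip(tx + rng.normal(0.0, config.town_scatter_km), 0.0, extent))
                y = float(np.clip(ty + rng.normal(0.0, config.town_scatter_km), 0.0, extent))
            lon, lat = _km_to_lonlat(x, y)
            scores = {
                area: _draw_score_pair(mean, sd, config.structural_process_corr, rng)
                for area in SERVICE_AREAS
            }
            caseload = {}
            for area in SERVICE_AREAS:
                base = float(rng.lognormal(config.caseload_log_mean, config.caseload_log_sd))
                if config.caseload_quality_beta > 0.0:
                    base *= math.exp(
                        config.caseload_quality_beta * (scores[area][1] - mean)
                    )
                caseload[area] = base
            facilities.append(
                FacilityRecord(
                    facility_id=f"F{serial:03d}",
                    category=category,
                    district=_district_of(x, y, extent, config.n_districts),
                    longitude=lon,
                    latitude=lat,
                    caseload=caseload,
                    structural_score={a: scores[a][0] for a in SERVICE_AREAS},
                    process_score={a: scores[a][1] for a in SERVICE_AREAS},
                )
            )
            serial += 1
    return facilities


def generate_region(config: GeneratorConfig | None = None, seed: int | None = None) -> RegionDataset:
    """Generate a full synthetic region; bit-identical for identical config + seed."""
    config = config or GeneratorConfig()
    if seed is not None:
        config = GeneratorConfig(**{**config.to_metadata(), "seed": seed})
    config.validate()
    rng = np.random.default_rng(config.seed)
    extent = config.region_extent_km

    towns = rng.uniform(0.0, extent, size=(config.n_towns, 2))
    facilities = _place_facilities(config, towns, rng)

    clusters = []
    for i in range(config.n_clusters):
        x, y = rng.uniform(0.0, extent, size=2)
        lon, lat = _km_to_lonlat(x, y)
        clusters.append(
            ClusterRecord(
                cluster_id=f"C{i:02d}",
                longitude=lon,
                latitude=lat,
                district=_district_of(x, y, extent, config.n_districts),
                weight=1.0,
            )
        )

    # lazy per-(cluster, category) gravity choice distributions
    by_category: dict[str, list[FacilityRecord]] = {}
    for f in facilities:
        by_category.setdefault(str(f.category), []).append(f)
    choice_cache: dict[tuple[str, str, str], tuple[list[str], np.ndarray]] = {}

    def draw_facility(cluster: ClusterRecord, cat_token: str, area: str) -> str:
        key = (cluster.cluster_id, cat_token, area)
        if key not in choice_cache:
            cands = by_category[cat_token]
            weights = np.array(
                [
                    max(f.caseload[area], 1e-9)
                    * math.exp(
                        -distance_km(
                            (cluster.longitude, cluster.latitude),
                            (f.longitude, f.latitude),
                        )
                        / config.distance_decay_km
                    )
                    * math.exp(config.quality_preference * f.process_score[area])
                    for f in cands
                ]
            )
            choice_cache[key] = ([f.facility_id for f in cands], weights / weights.sum())
        ids, probs = choice_cache[key]
        return ids[int(rng.choice(len(ids), p=probs))]

    # two-stage choice: a cluster-specific probability of seeking any care,
    # then a cluster-independent conditional source mix.  Marginally this
    # reproduces category_mix exactly while adding the between-cluster
    # care-seeking heterogeneity real surveys show.
    seek_p: dict[str, np.ndarray] = {}
    cond_mix: dict[str, tuple[list[str], np.ndarray]] = {}
    for area in SERVICE_AREAS:
        mix = config.category_mix[area]
        p_seek = 1.0 - mix.get(NO_CARE, 0.0)
        seek_p[area] = cluster_seek_propensities(
            p_seek, config.n_clusters, config.care_seeking_icc, rng
        )
        keys = sorted(k for k in mix if k != NO_CARE)
        probs = np.array([mix[k] for k in keys], dtype=float)
        cond_mix[area] = (keys, probs / probs.sum() if probs.sum() > 0 else probs)

    def draw_source(cluster_pos: int, cluster: ClusterRecord, area: str) -> CareSource | None:
        if rng.random() >= seek_p[area][cluster_pos]:
            return None
        keys, probs = cond_mix[area]
        token = keys[int(rng.choice(len(keys), p=probs))]
        if token == UNSKILLED:
            return CareSource(category=None)
        fid = draw_facility(cluster, token, area)
        return CareSource(category=ProviderCategory.parse(token), stated_facility_id=fid)

    episodes = []
    serial = 0
    plan = [("delivery", config.n_deliveries), ("sick_child", config.n_sick_children)]
    for area, n in plan:
        for _ in range(n):
            pos = int(rng.integers(config.n_clusters))
            cluster = clusters[pos]
            sources = []
            first = draw_source(pos, cluster, area)
            if first is not None:
                sources.append(first)
                if (
                    area == "sick_child"
                    and rng.random() < config.p_second_source_sick_child
                ):
                    second = draw_source(pos, cluster, area)
                    if second is not None:
                        sources.append(second)
            episodes.append(
                CareEpisode(
                    episode_id=f"E{serial:05d}",
                    cluster_id=cluster.cluster_id,
                    service_area=area,
                    sources=sources,
                    weight=1.0,
                )
            )
            serial += 1

    region = RegionDataset(
        facilities=facilities,
        clusters=clusters,
        episodes=episodes,
        metadata={"generator": config.to_metadata(), "seed": config.seed},
    )
    apply_unlinkable_mask(region, config.unlinkable_fraction, rng)
    region.resolve_sources()
    return region
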