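"""Effective-coverage cascade estimators with design-based confidence intervals.

Following the effective-coverage cascade for maternal and child health
indicators, three quantities are computed over the in-need population:

* **crude coverage** — the weighted proportion who sought care from a skilled
  (facility-based) provider;
* **input-adjusted coverage** — crude coverage discounted by the structural
  (readiness) score of each individual's linked provider; and
* **quality-adjusted coverage** — crude coverage discounted by the process
  (provision-of-care) score of the linked provider.

All three are weighted ratio means ``sum(w*s*q) / sum(w)`` with s the skilled
care-seeking indicator and q the linked score (q = 1 for crude coverage).
Variance treats household clusters as primary sampling units in a single
stratum and the linked provider scores as an extension of the household survey
record; error in the facility assessment itself is ignored by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from ecolink.linking import LinkResult
from ecolink.region_model import CareEpisode

INDICATOR_NAMES = ("crude", "input_adjusted", "quality_adjusted")

_Z95 = 1.959963984540054  # standard normal 97.5th percentile


@dataclass
class CoverageEstimate:
    indicator: str
    service_area: str
    point: float
    se: float
    ci_low: float
    ci_high: float
    n_episodes: int
    n_clusters: int
    method: str = ""
    dataset_tag: str = ""


def design_ci(
    per_episode_values: Sequence[tuple[str, float, float]], level: float = 0.95
) -> tuple[float, float, float]:
    """Taylor-linearized SE and symmetric CI for a weighted ratio mean.

    ``per_episode_values`` holds (cluster_id, weight, value) triples.  The
    estimator is r = sum(w v) / sum(w); its linearized variance with clusters
    as with-replacement PSUs in one stratum is

        var(r) = n/(n-1) * sum_c (u_c)^2 / W^2,   u_c = sum_{i in c} w_i (v_i - r)

    with n the number of clusters and W the total weight.  The CI is the
    normal approximation, clipped to [0, 1].
    """
    clusters: dict[str, float] = {}
    total_w = 0.0
    total_wv = 0.0
    for cluster_id, weight, value in per_episode_values:
        total_w += weight
        total_wv += weight * value
    if total_w <= 0:
        raise ValueError("total weight must be positive")
    r = total_wv / total_w
    for cluster_id, weight, value in per_episode_values:
        clusters[cluster_id] = clusters.get(cluster_id, 0.0) + weight * (value - r)
    n = len(clusters)
    if n < 2:
        raise ValueError("design-based variance requires at least 2 clusters")
    var = (n / (n - 1)) * sum(u * u for u in clusters.values()) / (total_w * total_w)
    se = math.sqrt(max(0.0, var))
    if not 0 < level < 1:
        raise ValueError("confidence level must be in (0, 1)")
    # inverse-normal quantile via Acklam-style rational approximation is
    # overkill here: only the conventional levels are ever used.
    z = {0.95: _Z95, 0.90: 1.6448536269514722, 0.99: 2.5758293035489004}.get(level)
    if z is None:
        raise ValueError(f"unsupported confidence level {level}")
    return se, max(0.0, r - z * se), min(1.0, r + z * se)


def _episode_value(episode: CareEpisode, link: LinkResult | None, indicator: str) -> float:
    skilled = link.skilled_care if link is not None else episode.sought_skilled_care
    if not skilled:
        return 0.0
    if indicator == "crude":
        return 1.0
    assert link is not None
    q = link.structural if indicator == "input_adjusted" else link.process
    if q is None:
        raise ValueError(f"episode {episode.episode_id!r} skilled but carries no score")
    return q


def effective_coverage(
    episodes: Sequence[CareEpisode],
    links: Iterable[LinkResult] | None,
    indicator: str,
    service_area: str,
    method: str = "",
    dataset_tag: str = "",
) -> CoverageEstimate:
    """Point estimate with design-based 95% CI for one cascade indicator.

    Requires one link result per in-need episode of the service area (links
    may be omitted entirely for the crude indicator, which needs only the
    care-seeking flag).
    """
    if indicator not in INDICATOR_NAMES:
        raise ValueError(f"unknown indicator {indicator!r}")
    episodes = [e for e in episodes if e.service_area == service_area and e.in_need]
    link_index: dict[str, LinkResult] = {}
    if links is not None:
        link_index = {l.episode_id: l for l in links}
    values = []
    for episode in episodes:
        link = link_index.get(episode.episode_id)
        if link is None and (indicator != "crude" or links is not None):
            raise ValueError(f"missing link for in-need episode {episode.episode_id!r}")
        values.append((episode.cluster_id, episode.weight, _episode_value(episode, link, indicator)))
    total_w = sum(w for _, w, _ in values)
    point = sum(w * v for _, w, v in values) / total_w
    se, ci_low, ci_high = design_ci(values)
    return CoverageEstimate(
        indicator=indicator,
        service_area=service_area,
        point=point,
        se=se,
        ci_low=ci_low,
        ci_high=ci_high,
        n_episodes=len(values),
        n_clusters=len({c for c, _, _ in values}),
        method=method,
        dataset_tag=dataset_tag,
    )


def crude_coverage(
    episodes: Sequence[CareEpisode], service_area: str, dataset_tag: str = ""
) -> CoverageEstimate:
    """Weighted proportion of in-need episodes with skilled (facility) care."""
    return effective_coverage(
        episodes, None, "crude", service_area, method="", dataset_tag=dataset_tag
    )
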