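"""Scenario orchestration: the full sampling-bias experiment on one region.

A scenario run (original, random-quality, or preferential-care-seeking)
produces:

* **exact-match references** — input- and quality-adjusted coverage for both
  service areas, linking each individual to their stated provider over the
  (possibly re-scored) facility census; the study's best estimate of truth;
* **census references** — the same indicators per ecological linking method
  (Euclidean nearest, administrative unit) against the full census; and
* **the sampled grid** — for every sample size and draw, both ecological
  methods applied to the sampled facility set, for both indicators and both
  service areas.  With the default design (3 sizes x 20 draws x 2 methods x
  2 indicators x 2 service areas) that is 480 sampled estimates, 160 per
  sample size and 240 per linking method.

A sampled estimate counts as an outlier when its point falls strictly outside
the 95% CI of the reference (exact-match or census) estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ecolink.coverage import CoverageEstimate, effective_coverage
from ecolink.linking import link_episodes
from ecolink.region_model import RegionDataset, SERVICE_AREAS, facilities_frame
from ecolink.sampling_quality import (
    QualitySimConfig,
    SampleDesign,
    apply_quality_simulation,
    draw_facility_sample,
)

ADJUSTED_INDICATORS = ("input_adjusted", "quality_adjusted")
ECOLOGICAL_METHODS = ("euclidean", "admin")

_GRID_KEY = ["service_area", "indicator", "method", "sample_size"]


@dataclass
class ScenarioResult:
    """Every estimate of one scenario plus outlier counts and summaries.

    ``estimates`` is a tidy frame with one row per estimate; ``dataset`` is
    'exact', 'census', or 'sample'; sampled rows carry sample_size and
    draw_index.  Points and CI bounds are proportions in [0, 1].
    """

    scenario: str
    estimates: pd.DataFrame
    outliers_vs_exact: pd.DataFrame = field(default_factory=pd.DataFrame)
    outliers_vs_census: pd.DataFrame = field(default_factory=pd.DataFrame)
    summaries: pd.DataFrame = field(default_factory=pd.DataFrame)
    diagnostics: dict = field(default_factory=dict)

    @property
    def sampled(self) -> pd.DataFrame:
        return self.estimates[self.estimates["dataset"] == "sample"]

    def reference(self, dataset: str, service_area: str, indicator: str, method: str = "") -> pd.Series:
        frame = self.estimates
        mask = (
            (frame["dataset"] == dataset)
            & (frame["service_area"] == service_area)
            & (frame["indicator"] == indicator)
        )
        if dataset == "census":
            mask &= frame["method"] == method
        rows = frame[mask]
        if len(rows) != 1:
            raise KeyError(f"expected one {dataset} reference, found {len(rows)}")
        return rows.iloc[0]


def _estimate_row(est: CoverageEstimate, dataset: str, sample_size=None, draw_index=None) -> dict:
    return {
        "dataset": dataset,
        "service_area": est.service_area,
        "indicator": est.indicator,
        "method": est.method,
        "sample_size": sample_size,
        "draw_index": draw_index,
        "point": est.point,
        "se": est.se,
        "ci_low": est.ci_low,
        "ci_high": est.ci_high,
        "n_episodes": est.n_episodes,
        "n_clusters": est.n_clusters,
    }


def count_outliers(points: Sequence[float], reference: CoverageEstimate | pd.Series) -> int:
    """Points strictly outside the reference 95% CI."""
    low = reference.ci_low if hasattr(reference, "ci_low") else reference["ci_low"]
    high = reference.ci_high if hasattr(reference, "ci_high") else reference["ci_high"]
    return int(sum(1 for p in points if p < low or p > high))


def summarize_estimates(sampled: pd.DataFrame) -> pd.DataFrame:
    """Median and IQR (linear-interpolation percentiles) per grid cell."""
    if sampled.empty:
        raise ValueError("no sampled estimates to summarize")

    def _one(group: pd.DataFrame) -> pd.Series:
        points = group["point"].to_numpy()
        q25, q50, q75 = np.percentile(points, [25, 50, 75])
        return pd.Series(
            {"median": q50, "iqr_low": q25, "iqr_high": q75, "n": len(points)}
        )

    return (
        sampled.groupby(_GRID_KEY, dropna=False)[["point"]]
        .apply(_one)
        .reset_index()
    )


def _rescored_region(region: RegionDataset, facilities) -> RegionDataset:
    clone = RegionDataset(
        facilities=list(facilities),
        clusters=region.clusters,
        episodes=region.episodes,
        metadata=dict(region.metadata),
    )
    clone.resolve_sources()
    return clone


def run_scenario(
    region: RegionDataset,
    scenario: str = "original",
    design: SampleDesign | None = None,
    qconfig: QualitySimConfig | None = None,
) -> ScenarioResult:
    """Run one full scenario: re-score, reference estimates, sampled grid, analysis."""
    design = design or SampleDesign()
    qconfig = qconfig or QualitySimConfig(mode=scenario, seed=design.seed)
    if qconfig.mode != scenario:
        raise ValueError(f"quality config mode {qconfig.mode!r} != scenario {scenario!r}")

    census, diagnostics = apply_quality_simulation(region, qconfig)
    study = _rescored_region(region, census)

    rows: list[dict] = []
    for area in SERVICE_AREAS:
        episodes = study.episodes_for(area)
        exact_links = link_episodes(study, "exact", service_area=area)
        for indicator in ADJUSTED_INDICATORS:
            est = effective_coverage(
                episodes, exact_links, indicator, area, method="exact", dataset_tag="exact"
            )
            rows.append(_estimate_row(est, "exact"))
        for method in ECOLOGICAL_METHODS:
            links = link_episodes(study, method, service_area=area)
            for indicator in ADJUSTED_INDICATORS:
                est = effective_coverage(
                    episodes, links, indicator, area, method=method, dataset_tag="census"
                )
                rows.append(_estimate_row(est, "census"))

    fallback_log = []
    for size in design.sample_sizes:
        for draw in range(design.n_draws):
            sample = draw_facility_sample(census, size, design, draw)
            for area in SERVICE_AREAS:
                episodes = study.episodes_for(area)
                for method in ECOLOGICAL_METHODS:
                    links = link_episodes(study, method, facilities=sample, service_area=area)
                    n_fallback = sum(1 for l in links if l.fallback_used)
                    fallback_log.append(
                        {
                            "sample_size": size,
                            "draw_index": draw,
                            "service_area": area,
                            "method": method,
                            "n_facilities": len(sample),
                            "n_fallback": n_fallback,
                        }
                    )
                    for indicator in ADJUSTED_INDICATORS:
                        est = effective_coverage(
                            episodes,
                            links,
                            indicator,
                            area,
                            method=method,
                            dataset_tag=f"sample_{size}_{draw}",
                        )
                        rows.append(_estimate_row(est, "sample", size, draw))

    estimates = pd.DataFrame(rows)
    result = ScenarioResult(scenario=scenario, estimates=estimates, diagnostics=diagnostics)
    result.diagnostics["fallback_log"] = pd.DataFrame(fallback_log)
    result.outliers_vs_exact = _outlier_table(result, "exact")
    result.outliers_vs_census = _outlier_table(result, "census")
    result.summaries = summarize_estimates(result.sampled)
    return result


def _outlier_table(result: ScenarioResult, reference_dataset: str) -> pd.DataFrame:
    """Outlier counts per grid cell against the exact or census reference."""
    records = []
    sampled = result.sampled
    for (area, indicator, method, size), group in sampled.groupby(_GRID_KEY, dropna=False):
        ref_method = method if reference_dataset == "census" else ""
        reference = result.reference(reference_dataset, area, indicator, ref_method)
        records.append(
            {
                "service_area": area,
                "indicator": indicator,
                "method": method,
                "sample_size": size,
                "n_outliers": count_outliers(group["point"].tolist(), reference),
                "n_estimates": len(group),
            }
        )
    return pd.DataFrame(records)


def outlier_margins(outliers: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Aggregate outlier counts by sample size and by linking method.

    With the default grid the by-size denominators are 160 (2 methods x 20
    draws x 2 areas x 2 indicators) and the by-method denominators 240
    (3 sizes x 20 draws x 2 areas x 2 indicators).
    """
    by_size = (
        outliers.groupby("sample_size")[["n_outliers", "n_estimates"]].sum().reset_index()
    )
    by_method = (
        outliers.groupby("method")[["n_outliers", "n_estimates"]].sum().reset_index()
    )
    total = pd.DataFrame(
        [
            {
                "n_outliers": int(outliers["n_outliers"].sum()),
                "n_estimates": int(outliers["n_estimates"].sum()),
            }
        ]
    )
    return {"by_size": by_size, "by_method": by_method, "total": total}


def export_report(result: ScenarioResult, directory: str | Path) -> set[Path]:
    """Write tidy estimates, outlier counts, Table-style summaries, strip plots."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: set[Path] = set()

    est_path = directory / "estimates.csv"
    result.estimates.to_csv(est_path, index=False)
    written.add(est_path)

    frames = []
    for ref_name, table in (
        ("exact", result.outliers_vs_exact),
        ("census", result.outliers_vs_census),
    ):
        margins = outlier_margins(table)
        for margin_name, frame in margins.items():
            frame = frame.copy()
            frame.insert(0, "reference", ref_name)
            frame.insert(1, "margin", margin_name)
            frames.append(frame)
    out_path = directory / "outliers.csv"
    pd.concat(frames, ignore_index=True).to_csv(out_path, index=False)
    written.add(out_path)

    summary = result.summaries.copy()
    for col in ("median", "iqr_low", "iqr_high"):
        summary[f"{col}_pct"] = (summary[col] * 100).round(1)
    sum_path = directory / "summary.csv"
    summary.to_csv(sum_path, index=False)
    written.add(sum_path)

    written |= _strip_plots(result, directory / "plots")
    return written


def _strip_plots(result: ScenarioResult, directory: Path) -> set[Path]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    directory.mkdir(parents=True, exist_ok=True)
    written: set[Path] = set()
    sizes = sorted(result.sampled["sample_size"].dropna().unique())
    for area in SERVICE_AREAS:
        fig, axes = plt.subplots(
            1, len(ADJUSTED_INDICATORS), figsize=(10, 4), sharey=True
        )
        for ax, indicator in zip(np.atleast_1d(axes), ADJUSTED_INDICATORS):
            exact = result.reference("exact", area, indicator)
            ax.axhline(exact["point"], color="red", lw=1.5, label="exact match")
            ax.axhspan(exact["ci_low"], exact["ci_high"], color="red", alpha=0.12)
            positions = {}
            tick = 0
            for method in ECOLOGICAL_METHODS:
                census = result.reference("census", area, indicator, method)
                for size in sizes:
                    cell = result.sampled[
                        (result.sampled["service_area"] == area)
                        & (result.sampled["indicator"] == indicator)
                        & (result.sampled["method"] == method)
                        & (result.sampled["sample_size"] == size)
                    ]
                    jitter = np.linspace(-0.18, 0.18, len(cell))
                    ax.plot(
                        tick + jitter, cell["point"], "o", ms=3, color="gray", alpha=0.6
                    )
                    ax.errorbar(
                        [tick],
                        [census["point"]],
                        yerr=[
                            [census["point"] - census["ci_low"]],
                            [census["ci_high"] - census["point"]],
                        ],
                        fmt="D",
                        ms=4,
                        color="tab:blue" if method == "admin" else "tab:green",
                        capsize=3,
                    )
                    positions[tick] = f"{method}\nn={int(size)}"
                    tick += 1
            ax.set_xticks(list(positions))
            ax.set_xticklabels(list(positions.values()), fontsize=7)
            ax.set_title(f"{indicator.replace('_', '-')} coverage")
            ax.set_ylabel("coverage")
        fig.suptitle(f"{result.scenario} scenario, {area.replace('_', ' ')}")
        fig.tight_layout()
        path = directory / f"{result.scenario}_{area}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.add(path)
    return written


def sample_facility_table(sample) -> pd.DataFrame:
    """Tidy table of one sampled facility set (for CLI export)."""
    return facilities_frame(sample)
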