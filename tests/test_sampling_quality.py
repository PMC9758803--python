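"""Facility sampling design and the two quality-score simulations."""

import numpy as np
import pytest

from ecolink.region_model import ClusterRecord, ProviderCategory
from ecolink.sampling_quality import (
    QualitySimConfig,
    SampleDesign,
    apply_preferential_rules,
    apply_quality_simulation,
    assign_random_quality,
    draw_facility_sample,
    facility_utilization,
    min_cluster_distance,
    spa_sample_size,
)


class TestSampleSize:
    @pytest.mark.parametrize(
        "n_frame, precision, expected",
        [
            (187, 0.10, 64),  # regional frame with FPC
            (10_000, 0.10, 96),  # FPC negligible: n0 = 96.04
        ],
    )
    def test_margin_of_error_formula(self, n_frame, precision, expected):
        assert spa_sample_size(n_frame, precision) == expected

    def test_precision_near_one_needs_single_facility(self):
        assert spa_sample_size(500, 0.99) == 1

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            spa_sample_size(100, 0.0)
        with pytest.raises(ValueError):
            spa_sample_size(100, 1.5)


class TestFacilitySampling:
    def test_referral_census_plus_n_first_level(self, default_region):
        design = SampleDesign(seed=3)
        sample = draw_facility_sample(default_region.facilities, 65, design, 0)
        assert len(sample) == 65 + 7
        referral_ids = {
            f.facility_id for f in default_region.facilities if f.category.level == "referral"
        }
        assert referral_ids <= {f.facility_id for f in sample}

    def test_exhaustive_sample_is_census(self, default_region):
        design = SampleDesign(seed=3)
        sample = draw_facility_sample(default_region.facilities, 187, design, 0)
        assert sorted(f.facility_id for f in sample) == sorted(
            f.facility_id for f in default_region.facilities
        )

    def test_oversized_sample_rejected(self, default_region):
        with pytest.raises(ValueError, match="exceeds"):
            draw_facility_sample(default_region.facilities, 188, SampleDesign(), 0)

    def test_draws_are_reproducible_and_distinct(self, default_region):
        design = SampleDesign(seed=5)
        a = draw_facility_sample(default_region.facilities, 65, design, 3)
        b = draw_facility_sample(default_region.facilities, 65, design, 3)
        c = draw_facility_sample(default_region.facilities, 65, design, 4)
        assert [f.facility_id for f in a] == [f.facility_id for f in b]
        assert [f.facility_id for f in a] != [f.facility_id for f in c]

    def test_inclusion_probabilities_proportional(self, default_region):
        """Each first-level facility appears with frequency ~ its stratum share of n=65."""
        design = SampleDesign(seed=7)
        counts: dict[str, int] = {}
        n_draws = 600
        for draw in range(n_draws):
            for f in draw_facility_sample(default_region.facilities, 65, design, draw):
                counts[f.facility_id] = counts.get(f.facility_id, 0) + 1
        first_level = [f for f in default_region.facilities if f.category.level == "first_level"]
        strata: dict[str, list] = {}
        for f in first_level:
            key = "public" if f.category.authority == "public" else "nonpublic"
            strata.setdefault(key, []).append(f)
        for key, members in strata.items():
            allocation = round(65 * len(members) / len(first_level))
            expected = allocation / len(members)
            for f in members:
                assert counts.get(f.facility_id, 0) / n_draws == pytest.approx(
                    expected, abs=0.06
                )


class TestRandomQuality:
    def test_scores_replaced_everything_else_kept(self, default_region):
        rng = np.random.default_rng(0)
        rescored = assign_random_quality(default_region.facilities, rng)
        for old, new in zip(default_region.facilities, rescored):
            assert new.facility_id == old.facility_id
            assert new.category == old.category
            assert new.caseload == old.caseload
            assert (new.longitude, new.latitude) == (old.longitude, old.latitude)
            for area in ("sick_child", "delivery"):
                assert 0.0 <= new.structural_score[area] <= 1.0
                assert 0.0 <= new.process_score[area] <= 1.0

    def test_category_medians_near_half(self, default_region):
        """Uniform redraws put the numerous first-level categories' medians near 50%."""
        rng = np.random.default_rng(1)
        rescored = assign_random_quality(default_region.facilities, rng)
        for cat in ("public_first_level", "private_first_level"):
            values = [
                f.structural_score["delivery"]
                for f in rescored
                if str(f.category) == cat
            ]
            assert float(np.median(values)) == pytest.approx(0.5, abs=0.1)

    def test_same_seed_reproduces(self, default_region):
        a = assign_random_quality(default_region.facilities, np.random.default_rng(9))
        b = assign_random_quality(default_region.facilities, np.random.default_rng(9))
        assert a == b


class TestUtilization:
    def test_counts_and_conservation(self, tiny_region):
        counts = facility_utilization(tiny_region.facilities, tiny_region.episodes)
        assert counts["F1"] == {"sick_child": 1, "delivery": 1}
        assert counts["F2"] == {"sick_child": 1, "delivery": 0}
        assert counts["F4"] == {"sick_child": 0, "delivery": 0}
        # conservation: sums equal resolvable care-seeking episode-source pairs
        total = {"sick_child": 0, "delivery": 0}
        for c in counts.values():
            for area in total:
                total[area] += c[area]
        assert total == {"sick_child": 4, "delivery": 1}


class TestMinClusterDistance:
    def test_colocated_cluster(self, tiny_region):
        assert min_cluster_distance(tiny_region.facilities[0], tiny_region.clusters) == 0.0

    def test_one_degree_offset(self, tiny_region):
        clusters = [ClusterRecord("C", 0.0, 1.0, "D1")]
        assert min_cluster_distance(tiny_region.facilities[0], clusters) == pytest.approx(
            111.195, abs=0.01
        )

    def test_is_a_lower_envelope(self, default_region):
        from ecolink.linking import distance_km

        f = default_region.facilities[0]
        d = min_cluster_distance(f, default_region.clusters)
        for c in default_region.clusters:
            assert d <= distance_km((f.longitude, f.latitude), (c.longitude, c.latitude)) + 1e-12

    def test_empty_cluster_list_rejected(self, tiny_region):
        with pytest.raises(ValueError):
            min_cluster_distance(tiny_region.facilities[0], [])


class TestPreferentialRules:
    def test_utilized_facility_gains_delta(self, tiny_region):
        # F2 has one sick-child user and score 0.2 -> 0.35
        config = QualitySimConfig(mode="preferential")
        rescored, _ = apply_preferential_rules(
            tiny_region.facilities, tiny_region.episodes, tiny_region.clusters, config, "sick_child"
        )
        f2 = next(f for f in rescored if f.facility_id == "F2")
        assert f2.structural_score["sick_child"] == pytest.approx(0.35)

    def test_underused_nearby_facility_loses_delta(self, tiny_region):
        # F2 has 0 delivery users (< 2) and is ~5.6 km from cluster C1
        config = QualitySimConfig(mode="preferential")
        rescored, _ = apply_preferential_rules(
            tiny_region.facilities, tiny_region.episodes, tiny_region.clusters, config, "delivery"
        )
        f2 = next(f for f in rescored if f.facility_id == "F2")
        assert f2.structural_score["delivery"] == pytest.approx(0.2 - 0.15)

    def test_remote_unused_facility_moves_by_median(self, tiny_region):
        # move F2 far away; with structural 0.2 < category median it sinks,
        # then re-test with a high score: it rises
        config = QualitySimConfig(mode="preferential")
        far = tiny_region.facilities
        f2 = next(f for f in far if f.facility_id == "F2")
        f2.longitude, f2.latitude = 3.0, 3.0
        rescored, _ = apply_preferential_rules(
            far, tiny_region.episodes, tiny_region.clusters, config, "delivery"
        )
        g2 = next(f for f in rescored if f.facility_id == "F2")
        assert g2.structural_score["delivery"] == pytest.approx(0.05)  # 0.2 < median 0.4
        f2.structural_score["delivery"] = 0.7  # above the 0.65 median of {0.6, 0.7}
        rescored, _ = apply_preferential_rules(
            far, tiny_region.episodes, tiny_region.clusters, config, "delivery"
        )
        g2 = next(f for f in rescored if f.facility_id == "F2")
        assert g2.structural_score["delivery"] == pytest.approx(0.85)

    def test_scores_clamped_to_unit_interval(self, tiny_region):
        config = QualitySimConfig(mode="preferential")
        f1 = tiny_region.facilities[0]
        f1.structural_score["sick_child"] = 0.95  # used facility: +0.15 clamps at 1
        rescored, _ = apply_preferential_rules(
            tiny_region.facilities, tiny_region.episodes, tiny_region.clusters, config, "sick_child"
        )
        g1 = next(f for f in rescored if f.facility_id == "F1")
        assert g1.structural_score["sick_child"] == 1.0

    def test_shift_magnitude_is_delta_in_the_interior(self, default_region):
        config = QualitySimConfig(mode="preferential")
        rescored, tally = apply_preferential_rules(
            default_region.facilities,
            default_region.episodes,
            default_region.clusters,
            config,
            "delivery",
        )
        moved = 0
        for old, new in zip(default_region.facilities, rescored):
            o = old.structural_score["delivery"]
            n = new.structural_score["delivery"]
            if 0.0 < n < 1.0:
                assert abs(n - o) == pytest.approx(0.15)
                moved += 1
            assert 0.0 <= n <= 1.0
        assert moved > 0
        assert tally["up"] > 0 and tally["down"] > 0


class TestQualitySimulationDispatch:
    def test_original_mode_is_identity(self, default_region):
        census, diag = apply_quality_simulation(default_region, QualitySimConfig(mode="original"))
        assert census == default_region.facilities
        assert diag == {}

    def test_unknown_mode_rejected(self, default_region):
        with pytest.raises(ValueError, match="mode"):
            apply_quality_simulation(default_region, QualitySimConfig(mode="bogus"))

    def test_preferential_reports_balance_diagnostics(self, default_region):
        census, diag = apply_quality_simulation(
            default_region, QualitySimConfig(mode="preferential", seed=1)
        )
        for area in ("sick_child", "delivery"):
            assert diag[area]["up"] + diag[area]["down"] == 2 * len(census)
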