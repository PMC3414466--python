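from __future__ import annotations

import math

import pytest

from seamount_ebsa import (
    PortfolioCell,
    Quality,
    SimulationConfig,
    Status,
    assess,
    ebsa_score,
    exact_high_ebsa_probability,
    portfolio_class,
    portfolio_proportions,
    simulate_dummy_seamounts,
)

from conftest import PRINTED, make_record


class TestPortfolioClass:
    @pytest.mark.parametrize(
        "ebsa,threat,cell",
        [
            ("high", "low", PortfolioCell.HIGH_EBSA_LOW_THREAT),   # Sedlo
            ("low", "high", PortfolioCell.LOW_EBSA_HIGH_THREAT),   # Rosemary
            ("low", "none", PortfolioCell.LOW_EBSA_LOW_THREAT),
            ("high", "none", PortfolioCell.HIGH_EBSA_LOW_THREAT),
            ("high", "high", PortfolioCell.HIGH_EBSA_HIGH_THREAT),
            ("low", "low", PortfolioCell.LOW_EBSA_LOW_THREAT),
        ],
    )
    def test_mapping(self, ebsa, threat, cell):
        assert portfolio_class(ebsa, threat) is cell

    def test_invalid_categories_rejected(self):
        with pytest.raises(ValueError):
            portfolio_class("medium", "low")
        with pytest.raises(ValueError):
            portfolio_class("high", "severe")

    @pytest.mark.parametrize("name", list(PRINTED))
    def test_case_studies_land_in_published_cells(self, config, by_name, name):
        assert assess(by_name[name], config).portfolio.value == PRINTED[name][6]


class TestSimulator:
    def test_zero_records(self):
        assert simulate_dummy_seamounts(SimulationConfig(0, seed=1)) == []

    def test_same_seed_is_identical(self):
        a = simulate_dummy_seamounts(SimulationConfig(50, seed=7))
        b = simulate_dummy_seamounts(SimulationConfig(50, seed=7))
        assert a == b

    def test_different_seed_differs(self):
        a = simulate_dummy_seamounts(SimulationConfig(50, seed=7))
        b = simulate_dummy_seamounts(SimulationConfig(50, seed=8))
        assert a != b

    def test_quality_always_high_and_records_complete(self, config):
        for rec in simulate_dummy_seamounts(SimulationConfig(20, seed=3)):
            for obs in list(rec.indicators.values()) + list(rec.threats.values()):
                if obs.status in (Status.PRESENT, Status.ABSENT):
                    assert obs.quality is Quality.HIGH
            assert len(rec.threats) == 9

    def test_mean_indicator_count_near_binomial(self):
        n = 1000
        records = simulate_dummy_seamounts(SimulationConfig(n, seed=11))
        counts = []
        for rec in records:
            counts.append(
                sum(1 for o in rec.indicators.values()
                    if o.status is Status.PRESENT)
            )
        mean = sum(counts) / n
        se = math.sqrt(10 * 0.25 / n)  # SE of the mean of Binomial(10, .5)
        assert abs(mean - 5.0) <= 3 * se

    def test_extreme_probabilities(self):
        all_on = simulate_dummy_seamounts(
            SimulationConfig(5, p_indicator=1.0, p_threat=1.0, seed=1)
        )
        for rec in all_on:
            assert all(
                o.status in (Status.PRESENT, Status.NOT_APPLICABLE)
                for o in rec.indicators.values()
            )
            assert all(o.status is Status.PRESENT for o in rec.threats.values())

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(10, p_indicator=1.5)


class TestProportions:
    def test_sum_to_one(self, config):
        records = simulate_dummy_seamounts(SimulationConfig(200, seed=5))
        props = portfolio_proportions(records, config.matrix)
        assert sum(props.values()) == pytest.approx(1.0)

    def test_all_absent_records_are_low_low(self, config):
        records = [make_record(name=f"r{i}") for i in range(10)]
        props = portfolio_proportions(records, config.matrix)
        assert props[PortfolioCell.LOW_EBSA_LOW_THREAT] == 1.0

    def test_all_four_cells_reachable(self, config):
        rich = {
            "vents": True, "macrophytes": True, "cold_water_corals": True,
            "sponge_aggregations": True, "aggregating_fishes": True,
        }
        heavy = {"trawl_bottom": True, "longline_pelagic": True,
                 "longline_bottom": True}
        cells = set()
        for ind, thr in [({}, {}), ({}, heavy), (rich, {}), (rich, heavy)]:
            rec = make_record(present_indicators=ind, present_threats=thr)
            cells.add(assess(rec, config).portfolio)
        assert cells == set(PortfolioCell)


class TestExactEnumeration:
    def test_degenerate_probabilities(self):
        assert exact_high_ebsa_probability(0.0) == 0.0
        assert exact_high_ebsa_probability(1.0, 1.0) == 1.0

    def test_all_threatened_vs_all_plain_brackets_default(self):
        lo = exact_high_ebsa_probability(0.5, 0.0)
        mid = exact_high_ebsa_probability(0.5, 0.5)
        hi = exact_high_ebsa_probability(0.5, 1.0)
        assert lo <= mid <= hi

    def test_simulated_high_fraction_matches_enumeration(self):
        n = 1000
        p_exact = exact_high_ebsa_probability(0.5, 0.5)
        records = simulate_dummy_seamounts(SimulationConfig(n, seed=13))
        frac = sum(
            1 for rec in records if ebsa_score(rec).category == "high"
        ) / n
        se = math.sqrt(p_exact * (1 - p_exact) / n)
        assert abs(frac - p_exact) <= 3 * se
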