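"""Cash-flow engine: discounting, yield ramp, revenue/consumables
arithmetic and full scenario cash-flow assembly."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from apisim import (
    CashFlow,
    EconomicParams,
    YieldRamp,
    annual_revenue,
    build_cashflow,
    consumables_requirement,
    make_scenario,
    npv,
    yield_fraction,
)


def brute_force_npv(investment, flows, rate, rest=0.0):
    """Independent spreadsheet-style discounting: one term per year."""
    total = -investment
    for t, flow in enumerate(flows, start=1):
        total += flow / (1.0 + rate) ** t
    total += rest / (1.0 + rate) ** len(flows)
    return total


# -- yield ramp --------------------------------------------------------


@pytest.mark.parametrize("year, frac", [(0, 0.0), (1, 0.30), (2, 0.45), (4, 0.75), (10, 0.90)])
def test_default_ramp_fractions(year, frac):
    assert yield_fraction(year) == frac


def test_ramp_rejects_out_of_range_year():
    with pytest.raises(ValueError):
        yield_fraction(11)
    with pytest.raises(ValueError):
        yield_fraction(-1)


def test_ramp_year_zero_must_be_zero():
    with pytest.raises(ValueError):
        YieldRamp((0.5, 0.3))


def test_compounding_ramp_shape():
    ramp = YieldRamp.compounding()
    f = ramp.fraction_by_year
    assert f[1] == 0.0 and f[2] == pytest.approx(0.30)
    assert f[3] == pytest.approx(0.345)  # +15 % of previous year
    assert f[6] == f[7] == f[8]
    assert f[9] == pytest.approx(f[8] * 0.85)


# -- npv ---------------------------------------------------------------


def test_npv_exact_cancellation():
    cf = CashFlow(1, 100.0, (110.0,))
    assert npv(cf, 0.10) == pytest.approx(0.0, abs=1e-12)


def test_npv_zero_rate_is_plain_sum():
    cf = CashFlow(3, 50.0, (10.0, 20.0, 30.0), rest_value_usd=5.0)
    assert npv(cf, 0.0) == pytest.approx(10 + 20 + 30 + 5 - 50)


def test_npv_matches_brute_force_oracle_on_published_baseline_row():
    """Engine NPV of the published baseline flow vector equals an
    independent per-year discounting oracle to the cent."""
    flows = (15, 17, 19, 16, 9, 7, 5, 4, 3, 13)
    cf = CashFlow(10, 459.0, flows)
    expected = brute_force_npv(459.0, flows, 0.10)
    assert npv(cf, 0.10) == pytest.approx(expected, abs=1e-9)
    assert npv(cf, 0.10) == pytest.approx(-385.86, abs=0.01)


def test_npv_rejects_degenerate_rate():
    with pytest.raises(ValueError):
        npv(CashFlow(1, 0.0, (1.0,)), -1.0)


@given(st.floats(min_value=0.0, max_value=0.5), st.floats(min_value=0.01, max_value=0.5))
def test_npv_decreasing_in_rate_for_positive_flows(r, dr):
    cf = CashFlow(5, 100.0, (50.0, 40.0, 30.0, 20.0, 10.0))
    assert npv(cf, r + dr) < npv(cf, r)


# -- revenue & consumables ---------------------------------------------


def test_annual_revenue_componentwise(econ):
    rev = annual_revenue(10.0, 2.0, 1.0, econ)
    assert rev["honey"] == pytest.approx(26.10)
    assert rev["beeswax"] == pytest.approx(6.02)
    assert rev["propolis"] == pytest.approx(4.00)
    assert rev["total"] == pytest.approx(36.12)
    assert annual_revenue(0, 0, 0, econ)["total"] == 0.0


@given(st.floats(min_value=0, max_value=1e4), st.floats(min_value=0.1, max_value=10))
def test_annual_revenue_scales_linearly(honey, k):
    base = annual_revenue(honey, honey / 3, honey / 50)["total"]
    scaled = annual_revenue(k * honey, k * honey / 3, k * honey / 50)["total"]
    assert scaled == pytest.approx(k * base, rel=1e-9)


@pytest.mark.parametrize(
    "honey, buckets, strainers",
    [(0.0, 0, 0), (40.0, 2, 2), (401.0, 21, 4), (13.42, 1, 2)],
)
def test_consumables_ceiling_arithmetic(honey, buckets, strainers):
    assert consumables_requirement(honey) == (buckets, strainers)


# -- build_cashflow ----------------------------------------------------


def test_baseline_year0_investment_matches_published_total(econ):
    """Baseline year-0 outlay: hives + smoker + suit + bucket + siting
    labour sums to the published 421 USD."""
    cf = build_cashflow(make_scenario("baseline"), econ)
    assert round(cf.investment_usd) == 421


def test_zero_prices_leave_only_costs(econ):
    free = dataclasses.replace(econ, price_honey=0.0, price_beeswax=0.0, price_propolis=0.0)
    cf = build_cashflow(make_scenario("baseline"), free)
    detail = cf.detail
    assert (detail["revenue_total"] == 0).all()
    assert (np.asarray(cf.net_flow_usd) <= 0).all()


def test_more_hives_cost_more(econ):
    small = build_cashflow(make_scenario("add_ktb", 5), econ)
    large = build_cashflow(make_scenario("add_ktb", 10), econ)
    assert large.investment_usd > small.investment_usd


def test_marketing_is_exact_share_of_revenue(econ):
    cf = build_cashflow(make_scenario("national_average"), econ)
    detail = cf.detail
    assert np.allclose(detail["cost_marketing"], econ.marketing_rate * detail["revenue_total"])


def test_propolis_quantity_constant_across_years(econ):
    cf = build_cashflow(make_scenario("add_langstroth", 20), econ)
    assert cf.detail["propolis_kg"].nunique() == 1


def test_monetary_homogeneity(econ):
    """Doubling every price and cost doubles investment and net flows."""
    spec = make_scenario("add_trees", 1000)
    base = build_cashflow(spec, econ)
    doubled_econ = dataclasses.replace(
        econ,
        **{
            name: 2 * getattr(econ, name)
            for name in (
                "price_honey", "price_beeswax", "price_propolis",
                "cost_log_hive", "cost_ktb_hive", "cost_langstroth_hive",
                "cost_smoker", "cost_bee_suit", "cost_gumboots", "cost_bucket",
                "cost_strainer_cloth", "labour_usd_per_day", "inspection_cost_usd",
                "lighting_baseline_usd", "lighting_improved_usd",
            )
        },
    )
    from apisim.forage import ForageParams

    doubled_forage = dataclasses.replace(
        ForageParams(),
        seedling_cost_usd=0.20, planting_cost_usd=0.06, weeding_cost_usd=0.06,
    )
    doubled = build_cashflow(spec, doubled_econ, doubled_forage)
    assert doubled.investment_usd == pytest.approx(2 * base.investment_usd)
    assert np.allclose(doubled.net_flow_usd, 2 * np.asarray(base.net_flow_usd))


def test_cashflow_reproducible(econ):
    spec = make_scenario("add_log", 15)
    a = build_cashflow(spec, econ)
    b = build_cashflow(spec, econ)
    assert a.investment_usd == b.investment_usd
    assert a.net_flow_usd == b.net_flow_usd


def test_tree_planting_exceeding_land_budget_rejected(econ):
    spec = dataclasses.replace(make_scenario("add_trees", 2000), land_budget_ha=0.1)
    with pytest.raises(ValueError, match="land budget"):
        build_cashflow(spec, econ)


def test_escalator_compounds_harvest_labour(econ):
    cf = build_cashflow(make_scenario("national_average"), econ)
    labour = cf.detail["cost_harvest_labour"].to_numpy()
    assert np.allclose(labour[1:] / labour[:-1], 1.10)
    baseline = build_cashflow(make_scenario("baseline"), econ)
    assert baseline.detail["cost_harvest_labour"].nunique() == 1
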