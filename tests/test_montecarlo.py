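"""Monte-Carlo NPV sampling, bounds construction and scenario ranking."""

import dataclasses
import math

import numpy as np
import pytest

from apisim import (
    BoundsConfig,
    NPVResult,
    build_cashflow,
    evaluate_scenarios,
    make_scenario,
    npv,
    npv_bounds,
    printed_scenarios,
    rank_scenarios,
    sample_npv,
    sample_npv_triangular,
    summarize,
)

ZERO_SPREAD = BoundsConfig(
    sd_price_honey=0.0, sd_price_beeswax=0.0, sd_price_propolis=0.0, honey_yield_cv=0.0
)


def _result(name, mean, invest=100.0, **kw):
    base = dict(
        name=name, investment_usd=invest, deterministic_npv=mean,
        npv_min=mean - 1, npv_max=mean + 1, mc_mean=mean, mc_se=0.1,
        n_iterations=10, seed=0,
    )
    base.update(kw)
    return NPVResult(**base)


# -- sampler -----------------------------------------------------------


def test_degenerate_interval_all_draws_equal():
    assert (sample_npv(5.0, 5.0, 100, seed=1) == 5.0).all()


def test_sampler_rejects_inverted_interval():
    with pytest.raises(ValueError):
        sample_npv(1.0, 0.0, 10, seed=1)


def test_sampler_deterministic_under_seed():
    a = sample_npv(-10.0, 50.0, 1000, seed=42)
    b = sample_npv(-10.0, 50.0, 1000, seed=42)
    assert (a == b).all()


def test_uniform_sample_mean_matches_closed_form():
    """Mean of n uniform(0,1) draws lies within 3·(1/√12)/√n of 1/2."""
    n = 100_000
    draws = sample_npv(0.0, 1.0, n, seed=3)
    assert ((draws >= 0) & (draws <= 1)).all()
    tol = 3 * (1 / math.sqrt(12)) / math.sqrt(n)
    assert abs(draws.mean() - 0.5) < tol


def test_triangular_sampler_respects_support_and_mode():
    draws = sample_npv_triangular(0.0, 2.0, 10.0, 50_000, seed=4)
    assert draws.min() >= 0 and draws.max() <= 10
    # triangular mean = (min + mode + max)/3
    assert draws.mean() == pytest.approx(4.0, abs=0.1)
    assert (sample_npv_triangular(3.0, 3.0, 3.0, 10, seed=1) == 3.0).all()


# -- summaries ---------------------------------------------------------


def test_summarize_constant_draws():
    mean, se = summarize([7.0] * 10)
    assert mean == 7.0 and se == 0.0


def test_summarize_hand_computed():
    mean, se = summarize([1.0, 3.0])
    assert mean == 2.0 and se == pytest.approx(1.0)


def test_summarize_uniform_se_closed_form():
    draws = sample_npv(0.0, 1.0, 10_000, seed=6)
    _, se = summarize(draws)
    assert se == pytest.approx((1 / math.sqrt(12)) / 100, rel=0.10)


def test_summarize_requires_two_draws():
    with pytest.raises(ValueError):
        summarize([1.0])


# -- bounds ------------------------------------------------------------


def test_zero_spread_bounds_collapse_to_deterministic(econ):
    spec = make_scenario("national_average")
    det = npv(build_cashflow(spec, econ), econ.discount_rate)
    lo, hi = npv_bounds(spec, econ, bounds_cfg=ZERO_SPREAD)
    assert lo == pytest.approx(det) and hi == pytest.approx(det)


def test_default_bounds_straddle_deterministic(econ):
    spec = make_scenario("add_langstroth", 20)
    det = npv(build_cashflow(spec, econ), econ.discount_rate)
    lo, hi = npv_bounds(spec, econ)
    assert lo < det < hi


def test_wider_price_spread_weakly_widens_interval(econ):
    spec = make_scenario("add_ktb", 10)
    narrow = npv_bounds(spec, econ, bounds_cfg=BoundsConfig(sd_price_honey=0.5))
    wide = npv_bounds(spec, econ, bounds_cfg=BoundsConfig(sd_price_honey=2.5))
    assert wide[0] <= narrow[0] and wide[1] >= narrow[1]


def test_explicit_bound_overrides(econ):
    spec = make_scenario("baseline")
    lo, hi = npv_bounds(spec, econ, bounds_cfg=BoundsConfig(npv_min=-5.0, npv_max=5.0))
    assert (lo, hi) == (-5.0, 5.0)
    with pytest.raises(ValueError):
        npv_bounds(spec, econ, bounds_cfg=BoundsConfig(npv_min=10.0, npv_max=-10.0))


# -- evaluation & ranking ----------------------------------------------


def test_single_result_rank_one():
    ranked = rank_scenarios([_result("only", 1.0)])
    assert ranked[0].rank == 1


def test_ranking_descending_by_mean():
    ranked = rank_scenarios([_result("a", 855.0), _result("b", 960.0), _result("c", -196.0)])
    assert [r.name for r in ranked] == ["b", "a", "c"]
    assert [r.rank for r in ranked] == [1, 2, 3]


def test_tie_breaks_on_lower_investment_then_name():
    ranked = rank_scenarios(
        [_result("x", 5.0, invest=100.0), _result("w", 5.0, invest=50.0)]
    )
    assert [r.name for r in ranked] == ["w", "x"]
    same = rank_scenarios([_result("b", 5.0), _result("a", 5.0)])
    assert [r.name for r in same] == ["a", "b"]


def test_ranking_invariant_to_input_order():
    results = [_result(n, m) for n, m in [("p", 3.0), ("q", 9.0), ("r", -1.0)]]
    fwd = rank_scenarios(results)
    rev = rank_scenarios(results[::-1])
    assert [(r.name, r.rank) for r in fwd] == [(r.name, r.rank) for r in rev]


def test_every_draw_in_bounds_and_mean_converges(econ):
    """Scenario evaluation: MC mean within 3 SE of the interval midpoint."""
    specs = [make_scenario("add_log", 20)]
    (res,) = evaluate_scenarios(specs, econ=econ, n_iterations=10_000, seed=1)
    assert res.npv_min <= res.mc_mean <= res.npv_max
    midpoint = (res.npv_min + res.npv_max) / 2
    assert abs(res.mc_mean - midpoint) < 3 * res.mc_se


def test_zero_width_bounds_make_mc_equal_deterministic(econ):
    results = evaluate_scenarios(
        printed_scenarios(), econ=econ, bounds_cfg=ZERO_SPREAD,
        n_iterations=100, seed=2,
    )
    for r in results:
        assert r.mc_mean == pytest.approx(r.deterministic_npv, abs=1e-9)
        assert r.mc_se == pytest.approx(0.0, abs=1e-9)
    ranked = rank_scenarios(results)
    by_det = sorted(results, key=lambda r: (-r.deterministic_npv, r.investment_usd, r.name))
    assert [r.name for r in ranked] == [r.name for r in by_det]


def test_adding_scenario_does_not_perturb_other_draws(econ):
    small = evaluate_scenarios(
        [make_scenario("baseline")], econ=econ, n_iterations=500, seed=9
    )
    larger = evaluate_scenarios(
        [make_scenario("baseline"), make_scenario("add_ktb", 5)],
        econ=econ, n_iterations=500, seed=9,
    )
    base_small = next(r for r in small if r.name == "baseline")
    base_larger = next(r for r in larger if r.name == "baseline")
    assert base_small.mc_mean == base_larger.mc_mean
    assert base_small.mc_se == base_larger.mc_se
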