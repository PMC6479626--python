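"""Municipal site ABM: payoff learning, event ledgers, conservation laws."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fsabm import BehaviourProbability, MunicipalConfig, adjust_probability, run_municipal
from fsabm.municipal import (
    CompanyState,
    FarmerState,
    GuardState,
    SiteState,
    company_disposal_event,
    compost_step,
    farmer_acquisition_event,
    renew_permit,
)


class ScriptedRng:
    """Deterministic stand-in for a Generator: returns queued uniforms."""

    def __init__(self, values):
        self.values = list(values)

    def random(self):
        return self.values.pop(0)


def make_guard(present=True, corrupt=False, p_enforce=0.5):
    g = GuardState(BehaviourProbability(p_enforce))
    g.present_today, g.corrupt_today = present, corrupt
    return g


class TestAdjustProbability:
    def test_worse_than_alternative_lowers_propensity(self):
        bp = adjust_probability(BehaviourProbability(0.5), 1000, 5000)
        assert bp.p == pytest.approx(0.496)

    def test_better_than_alternative_raises_propensity(self):
        bp = adjust_probability(BehaviourProbability(0.5), 5000, 1000)
        assert bp.p == pytest.approx(0.504)

    def test_tie_leaves_propensity_unchanged(self):
        assert adjust_probability(BehaviourProbability(0.2), 7, 7).p == 0.2

    @settings(max_examples=200, derandomize=True)
    @given(st.lists(st.tuples(st.floats(-1e9, 1e9), st.floats(-1e9, 1e9)), max_size=30),
           st.floats(0, 1))
    def test_clamped_to_unit_interval_for_any_payoff_stream(self, stream, p0):
        bp = BehaviourProbability(p0, multiplier=1e-3)
        for actual, potential in stream:
            bp = adjust_probability(bp, actual, potential)
            assert 0.0 <= bp.p <= 1.0


class TestCompanyEvent:
    def test_legal_visit_fee_goes_to_council_and_volume_booked(self):
        cfg = MunicipalConfig()
        c = CompanyState(BehaviourProbability(1.0))
        g, s = make_guard(present=True, corrupt=False), SiteState()
        # draws: action (legal), counterfactual catch (not caught)
        rec = company_disposal_event(c, g, s, cfg, ScriptedRng([0.0, 0.99]), tick=1)
        assert rec["action"] == "legal" and rec["payoff"] == -9000
        assert c.fees_paid == 9000 and s.council_cash == 9000
        assert s.legally_disposed == 3.0 and s.raw_volume == 3.0

    def test_corrupt_guard_takes_bribe_instead_of_fee(self):
        cfg = MunicipalConfig()
        c = CompanyState(BehaviourProbability(1.0))
        g, s = make_guard(present=True, corrupt=True), SiteState()
        company_disposal_event(c, g, s, cfg, ScriptedRng([0.0, 0.99]), tick=1)
        assert c.bribes_paid == 3000 and g.bribe_income == 3000
        assert s.council_cash == 0  # bribe never reaches the council

    def test_illegal_dump_uncaught_costs_nothing(self):
        cfg = MunicipalConfig()
        c = CompanyState(BehaviourProbability(0.0))
        g, s = make_guard(present=False), SiteState()
        rec = company_disposal_event(c, g, s, cfg, ScriptedRng([0.9, 0.99]), tick=1)
        assert rec["action"] == "illegal" and rec["payoff"] == 0
        assert s.illegally_dumped == 3.0 and c.total_outflow == 0

    def test_illegal_dump_caught_still_beats_paying_the_fee(self):
        # fine MK2000 < fee MK9000: being caught leaves illegal dumping the
        # better-paying action, so p_legal falls by 1e-6 * 7000
        cfg = MunicipalConfig()
        c = CompanyState(BehaviourProbability(0.5))
        g, s = make_guard(present=True, corrupt=False), SiteState()
        company_disposal_event(c, g, s, cfg, ScriptedRng([0.9, 0.05]), tick=1)
        assert c.fines_paid == 2000 and s.council_cash == 2000
        assert c.p_legal.p == pytest.approx(0.5 - 1e-6 * 7000)

    def test_valid_permit_makes_site_visit_free(self):
        cfg = MunicipalConfig(tariff_mode="monthly_permit")
        c = CompanyState(BehaviourProbability(1.0), permit_valid_until=40)
        g, s = make_guard(present=True, corrupt=False), SiteState()
        rec = company_disposal_event(c, g, s, cfg, ScriptedRng([0.0, 0.99]), tick=10)
        assert rec["payoff"] == 0 and c.fees_paid == 0
        assert s.legally_disposed == 3.0


class TestFarmerEvent:
    def test_theft_with_guard_absent_yields_one_bag(self):
        cfg = MunicipalConfig()
        f, g, s = FarmerState(BehaviourProbability(1.0)), make_guard(present=False), SiteState()
        s.receive_load(0, 3.0)
        rec = farmer_acquisition_event(f, g, s, cfg, ScriptedRng([0.0]), tick=1)
        assert rec["payoff"] == 5000
        assert s.stolen == pytest.approx(0.05)
        assert s.raw_volume == pytest.approx(2.95)

    def test_theft_caught_by_enforcing_guard_is_fined(self):
        cfg = MunicipalConfig()
        f, g, s = FarmerState(BehaviourProbability(1.0)), make_guard(corrupt=False), SiteState()
        s.receive_load(0, 3.0)
        rec = farmer_acquisition_event(f, g, s, cfg, ScriptedRng([0.0]), tick=1)
        assert rec["payoff"] == -20_000
        assert f.fines_paid == 20_000 and s.council_cash == 20_000
        assert s.stolen == 0.0

    def test_fence_blocks_removal_but_corrupt_guard_keeps_bribe(self):
        cfg = MunicipalConfig(refurbished=True, p_guard_present=1.0)
        f, g, s = FarmerState(BehaviourProbability(1.0)), make_guard(corrupt=True), SiteState()
        s.receive_load(0, 3.0)
        rec = farmer_acquisition_event(f, g, s, cfg, ScriptedRng([0.0]), tick=1)
        assert s.stolen == 0.0
        assert g.bribe_income == 3000 and rec["payoff"] == -3000

    def test_purchase_transfers_bag_and_credits_council(self):
        cfg = MunicipalConfig()
        f, g, s = FarmerState(BehaviourProbability(0.0)), make_guard(present=False), SiteState()
        s.compost_bags = 2
        rec = farmer_acquisition_event(f, g, s, cfg, ScriptedRng([0.99]), tick=1)
        assert rec["action"] == "buy"
        assert s.compost_bags == 1 and s.council_cash == 5000
        assert f.purchases_paid == 5000 and f.value_gained == 5000


class TestCompostAndPermits:
    def test_load_matures_into_bags_after_six_months(self):
        cfg = MunicipalConfig()
        s = SiteState()
        s.receive_load(0, 3.0)
        compost_step(s, 179, cfg)
        assert s.compost_bags == 0
        compost_step(s, 180, cfg)
        # 3 m3 * 0.5 yield / 0.05 m3 per bag = 30 bags, sold at the boundary
        assert s.bags_sold_bulk == 30
        assert s.council_cash == 30 * 5000
        assert s.raw_volume == 0.0

    def test_no_arrivals_no_sales_at_any_boundary(self):
        cfg = MunicipalConfig()
        s = SiteState()
        for t in range(0, 1081, 180):
            compost_step(s, t, cfg)
        assert s.council_cash == 0 and s.bags_sold_bulk == 0

    def test_monthly_permit_renewal_charges_each_company(self):
        cfg = MunicipalConfig(tariff_mode="monthly_permit", permit_fee=70_000)
        s = SiteState()
        companies = [CompanyState(BehaviourProbability(0.5)) for _ in range(5)]
        for c in companies:
            renew_permit(c, s, tick=30, cfg=cfg)
        assert s.council_cash == 350_000
        assert all(c.permit_valid(40) for c in companies)

    def test_per_visit_mode_renewal_is_noop(self):
        cfg = MunicipalConfig(tariff_mode="per_visit")
        s, c = SiteState(), CompanyState(BehaviourProbability(0.5))
        renew_permit(c, s, tick=30, cfg=cfg)
        assert s.council_cash == 0 and c.permit_valid_until is None


class TestRunMunicipal:
    def test_empty_system_stays_flat(self):
        cfg = MunicipalConfig(p_company_job=0.0, p_farmer_attempt=0.0, n_ticks=400)
        res = run_municipal(cfg, seed=0)
        assert (res.series[["legal_m3", "illegal_m3", "stolen_m3", "council_cash"]] == 0).all().all()

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_money_and_volume_conservation_exact(self, seed):
        res = run_municipal(MunicipalConfig(n_ticks=1000), seed=seed)
        assert abs(res.money_conservation_residual()) < 1e-6
        assert abs(res.site.volume_closure_residual()) < 1e-9

    def test_refurbished_site_never_loses_sludge_to_theft(self):
        cfg = MunicipalConfig(refurbished=True, p_guard_present=1.0, n_ticks=1000)
        for seed in range(5):
            res = run_municipal(cfg, seed=seed)
            assert res.final["stolen_m3"] == 0.0

    def test_propensities_remain_probabilities(self):
        res = run_municipal(MunicipalConfig(n_ticks=1500), seed=3)
        for c in res.companies:
            assert 0.0 <= c.p_legal.p <= 1.0
        for f in res.farmers:
            assert 0.0 <= f.p_steal.p <= 1.0
        assert 0.0 <= res.guard.p_enforce.p <= 1.0

    def test_frozen_propensities_match_closed_form_expectation(self):
        # multiplier = 0: p_legal fixed at 0.01, so
        # E[illegal m3] = n_ticks * n_companies * p_job * (1 - p_legal) * load
        cfg = MunicipalConfig(multiplier=0.0, n_ticks=2000)
        repeats = 30
        finals = [run_municipal(cfg, seed=s).final["illegal_m3"] for s in range(repeats)]
        q = cfg.p_company_job * (1 - cfg.p_company_legal_init)
        expected = cfg.n_ticks * cfg.n_companies * q * cfg.load_volume
        var_one = cfg.n_ticks * cfg.n_companies * q * (1 - q) * cfg.load_volume**2
        se = math.sqrt(var_one / repeats)
        assert abs(np.mean(finals) - expected) < 3 * se

    def test_deterministic_under_fixed_seed(self):
        a = run_municipal(MunicipalConfig(n_ticks=300), seed=7)
        b = run_municipal(MunicipalConfig(n_ticks=300), seed=7)
        assert a.series.equals(b.series)
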