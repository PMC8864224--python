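"""Cohort trace: occupancy, discounting, cost accrual, discretization."""

import math
from dataclasses import replace

import numpy as np
import pytest
from scipy import integrate

from psmcea.survival import ParametricSurvival, apply_hazard_ratio
from psmcea.trace import (
    AdverseEvent,
    AEProfile,
    ArmSpec,
    ModelConfig,
    arm_totals,
    build_trace,
    occupancy,
)

MONTHS_PER_YEAR = 12.0


def _bare_arm(pfs, os_, **kw):
    defaults = dict(
        name="arm",
        pfs_curve=pfs,
        os_curve=os_,
        drug_cost_per_cycle=0.0,
        test_cost_per_cycle=0.0,
        u_pfd=1.0,
        u_pd=1.0,
        test_cost_in_pd=False,
    )
    defaults.update(kw)
    return ArmSpec(**defaults)


class TestOccupancy:
    def test_everyone_progression_free_at_entry(self, pfs_model, os_model):
        arm = _bare_arm(pfs_model, os_model)
        assert occupancy(arm, 0.0) == (1.0, 0.0, 0.0)

    def test_identical_curves_leave_pd_empty(self, os_model):
        arm = _bare_arm(os_model, os_model)
        _, p_pd, _ = occupancy(arm, 14.0)
        assert p_pd == 0.0

    def test_half_cohort_dead_at_os_median(self, pfs_model, os_model):
        arm = _bare_arm(pfs_model, os_model)
        _, _, p_death = occupancy(arm, os_model.median())
        assert p_death == pytest.approx(0.5, abs=1e-9)

    def test_clipping_when_pfs_crosses_os(self, os_model):
        """A nominally higher PFS curve is clipped so PD occupancy stays >= 0."""
        higher = apply_hazard_ratio(os_model, 0.5)
        arm = _bare_arm(higher, os_model)
        p_pfd, p_pd, p_death = occupancy(arm, 12.0)
        assert p_pd == 0.0
        assert p_pfd + p_pd + p_death == pytest.approx(1.0, abs=1e-15)


class TestConservationAndShape:
    def test_cohort_conserved_every_cycle(self, ce_model):
        for trace in ce_model.traces().values():
            t = trace.table
            balance = (t["p_pfd"] + t["p_pd"] + t["p_death"] - 1.0).abs()
            assert balance.max() <= 1e-12
            assert t["p_death"].is_monotonic_increasing
            for col in ("p_pfd", "p_pd", "p_death"):
                assert t[col].between(0, 1).all()

    def test_qaly_never_exceeds_ly(self, ce_model):
        for trace in ce_model.traces().values():
            _, ly, qaly = trace.totals()
            assert qaly <= ly

    def test_horizon_shorter_than_cycle_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(horizon_years=0.01)


class TestAccumulation:
    def test_degenerate_config_ly_equals_qaly_equals_auc(self, pfs_model, os_model):
        """Zero costs, unit utilities, no discounting: LY = QALY = area under OS."""
        cfg = ModelConfig(horizon_years=10, annual_discount=0.0)
        arm = _bare_arm(pfs_model, os_model)
        cost, ly, qaly = arm_totals(build_trace(arm, cfg))
        assert cost == 0.0
        assert qaly == pytest.approx(ly, rel=1e-12)
        auc, _ = integrate.quad(os_model.sf, 0, cfg.n_cycles * cfg.cycle_months, limit=200)
        assert ly == pytest.approx(auc / MONTHS_PER_YEAR, rel=2e-3)

    def test_sorafenib_restricted_mean_os_ten_years(self, pfs_model, os_model):
        """Undiscounted 10-year mean OS of the reference arm matches the
        log-logistic closed form: full mean (1/lam)^(1/gamma)*(pi/gamma)/
        sin(pi/gamma) ~ 20.5 months minus the ~2.8-month tail beyond the
        horizon; numerical integration is the exact oracle."""
        cfg = ModelConfig(horizon_years=10, annual_discount=0.0)
        arm = _bare_arm(pfs_model, os_model)
        _, ly, _ = arm_totals(build_trace(arm, cfg))
        horizon_m = cfg.n_cycles * cfg.cycle_months
        oracle, _ = integrate.quad(os_model.sf, 0, horizon_m, limit=200)
        lam, gam = 0.01822555, 1.694566
        full_mean = (1 / lam) ** (1 / gam) * (math.pi / gam) / math.sin(math.pi / gam)
        tail = horizon_m ** (1 - gam) / (lam * (gam - 1))  # leading-order tail
        assert full_mean == pytest.approx(20.51, abs=0.01)
        assert oracle == pytest.approx(full_mean - tail, abs=0.05)
        assert ly * MONTHS_PER_YEAR == pytest.approx(oracle, rel=5e-3)

    def test_discounting_strictly_shrinks_totals(self, pfs_model, os_model):
        arm = _bare_arm(pfs_model, os_model, drug_cost_per_cycle=100.0)
        undisc = arm_totals(build_trace(arm, ModelConfig(annual_discount=0.0)))
        disc = arm_totals(build_trace(arm, ModelConfig(annual_discount=0.03)))
        assert all(d < u for d, u in zip(disc, undisc))

    def test_exponential_totals_match_closed_form(self):
        """With exponential curves the discounted person-time integrals have
        closed forms; the 21-day discretization agrees to 0.5%."""
        a, b = 0.20, 0.08  # PFS and OS rates per month
        disc_m = math.log(1.03) / 12.0  # continuous-time discount per month
        cfg = ModelConfig(horizon_years=60, annual_discount=0.03)
        arm = _bare_arm(
            ParametricSurvival("exponential", (a,)),
            ParametricSurvival("exponential", (b,)),
            u_pfd=0.76,
            u_pd=0.68,
        )
        _, ly, qaly = arm_totals(build_trace(arm, cfg))
        ly_closed = (1.0 / (b + disc_m)) / MONTHS_PER_YEAR
        pfd_closed = (1.0 / (a + disc_m)) / MONTHS_PER_YEAR
        qaly_closed = 0.76 * pfd_closed + 0.68 * (ly_closed - pfd_closed)
        assert ly == pytest.approx(ly_closed, rel=5e-3)
        assert qaly == pytest.approx(qaly_closed, rel=5e-3)

    def test_halving_cycle_length_stable_within_one_percent(self, ce_model):
        """Discretization check with half-cycle correction on."""
        arm = ce_model.arm_spec("combination")
        base = arm_totals(build_trace(arm, ce_model.model_config))
        fine_cfg = ModelConfig(
            cycle_days=10.5,
            horizon_years=ce_model.model_config.horizon_years,
        )
        # per-cycle costs, the cap and the second-line window must all track
        # the shorter cycle
        coarse_arm = ce_model.arm_spec("combination")
        fine_arm = replace(
            coarse_arm,
            drug_cost_per_cycle=coarse_arm.drug_cost_per_cycle / 2,
            test_cost_per_cycle=coarse_arm.test_cost_per_cycle / 2,
            subsequent_drug_cost_per_cycle=coarse_arm.subsequent_drug_cost_per_cycle / 2,
            bsc_cost_per_cycle=coarse_arm.bsc_cost_per_cycle / 2,
            max_treatment_cycles=fine_cfg.months_to_cycles(24),
            subsequent_max_cycles=12,
        )
        fine = arm_totals(build_trace(fine_arm, fine_cfg))
        for coarse_v, fine_v in zip(base, fine):
            assert fine_v == pytest.approx(coarse_v, rel=0.01)


class TestCostAccrual:
    def test_cost_scaling_leaves_outcomes_untouched(self, ce_model):
        base = ce_model.evaluate()
        scaled = ce_model.evaluate(
            {"cost_sorafenib": 1580.0, "cost_sintilimab": 1608.0, "cost_bsc": 714.0}
        )
        assert scaled.incremental_ly == pytest.approx(base.incremental_ly, rel=1e-12)
        assert scaled.incremental_qaly == pytest.approx(base.incremental_qaly, rel=1e-12)
        assert scaled.incremental_cost != base.incremental_cost

    def test_ae_burden_enters_once_at_entry(self, pfs_model, os_model):
        profile = AEProfile(
            (AdverseEvent("hypertension", 0.06, 1000.0, 0.16, duration_cycles=1),)
        )
        cfg = ModelConfig(horizon_years=5)
        plain = _bare_arm(pfs_model, os_model, u_pfd=0.76, u_pd=0.68)
        with_ae = _bare_arm(pfs_model, os_model, u_pfd=0.76, u_pd=0.68, ae_profile=profile)
        c0, _, q0 = arm_totals(build_trace(plain, cfg))
        c1, _, q1 = arm_totals(build_trace(with_ae, cfg))
        assert c1 - c0 == pytest.approx(0.06 * 1000.0, rel=1e-12)
        assert q0 - q1 == pytest.approx(0.06 * 0.16 * cfg.cycle_years, rel=1e-12)

    def test_treatment_cap_stops_drug_costs(self, pfs_model, os_model):
        cfg = ModelConfig(horizon_years=5)
        capped = _bare_arm(
            pfs_model, os_model, drug_cost_per_cycle=100.0, max_treatment_cycles=0
        )
        uncapped = _bare_arm(pfs_model, os_model, drug_cost_per_cycle=100.0)
        assert arm_totals(build_trace(capped, cfg))[0] == 0.0
        assert arm_totals(build_trace(uncapped, cfg))[0] > 0.0

    def test_subsequent_therapy_window_bounds_cost(self, pfs_model, os_model):
        """Second-line cost grows with the allowed duration and never exceeds
        charging the whole PD occupancy."""
        cfg = ModelConfig(horizon_years=10)
        costs = []
        for m in (0, 3, 6, 10_000):
            arm = _bare_arm(
                pfs_model,
                os_model,
                subsequent_proportion=1.0,
                subsequent_drug_cost_per_cycle=100.0,
                subsequent_max_cycles=m,
            )
            costs.append(arm_totals(build_trace(arm, cfg))[0])
        assert costs[0] == 0.0
        assert costs[0] < costs[1] < costs[2] <= costs[3]
        # unlimited window equals charging all PD person-time
        pd_arm = _bare_arm(
            pfs_model, os_model, subsequent_proportion=0.0, bsc_cost_per_cycle=100.0
        )
        all_pd_cost = arm_totals(build_trace(pd_arm, cfg))[0]
        assert costs[3] == pytest.approx(all_pd_cost, rel=1e-9)
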