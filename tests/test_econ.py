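"""Dosing, vial pricing, accrual arithmetic and CEA summary statistics."""

import copy

import numpy as np
import pandas as pd
import pytest

from seqcea.econ import (DoseSchedule, EconParams, StrategySpec, TreatmentLine, accrue,
                         ae_burden, build_strategy, calvert_dose, cea_table,
                         cycle_drug_cost, dose_cost, expected_outcomes, icer_matrix,
                         vial_cost)


class TestDosing:
    def test_calvert_example(self):
        assert calvert_dose(5.0, 70.0) == pytest.approx(475.0)

    def test_calvert_zero_auc(self):
        assert calvert_dose(0.0, 70.0) == 0.0

    def test_calvert_monotone(self):
        assert calvert_dose(6, 70) > calvert_dose(5, 70) > calvert_dose(5, 60)

    def test_docetaxel_vial_arithmetic(self, econ):
        # 75 mg/m2 x 1.72 m2 = 129 mg -> seven 20 mg vials
        cost = vial_cost(75 * 1.72, econ.drug_prices["docetaxel"])
        assert cost == pytest.approx(7 * 3.55)

    def test_camrelizumab_single_vial(self, econ):
        assert vial_cost(200, econ.drug_prices["camrelizumab"]) == pytest.approx(460.31)

    def test_vial_combination_minimizes_cost(self):
        vials = [(100.0, 10.0), (30.0, 4.0)]
        # 110 mg: 100+30 (14) beats 2x100 (20) and 4x30 (16)
        assert vial_cost(110, vials) == pytest.approx(14.0)

    def test_uncoverable_dose_raises(self):
        with pytest.raises(ValueError):
            vial_cost(10, [])

    def test_market_share_weighting(self, econ):
        carbo = dose_cost({"drug": "carboplatin", "auc": 5, "share": "carboplatin"}, econ)
        cis = dose_cost({"drug": "cisplatin", "per_m2": 75,
                         "share_complement": "carboplatin"}, econ)
        full_carbo = vial_cost(calvert_dose(5, econ.crcl), econ.drug_prices["carboplatin"])
        full_cis = vial_cost(75 * econ.bsa, econ.drug_prices["cisplatin"])
        assert carbo == pytest.approx(0.74 * full_carbo)
        assert cis == pytest.approx(0.26 * full_cis)


class TestAEBurden:
    def test_empty_profile(self):
        line = TreatmentLine("none", False, [], [])
        assert ae_burden(line) == (0.0, 0.0)

    def test_single_event_arithmetic(self):
        line = TreatmentLine("x", False, [], [("ae", 0.5, 100.0, 0.2, 36.525)])
        cost, qloss = ae_burden(line)
        assert cost == pytest.approx(50.0)
        assert qloss == pytest.approx(0.01)

    def test_docetaxel_line_hand_sum(self, econ):
        spec = build_strategy("CD", econ)
        cost, qloss = ae_burden(spec.second)
        expect_cost = 0.590 * 116.37 + 0.342 * 116.37 + 0.051 * 107.0
        expect_loss = (0.590 * 0.2 * 6.4 + 0.342 * 0.2 * 4.5 + 0.051 * 0.07 * 7.0) / 365.25
        assert cost == pytest.approx(expect_cost, abs=1e-9)
        assert qloss == pytest.approx(expect_loss, abs=1e-9)


class TestCycleDrugCost:
    def test_camrelizumab_cycle_cost(self, econ):
        spec = build_strategy("CAD", econ)
        c0 = cycle_drug_cost(spec.first, econ, 0)
        assert c0 > 460.0   # camrelizumab vial + backbone
        # beyond the 35-dose immunotherapy cap and 6-cycle chemo cap: zero
        assert cycle_drug_cost(spec.first, econ, 40) == 0.0

    def test_chemo_stops_at_cap(self, econ):
        spec = build_strategy("CD", econ)
        assert cycle_drug_cost(spec.first, econ, 5) > 0
        assert cycle_drug_cost(spec.first, econ, 6) == 0.0

    def test_nivolumab_q2w_pattern(self, econ):
        spec = build_strategy("CN", econ)
        per_dose = vial_cost(3 * econ.weight, econ.drug_prices["nivolumab"])
        c0 = cycle_drug_cost(spec.second, econ, 0)
        c1 = cycle_drug_cost(spec.second, econ, 1)
        # 21-day cycles over a 14-day schedule: alternating 2 and 1 doses
        assert {round(c0 / per_dose), round(c1 / per_dose)} == {1, 2}


def _bare_strategy(econ, u_first_immuno=False):
    """Strategy with no drugs, no monitoring-relevant doses and no AEs."""
    first = TreatmentLine("bare1", u_first_immuno, [], [])
    second = TreatmentLine("bare2", False, [], [])
    first.schedule = DoseSchedule(np.array([]), np.array([]))
    second.schedule = DoseSchedule(np.array([]), np.array([]))
    return StrategySpec("BARE", first, second)


class TestAccrue:
    def test_undiscounted_pfs_year(self, econ):
        e = copy.deepcopy(econ)
        e.discount_rate = 0.0
        e.monitoring_per_cycle = 0.0
        e.imaging_per_event = 0.0
        spec = _bare_strategy(e)
        cost, qaly, ly = accrue(1.0, 0.0, 0.0, spec, e)
        assert qaly == pytest.approx(0.70, abs=1e-12)
        assert ly == pytest.approx(1.0)

    def test_immediate_death_costs_end_of_life_only(self, econ):
        e = copy.deepcopy(econ)
        e.monitoring_per_cycle = 0.0
        e.imaging_per_event = 0.0
        spec = _bare_strategy(e)
        cost, qaly, ly = accrue(0.0, 0.0, 0.0, spec, e)
        assert cost == pytest.approx(2325.75)
        assert qaly == pytest.approx(0.0, abs=1e-12)

    def test_cost_linearity(self, econ, curves, strategy_map):
        spec = build_strategy("CAD", econ)
        c1, _, _ = accrue(0.8, 0.2, 0.7, spec, econ)
        e2 = copy.deepcopy(econ)
        e2.drug_prices = {d: [(mg, 2 * p) for mg, p in v]
                          for d, v in e2.drug_prices.items()}
        e2.bsc_per_cycle *= 2
        e2.end_of_life *= 2
        e2.monitoring_per_cycle *= 2
        e2.imaging_per_event *= 2
        e2.ae_costs = {k: 2 * v for k, v in e2.ae_costs.items()}
        spec2 = build_strategy("CAD", e2)
        c2, _, _ = accrue(0.8, 0.2, 0.7, spec2, e2)
        assert c2 == pytest.approx(2 * c1, rel=1e-12)

    def test_qaly_bounded_by_ly(self, econ):
        spec = build_strategy("CD", econ)
        rng = np.random.default_rng(0)
        for _ in range(20):
            t1, p2, o2 = rng.uniform(0, 3), rng.uniform(0, 1), rng.uniform(1, 2)
            _, q, l = accrue(t1, min(p2, o2), o2, spec, econ)
            assert q <= l + 1e-9

    def test_unit_utilities_no_discount_gives_ly(self, econ):
        e = copy.deepcopy(econ)
        e.discount_rate = 0.0
        e.u_pfs_immuno = e.u_pfs_chemo = e.u_pd1 = e.u_pd_end = 1.0
        spec = _bare_strategy(e)
        _, q, l = accrue(1.3, 0.4, 0.9, spec, e)
        assert q == pytest.approx(l, abs=1e-12)

    def test_horizon_truncation(self, econ):
        e = copy.deepcopy(econ)
        e.monitoring_per_cycle = 0.0
        e.imaging_per_event = 0.0
        spec = _bare_strategy(e)
        cost, qaly, ly = accrue(25.0, 0.0, 0.0, spec, e)
        assert ly == pytest.approx(e.horizon)
        # never progressed: no end-of-life cost, no PD accrual, no drugs
        assert cost == pytest.approx(ae_burden(spec.first)[0])


class TestCEATable:
    def test_printed_table_inputs(self):
        # published cost/QALY pairs: ICER and NMB arithmetic reproduced
        res = pd.DataFrame({"cost": [18131.0, 19026.0], "qaly": [1.283, 1.603]},
                           index=["CT", "CAD"])
        M = icer_matrix(res)
        assert M.loc["CAD", "CT"] == pytest.approx(2797, abs=1.0)
        tab = cea_table(res, wtp=19091.0)
        assert tab.loc["CAD", "nmb"] == pytest.approx(19091 * 1.603 - 19026, abs=0.5)
        assert tab.loc["CAD", "nmb"] == pytest.approx(11577, abs=25)

    def test_strict_dominance(self):
        res = pd.DataFrame({"cost": [10.0, 20.0], "qaly": [1.0, 0.9]},
                           index=["A", "B"])
        tab = cea_table(res, wtp=100.0)
        assert tab.loc["B", "dominated"]
        assert not tab.loc["A", "dominated"]
        assert icer_matrix(res).loc["B", "A"] == np.inf

    def test_zero_qaly_difference_flagged(self):
        res = pd.DataFrame({"cost": [10.0, 20.0], "qaly": [1.0, 1.0]},
                           index=["A", "B"])
        assert np.isnan(icer_matrix(res).loc["B", "A"])

    def test_frontier_mutually_nondominated(self):
        res = pd.DataFrame(
            {"cost": [0.0, 10.0, 12.0, 30.0], "qaly": [0.0, 1.0, 1.05, 1.5]},
            index=["A", "B", "C", "D"])
        tab = cea_table(res, wtp=50.0)
        front = tab[tab["on_frontier"]]
        for a in front.index:
            for b in front.index:
                if a != b:
                    assert not (front.loc[b, "cost"] <= front.loc[a, "cost"] and
                                front.loc[b, "qaly"] >= front.loc[a, "qaly"] and
                                (front.loc[b, "cost"] < front.loc[a, "cost"] or
                                 front.loc[b, "qaly"] > front.loc[a, "qaly"]))
        off = tab[~tab["on_frontier"]]
        assert all(off["dominated"] | off["extendedly_dominated"])

    def test_needs_two_strategies(self):
        res = pd.DataFrame({"cost": [1.0], "qaly": [1.0]}, index=["A"])
        with pytest.raises(ValueError):
            cea_table(res, wtp=1.0)


class TestImmunotherapyRule:
    def test_double_immunotherapy_rejected(self, econ):
        first = TreatmentLine("a", True, [], [])
        second = TreatmentLine("b", True, [], [])
        first.schedule = DoseSchedule(np.array([]), np.array([]))
        second.schedule = DoseSchedule(np.array([]), np.array([]))
        with pytest.raises(ValueError, match="immunotherapy"):
            StrategySpec("XX", first, second)

    def test_unknown_strategy_rejected(self, econ):
        with pytest.raises(ValueError, match="CAD"):
            build_strategy("ZZZ", econ)
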