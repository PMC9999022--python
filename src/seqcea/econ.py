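"""Costing, utilities and cost-effectiveness summary statistics.

Converts patient trajectories (or survivor curves directly, via the
deterministic cohort evaluator) into discounted costs and QALYs:

* drug acquisition with body-surface-area / Calvert / per-kg dosing and
  full-vial wastage at the cheapest covering vial combination,
* market-share-weighted chemotherapy backbones,
* follow-up/monitoring while on active treatment,
* one-off adverse-event costs and QALY losses at each line start,
* best-supportive-care cost per cycle in end-stage progression and an
  end-of-life cost at death,
* ICER / NMB / INMB, dominance and the efficiency frontier.

All money is 2022 USD; discounting is continuous-time at an annual rate
applied as (1+r)^-t.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd

from .curves import CYCLE_YEARS, HORIZON_YEARS, SurvivalCurve
from .params import load_regimens, load_strategies, load_tariff


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

@dataclass
class EconParams:
    """Scalar economic parameters resolved from the parameter table."""

    discount_rate: float
    u_pfs_immuno: float
    u_pfs_chemo: float
    u_pd1: float
    u_pd_end: float
    bsc_per_cycle: float
    end_of_life: float
    monitoring_per_cycle: float
    imaging_per_event: float
    imaging_every_n_cycles: int
    bsa: float
    crcl: float
    weight: float
    wtp: float
    wtp_second_line: float
    cycle_years: float = CYCLE_YEARS
    horizon: float = HORIZON_YEARS
    drug_prices: dict = field(default_factory=dict)
    market_shares: dict = field(default_factory=dict)
    ae_costs: dict = field(default_factory=dict)
    ae_disutilities: dict = field(default_factory=dict)
    ae_durations: dict = field(default_factory=dict)
    ae_rates: dict = field(default_factory=dict)
    price_multipliers: dict = field(default_factory=dict)

    @classmethod
    def from_table(cls, tariff: dict | None = None, regimens: dict | None = None) -> "EconParams":
        t1 = tariff or load_tariff()
        reg = regimens or load_regimens()
        costs = t1["costs"]
        mon = reg["monitoring"]
        per_cycle = sum(costs[i]["mean"] for i in mon["per_cycle"])
        imaging = sum(costs[i]["mean"] for i in mon["every_two_cycles"])
        u = t1["utilities"]
        return cls(
            discount_rate=t1["discount_rate"]["mean"],
            u_pfs_immuno=u["pfs_immunotherapy"]["mean"],
            u_pfs_chemo=u["pfs_chemotherapy"]["mean"],
            u_pd1=u["pd"]["mean"],
            u_pd_end=u["pd"]["mean"],
            bsc_per_cycle=costs["bsc_per_cycle"]["mean"],
            end_of_life=costs["end_of_life"]["mean"],
            monitoring_per_cycle=per_cycle,
            imaging_per_event=imaging,
            imaging_every_n_cycles=2,
            bsa=t1["population"]["bsa_m2"],
            crcl=t1["population"]["crcl_ml_min"],
            weight=t1["population"]["weight_kg"],
            wtp=t1["wtp"]["base"],
            wtp_second_line=t1["wtp"]["second_line"],
            horizon=t1["model"]["horizon_years"],
            cycle_years=t1["model"]["cycle_days"] / 365.25,
            drug_prices={d: [(v["mg"], v["price"]) for v in vials]
                         for d, vials in t1["drug_prices"].items()},
            market_shares={k: v["mean"] for k, v in t1["market_shares"].items()},
            ae_costs={k: v["mean"] for k, v in t1["adverse_events"]["costs"].items()},
            ae_disutilities={k: v["mean"]
                             for k, v in t1["adverse_events"]["disutilities"].items()},
            ae_durations=dict(t1["adverse_events"]["durations_days"]),
            ae_rates={reg_name: {ev: v["mean"] for ev, v in evs.items()}
                      for reg_name, evs in t1["adverse_events"]["rates"].items()},
        )

    def pfs_utility(self, immunotherapy: bool) -> float:
        return self.u_pfs_immuno if immunotherapy else self.u_pfs_chemo


# ---------------------------------------------------------------------------
# dosing and vial pricing
# ---------------------------------------------------------------------------

def calvert_dose(target_auc: float, crcl: float) -> float:
    """Carboplatin dose (mg) = AUC x (CrCl + 25)."""
    if target_auc < 0 or crcl < 0:
        raise ValueError("AUC and CrCl must be non-negative")
    return target_auc * (crcl + 25.0)


def vial_cost(dose_mg: float, vials: list[tuple[float, float]],
              multiplier: float = 1.0) -> float:
    """Cheapest full-vial combination covering ``dose_mg`` (no sharing).

    Exhaustive search over vial counts; with the small vial menus in the
    tariff this is instantaneous.
    """
    if dose_mg <= 0:
        return 0.0
    vials = sorted(vials, reverse=True)
    best = [np.inf]

    def rec(i: int, remaining: float, cost: float) -> None:
        if cost >= best[0]:
            return
        if remaining <= 0:
            best[0] = cost
            return
        if i == len(vials):
            return
        mg, price = vials[i]
        max_n = int(np.ceil(remaining / mg))
        for n in range(max_n, -1, -1):
            rec(i + 1, remaining - n * mg, cost + n * price)

    rec(0, dose_mg, 0.0)
    if not np.isfinite(best[0]):
        raise ValueError(f"no vial combination covers a {dose_mg} mg dose")
    return float(best[0] * multiplier)


def resolve_dose_mg(drug_cfg: dict, econ: EconParams) -> float:
    if "fixed_mg" in drug_cfg:
        return float(drug_cfg["fixed_mg"])
    if "per_m2" in drug_cfg:
        return float(drug_cfg["per_m2"]) * econ.bsa
    if "per_kg" in drug_cfg:
        return float(drug_cfg["per_kg"]) * econ.weight
    if "auc" in drug_cfg:
        return calvert_dose(float(drug_cfg["auc"]), econ.crcl)
    raise ValueError(f"drug entry without a dose rule: {drug_cfg}")


def dose_cost(drug_cfg: dict, econ: EconParams) -> float:
    """Share-weighted cost of one administration of a configured drug."""
    drug = drug_cfg["drug"]
    mg = resolve_dose_mg(drug_cfg, econ)
    mult = econ.price_multipliers.get(drug, 1.0)
    c = vial_cost(mg, econ.drug_prices[drug], mult)
    if "share" in drug_cfg:
        c *= econ.market_shares[drug_cfg["share"]]
    elif "share_complement" in drug_cfg:
        c *= 1.0 - econ.market_shares[drug_cfg["share_complement"]]
    return c


# ---------------------------------------------------------------------------
# treatment lines and strategies
# ---------------------------------------------------------------------------

@dataclass
class DoseSchedule:
    """Sorted administration offsets (years from line start) and costs."""

    times: np.ndarray
    costs: np.ndarray

    def cumulative_discounted(self, rate: float) -> np.ndarray:
        """cum[k] = discounted cost of the first k administrations."""
        df = (1.0 + rate) ** (-self.times)
        return np.concatenate([[0.0], np.cumsum(self.costs * df)])


@dataclass
class TreatmentLine:
    """One active treatment line: drugs, schedule and AE profile."""

    name: str
    immunotherapy: bool
    drug_cfgs: list[dict]
    ae_profile: list[tuple[str, float, float, float, float]]  # event, rate, cost, disutil, days
    schedule: DoseSchedule = None

    def build_schedule(self, econ: EconParams) -> None:
        times, costs = [], []
        for cfg in self.drug_cfgs:
            c = dose_cost(cfg, econ)
            interval = float(cfg.get("interval_days", 21)) / 365.25
            max_doses = cfg.get("max_doses")
            n = int(max_doses) if max_doses else int(np.ceil(econ.horizon / interval))
            per_cycle = int(cfg.get("doses_per_cycle", 1))
            for k in range(n):
                base = k * interval
                for j in range(per_cycle):
                    times.append(base + j * (7.0 / 365.25))
                    costs.append(c)
        order = np.argsort(times, kind="stable")
        self.schedule = DoseSchedule(np.asarray(times)[order], np.asarray(costs)[order])


def ae_burden(line: TreatmentLine) -> tuple[float, float]:
    """One-off (cost, QALY loss) applied at line start.

    cost = sum rate*cost_ae; QALY loss = sum rate*disutility*duration/365.25.
    """
    cost = sum(r * c for _, r, c, _, _ in line.ae_profile)
    qloss = sum(r * d * days / 365.25 for _, r, _, d, days in line.ae_profile)
    return cost, qloss


@dataclass
class StrategySpec:
    """An ordered pair of active treatment lines followed by BSC."""

    id: str
    first: TreatmentLine
    second: TreatmentLine

    def __post_init__(self) -> None:
        if self.first.immunotherapy and self.second.immunotherapy:
            raise ValueError(f"{self.id}: immunotherapy in both lines is not allowed")


def build_strategy(strategy_id: str, econ: EconParams, tariff: dict | None = None,
                   regimens: dict | None = None) -> StrategySpec:
    t1 = tariff or load_tariff()
    reg = regimens or load_regimens()
    strategies = load_strategies()
    if strategy_id not in strategies:
        raise ValueError(f"unknown strategy '{strategy_id}'; valid: {sorted(strategies)}")
    s = strategies[strategy_id]

    def make_line(line_key: str, name: str) -> TreatmentLine:
        cfg = reg[line_key][name]
        rates = econ.ae_rates.get(name, {})
        profile = [(ev, rate, econ.ae_costs[ev], econ.ae_disutilities[ev],
                    econ.ae_durations[ev]) for ev, rate in rates.items()]
        line = TreatmentLine(name, bool(cfg["immunotherapy"]), cfg["drugs"], profile)
        line.build_schedule(econ)
        return line

    return StrategySpec(strategy_id, make_line("first_line", s["first_line"]),
                        make_line("second_line", s["second_line"]))


def cycle_drug_cost(line: TreatmentLine, econ: EconParams, cycle_index: int) -> float:
    """Drug cost of administrations falling inside one model cycle."""
    if line.schedule is None:
        line.build_schedule(econ)
    lo = cycle_index * econ.cycle_years
    hi = lo + econ.cycle_years
    inside = (line.schedule.times >= lo - 1e-12) & (line.schedule.times < hi - 1e-12)
    return float(line.schedule.costs[inside].sum())


# ---------------------------------------------------------------------------
# discounting helpers
# ---------------------------------------------------------------------------

def _df(t, rate):
    return (1.0 + rate) ** (-np.asarray(t, dtype=float))


def _disc_integral(a, b, rate):
    """integral_a^b (1+r)^-s ds (elementwise, a <= b)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if rate == 0.0:
        return b - a
    ln = np.log1p(rate)
    return (_df(a, rate) - _df(b, rate)) / ln


def _monitoring_schedule(econ: EconParams) -> DoseSchedule:
    """Follow-up/monitoring as a dose-like schedule out to the horizon."""
    n = int(np.ceil(econ.horizon / econ.cycle_years))
    times, costs = [], []
    for k in range(n):
        t = k * econ.cycle_years
        c = econ.monitoring_per_cycle
        if k % econ.imaging_every_n_cycles == 0:
            c += econ.imaging_per_event
        times.append(t)
        costs.append(c)
    return DoseSchedule(np.asarray(times), np.asarray(costs))


# ---------------------------------------------------------------------------
# per-patient accrual (vectorized)
# ---------------------------------------------------------------------------

def accrue_cohort(t1, pfs2, os2, strategy: StrategySpec, econ: EconParams):
    """Discounted cost / QALY / LY for arrays of patient event times.

    ``t1`` is the first-line progression time, ``pfs2``/``os2`` the
    second-line progression and survival offsets (clock reset at first
    progression, ``pfs2 <= os2``).  All times in years; the horizon
    truncates everything.  Returns (cost, qaly, ly) arrays.
    """
    r = econ.discount_rate
    H = econ.horizon
    t1 = np.asarray(t1, dtype=float)
    pfs2 = np.asarray(pfs2, dtype=float)
    os2 = np.asarray(os2, dtype=float)

    t1c = np.minimum(t1, H)
    progressed = t1 < H
    R = np.where(progressed, H - t1, 0.0)
    p2c = np.minimum(pfs2, R)
    o2c = np.minimum(os2, R)
    died = progressed & (os2 < R)

    mon = _monitoring_schedule(econ)
    mon_cum = mon.cumulative_discounted(r)
    sched1 = strategy.first.schedule
    sched2 = strategy.second.schedule
    cum1 = sched1.cumulative_discounted(r)
    cum2 = sched2.cumulative_discounted(r)
    ae1_cost, ae1_loss = ae_burden(strategy.first)
    ae2_cost, ae2_loss = ae_burden(strategy.second)

    def sched_cost(cum, times, cap):
        n = np.searchsorted(times, cap, side="left")
        return cum[n]

    df_t1 = np.where(progressed, _df(t1c, r), 0.0)

    # --- costs
    cost = sched_cost(cum1, sched1.times, t1c)                       # line-1 drugs
    cost += sched_cost(mon_cum, mon.times, t1c)                      # line-1 monitoring
    cost += ae1_cost
    cost += df_t1 * sched_cost(cum2, sched2.times, p2c)              # line-2 drugs
    cost += df_t1 * sched_cost(mon_cum, mon.times, p2c)              # line-2 monitoring
    cost += df_t1 * ae2_cost
    bsc_rate = econ.bsc_per_cycle / econ.cycle_years
    cost += df_t1 * bsc_rate * _disc_integral(p2c, o2c, r)           # BSC in end-stage PD
    cost += np.where(died, df_t1 * _df(o2c, r) * econ.end_of_life, 0.0)

    # --- QALYs
    u1 = econ.pfs_utility(strategy.first.immunotherapy)
    qaly = u1 * _disc_integral(0.0, t1c, r)
    qaly += df_t1 * econ.u_pd1 * _disc_integral(0.0, p2c, r)
    qaly += df_t1 * econ.u_pd_end * _disc_integral(p2c, o2c, r)
    qaly -= ae1_loss + df_t1 * ae2_loss

    ly = t1c + np.where(progressed, o2c, 0.0)
    return cost, qaly, ly


def accrue(t1: float, pfs2: float, os2: float, strategy: StrategySpec,
           econ: EconParams) -> tuple[float, float, float]:
    """Single-patient discounted (cost, QALY, LY)."""
    c, q, l = accrue_cohort(np.array([t1]), np.array([pfs2]), np.array([os2]),
                            strategy, econ)
    return float(c[0]), float(q[0]), float(l[0])


# ---------------------------------------------------------------------------
# deterministic cohort evaluator (partitioned-survival arithmetic)
# ---------------------------------------------------------------------------

def expected_outcomes(strategy: StrategySpec, pfs1: SurvivalCurve,
                      pfs2: SurvivalCurve, os2: SurvivalCurve,
                      econ: EconParams) -> dict:
    """Expected discounted cost/QALY/LY by numerical integration.

    Exact cohort expectation of the micro-simulation model (comonotone
    second-line coupling) computed from the survivor curves alone; used
    as the micro-simulation oracle and as the fast PSA evaluator.
    """
    r = econ.discount_rate
    H = econ.horizon
    t = pfs1.times
    if abs(t[-1] - H) > 1e-9:
        raise ValueError("curves must span the model horizon")
    mid = 0.5 * (t[1:] + t[:-1])
    dS1 = -np.diff(pfs1.survival)
    S1m = 0.5 * (pfs1.survival[1:] + pfs1.survival[:-1])
    disc_int = _disc_integral(t[:-1], t[1:], r)

    # pfs2 is already capped at os2 on the grid (comonotone coupling)
    S2p = pfs2.survival
    S2o = os2.survival
    S2pm = 0.5 * (S2p[1:] + S2p[:-1])
    S2om = 0.5 * (S2o[1:] + S2o[:-1])
    dS2o = -np.diff(S2o)

    mon = _monitoring_schedule(econ)
    sched1 = strategy.first.schedule
    sched2 = strategy.second.schedule
    ae1_cost, ae1_loss = ae_burden(strategy.first)
    ae2_cost, ae2_loss = ae_burden(strategy.second)
    u1 = econ.pfs_utility(strategy.first.immunotherapy)
    bsc_rate = econ.bsc_per_cycle / econ.cycle_years

    # --- first line (line start at 0)
    def sched_expected(sched: DoseSchedule, S: SurvivalCurve | np.ndarray, times) -> float:
        """sum_k c_k df(s_k) P(duration > s_k)."""
        surv = S.survival if isinstance(S, SurvivalCurve) else S
        p = np.interp(sched.times, times, surv)
        return float(np.sum(sched.costs * _df(sched.times, r) * p))

    cost1 = sched_expected(sched1, pfs1, t) + sched_expected(mon, pfs1, t) + ae1_cost
    qaly1 = u1 * float(np.sum(S1m * disc_int))
    ly1 = float(np.trapezoid(pfs1.survival, t))

    # --- second line cumulatives as a function of remaining horizon R on grid
    p_dose2 = np.interp(sched2.times, t, S2p)
    dose2_terms = sched2.costs * _df(sched2.times, r) * p_dose2
    p_mon2 = np.interp(mon.times, t, S2p)
    mon2_terms = mon.costs * _df(mon.times, r) * p_mon2

    def cum_by_R(term_times, terms):
        """cum[i] = sum of terms with time < t[i] (R = t[i])."""
        order = np.argsort(term_times, kind="stable")
        tt, vv = np.asarray(term_times)[order], np.asarray(terms)[order]
        csum = np.concatenate([[0.0], np.cumsum(vv)])
        idx = np.searchsorted(tt, t, side="left")
        return csum[idx]

    cost2_drug_R = cum_by_R(sched2.times, dose2_terms)
    cost2_mon_R = cum_by_R(mon.times, mon2_terms)
    bsc_R = np.concatenate([[0.0], np.cumsum(bsc_rate * (S2om - S2pm) * disc_int)])
    eol_R = np.concatenate([[0.0], np.cumsum(dS2o * _df(mid, r) * econ.end_of_life)])
    q2_pd1_R = np.concatenate([[0.0], np.cumsum(econ.u_pd1 * S2pm * disc_int)])
    q2_pde_R = np.concatenate([[0.0], np.cumsum(econ.u_pd_end * (S2om - S2pm) * disc_int)])
    ly2_R = np.concatenate([[0.0], np.cumsum(S2om * np.diff(t))])

    cost2_R = cost2_drug_R + cost2_mon_R + bsc_R + eol_R + ae2_cost
    qaly2_R = q2_pd1_R + q2_pde_R - ae2_loss

    # --- integrate over the first-line progression time (mass dS1 at mid)
    n = len(mid)
    ridx = n - np.arange(n)  # remaining grid index for progression in interval i
    df_mid = _df(mid, r)
    cost = cost1 + float(np.sum(dS1 * df_mid * cost2_R[ridx]))
    qaly = qaly1 - ae1_loss + float(np.sum(dS1 * df_mid * qaly2_R[ridx]))
    ly = ly1 + float(np.sum(dS1 * ly2_R[ridx]))
    return {"cost": cost, "qaly": qaly, "ly": ly,
            "cost_first_line": cost1, "qaly_pfs": qaly1}


# ---------------------------------------------------------------------------
# CEA summary
# ---------------------------------------------------------------------------

def cea_table(results: pd.DataFrame, wtp: float,
              reference: str | None = None) -> pd.DataFrame:
    """CEA summary: NMB, INMB, dominance flags and frontier membership.

    ``results`` must be indexed by strategy with columns cost and qaly
    (and optionally ly).  Pairwise ICERs come from :func:`icer_matrix`.
    """
    if len(results) < 2:
        raise ValueError("need at least two strategies")
    out = results.copy()
    out["nmb"] = wtp * out["qaly"] - out["cost"]
    if reference is not None:
        out["inmb_vs_" + reference] = out["nmb"] - out.loc[reference, "nmb"]

    # strict dominance
    dominated = []
    for a in out.index:
        dom = any((out.loc[b, "cost"] <= out.loc[a, "cost"]) and
                  (out.loc[b, "qaly"] >= out.loc[a, "qaly"]) and
                  ((out.loc[b, "cost"] < out.loc[a, "cost"]) or
                   (out.loc[b, "qaly"] > out.loc[a, "qaly"]))
                  for b in out.index if b != a)
        dominated.append(dom)
    out["dominated"] = dominated

    # efficiency frontier with extended dominance
    cand = out[~out["dominated"]].sort_values(["qaly", "cost"])
    frontier = list(cand.index)
    changed = True
    while changed and len(frontier) > 2:
        changed = False
        for i in range(1, len(frontier) - 1):
            lo, m, hi = frontier[i - 1], frontier[i], frontier[i + 1]
            icer_in = ((out.loc[m, "cost"] - out.loc[lo, "cost"]) /
                       (out.loc[m, "qaly"] - out.loc[lo, "qaly"]))
            icer_out = ((out.loc[hi, "cost"] - out.loc[m, "cost"]) /
                        (out.loc[hi, "qaly"] - out.loc[m, "qaly"]))
            if icer_in > icer_out:      # extendedly dominated
                frontier.pop(i)
                changed = True
                break
    out["extendedly_dominated"] = [(s not in frontier) and not d
                                   for s, d in zip(out.index, out["dominated"])]
    out["on_frontier"] = [s in frontier for s in out.index]
    return out


def icer_matrix(results: pd.DataFrame) -> pd.DataFrame:
    """Pairwise ICERs (row vs column); dominance flagged with +/-inf.

    inf  = row more costly and less effective than column (dominated);
    -inf = row cheaper and more effective (dominant).  NaN on the
    diagonal and where the QALY difference is zero.
    """
    idx = results.index
    M = pd.DataFrame(np.nan, index=idx, columns=idx)
    for a in idx:
        for b in idx:
            if a == b:
                continue
            dc = results.loc[a, "cost"] - results.loc[b, "cost"]
            dq = results.loc[a, "qaly"] - results.loc[b, "qaly"]
            if dq == 0:
                M.loc[a, b] = np.nan
            elif dq > 0:
                M.loc[a, b] = dc / dq if dc > 0 else -np.inf
            else:
                M.loc[a, b] = np.inf if dc >= 0 else (dc / dq)
    return M
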