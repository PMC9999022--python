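"""One-way and probabilistic sensitivity analysis, scenarios and subgroups.

* OWSA: every parameter is pushed to its low/high bound while all
  others stay at base; the incremental net monetary benefit versus the
  reference strategy is recorded (tornado table).
* PSA: parameters are drawn from their tariff distributions (gamma for
  costs, beta for probabilities and utilities, normal on the coefficient
  scale for NMA coefficients) with method-of-moments parameters and
  SD = (high - low) / (2 * 1.96); the model is re-evaluated per draw
  with the deterministic cohort evaluator (the micro-simulation and the
  evaluator agree to Monte-Carlo error — itself a test).
* CEAC: the fraction of draws in which each strategy has maximal NMB,
  over a willingness-to-pay grid.
* Scenarios 1-5: alternative utility sets, patient-assistance-program
  prices, shorter horizons, and a third-line cost sweep.
* Subgroups: first-line comparison (7 regimens, docetaxel second line)
  and second-line comparison (3 regimens on a chemo first line) at the
  end-stage willingness-to-pay threshold.

The scenario/OWSA/PSA engines never mutate the base configuration; every
evaluation works on a deep copy of the parameter table.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .curve_engine import LifeTable, build_all_curves
from .curves import model_grid
from .econ import EconParams, build_strategy, cea_table, expected_outcomes
from .params import STRATEGY_IDS, load_strategies, load_tariff

_Z95 = 1.959963984540054


@dataclass
class ParamDistribution:
    """One uncertain parameter: distribution kind, base value and bounds.

    ``path`` locates the value inside the parameter table so draws can
    be written back into a copy of it.
    """

    name: str
    kind: str          # gamma | beta | normal | constant
    mean: float
    low: float
    high: float
    path: tuple

    def __post_init__(self) -> None:
        if self.kind not in ("gamma", "beta", "normal", "constant"):
            raise ValueError(f"unknown distribution kind '{self.kind}'")
        if self.kind == "beta" and not (0.0 <= self.mean <= 1.0):
            raise ValueError(f"{self.name}: beta mean must lie in (0, 1)")

    @property
    def sd(self) -> float:
        return abs(self.high - self.low) / (2.0 * _Z95)

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        m, s = self.mean, self.sd
        if self.kind == "constant" or s == 0:
            return np.full(n, m)
        if self.kind == "gamma":
            shape = (m / s) ** 2
            return rng.gamma(shape, m / shape, size=n)
        if self.kind == "beta":
            v = s ** 2
            if v >= m * (1 - m):
                v = 0.99 * m * (1 - m)
            nu = m * (1 - m) / v - 1
            return rng.beta(m * nu, (1 - m) * nu, size=n)
        return rng.normal(m, s, size=n)


def _set_path(table: dict, path: tuple, value: float) -> None:
    node = table
    for key in path[:-1]:
        node = node[key]
    node[path[-1]] = float(value)


def build_param_list(tariff: dict | None = None) -> list[ParamDistribution]:
    """Enumerate every uncertain parameter of the tariff."""
    t1 = tariff or load_tariff()
    out: list[ParamDistribution] = []

    def add(name, kind, entry, path):
        out.append(ParamDistribution(name, kind, float(entry["mean"]),
                                     float(entry["low"]), float(entry["high"]), path))

    for block, cfg in t1["fp_nma"].items():
        for trt, c in cfg["contrasts"].items():
            for j in range(len(c["d"])):
                out.append(ParamDistribution(
                    f"fp:{block}:{trt}:d{j}", "normal", float(c["d"][j]),
                    float(c["ci_low"][j]), float(c["ci_high"][j]),
                    ("fp_nma", block, "contrasts", trt, "d", j)))
    for ev, entry in t1["adverse_events"]["costs"].items():
        add(f"ae_cost:{ev}", "gamma", entry, ("adverse_events", "costs", ev, "mean"))
    for ev, entry in t1["adverse_events"]["disutilities"].items():
        add(f"ae_disutility:{ev}", "beta", entry,
            ("adverse_events", "disutilities", ev, "mean"))
    for regimen, evs in t1["adverse_events"]["rates"].items():
        for ev, entry in evs.items():
            add(f"ae_rate:{regimen}:{ev}", "beta", entry,
                ("adverse_events", "rates", regimen, ev, "mean"))
    for item, entry in t1["costs"].items():
        add(f"cost:{item}", "gamma", entry, ("costs", item, "mean"))
    for drug, vials in t1["drug_prices"].items():
        for i, v in enumerate(vials):
            out.append(ParamDistribution(
                f"price:{drug}:{v['mg']}mg", "gamma", float(v["price"]),
                float(v["low"]), float(v["high"]),
                ("drug_prices", drug, i, "price")))
    for share, entry in t1["market_shares"].items():
        add(f"market_share:{share}", "beta", entry, ("market_shares", share, "mean"))
    for u, entry in t1["utilities"].items():
        add(f"utility:{u}", "beta", entry, ("utilities", u, "mean"))
    add("discount_rate", "beta", t1["discount_rate"], ("discount_rate", "mean"))
    return out


# ---------------------------------------------------------------------------
# model evaluation from a (possibly modified) parameter table
# ---------------------------------------------------------------------------

def evaluate_table(tariff: dict, strategy_ids=STRATEGY_IDS,
                   life_table: LifeTable | None = None,
                   econ_overrides: dict | None = None,
                   horizon: float | None = None) -> pd.DataFrame:
    """Deterministic cohort outcomes (cost/qaly/ly) per strategy."""
    life_table = life_table or LifeTable.packaged()
    grid = model_grid(horizon) if horizon else None
    curves = build_all_curves(tariff, life_table, grid=grid)
    econ = EconParams.from_table(tariff)
    if horizon:
        econ.horizon = horizon
    if econ_overrides:
        for k, v in econ_overrides.items():
            setattr(econ, k, v)
    mapping = load_strategies()
    rows = {}
    for sid in strategy_ids:
        spec = build_strategy(sid, econ, tariff)
        first = curves[("first", mapping[sid]["first_line"])]
        second = curves[("second", mapping[sid]["second_line"])]
        res = expected_outcomes(spec, first.pfs, second.pfs, second.os, econ)
        rows[sid] = {"cost": res["cost"], "qaly": res["qaly"], "ly": res["ly"]}
    return pd.DataFrame(rows).T


# ---------------------------------------------------------------------------
# one-way sensitivity analysis
# ---------------------------------------------------------------------------

def owsa(params: list[ParamDistribution] | None = None, reference: str = "CAD",
         strategy_ids=STRATEGY_IDS, wtp: float | None = None,
         tariff: dict | None = None) -> pd.DataFrame:
    """Tornado table: INMB of each strategy versus ``reference`` with every
    parameter at its low and high bound; rows sorted by bar width."""
    import warnings

    base_t1 = tariff or load_tariff()
    if wtp is None:
        wtp = float(base_t1["wtp"]["base"])
    if params is None:
        params = build_param_list(base_t1)
    life = LifeTable.packaged()
    base = evaluate_table(base_t1, strategy_ids, life)
    base_nmb = wtp * base["qaly"] - base["cost"]

    rows = []
    for p in params:
        if not np.isfinite(p.low) or not np.isfinite(p.high):
            warnings.warn(f"{p.name}: missing bounds, skipped", stacklevel=2)
            continue
        inmbs = {}
        for side, val in (("low", p.low), ("high", p.high)):
            t1 = copy.deepcopy(base_t1)
            _set_path(t1, p.path, val)
            res = evaluate_table(t1, strategy_ids, life)
            nmb = wtp * res["qaly"] - res["cost"]
            inmbs[side] = nmb - nmb[reference]
        for sid in strategy_ids:
            if sid == reference:
                continue
            lo, hi = inmbs["low"][sid], inmbs["high"][sid]
            rows.append({"parameter": p.name, "strategy": sid,
                         "inmb_base": base_nmb[sid] - base_nmb[reference],
                         "inmb_low": lo, "inmb_high": hi, "width": abs(hi - lo)})
    return (pd.DataFrame(rows)
            .sort_values(["strategy", "width"], ascending=[True, False])
            .reset_index(drop=True))


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis
# ---------------------------------------------------------------------------

def draw_psa(params: list[ParamDistribution], n_draws: int = 10_000,
             seed: int = 0) -> pd.DataFrame:
    """Seeded parameter draws, one column per parameter."""
    rng = np.random.default_rng(seed)
    return pd.DataFrame({p.name: p.draw(rng, n_draws) for p in params})


def psa_run(draws: pd.DataFrame, params: list[ParamDistribution],
            strategy_ids=STRATEGY_IDS, tariff: dict | None = None) -> pd.DataFrame:
    """Per-draw cost/QALY per strategy via the cohort evaluator.

    Returns a long DataFrame (draw, strategy, cost, qaly).
    """
    base_t1 = tariff or load_tariff()
    by_name = {p.name: p for p in params}
    life = LifeTable.packaged()
    out = []
    for i in range(len(draws)):
        t1 = copy.deepcopy(base_t1)
        for name, val in draws.iloc[i].items():
            _set_path(t1, by_name[name].path, val)
        res = evaluate_table(t1, strategy_ids, life)
        for sid in strategy_ids:
            out.append({"draw": i, "strategy": sid,
                        "cost": res.loc[sid, "cost"], "qaly": res.loc[sid, "qaly"]})
    return pd.DataFrame(out)


def ceac(psa: pd.DataFrame, wtp_grid) -> pd.DataFrame:
    """P(strategy has maximal NMB) at each willingness-to-pay value."""
    strategies = sorted(psa["strategy"].unique())
    wide_c = psa.pivot(index="draw", columns="strategy", values="cost")[strategies]
    wide_q = psa.pivot(index="draw", columns="strategy", values="qaly")[strategies]
    rows = []
    for lam in np.asarray(wtp_grid, dtype=float):
        nmb = lam * wide_q.to_numpy() - wide_c.to_numpy()
        best = np.argmax(nmb, axis=1)
        share = np.bincount(best, minlength=len(strategies)) / len(best)
        for j, s in enumerate(strategies):
            rows.append({"wtp": lam, "strategy": s, "probability": share[j]})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# scenarios
# ---------------------------------------------------------------------------

def run_scenario(scenario: int, strategy_ids=STRATEGY_IDS,
                 tariff: dict | None = None, wtp: float | None = None):
    """Scenario analyses 1-5; returns a CEA table (or dict of tables)."""
    base_t1 = tariff or load_tariff()
    if wtp is None:
        wtp = float(base_t1["wtp"]["base"])
    ref = "CAD" if "CAD" in strategy_ids else list(strategy_ids)[0]
    t1 = copy.deepcopy(base_t1)

    if scenario == 1:
        u = t1["scenario_utilities"]["scenario1"]
        over = {"u_pfs_immuno": u["pfs"]["mean"], "u_pfs_chemo": u["pfs"]["mean"],
                "u_pd1": u["pd"]["mean"], "u_pd_end": u["pd"]["mean"]}
        res = evaluate_table(t1, strategy_ids, econ_overrides=over)
        return cea_table(res, wtp, reference=ref)
    if scenario == 2:
        u = t1["scenario_utilities"]["scenario2"]
        over = {"u_pfs_immuno": u["pfs_immunotherapy"]["mean"],
                "u_pfs_chemo": u["pfs_chemotherapy"]["mean"],
                "u_pd1": u["pd_second_line"]["mean"],
                "u_pd_end": u["pd_third_line"]["mean"]}
        res = evaluate_table(t1, strategy_ids, econ_overrides=over)
        return cea_table(res, wtp, reference=ref)
    if scenario == 3:
        pap = t1.get("pap_discounts", {})
        for drug, mult in pap.items():
            for vial in t1["drug_prices"][drug]:
                vial["price"] = vial["price"] * float(mult)
        res = evaluate_table(t1, strategy_ids)
        return cea_table(res, wtp, reference=ref)
    if scenario == 4:
        out = {}
        for horizon in (5.0, 10.0, 20.0):
            res = evaluate_table(t1, strategy_ids, horizon=horizon)
            out[horizon] = cea_table(res, wtp, reference=ref)
        return out
    if scenario == 5:
        out = {}
        for bsc in (0.0, 1000.0, 2000.0, 3000.0, 4000.0):
            res = evaluate_table(t1, strategy_ids, econ_overrides={"bsc_per_cycle": bsc})
            out[bsc] = cea_table(res, wtp, reference=ref)
        return out
    raise ValueError("scenario must be one of 1..5")


# ---------------------------------------------------------------------------
# subgroups
# ---------------------------------------------------------------------------

FIRST_LINE_SUBGROUP = ("CD", "ND", "PED", "SID", "CAD", "TID", "SUD")
SECOND_LINE_SUBGROUP = ("CD", "CT", "CN")


def subgroup(line: str, tariff: dict | None = None,
             results: pd.DataFrame | None = None) -> pd.DataFrame:
    """CEA table within the first-line or second-line comparison.

    First line: the seven regimens on a fixed docetaxel second line at
    the base threshold, referenced to CA+C.  Second line: the three
    options on a fixed chemotherapy first line at the end-stage
    threshold (2.55 x GDP per capita).
    """
    t1 = tariff or load_tariff()
    if line == "first":
        ids, lam, ref = FIRST_LINE_SUBGROUP, float(t1["wtp"]["base"]), "CAD"
    elif line == "second":
        ids, lam, ref = SECOND_LINE_SUBGROUP, float(t1["wtp"]["second_line"]), "CD"
    else:
        raise ValueError("line must be 'first' or 'second'")
    if results is None:
        results = evaluate_table(t1, ids)
    else:
        results = results.loc[list(ids), ["cost", "qaly"] +
                              (["ly"] if "ly" in results else [])]
    if len(results) == 1:
        out = results.copy()
        out["nmb"] = lam * out["qaly"] - out["cost"]
        return out
    return cea_table(results, lam, reference=ref)
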