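"""Sequential micro-simulation of the four-state treatment pathway.

Each simulated patient moves PFS -> first-stage PD (second-line
treatment, clock reset) -> end-stage PD (best supportive care) -> death.
First-line exit is governed by the strategy's first-line PFS curve; on
progression the second-line clock starts at zero and (PFS2, OS2) are
drawn from the second-line curves with a shared uniform rank (comonotone
coupling), which guarantees PFS2 <= OS2 per patient.  Everything is
truncated at the model horizon.

Common random numbers: the per-patient uniform draws depend only on
(seed, n_patients), so strategy contrasts share their Monte-Carlo noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .curves import CYCLE_YEARS, HORIZON_YEARS
from .curve_engine import TreatmentCurveSet, sample_event_time
from .econ import EconParams, StrategySpec, accrue_cohort


@dataclass
class SimulationConfig:
    n_patients: int = 10_000
    cycle_years: float = CYCLE_YEARS
    horizon: float = HORIZON_YEARS
    seed: int = 0
    discount_rate: float = 0.05
    coupling: str = "comonotone"     # or "independent"

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.horizon <= 0:
            raise ValueError("horizon must be > 0")
        if not 0.0 <= self.discount_rate <= 0.08:
            raise ValueError("discount rate outside the supported 0-8% range")
        if self.coupling not in ("comonotone", "independent"):
            raise ValueError("coupling must be 'comonotone' or 'independent'")


@dataclass
class PatientTrajectory:
    """State-entry times of a single simulated patient (years)."""

    t_progress1: float       # first-line progression (or horizon if none)
    t_progress2: float       # second-line progression offset (clock reset)
    t_death: float           # absolute death time (or horizon if censored)
    beyond_horizon: bool     # still alive (in some state) at the horizon

    def state_at(self, t: float) -> str:
        if t >= self.t_death:
            if not self.beyond_horizon:
                return "death"
            t = self.t_death - 1e-12   # alive at the horizon: clamp into model
        if t < self.t_progress1:
            return "pfs"
        if t < self.t_progress1 + self.t_progress2:
            return "pd1"
        return "pd_end"


def common_random_numbers(config: SimulationConfig) -> np.ndarray:
    """Per-patient uniforms, shape (n_patients, 3): first-line rank,
    second-line shared rank, independent second-line PFS rank."""
    rng = np.random.default_rng(config.seed)
    u = rng.uniform(size=(config.n_patients, 3))
    return np.clip(u, 1e-12, 1 - 1e-12)


def draw_event_times(first: TreatmentCurveSet, second: TreatmentCurveSet,
                     u: np.ndarray, coupling: str = "comonotone"):
    """(t1, pfs2, os2) arrays from per-patient uniforms."""
    t1 = sample_event_time(first.pfs, u[:, 0])
    os2 = sample_event_time(second.os, u[:, 1])
    u_p = u[:, 1] if coupling == "comonotone" else u[:, 2]
    pfs2 = np.minimum(sample_event_time(second.pfs, u_p), os2)
    return t1, pfs2, os2


def simulate_patient(strategy: StrategySpec, first: TreatmentCurveSet,
                     second: TreatmentCurveSet, u: np.ndarray,
                     config: SimulationConfig) -> PatientTrajectory:
    """Route one patient through the model from its three uniform draws."""
    t1, pfs2, os2 = draw_event_times(first, second, u.reshape(1, 3), config.coupling)
    H = config.horizon
    t1, pfs2, os2 = float(t1[0]), float(pfs2[0]), float(os2[0])
    if t1 >= H:
        return PatientTrajectory(H, 0.0, H, True)
    death = t1 + os2
    beyond = death >= H
    return PatientTrajectory(t1, min(pfs2, max(H - t1, 0.0)), min(death, H), beyond)


@dataclass
class CohortResult:
    """Cohort summaries of one strategy under one random-number stream."""

    strategy: str
    n_patients: int
    seed: int
    mean_cost: float
    mean_qaly: float
    mean_ly: float
    se_cost: float
    se_qaly: float
    se_ly: float
    occupancy: pd.DataFrame = field(repr=False, default=None)
    per_patient: pd.DataFrame = field(repr=False, default=None)


def simulate_cohort(strategy: StrategySpec, first: TreatmentCurveSet,
                    second: TreatmentCurveSet, econ: EconParams,
                    config: SimulationConfig, u: np.ndarray | None = None,
                    keep_patients: bool = False,
                    occupancy: bool = False) -> CohortResult:
    """Simulate ``n_patients`` trajectories and accrue costs and QALYs.

    Passing the same ``u`` (or the same seed) yields bit-identical
    results; pass one shared ``u`` across strategies for common random
    numbers.
    """
    if u is None:
        u = common_random_numbers(config)
    t1, pfs2, os2 = draw_event_times(first, second, u, config.coupling)
    cost, qaly, ly = accrue_cohort(t1, pfs2, os2, strategy, econ)
    n = len(cost)

    occ = None
    if occupancy:
        H, dt = config.horizon, config.cycle_years
        edges = np.arange(0.0, H + dt / 2, dt)
        prog = t1 < H
        death = np.where(prog, np.minimum(t1 + os2, H), H)
        alive_beyond = ~prog | (t1 + os2 >= H)
        rows = []
        for lo in edges[:-1]:
            in_pfs = (t1 > lo).mean()
            in_pd1 = ((t1 <= lo) & (t1 + pfs2 > lo) & prog).mean()
            in_pde = ((t1 + pfs2 <= lo) & (t1 + os2 > lo) & prog).mean()
            dead = np.clip(1.0 - in_pfs - in_pd1 - in_pde, 0.0, 1.0)
            rows.append((lo / dt, in_pfs, in_pd1, in_pde, dead))
        occ = pd.DataFrame(rows, columns=["cycle", "fraction_pfs", "fraction_pd1",
                                          "fraction_pd_end", "fraction_dead"])

    per = None
    if keep_patients:
        per = pd.DataFrame({"t_progress1": t1, "t_progress2": pfs2, "t_os2": os2,
                            "cost": cost, "qaly": qaly, "ly": ly})

    return CohortResult(
        strategy.id, n, config.seed,
        float(cost.mean()), float(qaly.mean()), float(ly.mean()),
        float(cost.std(ddof=1) / np.sqrt(n)), float(qaly.std(ddof=1) / np.sqrt(n)),
        float(ly.std(ddof=1) / np.sqrt(n)), occ, per)


def run_strategies(strategy_ids, curves: dict, econ: EconParams,
                   config: SimulationConfig, tariff: dict | None = None,
                   strategies_cfg: dict | None = None) -> pd.DataFrame:
    """Simulate several strategies under common random numbers.

    ``curves`` is the output of :func:`seqcea.curve_engine.build_all_curves`.
    Returns a DataFrame indexed by strategy with cost/qaly/ly means and SEs.
    """
    from .econ import build_strategy
    from .params import load_strategies

    mapping = strategies_cfg or load_strategies()
    u = common_random_numbers(config)
    rows = {}
    for sid in strategy_ids:
        spec = build_strategy(sid, econ, tariff)
        first = curves[("first", mapping[sid]["first_line"])]
        second = curves[("second", mapping[sid]["second_line"])]
        res = simulate_cohort(spec, first, second, econ, config, u=u)
        rows[sid] = {"cost": res.mean_cost, "qaly": res.mean_qaly, "ly": res.mean_ly,
                     "se_cost": res.se_cost, "se_qaly": res.se_qaly, "se_ly": res.se_ly}
    return pd.DataFrame(rows).T
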