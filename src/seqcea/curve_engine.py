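"""Assembly of the per-treatment survivor functions used by the simulator.

First-line PFS curves start from the chemotherapy reference (log-logistic
fit to the reference trial) and are adjusted by each combination's
time-varying FP hazard ratio.  Second-line curves start from the
docetaxel OS/PFS references; nivolumab and tislelizumab are FP-adjusted.
General-population mortality is spliced in after the curve's own hazard
falls below the age-specific background hazard, and event times are
drawn by inverse-CDF interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .curves import CYCLE_YEARS, HORIZON_YEARS, SurvivalCurve, model_grid
from .fp_nma import hr_apply
from .params import (FIRST_LINE_TREATMENTS, SECOND_LINE_TREATMENTS, load_life_table,
                     load_tariff, nma_block, reference_fit)
from .survival_fit import curve_from_fit


@dataclass
class TreatmentCurveSet:
    """The survivor functions of one treatment at one line."""

    treatment: str
    line: str                     # 'first' | 'second'
    pfs: SurvivalCurve
    os: SurvivalCurve | None = None

    def __post_init__(self) -> None:
        if self.os is not None:
            if np.any(self.pfs.survival > self.os.survival + 1e-9):
                raise ValueError(f"{self.treatment}: PFS exceeds OS on the grid")


@dataclass
class LifeTable:
    """Age-band annual mortality probabilities (general population)."""

    ages: np.ndarray
    annual_mortality: np.ndarray

    def __post_init__(self) -> None:
        q = self.annual_mortality
        if np.any((q <= 0) | (q >= 1)):
            raise ValueError("annual mortality probabilities must lie in (0, 1)")
        if self.ages.max() < 100:
            raise ValueError("life table must extend to at least age 100")

    @classmethod
    def from_csv(cls, path) -> "LifeTable":
        df = pd.read_csv(path)
        return cls(df["age"].to_numpy(float), df["annual_mortality"].to_numpy(float))

    @classmethod
    def packaged(cls) -> "LifeTable":
        df = load_life_table()
        return cls(df["age"].to_numpy(float), df["annual_mortality"].to_numpy(float))

    def hazard_at_age(self, age) -> np.ndarray:
        """Continuous-time hazard -ln(1-q) at (possibly fractional) ages."""
        q = np.interp(age, self.ages, self.annual_mortality)
        return -np.log1p(-q)


# ---------------------------------------------------------------------------
# curve construction
# ---------------------------------------------------------------------------

def build_first_line_pfs(treatment: str, tariff: dict | None = None,
                         grid: np.ndarray | None = None) -> SurvivalCurve:
    """First-line PFS curve for one of the seven regimens."""
    if treatment not in FIRST_LINE_TREATMENTS:
        raise ValueError(
            f"unknown first-line treatment '{treatment}'; valid: {FIRST_LINE_TREATMENTS}")
    tariff = tariff or load_tariff()
    grid = model_grid() if grid is None else grid
    ref = curve_from_fit(reference_fit(tariff, "first_line_pfs_chemo"), grid)
    if treatment == "chemo":
        return ref
    block = nma_block(tariff, "first_line_pfs")
    return hr_apply(ref, block.coefficients[treatment], block.spec,
                    floor=block.basis_floor,
                    effect_horizon=block.effect_horizons[treatment])


def build_second_line_curves(treatment: str, tariff: dict | None = None,
                             grid: np.ndarray | None = None) -> TreatmentCurveSet:
    """Second-line PFS and OS curves (docetaxel reference or FP-adjusted)."""
    if treatment not in SECOND_LINE_TREATMENTS:
        raise ValueError(
            f"unknown second-line treatment '{treatment}'; valid: {SECOND_LINE_TREATMENTS}")
    tariff = tariff or load_tariff()
    grid = model_grid() if grid is None else grid
    os_ref = curve_from_fit(reference_fit(tariff, "second_line_os_docetaxel"), grid)
    pfs_ref = curve_from_fit(reference_fit(tariff, "second_line_pfs_docetaxel"), grid)
    if treatment == "docetaxel":
        pfs, os = pfs_ref, os_ref
    else:
        os_block = nma_block(tariff, "second_line_os")
        pfs_block = nma_block(tariff, "second_line_pfs")
        os = hr_apply(os_ref, os_block.coefficients[treatment], os_block.spec,
                      floor=os_block.basis_floor,
                      effect_horizon=os_block.effect_horizons[treatment])
        pfs = hr_apply(pfs_ref, pfs_block.coefficients[treatment], pfs_block.spec,
                       floor=pfs_block.basis_floor,
                       effect_horizon=pfs_block.effect_horizons[treatment])
    # logical ordering: progression cannot come after death
    pfs = pfs.with_survival(np.minimum(pfs.survival, os.survival))
    return TreatmentCurveSet(treatment, "second", pfs, os)


def splice_background_mortality(curve: SurvivalCurve, life_table: LifeTable,
                                cohort_age: float) -> SurvivalCurve:
    """Replace the curve's hazard by background mortality after the plateau.

    The plateau point is the first grid interval whose curve hazard
    falls below the age-specific background hazard; from there on the
    background hazard applies (never less than it).  If the curve never
    plateaus within the horizon it is returned unchanged.
    """
    import warnings

    h = curve.interval_hazards()
    mid = 0.5 * (curve.times[1:] + curve.times[:-1])
    bg = life_table.hazard_at_age(cohort_age + mid)
    below = np.where(h < bg)[0]
    if len(below) == 0:
        warnings.warn("no plateau within horizon; curve returned unchanged",
                      stacklevel=2)
        return curve
    k = below[0]
    h_new = h.copy()
    h_new[k:] = np.maximum(h[k:], bg[k:])
    return SurvivalCurve.from_interval_hazards(curve.times, h_new)


def sample_event_time(curve: SurvivalCurve, u) -> np.ndarray:
    """Inverse-CDF event times for uniforms ``u`` in (0, 1).

    ``u`` below the survivor value at the horizon maps to the horizon
    itself ("beyond-horizon"); callers treat such times as censored at
    the grid end.
    """
    u = np.asarray(u, dtype=float)
    if np.any((u <= 0) | (u >= 1)):
        raise ValueError("u must lie strictly inside (0, 1)")
    return np.interp(-u, -curve.survival, curve.times)


# ---------------------------------------------------------------------------
# full curve sets for the decision model
# ---------------------------------------------------------------------------

def build_all_curves(tariff: dict | None = None, life_table: LifeTable | None = None,
                     cohort_age: float | None = None, grid: np.ndarray | None = None,
                     background: bool = True) -> dict:
    """All first-line PFS curves and second-line curve sets, spliced with
    background mortality, keyed by ('first'|'second', treatment)."""
    tariff = tariff or load_tariff()
    grid = model_grid() if grid is None else grid
    life_table = life_table or LifeTable.packaged()
    if cohort_age is None:
        cohort_age = float(tariff["population"]["cohort_age"])
    out = {}
    import warnings
    for trt in FIRST_LINE_TREATMENTS:
        c = build_first_line_pfs(trt, tariff, grid)
        if background:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                c = splice_background_mortality(c, life_table, cohort_age)
        out[("first", trt)] = TreatmentCurveSet(trt, "first", c)
    for trt in SECOND_LINE_TREATMENTS:
        cs = build_second_line_curves(trt, tariff, grid)
        if background:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                os = splice_background_mortality(cs.os, life_table, cohort_age)
                pfs = cs.pfs.with_survival(np.minimum(cs.pfs.survival, os.survival))
            cs = TreatmentCurveSet(trt, "second", pfs, os)
        out[("second", trt)] = cs
    return out
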