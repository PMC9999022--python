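"""Synthetic trial generation for end-to-end testing of the pipeline.

No trial in the evidence network deposits patient-level data, so every
upstream stage (digitization handling, Guyot reconstruction, parametric
fitting, FP network meta-analysis) is exercised on synthetic trials with
known hazard structure: parametric event times, optional time-varying
hazard ratios from a fractional-polynomial model, administrative and
random censoring, and a digitization emulator with small jitter noise.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .curves import IPDSet, SurvivalCurve
from .km_ipd import KMDigitization, km_estimate, step_eval


@dataclass
class ArmSpec:
    """One trial arm: a treatment name, a hazard model and a sample size.

    ``family``/``params`` give the baseline parametric model; if
    ``fp_coeffs``/``fp_powers`` are set the arm's hazard is the baseline
    hazard times the fractional-polynomial hazard ratio exp(d . basis(t))
    with t in ``fp_time_unit`` units per year.
    """

    treatment: str
    family: str = "exponential"
    params: dict = field(default_factory=lambda: {"rate": 1.0})
    n: int = 200
    fp_coeffs: tuple | None = None
    fp_powers: tuple | None = None
    fp_time_unit: float = 1.0


@dataclass
class TrialSpec:
    arms: list[ArmSpec]
    cutoff: float = 3.0                 # administrative censoring time (years)
    censor_rate: float = 0.1            # random early-dropout probability
    at_risk_times: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be > 0")
        for arm in self.arms:
            if arm.n < 10:
                raise ValueError("need n >= 10 per arm")


def _arm_curve(arm: ArmSpec, horizon: float, n_grid: int = 4000) -> SurvivalCurve:
    from .survival_fit import ParametricFit, survival_eval
    from .fp_nma import FPModelSpec, FPCoefficients, fp_log_hr

    times = np.linspace(0.0, horizon, n_grid)
    fit = ParametricFit(arm.family, dict(arm.params), 0.0, len(arm.params))
    s = np.clip(survival_eval(fit, times), 0.0, 1.0)
    s = np.minimum.accumulate(s)
    s[0] = 1.0
    base = SurvivalCurve(times, s)
    if arm.fp_coeffs is None:
        return base
    spec = FPModelSpec(order=len(arm.fp_powers), powers=tuple(arm.fp_powers))
    coeffs = FPCoefficients(treatment=arm.treatment, reference="ref",
                            d=np.asarray(arm.fp_coeffs, dtype=float),
                            time_unit_per_year=arm.fp_time_unit)
    mid = 0.5 * (times[1:] + times[:-1])
    # floor the basis argument at half the first step and clip the exponent:
    # negative FP powers diverge at t -> 0
    x = np.maximum(mid * arm.fp_time_unit, 0.5 * (times[1] - times[0]) * arm.fp_time_unit)
    hr = np.exp(np.clip(fp_log_hr(x, coeffs, spec), -80.0, 80.0))
    h = base.interval_hazards() * hr
    return SurvivalCurve.from_interval_hazards(times, h)


def _sample_times(curve: SurvivalCurve, u: np.ndarray) -> np.ndarray:
    """Inverse-CDF sampling from a tabulated survivor function."""
    return np.interp(-u, -curve.survival, curve.times)


def generate_trial(spec: TrialSpec) -> dict[str, IPDSet]:
    """Simulate one trial; returns an IPDSet per arm keyed by treatment."""
    rng = np.random.default_rng(spec.seed)
    out = {}
    horizon = spec.cutoff * 6.0
    for arm in spec.arms:
        curve = _arm_curve(arm, horizon)
        u = rng.uniform(size=arm.n)
        times = np.maximum(_sample_times(curve, u), 1e-9)
        events = np.ones(arm.n, dtype=int)
        # administrative censoring at cutoff
        admin = times >= spec.cutoff
        times[admin] = spec.cutoff
        events[admin] = 0
        # random early dropout
        if spec.censor_rate > 0:
            drop = rng.uniform(size=arm.n) < spec.censor_rate
            drop_t = rng.uniform(size=arm.n) * times
            times = np.where(drop, np.maximum(drop_t, 1e-9), times)
            events = np.where(drop, 0, events)
        out[arm.treatment] = IPDSet(times, events)
    return out


def generate_km_digitization(ipd: IPDSet, n_grid: int = 100,
                             at_risk_times: np.ndarray | None = None,
                             jitter: float = 0.002, seed: int = 0) -> KMDigitization:
    """Emulate manual digitization of the KM plot of an IPD set.

    The KM step function is read off on ``n_grid`` evenly spaced times
    with additive jitter (clipped to preserve monotonicity); the at-risk
    table is computed exactly at ``at_risk_times``.
    """
    if n_grid < 10:
        raise ValueError("need a grid of at least 10 points")
    rng = np.random.default_rng(seed)
    km = km_estimate(ipd)
    tmax = ipd.times.max()
    grid = np.linspace(0.0, tmax, n_grid)
    s = step_eval(km, grid)
    if jitter > 0:
        s = s + rng.uniform(-jitter, jitter, size=len(s))
        s = np.minimum.accumulate(np.clip(s, 0.0, 1.0))
        s[0] = 1.0
    if at_risk_times is None:
        at_risk_times = np.linspace(0.0, tmax * 0.9, 7)
    at_risk_times = np.asarray(at_risk_times, dtype=float)
    counts = np.array([(ipd.times >= tt - 1e-12).sum() for tt in at_risk_times])
    return KMDigitization(grid, s, at_risk_times, counts,
                          total_events=int(ipd.events.sum()))


def generate_network(contrasts: dict[str, tuple], reference: str = "ref",
                     family: str = "exponential", params: dict | None = None,
                     powers: tuple = (-2.0,), n_per_arm: int = 500,
                     cutoff: float = 3.0, censor_rate: float = 0.05,
                     time_unit_per_year: float = 1.0,
                     seed: int = 0) -> tuple[dict, list[dict]]:
    """Star network: one two-arm trial per contrast versus the reference.

    ``contrasts`` maps treatment name -> true FP coefficient vector.
    Returns (ipd_by_arm, manifest) where arm keys are ``study:treatment``
    and the manifest lists study/treatment/reference rows.
    """
    if not contrasts:
        raise ValueError("network must contain at least one contrast")
    params = params or {"rate": 1.0}
    ipd_by_arm: dict[str, IPDSet] = {}
    manifest = []
    for j, (trt, coeffs) in enumerate(sorted(contrasts.items())):
        study = f"study{j + 1}"
        arms = [
            ArmSpec(reference, family, dict(params), n_per_arm),
            ArmSpec(trt, family, dict(params), n_per_arm,
                    fp_coeffs=tuple(coeffs), fp_powers=tuple(powers),
                    fp_time_unit=time_unit_per_year),
        ]
        trial = generate_trial(TrialSpec(arms, cutoff=cutoff, censor_rate=censor_rate,
                                         seed=seed + 1000 * (j + 1)))
        for trt_name, ipd in trial.items():
            ipd_by_arm[f"{study}:{trt_name}"] = ipd
            manifest.append({"study": study, "arm": f"{study}:{trt_name}",
                             "treatment": trt_name, "reference": reference})
    return ipd_by_arm, manifest
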