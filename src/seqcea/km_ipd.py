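"""Digitized Kaplan–Meier curves and pseudo-IPD reconstruction.

Published trials rarely release individual patient data (IPD).  The
standard workaround is to digitize the published KM curves together with
the numbers-at-risk table and reconstruct pseudo-IPD with the Guyot
algorithm: within each at-risk interval, censorings are spread uniformly
and event counts are chosen so that the reconstructed KM estimate tracks
the digitized survival probabilities while the implied numbers at risk
match the published table exactly.

Times are handled internally in years; the CSV readers accept a
``time_unit`` of days, months or years (1 month = 365.25/12 days).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

from .curves import IPDSet, SurvivalCurve

logger = logging.getLogger(__name__)

_TIME_UNIT_YEARS = {"days": 1.0 / 365.25, "months": 1.0 / 12.0, "years": 1.0}

_MONOTONE_TOL = 1e-9


class KMFormatError(ValueError):
    """Raised for malformed digitization files."""


class KMValidationError(ValueError):
    """Raised when digitized coordinates violate KM invariants."""


@dataclass
class KMDigitization:
    """Digitized KM coordinates plus the numbers-at-risk table.

    ``curve_times``/``curve_survival`` are the digitized clicks (years,
    probability); ``at_risk_times``/``at_risk_counts`` the published
    at-risk schedule.  A (0, 1) point is prepended if absent, duplicate
    times are collapsed keeping the lower survival value.
    """

    curve_times: np.ndarray
    curve_survival: np.ndarray
    at_risk_times: np.ndarray
    at_risk_counts: np.ndarray
    total_events: int | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.curve_times, dtype=float)
        s = np.asarray(self.curve_survival, dtype=float)
        if len(t) != len(s) or len(t) == 0:
            raise KMValidationError("curve times/survival must be non-empty and equal length")
        order = np.argsort(t, kind="stable")
        t, s = t[order], s[order]
        # collapse duplicate times keeping the lower (later) survival value
        keep_t, keep_s = [], []
        for ti, si in zip(t, s):
            if keep_t and ti == keep_t[-1]:
                keep_s[-1] = min(keep_s[-1], si)
            else:
                keep_t.append(ti)
                keep_s.append(si)
        t, s = np.array(keep_t), np.array(keep_s)
        if np.any(t < 0):
            raise KMValidationError("curve times must be >= 0")
        if np.any(s < -_MONOTONE_TOL) or np.any(s > 1 + _MONOTONE_TOL):
            raise KMValidationError("survival values must lie in [0, 1]")
        rises = np.where(np.diff(s) > _MONOTONE_TOL)[0]
        if len(rises):
            k = rises[0]
            raise KMValidationError(
                f"survival rises {s[k]:.6g} -> {s[k + 1]:.6g} at row {k + 1} (t={t[k + 1]:.6g})"
            )
        s = np.minimum.accumulate(np.clip(s, 0.0, 1.0))
        if t[0] != 0.0 or s[0] < 1.0:
            # anchor the curve at (0, 1); a digitized first click at t=0 with
            # S<1 is treated as an instantaneous drop from 1
            t = np.concatenate([[0.0], t[t > 0]])
            s = np.concatenate([[1.0], s[-(len(t) - 1):] if len(t) > 1 else []])
        self.curve_times, self.curve_survival = t, s

        rt = np.asarray(self.at_risk_times, dtype=float)
        rc = np.asarray(self.at_risk_counts, dtype=float)
        if len(rt) != len(rc) or len(rt) == 0:
            raise KMValidationError("at-risk times/counts must be non-empty and equal length")
        order = np.argsort(rt, kind="stable")
        rt, rc = rt[order], rc[order]
        if np.any(rt < 0):
            raise KMValidationError("at-risk times must be >= 0")
        if np.any(np.diff(rc) > 0):
            raise KMValidationError("at-risk counts must be non-increasing")
        if np.any(rc < 0) or np.any(rc != np.round(rc)):
            raise KMValidationError("at-risk counts must be non-negative integers")
        self.at_risk_times, self.at_risk_counts = rt, rc.astype(int)

    @property
    def n_initial(self) -> int:
        return int(self.at_risk_counts[0])


def read_km_csv(km_path, atrisk_path, time_unit: str = "years",
                total_events: int | None = None) -> KMDigitization:
    """Read digitized curve and at-risk CSVs into a validated KMDigitization.

    ``km_path`` needs columns ``time,survival``; ``atrisk_path`` columns
    ``time,n_at_risk``.  Rows are sorted by time; duplicate times are
    collapsed keeping the lower survival.
    """
    if time_unit not in _TIME_UNIT_YEARS:
        raise KMFormatError(f"time_unit must be one of {sorted(_TIME_UNIT_YEARS)}")
    scale = _TIME_UNIT_YEARS[time_unit]
    try:
        km = pd.read_csv(km_path)
        ar = pd.read_csv(atrisk_path)
    except (pd.errors.EmptyDataError, pd.errors.ParserError) as exc:
        raise KMFormatError(f"unreadable digitization CSV: {exc}") from exc
    for col in ("time", "survival"):
        if col not in km.columns:
            raise KMFormatError(f"{km_path}: missing required column '{col}'")
    for col in ("time", "n_at_risk"):
        if col not in ar.columns:
            raise KMFormatError(f"{atrisk_path}: missing required column '{col}'")
    return KMDigitization(
        curve_times=km["time"].to_numpy() * scale,
        curve_survival=km["survival"].to_numpy(),
        at_risk_times=ar["time"].to_numpy() * scale,
        at_risk_counts=ar["n_at_risk"].to_numpy(),
        total_events=total_events,
    )


def write_km_csv(km: KMDigitization, km_path, atrisk_path, time_unit: str = "years") -> None:
    """Write a digitization back to the two-file CSV dialect."""
    scale = _TIME_UNIT_YEARS[time_unit]
    pd.DataFrame({"time": km.curve_times / scale, "survival": km.curve_survival}).to_csv(
        km_path, index=False)
    pd.DataFrame({"time": km.at_risk_times / scale, "n_at_risk": km.at_risk_counts}).to_csv(
        atrisk_path, index=False)


def write_ipd_csv(ipd: IPDSet, path, time_unit: str = "years") -> None:
    scale = _TIME_UNIT_YEARS[time_unit]
    pd.DataFrame({"time": ipd.times / scale, "event": ipd.events}).to_csv(path, index=False)


def read_ipd_csv(path, time_unit: str = "years") -> IPDSet:
    scale = _TIME_UNIT_YEARS[time_unit]
    df = pd.read_csv(path)
    return IPDSet(df["time"].to_numpy() * scale, df["event"].to_numpy())


# ---------------------------------------------------------------------------
# Guyot reconstruction
# ---------------------------------------------------------------------------

def guyot_reconstruct(km: KMDigitization) -> IPDSet:
    """Reconstruct pseudo-IPD from a digitized KM curve (Guyot algorithm).

    Censorings are spread uniformly across each at-risk interval's
    digitized sub-steps (the published default); event counts per click
    are chosen so the running product-limit estimate matches the
    digitized survival, and the censoring totals are iterated until the
    implied number at risk at each published at-risk time matches the
    table exactly.  Beyond the last published at-risk time no censoring
    is assumed unless ``total_events`` pins it down.
    """
    t = km.curve_times
    s = km.curve_survival
    rt, rc = km.at_risk_times, km.at_risk_counts

    # drop at-risk entries with zero counts: truncate curve there
    zero = np.where(rc == 0)[0]
    if len(zero) and rt[zero[0]] < t[-1]:
        cut = rt[zero[0]]
        logger.warning("at-risk count 0 at t=%.4g before end of curve; truncating", cut)
        keep = t <= cut
        t, s = t[keep], s[keep]
        rt, rc = rt[: zero[0]], rc[: zero[0]]
    if len(rt) == 0:
        raise KMValidationError("need at least one positive at-risk entry")
    K = len(t)

    # interval index of each click: clicks in [rt[i], rt[i+1]) belong to i;
    # the final interval extends to the end of the curve.
    lower = np.searchsorted(t, rt, side="left")
    bounds = list(lower) + [K]
    nI = len(rt)

    d = np.zeros(K, dtype=int)        # events at click k
    c = np.zeros(K, dtype=int)        # censorings in (t[k-1]? assigned to click k's slot)
    cen_t: list[list[float]] = [[] for _ in range(K)]

    n_hat = np.zeros(K + 1)
    n_hat[bounds[0]] = rc[0]
    KM_hat = np.ones(K)
    last_surv = 1.0  # reconstructed KM at the previous event click

    for i in range(nI):
        lo, hi = bounds[i], bounds[i + 1]
        if hi <= lo:
            continue
        n_start = rc[i]
        target = rc[i + 1] if i + 1 < nI else None
        t_end = rt[i + 1] if i + 1 < nI else t[-1]

        # initial censoring guess: at-risk drop not explained by KM events
        ncen = 0
        if target is not None:
            s_lo = max(s[lo], 1e-12)
            s_next = s[bounds[i + 1]] if bounds[i + 1] < K else s[-1]
            expected_events = int(round(n_start * (1.0 - s_next / s_lo)))
            ncen = max(0, int(n_start - target) - expected_events)
        # iterate censoring count until published at-risk matches
        best = None
        prev_guess = None
        for _ in range(60):
            d_i, c_i, cen_times, n_end, surv_end = _process_interval(
                t, s, lo, hi, n_start, ncen, t[lo] if i == 0 else rt[i], t_end,
                KM_prev=last_surv)
            if target is None:
                best = (d_i, c_i, cen_times, n_end, surv_end)
                break
            diff = n_end - int(target)
            best = (d_i, c_i, cen_times, n_end, surv_end)
            if diff == 0:
                break
            new_guess = ncen + diff
            if new_guess == prev_guess or new_guess < 0 or new_guess > n_start:
                break
            prev_guess = ncen
            ncen = new_guess
        d_i, c_i, cen_times, n_end, surv_end = best
        if target is not None and n_end != int(target):
            d_i, c_i, cen_times, n_end, surv_end = _enforce_target(
                d_i, c_i, cen_times, int(n_start), int(target), t_end, last_surv)
        d[lo:hi] = d_i
        c[lo:hi] = c_i
        for k in range(lo, hi):
            cen_t[k] = cen_times[k - lo]
        last_surv = surv_end
        if i + 1 < nI:
            n_hat[bounds[i + 1]] = n_end
        else:
            # patients still at risk at the end of the curve: censored there
            if n_end > 0:
                c[K - 1] += n_end
                cen_t[K - 1] = list(cen_t[K - 1]) + [float(t[-1])] * int(n_end)

    if km.total_events is not None:
        achieved = int(d.sum())
        if achieved != km.total_events:
            warnings.warn(
                f"total_events={km.total_events} not matched (achieved {achieved}); "
                "proceeding without the constraint", stacklevel=2)

    times, events = [], []
    for k in range(K):
        times.extend([t[k]] * d[k])
        events.extend([1] * d[k])
        times.extend(cen_t[k])
        events.extend([0] * len(cen_t[k]))
    if not times:
        # fully flat curve with no drops and no censoring: everyone censored at end
        times = [t[-1]] * int(rc[0])
        events = [0] * int(rc[0])
    times = np.maximum(np.asarray(times, dtype=float), 1e-12)
    return IPDSet(times, np.asarray(events))


def _enforce_target(d, c, cen_times, n_start, target, t_end, KM_prev):
    """Force the interval's closing at-risk count to the published value.

    Rounding of click-level event counts can leave a residual the
    censoring loop cannot absorb; the residual is resolved by trimming
    events from the last clicks (too many removals) or adding censorings
    at the interval end (too few), then the product-limit level is
    recomputed.
    """
    d = d.copy()
    c = c.copy()
    cen_times = [list(x) for x in cen_times]
    K = len(d)
    residual = (n_start - int(d.sum() + c.sum())) - target
    while residual < 0:                      # removed too many: trim events
        k = int(np.max(np.nonzero(d)[0])) if d.any() else None
        if k is None:
            if c.sum() == 0:
                break
            k = int(np.max(np.nonzero(c)[0]))
            c[k] -= 1
            cen_times[k].pop()
        else:
            d[k] -= 1
        residual += 1
    if residual > 0:                         # too few: censor at interval end
        c[K - 1] += residual
        cen_times[K - 1].extend([float(t_end)] * residual)
    # recompute the running KM level with the adjusted counts
    n = float(n_start)
    surv = KM_prev
    for k in range(K):
        if d[k] > 0 and n > 0:
            surv *= 1.0 - d[k] / n
        n -= d[k] + c[k]
    return d, c, cen_times, target, surv


def _process_interval(t, s, lo, hi, n_start, ncen, t_start, t_end, KM_prev):
    """One pass over clicks lo..hi-1 given a censoring total for the interval.

    Censor times are spread uniformly over (t_start, t_end]; each is
    assigned to the preceding click's slot so the running at-risk count
    is depleted in time order.  Returns per-click events/censorings, the
    censor times per click, the at-risk count at the end of the interval
    and the reconstructed KM level at the last event.
    """
    K = hi - lo
    d = np.zeros(K, dtype=int)
    c = np.zeros(K, dtype=int)
    cen_times: list[list[float]] = [[] for _ in range(K)]
    if ncen > 0:
        span = t_end - t_start
        pos = t_start + (np.arange(1, ncen + 1) - 0.5) / ncen * span
        # censor j occurs after the last click <= pos_j
        idx = np.searchsorted(t[lo:hi], pos, side="right") - 1
        idx = np.clip(idx, 0, K - 1)
        for j, k in enumerate(idx):
            c[k] += 1
            cen_times[k].append(float(pos[j]))

    n = float(n_start)
    surv = KM_prev
    for k in range(K):
        sk = s[lo + k]
        if surv > 0 and n > 0:
            dk = int(round(n * (1.0 - sk / surv)))
        else:
            dk = 0
        dk = max(0, min(dk, int(n)))
        d[k] = dk
        if dk > 0 and n > 0:
            surv = surv * (1.0 - dk / n)
        n -= dk + c[k]
        n = max(n, 0.0)
    return d, c, cen_times, int(round(n)), surv


# ---------------------------------------------------------------------------
# Product-limit estimation
# ---------------------------------------------------------------------------

def km_estimate(ipd: IPDSet) -> SurvivalCurve:
    """Kaplan–Meier estimate as a right-continuous step curve.

    The returned grid is [0, distinct event times...] carrying the
    post-drop survival values; use :func:`step_eval` for step-function
    evaluation at arbitrary times.
    """
    kmf = KaplanMeierFitter()
    kmf.fit(ipd.times, event_observed=ipd.events)
    sf = kmf.survival_function_
    times = sf.index.to_numpy(dtype=float)
    surv = sf.iloc[:, 0].to_numpy(dtype=float)
    if times[0] != 0.0:
        times = np.concatenate([[0.0], times])
        surv = np.concatenate([[1.0], surv])
    return SurvivalCurve(times, np.minimum.accumulate(np.clip(surv, 0, 1)))


def step_eval(curve: SurvivalCurve, t) -> np.ndarray:
    """Evaluate a step-represented curve right-continuously at times t."""
    idx = np.searchsorted(curve.times, np.asarray(t, dtype=float), side="right") - 1
    idx = np.clip(idx, 0, len(curve.times) - 1)
    return curve.survival[idx]
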