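"""Packaged model parameters and their typed accessors.

The printed parameter table of the source study (NMA coefficients,
reference-curve parameters, adverse-event profiles, unit prices,
utilities) ships as YAML under ``seqcea/data``; this module loads it and
exposes constructors for the objects the pipeline consumes.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .fp_nma import FPCoefficients, FPModelSpec
from .survival_fit import ParametricFit

_DATA = resources.files("seqcea") / "data"


def _load_yaml(name: str) -> dict:
    with (_DATA / name).open("r", encoding="utf-8") as fh:
        return yaml.safe_load(fh)


def load_tariff() -> dict:
    """The full parameter table (deep-copied so callers may mutate)."""
    return copy.deepcopy(_load_yaml("tariff.yaml"))


def load_regimens() -> dict:
    return copy.deepcopy(_load_yaml("regimens.yaml"))


def load_strategies() -> dict[str, dict]:
    return copy.deepcopy(_load_yaml("strategies.yaml"))["strategies"]


def load_life_table() -> pd.DataFrame:
    with (_DATA / "life_table_synthetic.csv").open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh)


# ---------------------------------------------------------------------------
# typed views
# ---------------------------------------------------------------------------

@dataclass
class NMABlock:
    """One NMA (e.g. first-line PFS): FP spec plus contrast coefficients."""

    spec: FPModelSpec
    reference: str
    basis_floor: float
    coefficients: dict[str, FPCoefficients]
    effect_horizons: dict[str, float | None]
    immunotherapy: dict[str, bool]


def nma_block(tariff: dict, which: str) -> NMABlock:
    """Build an :class:`NMABlock` for 'first_line_pfs', 'second_line_os' or
    'second_line_pfs'."""
    cfg = tariff["fp_nma"][which]
    spec = FPModelSpec(order=cfg["order"], powers=tuple(float(p) for p in cfg["powers"]))
    unit = float(cfg["time_unit_per_year"])
    coefs, horizons, immuno = {}, {}, {}
    for trt, c in cfg["contrasts"].items():
        coefs[trt] = FPCoefficients(
            treatment=trt, reference=cfg["reference"],
            d=np.asarray(c["d"], dtype=float),
            ci_low=np.asarray(c["ci_low"], dtype=float),
            ci_high=np.asarray(c["ci_high"], dtype=float),
            time_unit_per_year=unit,
        )
        horizons[trt] = c.get("effect_horizon_years")
        immuno[trt] = bool(c.get("immunotherapy", False))
    return NMABlock(spec, cfg["reference"], float(cfg["basis_floor"]), coefs,
                    horizons, immuno)


def reference_fit(tariff: dict, which: str) -> ParametricFit:
    """Parametric reference-curve model ('first_line_pfs_chemo', ...)."""
    cfg = tariff["reference_curves"][which]
    params = {k: float(v) for k, v in cfg["params"].items()}
    return ParametricFit(cfg["family"], params, loglik=float("nan"),
                         n_params=len(params))


FIRST_LINE_TREATMENTS = ("chemo", "N+C", "P+C", "T+C", "CA+C", "SI+C", "SU+C")
SECOND_LINE_TREATMENTS = ("docetaxel", "nivolumab", "tislelizumab")
STRATEGY_IDS = ("ND", "NT", "NN", "CD", "CT", "CN", "PED", "SID", "CAD", "TID", "SUD")
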