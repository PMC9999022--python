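#!/usr/bin/env python
"""Scenario analyses: alternative utilities, PAP prices, horizons, BSC cost.

1. utilities 0.804 (PFS) / 0.321 (PD);
2. utilities 0.877/0.823 (PFS immuno/chemo), 0.768/0.703 (PD1/end-stage);
3. patient-assistance-program prices for sugemalimab, nivolumab and
   pembrolizumab;
4. 5-, 10- and 20-year horizons;
5. third-line (BSC) cost swept 0-4,000 USD per cycle.
"""

import pathlib

import pandas as pd

from seqcea.sensitivity import run_scenario

OUT = pathlib.Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)


def main() -> None:
    for sid in (1, 2, 3):
        tab = run_scenario(sid)
        tab.to_csv(OUT / f"scenario{sid}.csv")
        print(f"--- scenario {sid}: best NMB = {tab['nmb'].idxmax()}")
        print(tab[["cost", "qaly", "nmb"]].round(3).to_string())

    out4 = run_scenario(4)
    frames = []
    for h, tab in out4.items():
        tab = tab.copy()
        tab["horizon_years"] = h
        frames.append(tab)
        print(f"--- scenario 4, horizon {h:.0f} y: best NMB = {tab['nmb'].idxmax()}")
    pd.concat(frames).to_csv(OUT / "scenario4.csv")

    out5 = run_scenario(5)
    frames = []
    for c, tab in out5.items():
        tab = tab.copy()
        tab["bsc_per_cycle"] = c
        frames.append(tab)
        print(f"--- scenario 5, third-line cost {c:.0f}/cycle: "
              f"best NMB = {tab['nmb'].idxmax()}")
    pd.concat(frames).to_csv(OUT / "scenario5.csv")
    print(f"\nwrote scenario1..5 CSVs under {OUT}")


if __name__ == "__main__":
    main()
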