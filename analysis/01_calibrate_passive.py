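#!/usr/bin/env python
"""Passive calibration of the CA1 PV-IN model.

Measures input resistance, membrane time constant and capacitance from
small current steps at rest, and checks them against the leak-only
analytic limit.  The published calibration for this cell is R_in =
80.6 MOhm, tau = 4.1 ms, C = 50.9 pF.
"""
import argparse
from pathlib import Path

import pandas as pd

from pvin import analysis as an
from pvin.integrate import resting_state
from pvin.params import load_params


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    p = load_params("ca1_chamberland_modified")
    props = an.measure_passive(p)
    rest = resting_state(p)

    leak_only = p.replace(g_Kv3=0.0, g_Kv1=0.0, g_Na=0.0)
    r_leak = 1.0 / (p.g_L * 1e-3 * p.area) / 1e6
    props_leak = an.measure_passive(leak_only)

    df = pd.DataFrame([
        {"variant": "ca1_full", **props.__dict__},
        {"variant": "leak_only", **props_leak.__dict__},
    ])
    out = args.out_dir / "passive_properties.csv"
    df.to_csv(out, index=False)

    print(f"resting potential: {rest[0]:.2f} mV (q at rest = {rest[5]:.3f})")
    print(f"R_in = {props.R_in_MOhm:.2f} MOhm  (leak-only analytic "
          f"{r_leak:.2f}, measured {props_leak.R_in_MOhm:.2f})")
    print(f"tau  = {props.tau_ms:.3f} ms (monoexponential fit, rmse "
          f"{props.fit_rmse_mV:.2g} mV)")
    print(f"C    = {props.C_pF:.2f} pF from tau = R C "
          f"(area fixes the true value at {p.C_total_pF:.1f} pF)")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
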