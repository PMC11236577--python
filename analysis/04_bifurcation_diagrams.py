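#!/usr/bin/env python
"""Fast/slow bifurcation diagrams with q as the parameter.

For each holding current, traces the equilibrium branch with
stability, locates the subcritical Hopf, follows the stable limit
cycle (V max/min and period) up to the saddle-node of periodics, and
estimates the unstable cycle's amplitude by basin-boundary bisection
inside the bistable window.
"""
import argparse
from pathlib import Path

import numpy as np

from pvin import bifurcation as bf
from pvin.params import load_params


def diagram(p, I_app, out_dir):
    branch = bf.continue_equilibria(p, I_app, (0.55, 0.0))
    hopf = bf.detect_hopf(branch, p, I_app_pA=I_app, classify=True)[0]
    snpo = bf.detect_snpo(p, I_app, tol=1e-3)
    branch.to_frame().to_csv(out_dir / f"eq_branch_{I_app:.0f}pA.csv",
                             index=False)

    cycles = bf.limit_cycle_branch(
        p, I_app,
        q_stable=np.linspace(0.0, snpo, 25),
        q_unstable=np.linspace(hopf.value + 0.01, snpo - 0.02, 8))
    cyc_df = cycles.to_frame()
    cyc_df.to_csv(out_dir / f"limit_cycles_{I_app:.0f}pA.csv", index=False)
    return hopf, snpo, cyc_df


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    p = load_params("ca1_chamberland_modified")
    for I_app in (450.0, 330.0):
        hopf, snpo, cyc = diagram(p, I_app, args.out_dir)
        stable = cyc[cyc.stable]
        print(f"I_app = {I_app:.0f} pA: subcritical Hopf at "
              f"q = {hopf.value:.5f}; SNPO at q = {snpo:.3f}; "
              f"bistable window width {snpo - hopf.value:.3f}; "
              f"cycle period {stable.period_ms.min():.1f}-"
              f"{stable.period_ms.max():.1f} ms")


if __name__ == "__main__":
    main()
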