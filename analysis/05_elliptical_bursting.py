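#!/usr/bin/env python
"""Elliptical bursting: the slow variable carries the fast subsystem
across the Hopf and the saddle-node of periodics.

At moderate current the Kv1 availability q climbs during spiking until
the stable cycle dies at the SNPO, the trajectory collapses onto the
depolarized fixed point, q decays back below the Hopf, and spiking
restarts.  This script documents where that alternation lives in this
model: at g_Kv1 = 5 mS/cm2 and 330 pA the cycle-equilibrium of q sits
just (~2%) below the SNPO, so firing is tonic there and the bursting
band sits at higher Kv1 conductance (or slightly lower current); the
g_Kv1 = 10 mS/cm2 row bursts with a multi-second period.
"""
import argparse
from pathlib import Path

import numpy as np

from pvin import bifurcation as bf
from pvin.integrate import integrate, resting_state
from pvin.params import load_params
from pvin.stimulus import step_protocol


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    ap.add_argument("--duration", type=float, default=8000.0)
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    p = load_params("ca1_chamberland_modified")
    for g, I in ((5.0, 330.0), (10.0, 330.0)):
        pp = p.replace(g_Kv1=g)
        res = integrate(pp, step_protocol(I, args.duration),
                        y0=resting_state(pp))
        label = bf.classify_trace(res.spike_times, args.duration)
        snpo = bf.detect_snpo(pp, I, tol=1e-3)
        tail = res.t > args.duration - 2000.0
        q_lo, q_hi = res.q[tail].min(), res.q[tail].max()
        out = args.out_dir / f"burst_trace_g{g:.0f}_I{I:.0f}.csv"
        res.export_csv(out, every=40)
        print(f"g_Kv1 = {g:.0f} mS/cm2, {I:.0f} pA: {label} "
              f"({res.spike_times.size} spikes in "
              f"{args.duration/1000:.0f} s); q range "
              f"[{q_lo:.3f}, {q_hi:.3f}] vs SNPO {snpo:.3f} -> {out}")


if __name__ == "__main__":
    main()
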