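#!/usr/bin/env python
"""Firing-regime phase diagram over (g_Kv1, I_app).

Classifies 3 s step responses on the published grid (current 0-1000 pA
in 30 pA increments, g_Kv1 0-10 mS/cm2 in 1 mS/cm2 steps) into
quiescent / transient / elliptical bursting / tonic.
"""
import argparse
import collections
from pathlib import Path

from pvin import bifurcation as bf
from pvin.params import load_params


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    p = load_params("ca1_chamberland_modified")
    grid = bf.regime_scan(p)
    df = grid.to_frame()
    out = args.out_dir / "phase_diagram.csv"
    df.to_csv(out)

    counts = collections.Counter(grid.labels.ravel())
    print(f"{df.shape[0]} x {df.shape[1]} grid: "
          + ", ".join(f"{k} {v}" for k, v in sorted(counts.items())))
    for g, I in ((0.0, 450.0), (2.0, 240.0), (5.0, 330.0)):
        print(f"  ({g:.0f} mS/cm2, {I:.0f} pA): {df.loc[g, I]}")
    print(f"wrote {out} (legend: {', '.join(bf.REGIMES)})")


if __name__ == "__main__":
    main()
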