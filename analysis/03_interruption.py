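#!/usr/bin/env python
"""Persistent interruption of tonic firing by a mock IPSP.

Runs the canonical noiseless protocol (450 pA hold; sharp 100 pA drop
then a 200 ms linear ramp back) and exports the voltage and q traces
together with the frozen-q equilibrium branch, so the trajectory can
be read against the bifurcation diagram: capture onto the depolarized
stable fixed point, slow leftward drift as q decays, passage through
the subcritical Hopf, and the growing subthreshold oscillation that
ends the silence.
"""
import argparse
from pathlib import Path

import numpy as np

from pvin import analysis as an
from pvin import bifurcation as bf
from pvin.params import load_params


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    p = load_params("ca1_chamberland_modified")
    res, out = an.run_interruption(p)
    trace_out = args.out_dir / "interruption_trace.csv"
    res.export_csv(trace_out, every=20)   # 0.5 ms resolution

    branch = bf.continue_equilibria(p, 450.0, (0.4, 0.0))
    hopf = bf.detect_hopf(branch, p, I_app_pA=450.0, classify=True)[0]
    branch_out = args.out_dir / "equilibrium_branch_450pA.csv"
    branch.to_frame().to_csv(branch_out, index=False)

    pre = res.spike_times[res.spike_times < out.offset_ms - 200.0]
    f_pre = 1000.0 / np.median(np.diff(pre[-50:]))
    t_resume = out.offset_ms + out.duration_ms
    i_hb = np.argmax((res.t > out.offset_ms)
                     & (res.q < hopf.value))
    print(f"tonic firing before the IPSP: {f_pre:.1f} Hz, q settles at "
          f"{res.q[int(out.offset_ms / res.dt) - 20000]:.3f}")
    print(f"noiseless interruption: {out.duration_ms:.0f} ms of silence "
          f"beyond the IPSP (pre-IPSP ISI {out.pre_isi_ms:.1f} ms)")
    print(f"subcritical Hopf at q = {hopf.value:.5f} "
          f"({hopf.criticality}); q crosses it at "
          f"t = {res.t[i_hb] - out.offset_ms:.0f} ms after offset, the "
          f"remaining {t_resume - res.t[i_hb]:.0f} ms is slow passage "
          f"along the weakly repelling branch")
    print(f"wrote {trace_out} and {branch_out}")


if __name__ == "__main__":
    main()
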