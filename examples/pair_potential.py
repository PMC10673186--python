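"""Membrane-mediated attraction between bound complexes: w(r) and B2.

Positions of bound complexes are snapshotted during the run; their pair
correlation g(r) under periodic minimum-image distances yields the
potential of mean force w(r) = -ln g(r) and the second virial coefficient
B2 = -pi * int (e^{-w} - 1) r dr. Suppressed membrane fluctuations around
each complex make w(r) < 0 (entropic attraction) and B2 < 0.
"""

import numpy as np

from memadh import McSchedule, ModelParams, run_simulation
from memadh.observables import complex_pair_correlation, second_virial

p = ModelParams(Lx=48, Ly=48, NL=22, lb=6.6)  # low density: strongest attraction
sch = McSchedule(n_cycles=120_000, n_equil=30_000, seed=1, snapshot_every=100)

traj = run_simulation(p, sch)
pf = complex_pair_correlation(traj, bin_width=15.0)
good = pf.counts >= 100

print("  r (nm)    g(r)     w(r) (kBT)  counts")
for r, g, w, c in zip(pf.r_centers[good][:8], pf.g[good][:8],
                      pf.w[good][:8], pf.counts[good][:8]):
    print(f"  {r:6.1f}  {g:7.3f}  {w:+9.3f}  {c:7d}")

vir = second_virial(pf)
print(f"max |w| over adequate bins: {np.nanmax(np.abs(pf.w[good])):.2f} kBT")
print(f"B2 = {vir.b2_um2:.4g} um^2 "
      f"(truncation sensitivity {vir.truncation_error_nm2 * 1e-6:.1g} um^2)")
# Contact attraction of a few tenths of kBT decaying with r; B2 < 0. In this
# sub-micron box the long-range tail of w(r) is cut off, so |B2| is well
# below the micron-box value; signs and trends are unaffected.
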