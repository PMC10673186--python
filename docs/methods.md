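# Methods

## Model

The package simulates a biomimetic adhesion geometry: a giant plasma
membrane vesicle (or any fluid membrane) carrying mobile ligands, adhering
to a flat substrate coated with immobilized receptors. The membrane is
discretized into square patches of edge `a = 15 nm`, one immobilized
receptor under each patch (receptor density `1/a^2 ~ 4400/um^2`). Patch `i`
carries a continuous separation `l_i > 0` (nm) from the substrate and a
binary occupancy `n_i` for a mobile ligand; at most one ligand per patch.

The Hamiltonian, in units of kBT, is `H = H_el + H_int` with

* bending energy `H_el = (kappa / 2 a^2) * sum_i (Lap l_i)^2`, where `Lap`
  is the 5-point lattice Laplacian with periodic boundaries (equal to twice
  the local mean curvature times `a^2` in the continuum limit). No tension
  and no spontaneous curvature: both vanish for the membranes this model
  targets, and are deliberately not configurable.
* binding energy `H_int = sum_i n_i V(l_i)` with the square well
  `V(l) = -U` for `|l - lb| < lwe/2`, else 0. The well edge itself is
  unbound (`Theta(0) = 0`); this measure-zero convention is fixed for
  reproducibility and has no physical effect.

A patch with an in-well ligand is a receptor-ligand complex ("bond").
The hard wall `l_i > 0` encodes steric repulsion from the passivated
substrate; no other non-specific interaction exists.

### Parameters

| symbol | meaning | default | origin |
|---|---|---|---|
| `a` | patch size (nm) | 15 | one receptor per patch at the plated density |
| `kappa` | bending rigidity (kBT) | 10 | flicker spectroscopy of vesicle membranes |
| `U` | well depth (kBT) | 9 | `K3D = a^2 lwe e^U` at Kd = 1 uM (see Calibration) |
| `lwe` | well width (nm) | 1.2 | flexibility of the bound complex |
| `lb` | rest separation (nm) | 7.8 | complex length minus passivation-layer thickness; swept 5.4-10.2 |
| `Lx, Ly` | lattice size | 400 x 400 | 6 um adhesion zone (A = 36 um^2) |
| `NL` | ligand count | 1080-3240 | 30-90 ligands/um^2 |

## Monte Carlo protocol

Two Metropolis move types: (i) vertical displacement of one patch height by
`u` uniform in [-1.5, +1.5] nm, rejected outright if `l + u <= 0`; (ii) hop
of one ligand to one of its four nearest-neighbour patches, rejected if
occupied, otherwise accepted with `min(1, e^{-dV})`. One cycle performs
`10 * Lx * Ly` vertical attempts then `NL` hop attempts (10:1 mix mirrors
the separation of undulation and diffusion time scales). Site and ligand
selection is uniform with replacement — this preserves detailed balance
without sequential-sweep artifacts; results are insensitive to the
alternative sweep ordering. Rejected attempts advance the clock (standard
Metropolis time convention).

Initial condition: flat membrane at `l = lb`, ligands on uniformly random
distinct patches. This starts fully bound and minimizes equilibration
transients; the first `n_equil` cycles (1/6 of the run by default) are
excluded from every analysis.

The compiled kernel keeps a cached Laplacian field, so a vertical move
needs five cached values:
`dH_el = (kappa/2a^2) (-8 u Lap_i + 2 u sum_nn Lap_k + 20 u^2)`.
An incremental-vs-recomputed energy test pins this bookkeeping to 1e-8 kBT
over 1e4 moves. The RNG is xorshift128+ seeded via splitmix64, owned by the
kernel: runs are bit-reproducible for a given seed and resumable in chunks.

Every change of the bond count is recorded with timestamp
`cycle + attempt_index / attempts_per_cycle` (events within one cycle stay
ordered and dwell times resolve below one cycle) plus a tag for the move
type that caused it.

## Observables

Scalar samples (bond count, spatial mean and mean square of `l`) are taken
every 10 cycles; bound-complex positions are snapshotted at a configurable
cadence. From the post-equilibration window:

* concentrations `[RL] = <n_b>/A`, `[L] = (NL - <n_b>)/A`,
  `[R] = (NR - <n_b>)/A` and the affinity `K2D = [RL]/([R][L])`, using the
  free receptor density as the defining equation states. Because
  `n_b << NR`, using the total receptor density instead changes K2D by
  <3%; both are exported (the figures-style convention multiplies K2D by
  the plated receptor density).
* roughness `xi = (<l^2> - <l>^2)^(1/2)` over space and time. For an
  unpinned membrane the mean height is a zero mode (it random-walks), so a
  per-frame spatial variance estimator is also provided; for adhered
  systems the two coincide.
* pair correlation `g(r)` of complex positions (patch centres — the model
  has no sub-patch resolution) with minimum-image periodic distances,
  binned at one lattice constant by default, normalized with exact annulus
  areas so an ideal gas gives `g = 1`. The potential of mean force is
  `w(r) = -ln g(r)`; bins are only interpreted where the pair count is
  adequate (>= 100 by default in the drivers).
* second virial coefficient `B2 = -pi int (e^{-w} - 1) r dr` by
  trapezoidal quadrature over the bins up to `r_cut` (half-box by default;
  the true integral extends to the ~1 um decay length of w, so sub-micron
  boxes bound the magnitude from below). Bins with `g = 0` inside a hard
  core contribute the full excluded-area term. The value recomputed at
  `0.8 r_cut` is reported as a truncation-sensitivity estimate.
* errors by block averaging (20 blocks) — appropriate for correlated MC
  series.

## Binding kinetics

Binding/unbinding events map the trajectory onto a birth-death chain over
the bond number `n` with `k+(n) = (NR-n)(NL-n) kon(n) / A` and
`k-(n) = n koff(n)`. Maximizing the dwell-time likelihood gives the
closed-form estimators

    kon(n) = Nn+ A / ((NR-n)(NL-n) Tn),    koff(n) = Nn- / (n Tn).

Leading/trailing window segments contribute dwell time but no counts (the
standard censored-dwell treatment). Near the dwell-weighted mean `n_bar`
the estimates plateau; the package reports the value at `round(n_bar)`
(falling back to the nearest defined state when a denominator vanishes
there, e.g. `kon` at `n = NL`) plus a dwell-weighted average over the
states covering the central 68% of dwell time as a robustness check.

**What counts as an event.** The geometric bond indicator
`|l_i - lb| < lwe/2` recrosses the sharp well edge many times per cycle
while a ligand sits on its receptor patch: the square well has a zero-width
barrier, so these vertical-move flips are diffusive recrossings with no
separation of time scales (coarse-graining the trace shows no rate
plateau), and counting them as dissociations would put koff near 13 1/s —
an order of magnitude above what surface-sensitive experiments report for
this pair. The kinetic analysis therefore counts as transitions only the
bond-count changes caused by ligand translocation: a dissociation is a
ligand leaving a receptor patch from within the binding range, an
association is a ligand arriving into it. Vertical in/out-of-well motion is
treated as internal breathing of the adhered state. Hop-driven bind and
unbind counts balance in equilibrium (each channel separately), so the
kinetic ratio kon/koff remains consistent with the thermodynamic K2D — a
property the suite asserts on every regression run. With this definition
`ln(koff tau) ~ -U`: unbinding is reaction-limited, and koff is insensitive
to membrane roughness, while kon inherits the `1/xi` roughness dependence
of the affinity.

Dwell times are in cycles; physical units follow from the cycle time
`tau = 60 us`, fixed by ligand diffusion (`D ~ 1 um^2/s` over a 15 nm
patch; note `a^2/D = 225 us` — the adopted 60 us corresponds to the
`a^2/4D` convention for 2D diffusion, and matches the equivalence of a
6e7-cycle run with about one hour of real time). `tau` is configurable
everywhere it enters.

## Calibration

`U = ln(K3D / (a^2 lwe))` with `K3D = 1/Kd`; at Kd = 1 uM, `a = 15 nm`,
`lwe = 1.2 nm` this gives 8.72 kBT, rounded to the integer 9 used in
production runs. Avogadro's number is the exact SI value. Concentration
conversions (`1 uM = 6.022e-7 nm^-3`) are exact to double precision.

## Synthetic data generators

The `experiments` module generates reference datasets with known ground
truth, used as oracles by the test suite:

* **Gaussian membranes** sampled spectrally with the exact lattice
  fluctuation spectrum `<|l_q|^2> = N a^2 / (kappa lambda_q^2)` — exact
  equilibrium samples of the free membrane (no wall, no ligands).
* **Poisson and hard-disk point patterns** for the g(r)/B2 pipeline (ideal
  gas gives `g = 1`; an exclusion core gives `g = 0` and the closed-form
  excluded-area virial).
* **Gillespie birth-death traces** with prescribed kon*, koff* for
  estimator recovery tests.

These generators emulate the *statistics* the analysis assumes, not the
dynamics of the interacting model: passing recovery tests demonstrates the
estimators and quadratures are correct, not that the MC model describes any
particular experiment. The simulation-facing checks (equipartition
roughness, frozen-field Boltzmann occupancy, pinned-site height density,
acceptance-rate oracle, detailed-balance consistency of K2D) close that
gap at small scale.

## Problem sizes and finite-box effects

Production-fidelity geometry is 400x400 patches (6 um box) and 6e7 cycles
(~1 h of physical time) — days of CPU time per condition. The package's
regression tier runs desk-scale systems chosen so that the *local*
observables are converged: 40x40-64x64 boxes (0.6-1 um), 1e5-3e5 cycles.
At these sizes K2D, xi, kon, koff are stable across box sizes (64x64 vs
128x128 agree within a few percent), while two quantities remain
box-limited by construction:

* the PMF range and |B2|: w(r) decays on the micron scale, so a sub-micron
  box truncates the attraction; desk-scale |B2| (~0.002-0.01 um^2) bounds
  the micron-box magnitude (~0.6 um^2) from below. Signs, bounds and
  orderings (w < 0, |w| < 2 kBT, B2 < 0, B2 increasing with concentration
  and rest length) are box-robust and are what the desk tier asserts.
* koff sits ~10% below its micron-box value (1.54-1.59 1/s at desk scale
  vs 1.7-1.8 at full scale): the probability that a neighbour patch lies
  outside the binding range grows with the long-wavelength roughness that
  only a large box supports. `ln(koff tau) ~ -U` holds at every scale.

## Numerical choices

* Lattice Laplacian: standard 5-point stencil (simplest scheme with the
  correct continuum limit for the bending energy).
* Energies in kBT, lengths in nm throughout the hot path; unit conversions
  only in `calibration` and at reporting boundaries.
* Event buffers grow geometrically; the kernel returns at a cycle boundary
  when headroom runs low and resumes exactly (RNG state, Laplacian cache
  and ligand table are caller-owned arrays).
* `koff(0)` and `kon(min(NR, NL))` are undefined, reported as NaN, never
  zero; states never visited are NaN likewise.
* g(r) bins with zero expected count are NaN; `w` is NaN wherever
  `g = 0`.
* Degenerate master-curve fits (x-range < 1.5x) are rejected rather than
  silently fitted.

## Known limitations

* Receptors are immobilized and saturate at one per patch; no receptor
  diffusion, no multi-ligand occupancy.
* No membrane tension or spontaneous curvature; no direct complex-complex
  interaction — all attraction is fluctuation-mediated.
* Proteins are structureless: conformational and rotational entropy of the
  binders is folded into U and lwe.
* Lateral resolution is one patch (15 nm) and temporal resolution one
  cycle (~60 us); sub-patch positioning of complexes does not exist, which
  imprints mild lattice artifacts on g(r) at the first few bins.
* The square well has no barrier: the geometric bond indicator flickers at
  the well edge, which is why kinetic events are defined at the
  translocation level (see above).
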