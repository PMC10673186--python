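"""Parameter sweeps, master-curve fits, and synthetic test-data generators.

The sweep driver reruns the full pipeline (simulation -> affinity,
roughness, kinetics, pair statistics) over a grid of rest separations lb
and ligand counts NL, one row per (lb, NL, seed). Two box presets are
provided: the full-fidelity geometry (400x400 patches, 6 um box, 6e7
cycles) and a desk-scale geometry (64x64 patches, ~1 um box) for which
local observables — affinity, roughness, rate constants — are converged,
while the magnitude of the micron-ranged pair potential and of B2 is
box-limited and comparable only in shape.

The central collapse is the master curve y = c / xi_perp: the product of
affinity and receptor density (or the on-rate constant) against membrane
roughness, fitted by one-parameter least squares.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kinetics import mle_rates, tally, to_physical, trace_from_trajectory
from .mc import McSchedule, run_simulation
from .model import ModelParams
from .observables import complex_pair_correlation, second_virial, summarize

__all__ = [
    "SweepSpec",
    "run_single",
    "run_sweep",
    "fit_master_curve",
    "make_fixtures",
    "gaussian_membrane_field",
    "poisson_pattern",
    "hard_disk_pattern",
    "gillespie_birth_death",
]


@dataclass(frozen=True)
class SweepSpec:
    """Grid of simulation conditions.

    lb_values in nm; NL_values are ligand counts on the given lattice;
    seeds are replicate RNG seeds per grid point.
    """

    Lx: int = 64
    Ly: int = 64
    lb_values: tuple[float, ...] = (5.4, 6.6, 7.8, 9.0, 10.2)
    NL_values: tuple[int, ...] = (28, 37, 46, 55, 65, 74, 83)
    seeds: tuple[int, ...] = (1, 2, 3)
    n_cycles: int = 2_000_000
    n_equil: int = 400_000
    sample_every: int = 10
    snapshot_every: int = 200
    tau_us: float = 60.0
    a: float = 15.0
    kappa: float = 10.0
    U: float = 9.0
    lwe: float = 1.2

    def __post_init__(self) -> None:
        # per-run parameter validation happens inside the sweep so that a bad
        # grid point is recorded as a failed row instead of aborting the grid
        if not self.lb_values or not self.NL_values or not self.seeds:
            raise ValueError("lb_values, NL_values and seeds must be non-empty")


def run_single(
    p: ModelParams, sch: McSchedule, tau_us: float = 60.0, bin_width: float | None = None
) -> dict:
    """One full pipeline run -> flat result record (a sweep-table row)."""
    traj = run_simulation(p, sch)
    s = summarize(traj)
    est = mle_rates(tally(trace_from_trajectory(traj)), p)
    ph = to_physical(est, tau_us)
    row = {
        "lb": p.lb,
        "NL": p.NL,
        "seed": sch.seed,
        "Lx": p.Lx,
        "Ly": p.Ly,
        "area_um2": p.area_um2,
        "RL_conc": s.RL_conc,
        "L_conc": s.L_conc,
        "R_conc": s.R_conc,
        "K2D_um2": s.K2D,
        "K2D_err": s.K2D_err,
        "K2D_total_receptor_um2": s.K2D_total_receptor,
        "mean_l_nm": s.mean_l,
        "roughness_nm": s.roughness,
        "roughness_err": s.roughness_err,
        "n_bonds_mean": s.n_bonds_mean,
        "n_bar": est.n_bar,
        "kon_nm2_cycle": est.kon,
        "koff_per_cycle": est.koff,
        "kon_um2_s": ph.kon,
        "koff_per_s": ph.koff,
        "koff_window_per_s": ph.koff_window,
        "K2D_kinetic_um2": est.K2D * 1e-6,
        "n_events": int(est.n_plus.sum() + est.n_minus.sum()),
    }
    try:
        pf = complex_pair_correlation(traj)
        vir = second_virial(pf)
        good = pf.counts >= 25  # bins with adequate statistics for w(r)
        row["B2_um2"] = vir.b2_um2
        row["B2_trunc_err_um2"] = vir.truncation_error_nm2 * 1e-6
        row["w_min_kbt"] = float(np.nanmin(pf.w[good])) if good.any() else np.nan
        row["w_max_abs_kbt"] = float(np.nanmax(np.abs(pf.w[good]))) if good.any() else np.nan
    except ValueError:
        row["B2_um2"] = np.nan
        row["B2_trunc_err_um2"] = np.nan
        row["w_min_kbt"] = np.nan
        row["w_max_abs_kbt"] = np.nan
    return row


def run_sweep(spec: SweepSpec, out_csv: str | None = None, progress: bool = False) -> pd.DataFrame:
    """Run the (lb, NL, seed) grid; rows are written incrementally if out_csv is given.

    A failed grid point is recorded with an ``error`` column and the sweep
    continues.
    """
    rows: list[dict] = []
    for lb in spec.lb_values:
        for NL in spec.NL_values:
            for seed in spec.seeds:
                try:
                    p = ModelParams(
                        a=spec.a, kappa=spec.kappa, U=spec.U, lwe=spec.lwe,
                        lb=lb, Lx=spec.Lx, Ly=spec.Ly, NL=NL,
                    )
                    sch = McSchedule(
                        n_cycles=spec.n_cycles, n_equil=spec.n_equil,
                        sample_every=spec.sample_every,
                        snapshot_every=spec.snapshot_every, seed=seed,
                    )
                    row = run_single(p, sch, spec.tau_us)
                except Exception as exc:  # record and continue
                    row = {"lb": lb, "NL": NL, "seed": seed, "error": str(exc)}
                rows.append(row)
                if progress:
                    print(f"lb={lb} NL={NL} seed={seed} done", flush=True)
                if out_csv is not None:
                    pd.DataFrame(rows).to_csv(out_csv, index=False)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class MasterCurveFit:
    """One-parameter fit y = c / x with per-group coefficients."""

    c: float
    residual_rms: float
    per_group_c: dict = field(default_factory=dict)


def fit_master_curve(
    x: np.ndarray, y: np.ndarray, groups: np.ndarray | None = None
) -> MasterCurveFit:
    """Least-squares fit of y = c / x (single parameter, residuals in y).

    Minimizing sum (y_i - c/x_i)^2 gives c = sum(y_i/x_i) / sum(1/x_i^2).
    With a ``groups`` label array the same fit is repeated per group, which
    quantifies how well different conditions collapse onto one curve.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    m = np.isfinite(x) & np.isfinite(y)
    x, y = x[m], y[m]
    if x.size < 4:
        raise ValueError("need at least 4 points for a master-curve fit")
    if x.max() / x.min() < 1.5:
        raise ValueError(
            f"degenerate x-range: max/min = {x.max() / x.min():.2f} < 1.5"
        )
    inv = 1.0 / x
    c = float((y * inv).sum() / (inv * inv).sum())
    rms = float(np.sqrt(np.mean((y - c * inv) ** 2)))
    per_group: dict = {}
    if groups is not None:
        groups = np.asarray(groups)[m]
        for gval in np.unique(groups):
            gm = groups == gval
            ginv = inv[gm]
            per_group[gval] = float((y[gm] * ginv).sum() / (ginv * ginv).sum())
    return MasterCurveFit(c=c, residual_rms=rms, per_group_c=per_group)


# ---------------------------------------------------------------------------
# Synthetic data generators (seeded, reproducible). These provide exact
# reference inputs for the analysis pipeline: Gaussian membranes with the
# exact lattice fluctuation spectrum, ideal-gas and hard-core point patterns
# for g(r)/B2, and birth-death event traces with known rate constants for
# the kinetics estimators.
# ---------------------------------------------------------------------------

def gaussian_membrane_field(
    Lx: int, Ly: int, kappa: float, a: float, rng: np.random.Generator, mean: float = 0.0
) -> np.ndarray:
    """Equilibrium sample of the free (unbound) membrane by spectral sampling.

    Fourier modes of the discrete bending Hamiltonian are independent
    Gaussians with <|l_q|^2> = N a^2 / (kappa lambda_q^2),
    lambda_q = 4 - 2cos(qx a) - 2cos(qy a); the zero mode is set to
    ``mean``. Returns an (Lx, Ly) field in nm.
    """
    w = rng.standard_normal((Lx, Ly))
    wq = np.fft.fft2(w)  # <|wq|^2> = N
    mx = 2.0 * np.pi * np.arange(Lx) / Lx
    my = 2.0 * np.pi * np.arange(Ly) / Ly
    lam = 4.0 - 2.0 * np.cos(mx)[:, None] - 2.0 * np.cos(my)[None, :]
    amp = np.zeros_like(lam)
    nz = lam != 0
    amp[nz] = a / (np.sqrt(kappa) * lam[nz])
    field = np.fft.ifft2(wq * amp).real
    return field + mean


def poisson_pattern(
    rho_per_um2: float, box_nm: tuple[float, float], rng: np.random.Generator
) -> np.ndarray:
    """Ideal-gas point pattern: Poisson count, uniform positions (nm)."""
    Bx, By = box_nm
    n = rng.poisson(rho_per_um2 * Bx * By * 1e-6)
    return rng.uniform((0.0, 0.0), (Bx, By), size=(n, 2))


def hard_disk_pattern(
    n: int,
    sigma_nm: float,
    box_nm: tuple[float, float],
    rng: np.random.Generator,
    n_sweeps: int = 200,
) -> np.ndarray:
    """Periodic hard-disk configuration (exclusion diameter sigma) by MC.

    Random sequential insertion followed by local displacement sweeps;
    valid at low packing fraction.
    """
    Bx, By = box_nm
    pts = np.empty((n, 2))
    placed = 0
    attempts = 0
    while placed < n:
        attempts += 1
        if attempts > 100_000 * n:
            raise RuntimeError("hard-disk insertion failed: packing too dense")
        q = rng.uniform((0.0, 0.0), (Bx, By))
        d = pts[:placed] - q
        d[:, 0] -= Bx * np.round(d[:, 0] / Bx)
        d[:, 1] -= By * np.round(d[:, 1] / By)
        if placed == 0 or (d**2).sum(axis=1).min() >= sigma_nm**2:
            pts[placed] = q
            placed += 1
    step = sigma_nm
    for _ in range(n_sweeps):
        for i in range(n):
            q = np.mod(pts[i] + rng.uniform(-step, step, 2), (Bx, By))
            d = np.delete(pts, i, axis=0) - q
            d[:, 0] -= Bx * np.round(d[:, 0] / Bx)
            d[:, 1] -= By * np.round(d[:, 1] / By)
            if (d**2).sum(axis=1).min() >= sigma_nm**2:
                pts[i] = q
    return pts


def gillespie_birth_death(
    kon: float,
    koff: float,
    p: ModelParams,
    t_end: float,
    rng: np.random.Generator,
    n0: int = 0,
):
    """Exact stochastic simulation of the bond-number birth-death chain.

    Propensities k+(n) = (NR-n)(NL-n) kon / A and k-(n) = n koff with kon in
    nm^2/cycle, koff in 1/cycle, A in nm^2. Returns an
    :class:`~memadh.kinetics.EventTrace` on [0, t_end].
    """
    from .kinetics import EventTrace

    NR, NL, A = p.n_receptors, p.NL, p.area_nm2
    n = n0
    t = 0.0
    times: list[float] = []
    ns: list[int] = []
    nmax = min(NR, NL)
    while True:
        a_plus = (NR - n) * (NL - n) * kon / A if n < nmax else 0.0
        a_minus = n * koff
        a_tot = a_plus + a_minus
        if a_tot <= 0:
            break
        t += rng.exponential(1.0 / a_tot)
        if t >= t_end:
            break
        n += 1 if rng.random() < a_plus / a_tot else -1
        times.append(t)
        ns.append(n)
    return EventTrace(
        times=np.array(times), n_after=np.array(ns, dtype=np.int64),
        t_start=0.0, t_end=t_end, n_initial=n0,
    )


def make_fixtures(kind: str, params: dict, seed: int):
    """Dispatch synthetic-dataset generation by kind.

    Kinds: ``gaussian_membrane``, ``poisson``, ``hard_disk``,
    ``birth_death``. All outputs are deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    if kind == "gaussian_membrane":
        return gaussian_membrane_field(
            params["Lx"], params["Ly"], params["kappa"], params["a"], rng,
            params.get("mean", 0.0),
        )
    if kind == "poisson":
        return poisson_pattern(params["rho_per_um2"], params["box_nm"], rng)
    if kind == "hard_disk":
        return hard_disk_pattern(
            params["n"], params["sigma_nm"], params["box_nm"], rng,
            params.get("n_sweeps", 200),
        )
    if kind == "birth_death":
        return gillespie_birth_death(
            params["kon"], params["koff"], params["model"], params["t_end"], rng,
            params.get("n0", 0),
        )
    raise ValueError(f"unknown fixture kind: {kind!r}")
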