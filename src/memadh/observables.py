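"""Equilibrium observables of the adhering membrane.

From a trajectory this module extracts:

* the area concentrations of complexes [RL], free ligands [L] and free
  receptors [R], and the two-dimensional affinity K2D = [RL]/([R][L]);
* the mean separation <l> and the membrane roughness
  xi_perp = (<l^2> - <l>^2)^(1/2), the standard deviation of the separation
  field over space and time;
* the pair correlation function g(r) of bound complexes under periodic
  minimum-image distances, the potential of mean force w(r) = -ln g(r)
  (kBT), and the second virial coefficient

      B2 = -pi * integral_0^rcut (e^{-w(r)} - 1) r dr

  of the effective complex-complex interaction (negative = net attraction).

Statistical errors on scalar observables come from block averaging (20
blocks by default), appropriate for correlated Monte Carlo series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import ModelParams

__all__ = [
    "ObservableSummary",
    "PairFunction",
    "VirialResult",
    "block_average",
    "summarize",
    "pair_correlation",
    "complex_pair_correlation",
    "second_virial",
    "free_membrane_roughness_sq",
]


def block_average(series: np.ndarray, n_blocks: int = 20) -> tuple[float, float]:
    """Mean and standard error of a correlated series via block averaging."""
    x = np.asarray(series, dtype=np.float64)
    if x.size == 0:
        return np.nan, np.nan
    nb = min(n_blocks, x.size)
    blocks = np.array_split(x, nb)
    means = np.array([b.mean() for b in blocks])
    err = means.std(ddof=1) / np.sqrt(nb) if nb > 1 else np.nan
    return float(x.mean()), float(err)


@dataclass(frozen=True)
class ObservableSummary:
    """Time-averaged equilibrium quantities of one run with standard errors.

    Concentrations are per um^2; K2D in um^2. ``K2D_total_receptor`` uses
    the total receptor density NR/A instead of the free one — the convention
    in which affinities are often reported against the plated receptor
    concentration; with n_bonds << NR the two differ by a few percent at
    most. ``roughness`` is the full space-and-time standard deviation of l;
    ``frame_roughness`` averages the per-frame spatial variance instead,
    which discards drift of the mean height (the appropriate estimator for
    an unpinned membrane, whose mean height performs a random walk).
    """

    RL_conc: float
    L_conc: float
    R_conc: float
    K2D: float
    K2D_total_receptor: float
    mean_l: float
    roughness: float
    frame_roughness: float
    RL_err: float
    L_err: float
    R_err: float
    K2D_err: float
    mean_l_err: float
    roughness_err: float
    n_bonds_mean: float
    n_samples: int
    K2D_defined: bool = True


def summarize(traj, n_blocks: int = 20) -> ObservableSummary:
    """Equilibrium summary of a trajectory's post-equilibration samples."""
    p: ModelParams = traj.params
    m = traj.post_equil_mask()
    nb = traj.sample_nb[m].astype(np.float64)
    ml = traj.sample_mean_l[m]
    ml2 = traj.sample_mean_l2[m]
    if nb.size == 0:
        raise ValueError("trajectory has no post-equilibration samples")
    A = p.area_um2
    NR, NL = p.n_receptors, p.NL

    nb_mean, nb_err = block_average(nb, n_blocks)
    rl = nb_mean / A
    free_l = (NL - nb_mean) / A
    free_r = (NR - nb_mean) / A
    defined = free_l > 0 and free_r > 0

    # per-block K2D spread captures the correlated fluctuations of nb
    blocks = np.array_split(nb, min(n_blocks, nb.size))
    with np.errstate(divide="ignore", invalid="ignore"):
        k2d_blocks = np.array(
            [b.mean() / A / (((NL - b.mean()) / A) * ((NR - b.mean()) / A)) for b in blocks]
        )
    k2d = rl / (free_l * free_r) if defined else np.nan
    finite_blocks = k2d_blocks[np.isfinite(k2d_blocks)]
    k2d_err = (
        float(finite_blocks.std(ddof=1) / np.sqrt(finite_blocks.size))
        if defined and finite_blocks.size > 1
        else np.nan
    )
    k2d_tot = rl / (free_l * (NR / A)) if free_l > 0 else np.nan

    ml_mean, ml_err = block_average(ml, n_blocks)
    ml2_mean, _ = block_average(ml2, n_blocks)
    rough_sq = ml2_mean - ml_mean**2
    rough = float(np.sqrt(max(rough_sq, 0.0)))
    frame_rough = float(np.sqrt(max(np.mean(ml2 - ml * ml), 0.0)))
    # error of xi via blocks of the second moment
    rblocks = np.array_split(np.arange(nb.size), min(n_blocks, nb.size))
    xi_blocks = [
        np.sqrt(max(ml2[ix].mean() - ml[ix].mean() ** 2, 0.0)) for ix in rblocks
    ]
    rough_err = (
        float(np.std(xi_blocks, ddof=1) / np.sqrt(len(xi_blocks)))
        if len(xi_blocks) > 1
        else np.nan
    )

    return ObservableSummary(
        RL_conc=rl,
        L_conc=free_l,
        R_conc=free_r,
        K2D=k2d,
        K2D_total_receptor=k2d_tot,
        mean_l=ml_mean,
        roughness=rough,
        frame_roughness=frame_rough,
        RL_err=nb_err / A,
        L_err=nb_err / A,
        R_err=nb_err / A,
        K2D_err=k2d_err,
        mean_l_err=ml_err,
        roughness_err=rough_err,
        n_bonds_mean=nb_mean,
        n_samples=int(nb.size),
        K2D_defined=bool(defined),
    )


@dataclass(frozen=True)
class PairFunction:
    """Binned pair statistics: g(r), w(r) = -ln g(r), raw pair counts.

    Radii in nm; w in kBT, NaN where g = 0. Normalization is to an ideal
    gas at the same instantaneous particle number, using exact annulus
    areas, so a Poisson pattern gives g identically 1 up to counting noise.
    """

    r_centers: np.ndarray
    r_edges: np.ndarray
    g: np.ndarray
    w: np.ndarray
    counts: np.ndarray
    expected: np.ndarray
    n_snapshots: int
    box: tuple[float, float]


def pair_correlation(
    snapshots: list[np.ndarray],
    box: tuple[float, float],
    bin_width: float,
    r_max: float | None = None,
) -> PairFunction:
    """2D pair correlation of point patterns under periodic boundaries.

    Parameters
    ----------
    snapshots : list of (k, 2) arrays
        Particle positions (nm) in each configuration; snapshots with
        fewer than two particles contribute nothing.
    box : (Bx, By)
        Periodic box edge lengths (nm). Minimum-image distances are used,
        so r_max may not exceed half the shorter edge.
    bin_width : float
        Radial bin width (nm); the natural choice is the lattice constant.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    Bx, By = box
    half = min(Bx, By) / 2.0
    if r_max is None:
        r_max = half
    if r_max > half + 1e-9:
        raise ValueError(f"r_max={r_max} exceeds half-box {half}")
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    edges = edges[edges <= r_max + 1e-9]
    if edges[-1] < r_max - 1e-9:
        edges = np.append(edges, r_max)
    nbins = edges.size - 1
    counts = np.zeros(nbins, dtype=np.int64)
    area = Bx * By
    annulus = np.pi * (edges[1:] ** 2 - edges[:-1] ** 2)
    expected = np.zeros(nbins, dtype=np.float64)
    used = 0
    for pts in snapshots:
        pts = np.asarray(pts, dtype=np.float64)
        k = pts.shape[0]
        if k < 2:
            continue
        used += 1
        d = pts[:, None, :] - pts[None, :, :]
        d[..., 0] -= Bx * np.round(d[..., 0] / Bx)
        d[..., 1] -= By * np.round(d[..., 1] / By)
        r = np.sqrt((d**2).sum(axis=-1))
        iu = np.triu_indices(k, 1)
        counts += np.histogram(r[iu], bins=edges)[0]
        expected += k * (k - 1) / 2.0 * annulus / area
    if used == 0:
        raise ValueError("need at least one snapshot with >= 2 particles")
    with np.errstate(divide="ignore", invalid="ignore"):
        g = np.where(expected > 0, counts / expected, np.nan)
        w = np.where(g > 0, -np.log(g), np.nan)
    return PairFunction(
        r_centers=0.5 * (edges[:-1] + edges[1:]),
        r_edges=edges,
        g=g,
        w=w,
        counts=counts,
        expected=expected,
        n_snapshots=used,
        box=(float(Bx), float(By)),
    )


def complex_pair_correlation(
    traj, bin_width: float | None = None, r_max: float | None = None
) -> PairFunction:
    """g(r) and w(r) of bound complexes from trajectory snapshots.

    Complex positions are patch centres (lattice coordinates times a);
    sub-patch resolution does not exist in the model. Default bin width is
    one lattice constant.
    """
    p: ModelParams = traj.params
    if bin_width is None:
        bin_width = p.a
    pts = []
    for _, sites in traj.iter_snapshots(post_equil=True):
        xy = np.column_stack((sites // p.Ly, sites % p.Ly)).astype(np.float64) * p.a
        pts.append(xy)
    return pair_correlation(pts, (p.Lx * p.a, p.Ly * p.a), bin_width, r_max)


@dataclass(frozen=True)
class VirialResult:
    """Second virial coefficient with a truncation-sensitivity estimate (nm^2)."""

    b2_nm2: float
    b2_inner_nm2: float  # same integral truncated at 0.8 * r_cut
    r_cut: float

    @property
    def b2_um2(self) -> float:
        return self.b2_nm2 * 1e-6

    @property
    def truncation_error_nm2(self) -> float:
        return abs(self.b2_nm2 - self.b2_inner_nm2)


def second_virial(pf: PairFunction, r_cut: float | None = None) -> VirialResult:
    """B2 = -pi * int (e^{-w} - 1) r dr by trapezoidal quadrature over bins.

    Bins with g = 0 (inside a hard core) contribute the full excluded-area
    term, since e^{-w} - 1 = -1 there. The integral is truncated at r_cut
    (default: the largest binned radius, itself at most half the box); the
    value recomputed at 0.8 * r_cut quantifies truncation sensitivity.
    """
    if r_cut is None:
        r_cut = float(pf.r_edges[-1])
    m = pf.r_centers <= r_cut
    r = pf.r_centers[m]
    h = np.where(np.isnan(pf.g[m]), 0.0, pf.g[m]) - 1.0  # e^{-w} - 1 = g - 1
    integrand = np.concatenate(([0.0], h * r))
    r = np.concatenate(([0.0], r))
    b2 = -np.pi * np.trapezoid(integrand, r)
    mi = r <= 0.8 * r_cut
    b2_inner = -np.pi * np.trapezoid(integrand[mi], r[mi])
    return VirialResult(b2_nm2=float(b2), b2_inner_nm2=float(b2_inner), r_cut=float(r_cut))


def free_membrane_roughness_sq(Lx: int, Ly: int, kappa: float, a: float) -> float:
    """Equipartition roughness of the free (unbound, wall-free) membrane.

    For the discretized bending Hamiltonian the Fourier modes are
    independent Gaussians, giving

        xi^2 = (a^2 / (kappa N)) * sum_{q != 0} 1 / lambda_q^2,
        lambda_q = 4 - 2 cos(qx a) - 2 cos(qy a),

    with N = Lx * Ly. The q = 0 mode is the free translation of the mean
    height and is excluded; the sum therefore predicts the mean per-frame
    spatial variance.
    """
    mx = 2.0 * np.pi * np.arange(Lx) / Lx
    my = 2.0 * np.pi * np.arange(Ly) / Ly
    lam = 4.0 - 2.0 * np.cos(mx)[:, None] - 2.0 * np.cos(my)[None, :]
    lam[0, 0] = np.inf
    return float(a**2 / (kappa * Lx * Ly) * np.sum(1.0 / lam**2))
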