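"""Lattice model of a membrane adhering to a receptor-coated surface.

The membrane is a square lattice of patches of edge length ``a``. Each patch
``i`` carries a real separation ``l_i`` (nm) between the membrane and the
substrate, and a binary occupancy ``n_i`` marking whether a mobile ligand sits
on the patch. One immobilized receptor sits beneath every patch. A ligand is
bound (forms a receptor-ligand complex) when its patch separation lies inside
a square well of depth ``U``, width ``l_we``, centred at ``l_b``.

The Hamiltonian, in units of kBT, is

    H{l, n} = H_el{l} + H_int{l, n}

with the discretized bending energy

    H_el = (kappa / 2 a^2) * sum_i (Lap l_i)^2

where ``Lap`` is the 5-point lattice Laplacian with periodic wrap, and the
binding energy

    H_int = sum_i n_i V(l_i),    V(l) = -U * Theta(l_we/2 - |l - l_b|).

The Heaviside convention is Theta(x) = 1 for x > 0 and 0 otherwise, so a
separation exactly on the well edge counts as unbound. The membrane carries
no tension and no spontaneous curvature; the only non-specific interaction is
an optional hard wall ``l_i > 0`` representing steric repulsion from the
passivated substrate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ModelParams",
    "SystemState",
    "discrete_laplacian",
    "laplacian_field",
    "bending_energy",
    "binding_potential",
    "bond_field",
    "interaction_energy",
    "total_energy",
    "delta_energy_vertical",
]


@dataclass(frozen=True)
class ModelParams:
    """Physical and lattice parameters of the adhesion model.

    Parameters
    ----------
    a : float
        Patch edge length in nm. Default 15 nm, matching one immobilized
        receptor per patch at a surface density of 1/a^2.
    kappa : float
        Membrane bending rigidity in kBT. Default 10.
    U : float
        Depth of the receptor-ligand binding well in kBT. Default 9.
    lwe : float
        Width of the binding well in nm. Default 1.2.
    lb : float
        Centre of the binding well (rest separation of the bound complex) in
        nm. Default 7.8.
    Lx, Ly : int
        Lattice dimensions in patches.
    NL : int
        Number of mobile ligands (at most one per patch).
    NR : int or None
        Number of immobilized receptors. ``None`` means one receptor per
        patch, NR = Lx * Ly.
    hard_wall : bool
        Enforce l_i > 0 (steric repulsion from the substrate).
    """

    a: float = 15.0
    kappa: float = 10.0
    U: float = 9.0
    lwe: float = 1.2
    lb: float = 7.8
    Lx: int = 400
    Ly: int = 400
    NL: int = 1800
    NR: int | None = None
    hard_wall: bool = True

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError(f"patch size a must be positive, got {self.a}")
        if self.kappa <= 0:
            raise ValueError(f"bending rigidity kappa must be positive, got {self.kappa}")
        if self.U < 0:
            raise ValueError(f"well depth U must be non-negative, got {self.U}")
        if self.lwe <= 0:
            raise ValueError(f"well width lwe must be positive, got {self.lwe}")
        if self.hard_wall and self.lb <= self.lwe / 2:
            raise ValueError(
                f"binding well crosses the hard wall: lb={self.lb} <= lwe/2={self.lwe / 2}"
            )
        if self.Lx < 3 or self.Ly < 3:
            raise ValueError(f"lattice must be at least 3x3, got {self.Lx}x{self.Ly}")
        if not 0 <= self.NL <= self.Lx * self.Ly:
            raise ValueError(
                f"ligand count NL={self.NL} outside [0, {self.Lx * self.Ly}] (one per patch)"
            )
        if self.NR is not None and self.NR <= 0:
            raise ValueError(f"receptor count NR must be positive, got {self.NR}")

    @property
    def n_receptors(self) -> int:
        """Receptor count; defaults to one per patch."""
        return self.Lx * self.Ly if self.NR is None else self.NR

    @property
    def n_patches(self) -> int:
        return self.Lx * self.Ly

    @property
    def area_nm2(self) -> float:
        """Adhesion-zone area A = Lx * Ly * a^2 in nm^2 (always derived)."""
        return self.Lx * self.Ly * self.a**2

    @property
    def area_um2(self) -> float:
        return self.area_nm2 * 1e-6


@dataclass
class SystemState:
    """Full Monte Carlo configuration: separation field + ligand occupancy.

    ``l`` has shape (Lx, Ly) in nm; ``n`` is a 0/1 array of the same shape.
    The bound indicator is never stored: it is a pure function of (l, n).
    """

    l: np.ndarray
    n: np.ndarray

    def __post_init__(self) -> None:
        self.l = np.asarray(self.l, dtype=np.float64)
        self.n = np.asarray(self.n, dtype=np.int8)
        if self.l.shape != self.n.shape or self.l.ndim != 2:
            raise ValueError("l and n must be 2-D arrays of identical shape")

    @property
    def n_ligands(self) -> int:
        return int(self.n.sum())

    def validate(self, p: ModelParams) -> None:
        if self.l.shape != (p.Lx, p.Ly):
            raise ValueError(f"state shape {self.l.shape} != lattice {(p.Lx, p.Ly)}")
        if self.n_ligands != p.NL:
            raise ValueError(f"ligand count {self.n_ligands} != NL={p.NL}")
        if p.hard_wall and not (self.l > 0).all():
            raise ValueError("hard wall violated: some l_i <= 0")
        if not np.isin(self.n, (0, 1)).all():
            raise ValueError("occupancy n must be 0/1")


def laplacian_field(l: np.ndarray) -> np.ndarray:
    """5-point lattice Laplacian of the whole field with periodic wrap (nm)."""
    l = np.asarray(l, dtype=np.float64)
    return (
        np.roll(l, 1, axis=0)
        + np.roll(l, -1, axis=0)
        + np.roll(l, 1, axis=1)
        + np.roll(l, -1, axis=1)
        - 4.0 * l
    )


def discrete_laplacian(l: np.ndarray, i: tuple[int, int]) -> float:
    """Lattice Laplacian at a single patch, periodic in both directions.

    Equal to twice the local mean curvature times a^2 in the continuum limit;
    exactly zero for any field affine in the lattice coordinates.
    """
    l = np.asarray(l, dtype=np.float64)
    Lx, Ly = l.shape
    ix, iy = i
    return float(
        l[(ix + 1) % Lx, iy]
        + l[(ix - 1) % Lx, iy]
        + l[ix, (iy + 1) % Ly]
        + l[ix, (iy - 1) % Ly]
        - 4.0 * l[ix, iy]
    )


def bending_energy(l: np.ndarray, p: ModelParams) -> float:
    """Helfrich bending energy on the lattice, (kappa/2a^2) sum_i (Lap l_i)^2, in kBT."""
    lap = laplacian_field(l)
    return float(p.kappa / (2.0 * p.a**2) * np.sum(lap * lap))


def binding_potential(li: float | np.ndarray, p: ModelParams) -> float | np.ndarray:
    """Square-well receptor-ligand potential V(l) in kBT.

    Returns -U strictly inside the well |l - lb| < lwe/2 and 0 outside;
    the well edge itself is outside (Theta(0) = 0).
    """
    inside = np.abs(np.asarray(li) - p.lb) < p.lwe / 2
    v = np.where(inside, -p.U, 0.0)
    return float(v) if np.isscalar(li) else v


def bond_field(s: SystemState, p: ModelParams) -> np.ndarray:
    """0/1 indicator of receptor-ligand complexes: occupied patch inside the well."""
    return ((s.n == 1) & (np.abs(s.l - p.lb) < p.lwe / 2)).astype(np.int8)


def interaction_energy(s: SystemState, p: ModelParams) -> float:
    """Total binding energy sum_i n_i V(l_i) = -U * (number of complexes), in kBT."""
    return -p.U * float(bond_field(s, p).sum())


def total_energy(s: SystemState, p: ModelParams) -> float:
    return bending_energy(s.l, p) + interaction_energy(s, p)


def delta_energy_vertical(
    s: SystemState, i: tuple[int, int], l_new: float, p: ModelParams
) -> float:
    """Energy change of displacing patch ``i`` to separation ``l_new``, in kBT.

    Only the five Laplacians that involve the displaced site change, so the
    evaluation touches the 13-site stencil neighbourhood; the result equals
    the full-energy difference exactly (up to roundoff). The caller is
    responsible for screening hard-wall violations (l_new <= 0) beforehand.
    """
    Lx, Ly = s.l.shape
    ix, iy = i
    if not (0 <= ix < Lx and 0 <= iy < Ly):
        raise IndexError(f"patch index {i} outside {Lx}x{Ly} lattice")
    u = l_new - s.l[ix, iy]
    pref = p.kappa / (2.0 * p.a**2)
    lap_c = discrete_laplacian(s.l, (ix, iy))
    lap_nn = (
        discrete_laplacian(s.l, ((ix + 1) % Lx, iy))
        + discrete_laplacian(s.l, ((ix - 1) % Lx, iy))
        + discrete_laplacian(s.l, (ix, (iy + 1) % Ly))
        + discrete_laplacian(s.l, (ix, (iy - 1) % Ly))
    )
    # (lap_c - 4u)^2 - lap_c^2 at the site; (lap_k + u)^2 - lap_k^2 at each neighbour
    d_el = pref * (-8.0 * u * lap_c + 2.0 * u * lap_nn + 20.0 * u * u)
    d_int = 0.0
    if s.n[ix, iy] == 1:
        d_int = binding_potential(l_new, p) - binding_potential(float(s.l[ix, iy]), p)
    return float(d_el + d_int)
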