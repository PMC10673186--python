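"""Physical-unit bridge between the lattice model and experiment.

The binding-well depth U is calibrated from the solution-phase dissociation
constant of the receptor-ligand pair via

    K3D = a^2 * lwe * exp(U / kBT)

which identifies the bound-state volume per receptor site with a^2 * lwe.
Physical time enters through the duration tau of one MC cycle, fixed by
matching ligand diffusion: with a patch size of 15 nm and a membrane-protein
diffusion coefficient of about 1 um^2/s, tau is approximately 60 us, so a
60-million-cycle run covers about one hour of real time.

All energies are in kBT at room temperature; lengths in nm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "AVOGADRO",
    "PhysicalConstants",
    "micromolar_to_per_nm3",
    "per_nm3_to_micromolar",
    "binding_energy_from_k3d",
    "k3d_from_binding_energy",
    "simulated_physical_time",
]

AVOGADRO = 6.02214076e23  # exact (SI)

# 1 uM = 1e-6 mol/L * N_A / (1e24 nm^3/L)
_UM_TO_PER_NM3 = 1e-6 * AVOGADRO * 1e-24


def micromolar_to_per_nm3(c_um: float) -> float:
    """Convert a concentration in micromolar to number density in nm^-3."""
    if c_um < 0:
        raise ValueError("concentration must be non-negative")
    return c_um * _UM_TO_PER_NM3


def per_nm3_to_micromolar(c_nm3: float) -> float:
    """Inverse of :func:`micromolar_to_per_nm3`."""
    if c_nm3 < 0:
        raise ValueError("density must be non-negative")
    return c_nm3 / _UM_TO_PER_NM3


def binding_energy_from_k3d(
    a: float, lwe: float, kd_um: float
) -> tuple[float, int]:
    """Well depth U (kBT) from the 3D dissociation constant.

    Inverts K3D = a^2 * lwe * e^U with K3D = 1/Kd in nm^3. Returns the raw
    value and its nearest integer (the model uses integer-kBT well depths).
    A Kd so large that K3D < a^2*lwe would give U < 0, i.e. binding weaker
    than the entropic volume factor — unphysical for an adhesive bond here.
    """
    if a <= 0 or lwe <= 0 or kd_um <= 0:
        raise ValueError("a, lwe and Kd must be positive")
    k3d_nm3 = 1.0 / micromolar_to_per_nm3(kd_um)
    U = float(np.log(k3d_nm3 / (a * a * lwe)))
    if U < 0:
        raise ValueError(
            f"K3D = {k3d_nm3:.3g} nm^3 < a^2*lwe = {a * a * lwe:.3g} nm^3 implies U < 0"
        )
    return U, int(round(U))


def k3d_from_binding_energy(a: float, lwe: float, U: float) -> float:
    """Forward relation K3D = a^2 * lwe * e^U, in nm^3."""
    if a <= 0 or lwe <= 0:
        raise ValueError("a and lwe must be positive")
    return a * a * lwe * float(np.exp(U))


def simulated_physical_time(n_cycles: int, tau_us: float = 60.0) -> float:
    """Physical duration of a run in hours: n_cycles * tau."""
    if n_cycles < 0 or tau_us <= 0:
        raise ValueError("need n_cycles >= 0 and tau_us > 0")
    return n_cycles * tau_us * 1e-6 / 3600.0


@dataclass(frozen=True)
class PhysicalConstants:
    """Experimental anchors of the calibration.

    kd_um: solution dissociation constant (uM); D_um2_s: membrane-protein
    diffusion coefficient (um^2/s); tau_us: physical duration of one MC
    cycle (us).
    """

    kd_um: float = 1.0
    D_um2_s: float = 1.0
    tau_us: float = 60.0

    def __post_init__(self) -> None:
        if self.kd_um <= 0 or self.D_um2_s <= 0 or self.tau_us <= 0:
            raise ValueError("all physical constants must be positive")

    @property
    def k3d_nm3(self) -> float:
        return 1.0 / micromolar_to_per_nm3(self.kd_um)
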