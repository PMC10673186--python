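"""Metropolis Monte Carlo sampling of the adhering membrane.

Two move types drive the dynamics, mirroring the physical time scales of
membrane undulations and protein diffusion:

(i)  vertical displacement of a single patch separation by a uniform step
     in [-delta, +delta] (default delta = 1.5 nm), rejected outright if it
     would put the patch at or below the hard wall (l <= 0);
(ii) hop of a single ligand to one of its four nearest-neighbour patches,
     rejected if the target patch is occupied.

One MC cycle attempts, on average, ten vertical displacements per patch and
one hop per ligand. Sites and ligands are drawn uniformly at random with
replacement, which satisfies detailed balance without sweep-ordering
artifacts. Rejected attempts advance the clock (standard Metropolis time
convention), and every change of the bond count is logged with a
fractional-cycle timestamp, so dwell times between binding/unbinding events
are resolved below one cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernel
from .model import ModelParams, SystemState, bond_field, binding_potential, delta_energy_vertical, laplacian_field

__all__ = [
    "McSchedule",
    "Trajectory",
    "run_simulation",
    "attempt_vertical_move",
    "attempt_ligand_hop",
    "initial_state",
    "neighbour_table",
]


@dataclass(frozen=True)
class McSchedule:
    """Monte Carlo protocol: cycle counts, move mix, step size, cadences.

    ``n_equil`` cycles are excluded from every analysis window. The default
    move mix (ten vertical sweeps and one ligand sweep per cycle) and the
    1.5 nm maximum step reflect the separation of membrane-undulation and
    protein-diffusion time scales.
    """

    n_cycles: int = 60_000_000
    n_equil: int = 10_000_000
    vertical_sweeps_per_cycle: int = 10
    ligand_sweeps_per_cycle: int = 1
    max_vertical_step: float = 1.5
    sample_every: int = 10
    snapshot_every: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cycles <= 0:
            raise ValueError("n_cycles must be positive")
        if not 0 <= self.n_equil < self.n_cycles:
            raise ValueError(f"need 0 <= n_equil < n_cycles, got {self.n_equil}, {self.n_cycles}")
        if self.max_vertical_step <= 0:
            raise ValueError("max_vertical_step must be positive")
        if self.vertical_sweeps_per_cycle < 0 or self.ligand_sweeps_per_cycle < 0:
            raise ValueError("sweep counts must be non-negative")
        if self.vertical_sweeps_per_cycle + self.ligand_sweeps_per_cycle == 0:
            raise ValueError("at least one move type per cycle required")


@dataclass
class Trajectory:
    """Everything one MC run produces.

    Scalar observables (bond count, spatial mean and mean square of the
    separation field) are sampled every ``sample_every`` cycles over the
    whole run; analysis helpers expose the post-equilibration window.
    ``events`` is the complete time-ordered record of bond-count changes;
    ``snapshots`` hold the flat lattice indices of bound complexes.
    """

    params: ModelParams
    schedule: McSchedule
    sample_cycles: np.ndarray  # int64, cycle stamp of each scalar sample
    sample_nb: np.ndarray  # int64, bond count
    sample_mean_l: np.ndarray  # float64, spatial mean of l (nm)
    sample_mean_l2: np.ndarray  # float64, spatial mean of l^2 (nm^2)
    snapshot_cycles: np.ndarray  # int64
    snapshot_counts: np.ndarray  # int64, complexes per snapshot
    snapshot_sites: np.ndarray  # int64, packed flat site indices
    event_times: np.ndarray  # float64, fractional cycles, strictly increasing
    event_nb: np.ndarray  # int32, bond count after each event
    event_channel: np.ndarray  # int8, 0 = vertical move caused it, 1 = ligand hop
    nb_initial: int  # bond count at cycle 0
    acceptance: dict = field(default_factory=dict)
    final_state: SystemState | None = None
    version: str = "1"

    @property
    def n_events(self) -> int:
        return int(self.event_times.shape[0])

    def post_equil_mask(self) -> np.ndarray:
        return self.sample_cycles >= self.schedule.n_equil

    def iter_snapshots(self, post_equil: bool = True):
        """Yield (cycle, sites) pairs; sites are flat lattice indices."""
        offsets = np.concatenate(([0], np.cumsum(self.snapshot_counts)))
        for k, cyc in enumerate(self.snapshot_cycles):
            if post_equil and cyc < self.schedule.n_equil:
                continue
            yield int(cyc), self.snapshot_sites[offsets[k] : offsets[k + 1]]

    def nb_at(self, t: float) -> int:
        """Bond count at time t (cycles), reconstructed from the event trace."""
        k = int(np.searchsorted(self.event_times, t, side="right"))
        return int(self.event_nb[k - 1]) if k > 0 else self.nb_initial


def neighbour_table(Lx: int, Ly: int) -> np.ndarray:
    """Periodic nearest-neighbour flat indices, shape (Lx*Ly, 4): +x, -x, +y, -y."""
    idx = np.arange(Lx * Ly).reshape(Lx, Ly)
    return np.stack(
        [
            np.roll(idx, -1, axis=0).ravel(),
            np.roll(idx, 1, axis=0).ravel(),
            np.roll(idx, -1, axis=1).ravel(),
            np.roll(idx, 1, axis=1).ravel(),
        ],
        axis=1,
    ).astype(np.int64)


def initial_state(p: ModelParams, rng: np.random.Generator) -> SystemState:
    """Flat membrane at the well centre, ligands on random distinct patches."""
    l = np.full((p.Lx, p.Ly), p.lb, dtype=np.float64)
    n = np.zeros(p.Lx * p.Ly, dtype=np.int8)
    sites = rng.choice(p.Lx * p.Ly, size=p.NL, replace=False)
    n[sites] = 1
    return SystemState(l=l, n=n.reshape(p.Lx, p.Ly))


def run_simulation(
    p: ModelParams, schedule: McSchedule, state: SystemState | None = None
) -> Trajectory:
    """Run the full MC protocol; deterministic for a given schedule seed."""
    rng = np.random.default_rng(schedule.seed)
    if state is None:
        state = initial_state(p, rng)
    state.validate(p)

    N = p.n_patches
    NL = p.NL
    l = state.l.ravel().copy()
    occ = state.n.ravel().astype(np.int8).copy()
    lig = np.flatnonzero(occ == 1).astype(np.int64)
    lap = laplacian_field(state.l).ravel().copy()
    nbr = neighbour_table(p.Lx, p.Ly)
    nb0 = int(bond_field(state, p).sum())
    nb_box = np.array([nb0], dtype=np.int64)
    rng_state = _kernel.seed_rng_state(schedule.seed)

    n_vert = schedule.vertical_sweeps_per_cycle * N
    n_hop = schedule.ligand_sweeps_per_cycle * NL
    n_samples = schedule.n_cycles // schedule.sample_every if schedule.sample_every > 0 else 0
    n_snaps = schedule.n_cycles // schedule.snapshot_every if schedule.snapshot_every > 0 else 0

    samp_nb = np.zeros(n_samples, dtype=np.int64)
    samp_sl = np.zeros(n_samples, dtype=np.float64)
    samp_sl2 = np.zeros(n_samples, dtype=np.float64)
    snap_counts = np.zeros(n_snaps, dtype=np.int64)
    snap_flat = np.zeros(n_snaps * NL, dtype=np.int64)
    counters = np.zeros(4, dtype=np.int64)

    ev_cap = max(1 << 18, 4 * (n_vert + n_hop))
    ev_t = np.empty(ev_cap, dtype=np.float64)
    ev_n = np.empty(ev_cap, dtype=np.int32)
    ev_c = np.empty(ev_cap, dtype=np.int8)
    ev_count = 0

    cycle = 0
    while cycle < schedule.n_cycles:
        cycle, ev_count = _kernel.run_chunk(
            l, lap, occ, lig, nbr, nb_box, rng_state,
            cycle, schedule.n_cycles, n_vert, n_hop,
            p.kappa / (2.0 * p.a**2), p.U, p.lwe / 2.0, p.lb,
            schedule.max_vertical_step, p.hard_wall,
            schedule.sample_every, schedule.snapshot_every,
            ev_t, ev_n, ev_c, ev_count,
            samp_nb, samp_sl, samp_sl2, snap_counts, snap_flat, counters,
        )
        if cycle < schedule.n_cycles:  # event buffer filled: grow and resume
            ev_t = np.concatenate([ev_t, np.empty(ev_cap, dtype=np.float64)])
            ev_n = np.concatenate([ev_n, np.empty(ev_cap, dtype=np.int32)])
            ev_c = np.concatenate([ev_c, np.empty(ev_cap, dtype=np.int8)])
            ev_cap = ev_t.shape[0]

    # repack snapshots (drop unused tail per snapshot)
    offsets = np.concatenate(([0], np.cumsum(snap_counts)))
    packed = np.empty(int(offsets[-1]), dtype=np.int64)
    for k in range(n_snaps):
        packed[offsets[k] : offsets[k + 1]] = snap_flat[k * NL : k * NL + snap_counts[k]]

    final = SystemState(l=l.reshape(p.Lx, p.Ly), n=occ.reshape(p.Lx, p.Ly))
    acc = {
        "vertical_attempts": int(counters[0]),
        "vertical_accepted": int(counters[1]),
        "hop_attempts": int(counters[2]),
        "hop_accepted": int(counters[3]),
        "vertical_rate": counters[1] / counters[0] if counters[0] else np.nan,
        "hop_rate": counters[3] / counters[2] if counters[2] else np.nan,
    }
    se = schedule.sample_every
    sne = schedule.snapshot_every
    return Trajectory(
        params=p,
        schedule=schedule,
        sample_cycles=(np.arange(1, n_samples + 1) * se - 1) if n_samples else np.empty(0, np.int64),
        sample_nb=samp_nb,
        sample_mean_l=samp_sl / N,
        sample_mean_l2=samp_sl2 / N,
        snapshot_cycles=(np.arange(1, n_snaps + 1) * sne - 1) if n_snaps else np.empty(0, np.int64),
        snapshot_counts=snap_counts,
        snapshot_sites=packed,
        event_times=ev_t[:ev_count].copy(),
        event_nb=ev_n[:ev_count].copy(),
        event_channel=ev_c[:ev_count].copy(),
        nb_initial=nb0,
        acceptance=acc,
        final_state=final,
    )


# ---------------------------------------------------------------------------
# Pure-Python reference moves. These implement exactly the same proposal and
# acceptance rules as the compiled kernel, one attempt at a time, and exist
# for unit tests (energy bookkeeping, detailed balance on small systems) and
# as readable documentation of the move semantics.
# ---------------------------------------------------------------------------

def attempt_vertical_move(
    s: SystemState,
    p: ModelParams,
    rng: np.random.Generator,
    max_step: float = 1.5,
    site: tuple[int, int] | None = None,
) -> tuple[bool, int, float]:
    """One type-(i) attempt. Returns (accepted, bond_change, applied dH)."""
    Lx, Ly = s.l.shape
    if site is None:
        flat = int(rng.integers(Lx * Ly))
        site = (flat // Ly, flat % Ly)
    u = float(rng.uniform(-max_step, max_step))
    l_old = float(s.l[site])
    l_new = l_old + u
    if p.hard_wall and l_new <= 0.0:
        return False, 0, 0.0
    dH = delta_energy_vertical(s, site, l_new, p)
    if dH > 0.0 and rng.random() >= np.exp(-dH):
        return False, 0, 0.0
    dnb = 0
    if s.n[site] == 1:
        dnb = int(abs(l_new - p.lb) < p.lwe / 2) - int(abs(l_old - p.lb) < p.lwe / 2)
    s.l[site] = l_new
    return True, dnb, dH


def attempt_ligand_hop(
    s: SystemState, p: ModelParams, rng: np.random.Generator
) -> tuple[bool, int, float]:
    """One type-(ii) attempt. Returns (accepted, bond_change, applied dH_int)."""
    occ_sites = np.argwhere(s.n == 1)
    if occ_sites.shape[0] == 0:
        raise ValueError("no ligands to move")
    src = tuple(occ_sites[int(rng.integers(occ_sites.shape[0]))])
    Lx, Ly = s.l.shape
    moves = (((1, 0)), ((-1, 0)), ((0, 1)), ((0, -1)))
    dx, dy = moves[int(rng.integers(4))]
    dst = ((src[0] + dx) % Lx, (src[1] + dy) % Ly)
    if s.n[dst] == 1:
        return False, 0, 0.0
    dH = float(binding_potential(float(s.l[dst]), p) - binding_potential(float(s.l[src]), p))
    if dH > 0.0 and rng.random() >= np.exp(-dH):
        return False, 0, 0.0
    in_src = abs(float(s.l[src]) - p.lb) < p.lwe / 2
    in_dst = abs(float(s.l[dst]) - p.lb) < p.lwe / 2
    s.n[src] = 0
    s.n[dst] = 1
    return True, int(in_dst) - int(in_src), dH
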