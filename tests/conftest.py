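"""Shared fixtures.

The expensive Monte Carlo runs are session-scoped and shared across test
modules: a desk-scale parameter grid (affinity/roughness/PMF regression), a
longer single run at the reference condition (kinetics), and a free-membrane
run (roughness oracle). Sizes are chosen so the whole suite completes on one
CPU core in well under half an hour while keeping enough statistics for the
stated tolerances.
"""

from __future__ import annotations

import numpy as np
import pytest

from memadh import McSchedule, ModelParams, run_simulation
from memadh.experiments import SweepSpec, run_sweep


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def desk_grid():
    """Desk-scale (lb x NL) sweep: 40x40 patches (0.6 um box), densities
    ~30/60/90 ligands per um^2, one seed per point.

    The low-density points get a longer schedule: with few bonds pinning the
    membrane, the slowest undulation mode relaxes in ~2e4 cycles, so their
    equilibration window is set to ~4x that; at the higher densities the
    pinning shortens relaxation and the shorter schedule is adequate.
    """
    import pandas as pd

    low = SweepSpec(
        Lx=40, Ly=40, lb_values=(6.6, 7.8), NL_values=(11,), seeds=(1,),
        n_cycles=220_000, n_equil=80_000, sample_every=10, snapshot_every=100,
    )
    high = SweepSpec(
        Lx=40, Ly=40, lb_values=(6.6, 7.8), NL_values=(22, 32), seeds=(1,),
        n_cycles=100_000, n_equil=25_000, sample_every=10, snapshot_every=100,
    )
    df = pd.concat([run_sweep(low), run_sweep(high)], ignore_index=True)
    assert "error" not in df.columns, f"sweep failures: {df}"
    return df


@pytest.fixture(scope="session")
def kinetics_run():
    """Reference-condition run (lb = 7.8 nm, ~60 ligands/um^2) on a 64x64
    lattice, long enough for ~700 lateral unbinding events."""
    p = ModelParams(Lx=64, Ly=64, NL=55, lb=7.8)
    sch = McSchedule(
        n_cycles=150_000, n_equil=30_000, seed=1,
        sample_every=10, snapshot_every=100,
    )
    return run_simulation(p, sch)


@pytest.fixture(scope="session")
def free_membrane_run():
    """Unbound, wall-free membrane: pure bending Hamiltonian, 32x32, 1e6 cycles."""
    p = ModelParams(Lx=32, Ly=32, NL=0, hard_wall=False)
    sch = McSchedule(
        n_cycles=1_000_000, n_equil=100_000, seed=2,
        sample_every=20, snapshot_every=0,
    )
    return run_simulation(p, sch)
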