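"""Monte Carlo engine: move semantics, detailed balance, roughness oracle."""

import numpy as np
import pytest
from scipy import stats

from memadh import McSchedule, ModelParams, SystemState, run_simulation
from memadh.experiments import gaussian_membrane_field
from memadh.mc import attempt_vertical_move, initial_state
from memadh.model import delta_energy_vertical
from memadh.observables import free_membrane_roughness_sq, summarize


class _ScriptedRng:
    """Deterministic stand-in driving one prescribed proposal."""

    def __init__(self, u: float, metropolis: float = 0.999999):
        self._u = u
        self._metropolis = metropolis

    def integers(self, n):
        return 0

    def uniform(self, lo, hi):
        return self._u

    def random(self):
        return self._metropolis


class TestMoveSemantics:
    def test_downhill_move_always_accepted(self):
        # relaxing a bump lowers the bending energy: accepted even when the
        # Metropolis draw is ~1
        p = ModelParams(Lx=8, Ly=8, NL=0)
        l = np.full((8, 8), 7.8)
        l[0, 0] += 1.4
        s = SystemState(l=l, n=np.zeros((8, 8)))
        ok, dnb, d = attempt_vertical_move(
            s, p, _ScriptedRng(u=-1.4), site=(0, 0)
        )
        assert ok and d < 0
        assert s.l[0, 0] == pytest.approx(7.8)

    def test_hard_wall_proposal_rejected_outright(self):
        p = ModelParams(Lx=8, Ly=8, NL=0)
        s = SystemState(l=np.full((8, 8), 0.5), n=np.zeros((8, 8)))
        ok, _, _ = attempt_vertical_move(s, p, _ScriptedRng(u=-0.5), site=(3, 3))
        assert not ok  # l_new = 0 violates l > 0
        ok, _, _ = attempt_vertical_move(s, p, _ScriptedRng(u=-0.6), site=(3, 3))
        assert not ok

    def test_wall_ignored_when_disabled(self):
        p = ModelParams(Lx=8, Ly=8, NL=0, hard_wall=False)
        s = SystemState(l=np.full((8, 8), 0.5), n=np.zeros((8, 8)))
        ok, _, _ = attempt_vertical_move(s, p, _ScriptedRng(u=-0.6, metropolis=0.0),
                                         site=(3, 3))
        assert ok
        assert s.l[3, 3] == pytest.approx(-0.1)


def test_pinned_site_height_samples_boltzmann_density():
    """Metropolis sampling of one site against the exact 1D density.

    With the 8 neighbours of a 3x3 lattice frozen at lb, displacing the
    centre by x costs 10*kappa*x^2/a^2 in bending plus the well term, so the
    stationary height density is exactly
    p(x) ~ exp(-10 kappa x^2 / a^2 - V(lb + x)).
    """
    p = ModelParams(Lx=3, Ly=3, NL=1, U=2.0, kappa=10.0)
    n = np.zeros((3, 3))
    n[1, 1] = 1
    s = SystemState(l=np.full((3, 3), p.lb), n=n)
    rng = np.random.default_rng(11)
    samples = np.empty(20_000)
    for i in range(samples.size):
        for _ in range(10):
            attempt_vertical_move(s, p, rng, site=(1, 1))
        samples[i] = s.l[1, 1]

    alpha = 10 * p.kappa / p.a**2
    xs = np.linspace(p.lb - 6, p.lb + 6, 4001)
    dens = np.exp(-alpha * (xs - p.lb) ** 2)
    dens[np.abs(xs - p.lb) < p.lwe / 2] *= np.exp(p.U)
    cdf_grid = np.cumsum(dens)
    cdf_grid /= cdf_grid[-1]

    def cdf(v):
        return np.interp(v, xs, cdf_grid)

    # thin to roughly independent samples before the KS test
    ks = stats.kstest(samples[::10], cdf)
    assert ks.pvalue > 0.01


def test_frozen_membrane_ligand_occupancy_matches_boltzmann():
    """With heights frozen, hop dynamics must reach the exact Boltzmann law.

    Half the patches sit in the binding well and half outside, so exact
    enumeration over the 256 single-ligand placements gives
    P(bound) = N_in e^U / (N_in e^U + N_out).
    """
    p = ModelParams(Lx=16, Ly=16, NL=1, U=2.0)
    rng = np.random.default_rng(5)
    l = np.where(rng.random((16, 16)) < 0.5, p.lb, p.lb + 4.0)
    n_in = int((l == p.lb).sum())
    n = np.zeros(256)
    n[7] = 1
    state = SystemState(l=l.copy(), n=n.reshape(16, 16))
    sch = McSchedule(
        n_cycles=200_000, n_equil=20_000, vertical_sweeps_per_cycle=0,
        ligand_sweeps_per_cycle=1, sample_every=10, snapshot_every=0, seed=6,
    )
    traj = run_simulation(p, sch, state=state)
    np.testing.assert_array_equal(traj.final_state.l.ravel(), l.ravel())  # frozen

    bound = traj.sample_nb[traj.post_equil_mask()].astype(float)
    p_exact = n_in * np.exp(p.U) / (n_in * np.exp(p.U) + (256 - n_in))
    blocks = np.array_split(bound, 20)
    means = np.array([b.mean() for b in blocks])
    se = means.std(ddof=1) / np.sqrt(len(blocks))
    assert abs(bound.mean() - p_exact) < 3 * se + 1e-3


def test_vertical_acceptance_matches_gaussian_model_oracle():
    """Long-run acceptance of height moves vs a brute-force equilibrium average.

    For the free membrane the acceptance probability is
    E[min(1, e^{-dH})] over equilibrium configurations and uniform proposals;
    the oracle evaluates it on independent spectral samples of the Gaussian
    model, the engine measures it along the Markov chain.
    """
    p = ModelParams(Lx=16, Ly=16, NL=0, hard_wall=False, U=0.0)
    warm = run_simulation(
        p, McSchedule(n_cycles=20_000, n_equil=1000, seed=3, sample_every=0,
                      snapshot_every=0)
    )
    measured = run_simulation(
        p,
        McSchedule(n_cycles=2000, n_equil=100, seed=4, sample_every=0,
                   snapshot_every=0),
        state=warm.final_state,
    )
    acc = measured.acceptance["vertical_rate"]

    rng = np.random.default_rng(9)
    vals = []
    for _ in range(400):
        field = gaussian_membrane_field(16, 16, p.kappa, p.a, rng, mean=7.8)
        s = SystemState(l=field, n=np.zeros((16, 16)))
        for _ in range(50):
            site = (int(rng.integers(16)), int(rng.integers(16)))
            u = rng.uniform(-1.5, 1.5)
            d = delta_energy_vertical(s, site, float(s.l[site] + u), p)
            vals.append(min(1.0, np.exp(-d)))
    vals = np.asarray(vals)
    oracle = vals.mean()
    # oracle error plus a conservative allowance for chain autocorrelation
    n_att = measured.acceptance["vertical_attempts"]
    sigma = vals.std() / np.sqrt(vals.size) + 0.5 / np.sqrt(n_att / 50)
    assert abs(acc - oracle) < 3 * sigma


class TestRunSimulation:
    def test_same_seed_bit_identical(self):
        p = ModelParams(Lx=16, Ly=16, NL=10)
        sch = McSchedule(n_cycles=3000, n_equil=500, seed=42, sample_every=10,
                         snapshot_every=100)
        t1 = run_simulation(p, sch)
        t2 = run_simulation(p, sch)
        np.testing.assert_array_equal(t1.event_times, t2.event_times)
        np.testing.assert_array_equal(t1.event_nb, t2.event_nb)
        np.testing.assert_array_equal(t1.sample_nb, t2.sample_nb)
        np.testing.assert_array_equal(t1.final_state.l, t2.final_state.l)
        np.testing.assert_array_equal(t1.final_state.n, t2.final_state.n)

    def test_different_seed_differs(self):
        p = ModelParams(Lx=16, Ly=16, NL=10)
        t1 = run_simulation(p, McSchedule(n_cycles=2000, n_equil=100, seed=1))
        t2 = run_simulation(p, McSchedule(n_cycles=2000, n_equil=100, seed=2))
        assert not np.array_equal(t1.final_state.l, t2.final_state.l)

    def test_conservation_and_hard_wall(self):
        p = ModelParams(Lx=16, Ly=16, NL=30)
        traj = run_simulation(p, McSchedule(n_cycles=5000, n_equil=500, seed=8))
        assert int(traj.final_state.n.sum()) == 30
        assert traj.final_state.l.min() > 0

    def test_event_trace_reconstructs_sampled_bond_count(self):
        """Cumulating events reproduces the independently counted bond number."""
        p = ModelParams(Lx=16, Ly=16, NL=30)
        sch = McSchedule(n_cycles=5000, n_equil=0, seed=8, sample_every=50)
        traj = run_simulation(p, sch)
        assert traj.n_events > 50
        assert np.all(np.diff(traj.event_times) > 0)
        steps = np.diff(np.concatenate(([traj.nb_initial], traj.event_nb)))
        assert set(np.abs(steps)) == {1}
        for cyc, nb in zip(traj.sample_cycles, traj.sample_nb):
            assert traj.nb_at(cyc + 1 - 1e-9) == nb

    def test_unphysical_params_rejected_before_running(self):
        with pytest.raises(ValueError):
            ModelParams(Lx=16, Ly=16, NL=5, lb=0.5, lwe=1.2)  # well in the wall
        with pytest.raises(ValueError):
            McSchedule(n_cycles=100, n_equil=100)

    def test_deep_well_binds_everything(self):
        # U = 20 kBT: unbinding is ~e^-20, essentially every ligand stays bound
        p = ModelParams(Lx=8, Ly=8, NL=4, U=20.0, lb=7.8)
        traj = run_simulation(p, McSchedule(n_cycles=20_000, n_equil=4000, seed=13))
        bound_fraction = traj.sample_nb[traj.post_equil_mask()].mean() / p.NL
        assert bound_fraction > 0.99

    def test_initial_state_ligands_on_distinct_patches(self, rng):
        p = ModelParams(Lx=16, Ly=16, NL=100)
        s = initial_state(p, rng)
        assert int(s.n.sum()) == 100
        assert s.n.max() == 1


def test_free_membrane_roughness_matches_equipartition(free_membrane_run):
    """MC roughness of the unbound membrane vs the closed-form lattice sum.

    The mean height is a zero mode (it random-walks), so the per-frame
    spatial variance is the estimator the q != 0 equipartition sum predicts.
    """
    s = summarize(free_membrane_run)
    xi_exact = np.sqrt(free_membrane_roughness_sq(32, 32, 10.0, 15.0))
    assert s.frame_roughness == pytest.approx(xi_exact, rel=0.05)
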