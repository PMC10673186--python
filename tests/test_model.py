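"""Hamiltonian and local-energy bookkeeping of the lattice model."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from memadh import (
    ModelParams,
    SystemState,
    bending_energy,
    binding_potential,
    bond_field,
    discrete_laplacian,
    interaction_energy,
    total_energy,
)
from memadh.model import delta_energy_vertical, laplacian_field
from memadh.mc import attempt_ligand_hop, attempt_vertical_move


def _loop_laplacian(l: np.ndarray) -> np.ndarray:
    """Independent brute-force 5-point stencil with explicit wrapping."""
    Lx, Ly = l.shape
    out = np.empty_like(l)
    for ix in range(Lx):
        for iy in range(Ly):
            out[ix, iy] = (
                l[(ix + 1) % Lx, iy]
                + l[(ix - 1) % Lx, iy]
                + l[ix, (iy + 1) % Ly]
                + l[ix, (iy - 1) % Ly]
                - 4 * l[ix, iy]
            )
    return out


class TestLaplacian:
    def test_constant_field_is_zero(self):
        l = np.full((5, 7), 7.8)
        assert discrete_laplacian(l, (2, 3)) == 0.0
        assert np.all(laplacian_field(l) == 0.0)

    def test_single_site_bump(self):
        l = np.zeros((6, 6))
        h = 2.3
        l[0, 0] = h
        assert discrete_laplacian(l, (0, 0)) == pytest.approx(-4 * h)
        assert discrete_laplacian(l, (1, 0)) == pytest.approx(h)
        assert discrete_laplacian(l, (5, 0)) == pytest.approx(h)  # periodic wrap
        assert discrete_laplacian(l, (3, 3)) == 0.0

    def test_matches_loop_oracle_on_random_field(self, rng):
        l = rng.normal(8.0, 2.0, size=(8, 8))
        expected = _loop_laplacian(l)
        for ix in range(8):
            for iy in range(8):
                assert discrete_laplacian(l, (ix, iy)) == pytest.approx(
                    expected[ix, iy], rel=1e-12
                )
        np.testing.assert_allclose(laplacian_field(l), expected, rtol=1e-12)

    def test_tilted_plane_vanishes_at_interior_sites(self):
        # affine fields are in the stencil's kernel away from the wrap seam
        x, y = np.meshgrid(np.arange(8), np.arange(8), indexing="ij")
        l = 0.3 * x - 0.7 * y + 5.0
        for ix in range(1, 7):
            for iy in range(1, 7):
                assert discrete_laplacian(l, (ix, iy)) == pytest.approx(0.0, abs=1e-12)

    @given(c=st.floats(-50, 50))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_linearity_under_constant_shift(self, c):
        rng = np.random.default_rng(7)
        l = rng.normal(8.0, 2.0, size=(6, 6))
        np.testing.assert_allclose(
            laplacian_field(l + c), laplacian_field(l), atol=1e-9
        )


class TestBendingEnergy:
    def test_flat_field_zero(self):
        p = ModelParams(Lx=8, Ly=8, NL=0)
        assert bending_energy(np.full((8, 8), 5.0), p) == 0.0

    def test_single_bump_closed_form(self):
        # stencil gives (-4h)^2 at the bump and h^2 at each of 4 neighbours:
        # Hel = (kappa/2a^2)(16+4)h^2 = 10 kappa h^2 / a^2 = 1 kBT here
        p = ModelParams(a=15.0, kappa=10.0, Lx=8, Ly=8, NL=0)
        l = np.full((8, 8), 7.8)
        l[3, 3] += 1.5
        assert bending_energy(l, p) == pytest.approx(1.0, rel=1e-12)

    def test_matches_double_loop_oracle(self, rng):
        p = ModelParams(a=15.0, kappa=10.0, Lx=8, Ly=8, NL=0)
        l = rng.normal(8.0, 1.0, size=(8, 8))
        lap = _loop_laplacian(l)
        expected = p.kappa / (2 * p.a**2) * np.sum(lap**2)
        assert bending_energy(l, p) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("c", [-3.0, 5.0, 100.0])
    def test_invariant_under_global_shift(self, c, rng):
        p = ModelParams(Lx=8, Ly=8, NL=0, hard_wall=False)
        l = rng.normal(8.0, 1.0, size=(8, 8))
        assert bending_energy(l + c, p) == pytest.approx(
            bending_energy(l, p), rel=1e-9
        )

    def test_invariant_under_lattice_translation(self, rng):
        p = ModelParams(Lx=8, Ly=8, NL=0)
        l = rng.normal(8.0, 1.0, size=(8, 8))
        assert bending_energy(np.roll(l, (3, 2), axis=(0, 1)), p) == pytest.approx(
            bending_energy(l, p), rel=1e-12
        )


class TestBindingPotential:
    def test_well_center_depth(self):
        p = ModelParams()
        assert binding_potential(p.lb, p) == -9.0

    def test_outside_well(self):
        p = ModelParams()
        assert binding_potential(p.lb + p.lwe, p) == 0.0
        assert binding_potential(0.1, p) == 0.0

    def test_exact_edge_is_outside(self):
        # Heaviside convention Theta(0) = 0: the edge itself is unbound.
        # Parameters chosen binary-representable so lb + lwe/2 is exact.
        p = ModelParams(lb=8.0, lwe=1.0)
        assert binding_potential(8.5, p) == 0.0
        assert binding_potential(7.5, p) == 0.0
        assert binding_potential(np.nextafter(8.5, 8.0), p) == -9.0


class TestInteractionEnergy:
    def test_no_ligands(self):
        p = ModelParams(Lx=6, Ly=6, NL=0)
        s = SystemState(l=np.full((6, 6), p.lb), n=np.zeros((6, 6)))
        assert interaction_energy(s, p) == 0.0

    def test_three_bound_ligands(self):
        p = ModelParams(Lx=6, Ly=6, NL=3)
        l = np.full((6, 6), 20.0)
        n = np.zeros((6, 6))
        for site in [(0, 0), (2, 3), (5, 5)]:
            l[site] = p.lb
            n[site] = 1
        s = SystemState(l=l, n=n)
        assert interaction_energy(s, p) == -27.0

    def test_random_state_equals_minus_u_times_bond_count(self, rng):
        p = ModelParams(Lx=8, Ly=8, NL=20)
        l = rng.uniform(0.5, 12.0, size=(8, 8))
        n = np.zeros(64)
        n[rng.choice(64, 20, replace=False)] = 1
        s = SystemState(l=l, n=n.reshape(8, 8))
        count = sum(
            1
            for ix in range(8)
            for iy in range(8)
            if s.n[ix, iy] == 1 and abs(l[ix, iy] - p.lb) < p.lwe / 2
        )
        assert interaction_energy(s, p) == pytest.approx(-p.U * count)
        # the ratio H_int / (-U) is always an integer bond count
        assert interaction_energy(s, p) / (-p.U) == pytest.approx(
            bond_field(s, p).sum()
        )


class TestDeltaEnergyVertical:
    def _random_state(self, rng, p):
        l = rng.uniform(4.0, 12.0, size=(p.Lx, p.Ly))
        n = np.zeros(p.Lx * p.Ly)
        n[rng.choice(p.Lx * p.Ly, p.NL, replace=False)] = 1
        return SystemState(l=l, n=n.reshape(p.Lx, p.Ly))

    def test_flat_field_bump_closed_form(self):
        p = ModelParams(a=15.0, kappa=10.0, Lx=8, Ly=8, NL=1)
        n = np.zeros((8, 8))
        n[4, 4] = 1
        s = SystemState(l=np.full((8, 8), p.lb), n=n)
        # unoccupied site: pure bending, 10 kappa h^2 / a^2
        h = 1.5
        assert delta_energy_vertical(s, (2, 2), p.lb + h, p) == pytest.approx(1.0)
        # occupied site leaving the well additionally pays +U
        assert delta_energy_vertical(s, (4, 4), p.lb + h, p) == pytest.approx(1.0 + 9.0)

    def test_in_well_to_in_well_has_no_binding_term(self):
        p = ModelParams(Lx=8, Ly=8, NL=1)
        n = np.zeros((8, 8))
        n[4, 4] = 1
        s = SystemState(l=np.full((8, 8), p.lb), n=n)
        u = 0.4 * p.lwe  # stays inside the well
        d_occupied = delta_energy_vertical(s, (4, 4), p.lb + u, p)
        d_empty = delta_energy_vertical(s, (2, 2), p.lb + u, p)
        assert d_occupied == pytest.approx(d_empty, rel=1e-12)

    def test_matches_full_energy_recomputation(self, rng):
        p = ModelParams(Lx=8, Ly=8, NL=12)
        s = self._random_state(rng, p)
        for _ in range(50):
            site = (int(rng.integers(8)), int(rng.integers(8)))
            l_new = float(rng.uniform(3.0, 13.0))
            before = total_energy(s, p)
            d = delta_energy_vertical(s, site, l_new, p)
            s2 = SystemState(l=s.l.copy(), n=s.n.copy())
            s2.l[site] = l_new
            assert d == pytest.approx(total_energy(s2, p) - before, rel=1e-10, abs=1e-10)

    def test_out_of_range_index_raises(self, rng):
        p = ModelParams(Lx=8, Ly=8, NL=0)
        s = SystemState(l=np.full((8, 8), 7.8), n=np.zeros((8, 8)))
        with pytest.raises(IndexError):
            delta_energy_vertical(s, (8, 0), 7.0, p)


def test_incremental_energy_bookkeeping_over_many_moves(rng):
    """Accumulated per-move energy changes track the total energy exactly."""
    p = ModelParams(Lx=12, Ly=12, NL=30)
    l = rng.uniform(5.0, 11.0, size=(12, 12))
    n = np.zeros(144)
    n[rng.choice(144, 30, replace=False)] = 1
    s = SystemState(l=l, n=n.reshape(12, 12))
    e = total_energy(s, p)
    accepted = 0
    for k in range(10_000):
        if k % 11 == 0 and p.NL > 0:
            ok, _, d = attempt_ligand_hop(s, p, rng)
        else:
            ok, _, d = attempt_vertical_move(s, p, rng)
        e += d
        accepted += ok
    assert accepted > 1000
    assert e == pytest.approx(total_energy(s, p), abs=1e-8)
    assert int(s.n.sum()) == 30  # ligand conservation through hops


class TestModelParamsValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"a": -1.0},
            {"kappa": 0.0},
            {"U": -2.0},
            {"lwe": 0.0},
            {"lb": 0.5, "lwe": 1.2},  # well crosses the hard wall
            {"Lx": 2},
            {"NL": 10_000_000},
            {"NR": 0},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ModelParams(**kwargs)

    def test_well_may_touch_wall_when_wall_disabled(self):
        ModelParams(lb=0.5, lwe=1.2, hard_wall=False)

    def test_area_is_derived(self):
        p = ModelParams(Lx=400, Ly=400, a=15.0)
        assert p.area_um2 == pytest.approx(36.0)
        assert p.n_receptors == 160_000
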