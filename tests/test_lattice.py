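"""Lattice representation, energies, and Metropolis dynamics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ising_ews.lattice import (
    LatticeState,
    MagnetizationSeries,
    ModelParams,
    flip_delta_energy,
    magnetization,
    metropolis_sweep,
    simulate,
    total_energy,
)


def checkerboard(L):
    rows, cols = np.indices((L, L))
    return LatticeState(((rows + cols) % 2 * 2 - 1).astype(np.int8))


class TestParams:
    def test_beta_is_inverse_kT(self):
        p = ModelParams(temperature=2.0, boltzmann_k=1.0)
        assert p.beta == 0.5

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"temperature": -1.0},
            {"temperature": 0.0},
            {"temperature": 2.0, "external_field": 0.1},
            {"temperature": 2.0, "coupling": -1.0},
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ModelParams(**kwargs)

    def test_acceptance_table_is_metropolis_rule(self):
        p = ModelParams(temperature=2.0)
        table = p.acceptance_table()
        assert (table[:5] == 1.0).all()  # dE <= 0 always accepted
        assert table[8] == pytest.approx(np.exp(-8 / 2.0))


class TestState:
    def test_all_up_and_random_constructors(self):
        assert magnetization(LatticeState.all_up(5)) == 1.0
        s = LatticeState.random(50, np.random.default_rng(0))
        assert set(np.unique(s.spins)) <= {-1, 1}
        # binomial oracle: |M| of N iid +/-1 spins is within 4/sqrt(N) w.h.p.
        assert abs(magnetization(s)) <= 4 / 50

    @pytest.mark.parametrize(
        "spins",
        [np.zeros((3, 3)), np.ones((2, 3)), np.ones((1, 1)), np.full((3, 3), 2)],
    )
    def test_invalid_lattices_rejected(self, spins):
        with pytest.raises(ValueError):
            LatticeState(spins)


class TestMagnetization:
    def test_aligned_lattice(self):
        assert magnetization(LatticeState.all_up(4)) == 1.0

    def test_checkerboard_cancels(self):
        assert magnetization(checkerboard(4)) == 0.0

    def test_three_up_one_down(self):
        s = LatticeState.all_up(2)
        s.spins[0, 0] = -1
        assert magnetization(s) == 0.5


class TestTotalEnergy:
    def test_aligned_4x4(self):
        p = ModelParams(temperature=1.0)
        assert total_energy(LatticeState.all_up(4), p) == -32.0

    def test_checkerboard_4x4(self):
        p = ModelParams(temperature=1.0)
        assert total_energy(checkerboard(4), p) == 32.0

    def test_2x2_single_flip_is_zero(self):
        # hand enumeration under the doubled-bond L=2 convention
        p = ModelParams(temperature=1.0)
        s = LatticeState.all_up(2)
        s.spins[1, 0] = -1
        assert total_energy(s, p) == 0.0

    def test_spin_flip_symmetry(self):
        p = ModelParams(temperature=1.0)
        rng = np.random.default_rng(3)
        s = LatticeState.random(6, rng)
        flipped = LatticeState(-s.spins)
        assert total_energy(s, p) == total_energy(flipped, p)


class TestFlipDeltaEnergy:
    def test_aligned_lattice_any_site(self):
        p = ModelParams(temperature=1.0)
        assert flip_delta_energy(LatticeState.all_up(4), p, (2, 3)) == 8.0

    def test_all_down_by_symmetry(self):
        p = ModelParams(temperature=1.0)
        s = LatticeState(-np.ones((4, 4), dtype=np.int8))
        assert flip_delta_energy(s, p, (0, 0)) == 8.0

    def test_balanced_neighbors_cost_nothing(self):
        p = ModelParams(temperature=1.0)
        s = LatticeState.all_up(4)
        s.spins[0, 1] = -1
        s.spins[2, 1] = -1  # site (1,1) now has two +1, two -1 neighbours
        assert flip_delta_energy(s, p, (1, 1)) == 0.0

    def test_out_of_range_site(self):
        p = ModelParams(temperature=1.0)
        with pytest.raises(IndexError):
            flip_delta_energy(LatticeState.all_up(3), p, (3, 0))

    @given(
        L=st.sampled_from([2, 3, 4, 5]),
        seed=st.integers(0, 2**31 - 1),
        data=st.data(),
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_total_energy_difference(self, L, seed, data):
        """dE from the local formula equals the global energy difference exactly."""
        p = ModelParams(temperature=1.0)
        s = LatticeState.random(L, np.random.default_rng(seed))
        row = data.draw(st.integers(0, L - 1))
        col = data.draw(st.integers(0, L - 1))
        before = total_energy(s, p)
        dE = flip_delta_energy(s, p, (row, col))
        s.spins[row, col] *= -1
        assert total_energy(s, p) - before == dE


class TestMetropolisSweep:
    def test_frozen_at_low_temperature(self):
        # all dE = +8, acceptance exp(-8/0.1) ~ 2e-35: nothing moves
        p = ModelParams(temperature=0.1)
        s = LatticeState.all_up(8)
        metropolis_sweep(s, p, np.random.default_rng(0))
        assert (s.spins == 1).all()

    def test_infinite_temperature_negates_magnetization(self):
        # acceptance -> 1: every spin flips exactly once during the sweep
        p = ModelParams(temperature=1e15)
        s = LatticeState.random(10, np.random.default_rng(1))
        m_before = magnetization(s)
        metropolis_sweep(s, p, np.random.default_rng(2))
        assert magnetization(s) == pytest.approx(-m_before)


class TestSimulate:
    def test_frozen_limit_stays_magnetized(self):
        p = ModelParams(temperature=0.1)
        series = simulate(p, 8, 50, init_mode="all_up", seed=5)
        assert (series.values == 1.0).all()

    def test_deterministic_from_seed(self):
        p = ModelParams(temperature=2.27)
        a = simulate(p, 16, 100, init_mode="random", seed=11)
        b = simulate(p, 16, 100, init_mode="random", seed=11)
        np.testing.assert_array_equal(a.values, b.values)
        np.testing.assert_array_equal(a.energies, b.energies)

    def test_different_seeds_differ(self):
        p = ModelParams(temperature=2.27)
        a = simulate(p, 16, 100, init_mode="random", seed=11)
        b = simulate(p, 16, 100, init_mode="random", seed=12)
        assert not np.array_equal(a.values, b.values)

    def test_trace_on_magnetization_grid(self):
        """Every value lies in [-1,1] on the 2/N grid of possible M values."""
        p = ModelParams(temperature=2.5)
        L = 6
        series = simulate(p, L, 200, init_mode="random", seed=3)
        assert (np.abs(series.values) <= 1).all()
        counts = series.values * L * L  # total spin: integer of lattice parity
        np.testing.assert_allclose(counts, np.round(counts), atol=1e-9)
        assert (np.round(counts) % 2 == (L * L) % 2).all()

    def test_energy_trace_matches_hamiltonian_scale(self):
        p = ModelParams(temperature=0.1)
        series = simulate(p, 4, 10, init_mode="all_up", seed=0)
        assert (series.energies == -32.0).all()

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"L": 1, "n_sweeps": 10},
            {"L": 4, "n_sweeps": 0},
            {"L": 4, "n_sweeps": 10, "init_mode": "hot"},
        ],
    )
    def test_invalid_arguments(self, kwargs):
        p = ModelParams(temperature=2.0)
        with pytest.raises(ValueError):
            simulate(p, **kwargs)


class TestSeries:
    def test_rejects_out_of_range_values(self):
        with pytest.raises(ValueError):
            MagnetizationSeries(
                values=np.array([0.0, 1.5]),
                temperature=2.0,
                side_length=4,
                seed=0,
                init_mode="random",
            )

    def test_post_burn_in_slices(self):
        s = MagnetizationSeries(
            values=np.linspace(-1, 1, 10),
            temperature=2.0,
            side_length=4,
            seed=0,
            init_mode="random",
            burn_in=4,
        )
        assert len(s.post_burn_in()) == 6
        assert s.n_total == 10
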