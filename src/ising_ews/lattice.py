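"""2-D Ising model on a periodic square lattice with Metropolis dynamics.

The model: ``N = L*L`` spins ``sigma = +/-1`` with nearest-neighbour coupling
``J`` and Hamiltonian ``H = -J * sum_<ij> sigma_i sigma_j`` (zero external
field). Configurations are weighted by the Boltzmann distribution
``P(sigma) ~ exp(-H/(k T))``. Single-spin-flip Metropolis dynamics generates a
Markov chain of configurations whose per-sweep total magnetization
``M = (1/N) sum_i sigma_i`` is the time series analysed by the indicator
modules.

Bond convention: the Hamiltonian sums each site with its right and down
neighbour under periodic wrap, i.e. ``2*L*L`` bond terms. For ``L >= 3`` this
counts every unordered nearest-neighbour pair exactly once; for ``L = 2`` the
wrap-around makes each pair appear twice. The convention is applied
consistently here and in :mod:`ising_ews.exact`, so all cross-checks agree;
production simulations use ``L >> 2`` where the distinction vanishes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from ._kernels import metropolis_trace

__all__ = [
    "ModelParams",
    "LatticeState",
    "MagnetizationSeries",
    "magnetization",
    "total_energy",
    "flip_delta_energy",
    "metropolis_sweep",
    "simulate",
    "INIT_MODES",
]

INIT_MODES = ("all_up", "random")


@dataclass(frozen=True)
class ModelParams:
    """Physical parameters of the Ising system.

    ``coupling`` (J) and ``boltzmann_k`` (k) fix the units; the study uses
    J = k = 1 so that the infinite-lattice critical temperature is
    ``2/ln(1 + sqrt(2)) ~= 2.27``. ``external_field`` (B) and
    ``magnetic_moment`` (mu) are carried for completeness of the Hamiltonian
    but any nonzero field is rejected: the zero-field symmetric case is the
    scope of this package.
    """

    temperature: float
    coupling: float = 1.0
    boltzmann_k: float = 1.0
    external_field: float = 0.0
    magnetic_moment: float = 1.0

    def __post_init__(self) -> None:
        if not self.temperature > 0:
            raise ValueError(f"temperature must be > 0, got {self.temperature}")
        if not self.coupling > 0:
            raise ValueError("coupling J must be > 0 (ferromagnetic case)")
        if not self.boltzmann_k > 0:
            raise ValueError("boltzmann_k must be > 0")
        if self.external_field != 0.0:
            raise ValueError(
                "nonzero external field is out of scope (B must be 0)"
            )

    @property
    def beta(self) -> float:
        """Inverse temperature 1/(k*T)."""
        return 1.0 / (self.boltzmann_k * self.temperature)

    def acceptance_table(self) -> np.ndarray:
        """Metropolis acceptance probabilities indexed by ``sigma*nsum + 4``.

        For a proposed flip of spin ``sigma`` with neighbour sum ``nsum``,
        ``dE = 2*J*sigma*nsum``; the move is accepted with probability
        ``min(1, exp(-dE/(k T)))`` (dE <= 0 always accepted).
        """
        s = np.arange(-4, 5)
        dE = 2.0 * self.coupling * s
        return np.minimum(1.0, np.exp(-self.beta * dE))


@dataclass
class LatticeState:
    """An ``L x L`` grid of spins in {-1, +1} with toroidal adjacency."""

    spins: np.ndarray

    def __post_init__(self) -> None:
        self.spins = np.ascontiguousarray(self.spins, dtype=np.int8)
        if self.spins.ndim != 2 or self.spins.shape[0] != self.spins.shape[1]:
            raise ValueError("spins must be a square 2-D array")
        if self.spins.shape[0] < 2:
            raise ValueError("side length must be >= 2")
        if not np.isin(self.spins, (-1, 1)).all():
            raise ValueError("every spin must be -1 or +1")

    @property
    def side_length(self) -> int:
        return self.spins.shape[0]

    @property
    def n_sites(self) -> int:
        return self.spins.size

    @classmethod
    def all_up(cls, L: int) -> "LatticeState":
        """All spins aligned with +1 (the low-temperature initial condition)."""
        return cls(np.ones((L, L), dtype=np.int8))

    @classmethod
    def random(cls, L: int, rng: np.random.Generator) -> "LatticeState":
        """Each spin +/-1 equiprobably (the near/above-critical initial condition)."""
        return cls(rng.choice(np.array([-1, 1], dtype=np.int8), size=(L, L)))

    def copy(self) -> "LatticeState":
        return LatticeState(self.spins.copy())


@dataclass
class MagnetizationSeries:
    """Per-sweep total magnetization trace with its provenance.

    ``values[t]`` is M after sweep ``t+1``; every value lies on the grid
    ``{-1, -1 + 2/N, ..., 1}``. ``energies`` carries the matching per-sweep
    total energy (used by the exact-enumeration validation harness).
    """

    values: np.ndarray
    temperature: float
    side_length: int
    seed: int
    init_mode: str
    burn_in: int = 0
    energies: Optional[np.ndarray] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.init_mode not in INIT_MODES:
            raise ValueError(f"init_mode must be one of {INIT_MODES}")
        if not (self.values >= -1).all() or not (self.values <= 1).all():
            raise ValueError("magnetization values must lie in [-1, 1]")
        if not 0 <= self.burn_in <= len(self.values):
            raise ValueError("burn_in must be in [0, n_total]")

    @property
    def n_total(self) -> int:
        return len(self.values)

    def post_burn_in(self) -> np.ndarray:
        """The trace with the initial transient removed."""
        return self.values[self.burn_in :]


def magnetization(state: LatticeState) -> float:
    """Total magnetization ``M = (1/N) sum_i sigma_i`` in [-1, 1]."""
    return float(state.spins.sum()) / state.n_sites


def total_energy(state: LatticeState, params: ModelParams) -> float:
    """Hamiltonian ``-J * sum_bonds sigma_i sigma_j`` (right+down convention)."""
    s = state.spins.astype(np.int64)
    bonds = (s * np.roll(s, -1, axis=0)).sum() + (s * np.roll(s, -1, axis=1)).sum()
    return -params.coupling * float(bonds)


def _neighbor_sum(spins: np.ndarray, row: int, col: int) -> int:
    L = spins.shape[0]
    return int(
        spins[(row - 1) % L, col]
        + spins[(row + 1) % L, col]
        + spins[row, (col - 1) % L]
        + spins[row, (col + 1) % L]
    )


def flip_delta_energy(
    state: LatticeState, params: ModelParams, site: tuple[int, int]
) -> float:
    """Energy change from flipping the spin at ``site = (row, col)``.

    ``dE = 2*J*sigma_site*sum(neighbours)``; identical to the difference of
    :func:`total_energy` before/after the flip for every lattice, including
    the double-counted L = 2 case (the neighbour sum then repeats each
    distinct neighbour twice, matching the bond convention).
    """
    row, col = site
    L = state.side_length
    if not (0 <= row < L and 0 <= col < L):
        raise IndexError(f"site {site} outside {L}x{L} lattice")
    sigma = int(state.spins[row, col])
    return 2.0 * params.coupling * sigma * _neighbor_sum(state.spins, row, col)


def metropolis_sweep(
    state: LatticeState, params: ModelParams, rng: np.random.Generator
) -> LatticeState:
    """One Metropolis sweep: every site proposed once, in a fresh random order.

    Pure-numpy reference implementation of the update rule used by the
    compiled kernel behind :func:`simulate`; updates are in place and
    sequential (each proposal sees all earlier flips of the same sweep).
    Flips are accepted when ``dE <= 0``, otherwise with probability
    ``exp(-dE/(k T))``.
    """
    L = state.side_length
    accept = params.acceptance_table()
    spins = state.spins
    order = rng.permutation(L * L)
    draws = rng.random(L * L)
    for i, flat in enumerate(order):
        row, col = divmod(int(flat), L)
        sigma = int(spins[row, col])
        p = accept[sigma * _neighbor_sum(spins, row, col) + 4]
        if p >= 1.0 or draws[i] < p:
            spins[row, col] = -sigma
    return state


def simulate(
    params: ModelParams,
    L: int,
    n_sweeps: int,
    init_mode: str = "all_up",
    seed: int = 0,
) -> MagnetizationSeries:
    """Evolve an ``L x L`` lattice for ``n_sweeps`` sweeps; record M each sweep.

    ``init_mode='all_up'`` starts fully magnetized (used below the critical
    temperature to avoid metastable two-cluster states); ``'random'`` draws
    each spin +/-1 equiprobably (used at and above criticality). The
    trajectory is a deterministic function of the arguments.
    """
    if n_sweeps < 1:
        raise ValueError("n_sweeps must be >= 1")
    if L < 2:
        raise ValueError("L must be >= 2")
    if init_mode == "all_up":
        state = LatticeState.all_up(L)
    elif init_mode == "random":
        state = LatticeState.random(L, np.random.default_rng(seed))
    else:
        raise ValueError(f"init_mode must be one of {INIT_MODES}")
    seed = int(seed)
    if not 0 <= seed < 2**32:
        raise ValueError("seed must fit in uint32")
    mag, energy = metropolis_trace(
        state.spins, n_sweeps, params.acceptance_table(), seed, params.coupling
    )
    return MagnetizationSeries(
        values=mag,
        temperature=params.temperature,
        side_length=L,
        seed=seed,
        init_mode=init_mode,
        energies=energy,
    )
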