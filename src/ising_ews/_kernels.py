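"""Compiled Metropolis sweep kernel.

The hot loop lives here so the public API in :mod:`ising_ews.lattice` stays
readable. The kernel seeds numba's internal RNG, so a trajectory is a pure
function of (initial spins, n_sweeps, acceptance table, seed).
"""

import numpy as np
from numba import njit


@njit(cache=True)
def metropolis_trace(spins, n_sweeps, accept, seed, coupling):
    """Run ``n_sweeps`` Metropolis sweeps in place, recording M and E per sweep.

    ``accept[s*sigma + 4]`` is the acceptance probability for flipping a spin
    ``sigma`` whose four periodic neighbours sum to ``s`` (dE = 2*J*sigma*s).
    A sweep visits every site exactly once in a fresh random permutation;
    updates are sequential, so each proposal sees all earlier flips of the
    same sweep.
    """
    np.random.seed(seed)
    L = spins.shape[0]
    N = L * L

    ip = np.empty(L, np.int64)
    im = np.empty(L, np.int64)
    for i in range(L):
        ip[i] = (i + 1) % L
        im[i] = (i - 1) % L

    m = 0
    for r in range(L):
        for c in range(L):
            m += spins[r, c]
    # bond convention: each site paired with its right and down neighbour
    e = 0.0
    for r in range(L):
        for c in range(L):
            e -= coupling * spins[r, c] * (spins[r, ip[c]] + spins[ip[r], c])

    perm = np.arange(N)
    mag = np.empty(n_sweeps)
    energy = np.empty(n_sweeps)
    for t in range(n_sweeps):
        for i in range(N - 1, 0, -1):  # Fisher-Yates shuffle
            j = np.random.randint(0, i + 1)
            tmp = perm[i]
            perm[i] = perm[j]
            perm[j] = tmp
        for i in range(N):
            site = perm[i]
            r = site // L
            c = site - r * L
            s = spins[r, c]
            nsum = (
                spins[im[r], c]
                + spins[ip[r], c]
                + spins[r, im[c]]
                + spins[r, ip[c]]
            )
            p = accept[s * nsum + 4]
            if p >= 1.0 or np.random.random() < p:
                spins[r, c] = -s
                m -= 2 * s
                e += 2.0 * coupling * s * nsum
        mag[t] = m / N
        energy[t] = e
    return mag, energy
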