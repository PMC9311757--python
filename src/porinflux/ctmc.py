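"""Brute-force Markov-chain oracles on a discretized 1D free-energy profile.

The channel interval is discretized into sites with nearest-neighbor hop
rates (detailed-balance split of the energy difference)

    k(i→i±1) = (D/Δz²) · exp(−β (F_{i±1} − F_i) / 2),

which recovers the Smoluchowski dynamics as Δz → 0.  Two oracles:

* an exact discrete mean-first-passage-time solve (tridiagonal linear
  system) for checking the double-quadrature MFPT, and
* a seeded Gillespie simulation of escape trajectories (numba-compiled)
  giving empirical escape-time and exit-side statistics for checking the
  rate construction.
"""

from __future__ import annotations

import numpy as np
from numba import njit
from scipy.linalg import solve_banded

from .fes import FES1D
from .transport import TransportConfig


def discretize_chain(
    fes: FES1D, config: TransportConfig,
    boundaries: tuple[float, float] | None = None, n_sites: int = 81,
):
    """Site positions, energies and hop rates (1/ns) of the lattice chain."""
    if boundaries is None:
        boundaries = config.channel if config.channel is not None else fes.channel
    a, b = boundaries
    z = np.linspace(a, b, n_sites)
    dz = z[1] - z[0]
    F = np.interp(z, fes.z, fes.F)
    pref = config.D_A2_ns / dz**2
    k_right = pref * np.exp(-0.5 * config.beta * (np.roll(F, -1) - F))[:-1]
    k_left = pref * np.exp(-0.5 * config.beta * (np.roll(F, 1) - F))[1:]
    return z, F, k_right, k_left  # k_right[i]: i→i+1; k_left[i-1]: i→i-1


def discrete_mfpt(
    fes: FES1D, config: TransportConfig, z_start: float,
    boundaries: tuple[float, float] | None = None, n_sites: int = 401,
) -> float:
    """Exact mean absorption time (ns) of the lattice chain, both ends absorbing."""
    z, _F, k_right, k_left = discretize_chain(fes, config, boundaries, n_sites)
    n_in = n_sites - 2
    # interior sites 1..n-2: R_i T_i - k+_i T_{i+1} - k-_i T_{i-1} = 1
    kp = k_right[1:]  # i→i+1 for interior i = 1..n-2
    km = k_left[:-1]  # i→i-1 for interior i (k_left[i-1])
    ab = np.zeros((3, n_in))
    ab[0, 1:] = -kp[:-1]
    ab[1, :] = kp + km
    ab[2, :-1] = -km[1:]
    T = solve_banded((1, 1), ab, np.ones(n_in))
    return float(np.interp(z_start, z[1:-1], T))


@njit(cache=True)
def _gillespie_escape(k_right, k_left, start, n_traj, seed):  # pragma: no cover
    np.random.seed(seed)
    n = k_right.size + 1  # number of sites
    times = np.empty(n_traj)
    exit_trans = np.zeros(n_traj, dtype=np.int64)
    for t in range(n_traj):
        i = start
        clock = 0.0
        while 0 < i < n - 1:
            kp = k_right[i]
            km = k_left[i - 1]
            rate = kp + km
            clock += np.random.exponential(1.0 / rate)
            if np.random.random() < kp / rate:
                i += 1
            else:
                i -= 1
        times[t] = clock
        exit_trans[t] = 1 if i == n - 1 else 0
    return times, exit_trans


def simulate_escape(
    fes: FES1D, config: TransportConfig, z_start: float,
    boundaries: tuple[float, float] | None = None,
    n_sites: int = 81, n_traj: int = 100_000, seed: int = 0,
) -> dict:
    """Gillespie escape statistics from ``z_start`` to the channel ends.

    Returns the empirical mean escape time (ns), the trans-exit fraction,
    and standard errors; ``seed`` fixes the trajectory stream.
    """
    z, _F, k_right, k_left = discretize_chain(fes, config, boundaries, n_sites)
    start = int(np.argmin(np.abs(z - z_start)))
    if start == 0 or start == z.size - 1:
        raise ValueError("start point coincides with an absorbing boundary")
    times, exit_trans = _gillespie_escape(k_right, k_left, start, n_traj,
                                          seed % 2**31)
    return {
        "mean_escape_ns": float(times.mean()),
        "sem_escape_ns": float(times.std() / np.sqrt(n_traj)),
        "phi_trans": float(exit_trans.mean()),
        "sem_phi_trans": float(exit_trans.std() / np.sqrt(n_traj)),
        "n_traj": n_traj,
        "start_z": float(z[start]),
    }
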