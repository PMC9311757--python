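"""Translocation currents, rates and dwell times from a 1D free-energy profile.

Model
-----
A substrate diffusing through a channel along z with a bulk-referenced
potential of mean force F(z) and a position-independent effective diffusion
constant D obeys the 1D Smoluchowski equation.  At low concentration the
steady-state current is linear in the concentration gradient with
permeability (Kramers-type integral over the channel interval)

    P = D σ_ref γ / ∫_cis^trans exp(F(z)/kT) dz ,

where σ_ref converts a 3D bulk concentration into a 1D boundary density
(default: the area of a 17 Å reference cylinder) and γ = 6.0221e-4
molecules/Å³ per M.  Saturation is described by a two-state (empty/occupied)
Markov model with single occupancy: entry rates kon·c and exit rates
koff_cis / koff_trans built from the mean first-passage time out of the
deepest channel well and the splitting probabilities; the saturated current
is Imax(cis→trans) = koff_trans and the dwell time is
τ_b = 1/(koff_trans + koff_cis).

All integrals are trapezoid quadratures, log-sum-exp stabilized where the
barrier can overflow exp().  The finite-difference Smoluchowski solver
serves as an internal brute-force oracle for the Kramers integral.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.linalg import solve_banded
from scipy.special import logsumexp

from .constants import (
    DEFAULT_D_NM2_PER_NS,
    DEFAULT_SIGMA_REF_A2,
    DEFAULT_TEMPERATURE_K,
    MOLAR_TO_PER_A3,
    NM2_PER_NS_TO_A2_PER_NS,
    PER_NS_TO_PER_S,
    kT,
)
from .fes import FES1D, find_features


@dataclass
class TransportConfig:
    """Knobs of the transport stage.

    D is the effective diffusion constant in nm²/ns; σ_ref the reference
    cross-section (Ų) converting molar concentration to 1D boundary
    density; the channel interval defaults to the one detected on the
    profile.
    """

    D: float = DEFAULT_D_NM2_PER_NS  # nm²/ns
    temperature: float = DEFAULT_TEMPERATURE_K  # K
    sigma_ref: float = DEFAULT_SIGMA_REF_A2  # Ų
    channel: tuple[float, float] | None = None  # Å

    def __post_init__(self) -> None:
        if self.D <= 0 or self.sigma_ref <= 0:
            raise ValueError("D and sigma_ref must be positive")
        if self.channel is not None and self.channel[0] >= self.channel[1]:
            raise ValueError("channel interval must satisfy z_cis < z_trans")

    @property
    def D_A2_ns(self) -> float:
        return self.D * NM2_PER_NS_TO_A2_PER_NS

    @property
    def beta(self) -> float:
        return 1.0 / kT(self.temperature)


@dataclass
class RateSet:
    """Two-state Markov rates of the single-occupancy channel."""

    kon_cis: float  # s⁻¹ M⁻¹
    kon_trans: float  # s⁻¹ M⁻¹
    koff_cis: float  # s⁻¹
    koff_trans: float  # s⁻¹
    tau_b: float  # s, = 1/(koff_trans + koff_cis)
    phi_cis: float
    phi_trans: float
    well_z: float  # Å, occupied-state position
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name in ("kon_cis", "kon_trans", "koff_cis", "koff_trans"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be ≥ 0")
        if abs(self.phi_cis + self.phi_trans - 1.0) > 1e-9:
            raise ValueError("splitting probabilities must sum to 1")


@dataclass
class CurrentCurve:
    """Current vs concentration with its linear and saturated characteristics."""

    concentration: np.ndarray  # M
    current: np.ndarray  # molecules/s
    permeability: float  # s⁻¹ M⁻¹
    imax: float  # s⁻¹ (= koff_trans)
    k_half: float  # M
    c_sat90: float  # M, where I = 0.9 Imax
    rates: RateSet


def _channel_grid(fes: FES1D, config: TransportConfig, n: int = 2001):
    a, b = config.channel if config.channel is not None else (
        fes.channel if fes.channel is not None else (fes.z[0], fes.z[-1]))
    if a < fes.z[0] or b > fes.z[-1]:
        raise ValueError(f"channel interval [{a}, {b}] outside the profile grid")
    z = np.linspace(a, b, n)
    return z, np.interp(z, fes.z, fes.F)


def permeability(fes: FES1D, config: TransportConfig) -> float:
    """Kramers-integral permeability P in molecules s⁻¹ M⁻¹.

    Computed in log-space, so arbitrarily high barriers underflow to P = 0
    rather than overflowing the quadrature.
    """
    z, F = _channel_grid(fes, config)
    w = np.empty_like(z)  # trapezoid weights
    w[1:-1] = (z[2:] - z[:-2]) / 2
    w[0] = (z[1] - z[0]) / 2
    w[-1] = (z[-1] - z[-2]) / 2
    log_integral = logsumexp(config.beta * F, b=w)  # log ∫ e^{βF} dz, Å
    log_P_ns = (np.log(config.D_A2_ns * config.sigma_ref * MOLAR_TO_PER_A3)
                - log_integral)
    return float(np.exp(log_P_ns) * PER_NS_TO_PER_S)


def smoluchowski_flux(
    fes: FES1D, config: TransportConfig, c_cis: float, c_trans: float,
    n_grid: int = 2000,
) -> float:
    """Steady-state flux (molecules/s) from a finite-difference Smoluchowski solve.

    Dirichlet boundary densities ρ = c·γ·σ_ref per unit z at the channel
    ends; the stationary equation d/dz[D e^{−βF} d/dz(e^{βF} ρ)] = 0 is
    discretized with interface-averaged mobilities and solved as a
    tridiagonal system.  This is the brute-force oracle for
    :func:`permeability`.
    """
    if n_grid < 100:
        raise ValueError("n_grid must be ≥ 100")
    z, F = _channel_grid(fes, config, n=n_grid)
    dz = z[1] - z[0]
    bF = config.beta * F
    bF_shift = -bF.max()  # keep exp(-βF) ≤ 1 in the mobilities
    bF = bF + bF_shift
    a_mid = np.exp(-0.5 * (bF[:-1] + bF[1:]))  # mobility at interfaces

    # Boundary densities equilibrated with the bulk reservoirs (F = 0 there):
    # in the variable u = e^{βF}ρ the Dirichlet value is simply c·γ·σ_ref.
    u0 = c_cis * MOLAR_TO_PER_A3 * config.sigma_ref
    uN = c_trans * MOLAR_TO_PER_A3 * config.sigma_ref

    n_in = n_grid - 2
    ab = np.zeros((3, n_in))
    rhs = np.zeros(n_in)
    ab[0, 1:] = a_mid[1:-1]  # super-diagonal
    ab[1, :] = -(a_mid[:-1] + a_mid[1:])
    ab[2, :-1] = a_mid[1:-1]  # sub-diagonal
    rhs[0] -= a_mid[0] * u0
    rhs[-1] -= a_mid[-1] * uN
    try:
        u_in = solve_banded((1, 1), ab, rhs)
    except np.linalg.LinAlgError as exc:
        raise RuntimeError(f"Smoluchowski linear solve failed: {exc}") from exc
    u = np.concatenate([[u0], u_in, [uN]])

    # J = -D e^{-βF} d(e^{βF}ρ)/dz; a_mid carries the gauge factor e^{+shift}
    # while the u boundary values are gauge-free, so restore e^{-shift} once.
    J_ns = -config.D_A2_ns * a_mid[0] * (u[1] - u[0]) / dz * np.exp(bF_shift)
    return float(J_ns * PER_NS_TO_PER_S)


def mfpt(
    fes: FES1D, config: TransportConfig, z_start: float,
    boundaries: tuple[float, float] | None = None,
    reflecting: str | None = None,
    n_grid: int = 4001,
) -> float:
    """Mean first-passage time (ns) from ``z_start`` to the boundaries.

    Double-quadrature solution of the adjoint (backward) equation
    D e^{βF} d/dz[e^{−βF} dT/dz] = −1 with two absorbing boundaries, or,
    with ``reflecting`` in {"cis", "trans"}, the classical single-barrier
    form with one reflecting end.
    """
    if boundaries is None:
        boundaries = config.channel if config.channel is not None else fes.channel
        if boundaries is None:
            boundaries = (float(fes.z[0]), float(fes.z[-1]))
    a, b = boundaries
    if not (a <= z_start <= b):
        raise ValueError(f"z_start {z_start} outside boundaries [{a}, {b}]")
    z = np.linspace(a, b, n_grid)
    F = np.interp(z, fes.z, fes.F)
    bF = config.beta * F
    D = config.D_A2_ns
    ep = np.exp(bF - bF.max())
    em = np.exp(-(bF - bF.min()))
    # scale factors restored explicitly below
    sp, sm = np.exp(bF.max()), np.exp(bF.min())

    if reflecting == "trans":  # mirror: reflecting at b, absorbing at a
        z, ep, em = z[::-1] * -1, ep[::-1], em[::-1]
        z_start = -z_start
        reflecting = "cis"

    G = cumulative_trapezoid(em, z, initial=0.0) / sm  # ∫ e^{-βF}, scaled back
    E = cumulative_trapezoid(ep, z, initial=0.0) * sp  # ∫ e^{+βF}

    if reflecting is None:
        inner = cumulative_trapezoid(ep * G, z, initial=0.0) * sp  # ∫ e^{βF} G
        C = inner[-1] / E[-1] / D
        Tz = C * E - inner / D
    elif reflecting == "cis":  # reflecting at a, absorbing at b
        inner = cumulative_trapezoid(ep * G, z, initial=0.0) * sp
        Tz = (inner[-1] - inner) / D
    else:
        raise ValueError(f"reflecting must be None, 'cis' or 'trans', got {reflecting!r}")
    return float(np.interp(z_start, z, Tz))


def splitting_probability(
    fes: FES1D, config: TransportConfig, z_start: float,
    boundaries: tuple[float, float] | None = None, n_grid: int = 4001,
) -> float:
    """Probability of reaching the trans boundary before the cis one."""
    if boundaries is None:
        boundaries = config.channel if config.channel is not None else fes.channel
    a, b = boundaries
    z = np.linspace(a, b, n_grid)
    bF = config.beta * np.interp(z, fes.z, fes.F)
    ep = np.exp(bF - bF.max())
    E = cumulative_trapezoid(ep, z, initial=0.0)
    return float(np.interp(z_start, z, E) / E[-1])


def rates_from_fes(fes: FES1D, config: TransportConfig) -> RateSet:
    """Two-state Markov rates from the profile.

    The occupied state is the deepest well inside the channel (wells within
    0.5 kT of each other: the widest wins, with a warning; no well at all:
    the deepest interior point, flagged).  The escape time is the MFPT from
    the well to both channel ends; koff splits it by the diffusive
    splitting probabilities.  kon_cis is fixed by linear-regime consistency
    kon_cis = P (koff_cis + koff_trans)/koff_trans, and mirrored for
    kon_trans, so the Markov current's initial slope equals the Kramers
    permeability by construction.
    """
    a, b = config.channel if config.channel is not None else fes.channel
    flags: list[str] = []
    wells = [f for f in find_features(fes) if f.kind == "minimum" and a < f.z < b]
    if wells:
        depth_sorted = sorted(wells, key=lambda f: f.value)
        best = depth_sorted[0]
        near = [w for w in depth_sorted if w.value - best.value < 0.5 * kT(fes.temperature)]
        if len(near) > 1:
            widths = [_well_width(fes, w.z) for w in near]
            best = near[int(np.argmax(widths))]
            warnings.warn(
                f"{len(near)} wells within 0.5 kT; using the widest at z={best.z:g} Å"
            )
        z_w = best.z
    else:
        sel = (fes.z > a) & (fes.z < b)
        z_w = float(fes.z[sel][np.argmin(fes.F[sel])])
        flags.append("no_well:deepest_interior_point")

    tau_escape_s = mfpt(fes, config, z_w, boundaries=(a, b)) / PER_NS_TO_PER_S
    phi_trans = splitting_probability(fes, config, z_w, boundaries=(a, b))
    phi_cis = 1.0 - phi_trans
    koff_trans = phi_trans / tau_escape_s
    koff_cis = phi_cis / tau_escape_s
    P = permeability(fes, config)
    ksum = koff_cis + koff_trans
    kon_cis = P * ksum / koff_trans if koff_trans > 0 else 0.0
    kon_trans = P * ksum / koff_cis if koff_cis > 0 else 0.0
    return RateSet(
        kon_cis=kon_cis, kon_trans=kon_trans,
        koff_cis=koff_cis, koff_trans=koff_trans,
        tau_b=1.0 / ksum, phi_cis=phi_cis, phi_trans=phi_trans,
        well_z=z_w, flags=flags,
    )


def _well_width(fes: FES1D, z_w: float, rise_kcal: float = 0.5) -> float:
    """Width of the well at z_w: distance between the points where F has
    risen by ``rise_kcal`` above the well bottom on each side."""
    F0 = float(fes.interp(z_w))
    zl = zr = z_w
    z, F = fes.z, fes.F
    left = z[z < z_w]
    for zz in left[::-1]:
        if np.interp(zz, z, F) > F0 + rise_kcal:
            zl = zz
            break
    for zz in z[z > z_w]:
        if np.interp(zz, z, F) > F0 + rise_kcal:
            zr = zz
            break
    return float(zr - zl)


def markov_current(rates: RateSet, c_cis: float, c_trans: float = 0.0) -> float:
    """Steady-state current (molecules/s) of the single-occupancy channel.

    I = (kon_cis c_cis koff_trans − kon_trans c_trans koff_cis)
        / (kon_cis c_cis + kon_trans c_trans + koff_cis + koff_trans).

    With c_trans = 0 this is monotone saturating toward koff_trans.
    """
    if c_cis < 0 or c_trans < 0:
        raise ValueError("concentrations must be ≥ 0")
    num = rates.kon_cis * c_cis * rates.koff_trans - rates.kon_trans * c_trans * rates.koff_cis
    den = rates.kon_cis * c_cis + rates.kon_trans * c_trans + rates.koff_cis + rates.koff_trans
    return float(num / den) if den > 0 else 0.0


def current_curve(
    fes: FES1D, config: TransportConfig, c_grid: np.ndarray,
    c_trans: float = 0.0,
) -> CurrentCurve:
    """Current vs cis concentration with P, Imax, K_half and c_sat90."""
    c_grid = np.asarray(c_grid, dtype=float)
    if np.any(c_grid <= 0) or np.any(np.diff(c_grid) <= 0):
        raise ValueError("c_grid must be positive and strictly ascending")
    rates = rates_from_fes(fes, config)
    I = np.array([markov_current(rates, c, c_trans) for c in c_grid])
    ksum = rates.koff_cis + rates.koff_trans
    k_half = ksum / rates.kon_cis if rates.kon_cis > 0 else np.inf
    return CurrentCurve(
        concentration=c_grid,
        current=I,
        permeability=permeability(fes, config),
        imax=rates.koff_trans,
        k_half=k_half,
        c_sat90=9.0 * k_half,
        rates=rates,
    )
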