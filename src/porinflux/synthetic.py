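"""Synthetic conformer ensembles and 2D free-energy surfaces with known truth.

These generators stand in for the two expensive inputs of a porin-permeation
study — solvated small-molecule MD ensembles and metadynamics free-energy
surfaces — so that every downstream stage (descriptors, marginalization,
transport) can be tested against an analytic ground truth.  All randomness
is seeded and reproducible.

Conformer templates
-------------------
``rod``             collinear atoms along z, rigid (identical frames).
``sphere_cluster``  a compact seeded cluster, rigid across frames.
``flexible_chain``  a chain whose internal bond directions fluctuate
                    frame-to-frame with a stated rms angle (radians);
                    zero flexibility reduces to the rigid rod.

Surface model
-------------
F(cv1, z) = m(z)·[ barrier·G(z; σ_b) − Σ depth·G(z − z_w; σ_w) + roughness ]
            + confinement(cv1) [+ cv1-coupling when non-separable]

where m(z) is a smoothstep mask that is exactly 0 over a ``bulk_width``
plateau at both z ends (the bulk reference downstream), and G is a unit
Gaussian.  In the separable case the marginal over CV1 is analytic: it is
the z-part itself, since the CV1 confinement contributes a constant that
cancels in bulk referencing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .ensemble import ConformerEnsemble, read_ensemble, write_ensemble
from .fes import FES1D, FES2D, read_fes2d, write_fes2d


@dataclass
class MoleculeSpec:
    """Recipe for a synthetic conformer ensemble."""

    template: str  # rod | sphere_cluster | flexible_chain
    n_atoms: int
    bond_length: float = 1.5  # Å
    atom_radius: float = 1.7  # Å
    charges: np.ndarray | None = None  # e, must sum to net_charge
    net_charge: float = 0.0
    flexibility: float = 0.0  # rms angular fluctuation, radians
    n_frames: int = 1
    seed: int = 0
    masses: np.ndarray | None = None

    _TEMPLATES = ("rod", "sphere_cluster", "flexible_chain")

    def __post_init__(self) -> None:
        if self.template not in self._TEMPLATES:
            raise ValueError(f"unknown template {self.template!r}; choose from {self._TEMPLATES}")
        if self.n_atoms < 1 or self.n_frames < 1:
            raise ValueError("n_atoms and n_frames must be ≥ 1")
        if self.atom_radius <= 0 or self.bond_length <= 0:
            raise ValueError("atom_radius and bond_length must be positive")
        if self.flexibility < 0:
            raise ValueError("flexibility must be ≥ 0")
        if self.charges is None:
            self.charges = np.full(self.n_atoms, self.net_charge / self.n_atoms)
        self.charges = np.asarray(self.charges, dtype=float)
        if self.charges.shape != (self.n_atoms,):
            raise ValueError("charges must have one entry per atom")
        if abs(self.charges.sum() - self.net_charge) > 1e-9:
            raise ValueError(
                f"charges sum to {self.charges.sum():.12g}, declared net charge "
                f"is {self.net_charge:.12g}"
            )
        if self.masses is None:
            self.masses = np.full(self.n_atoms, 12.0)
        self.masses = np.asarray(self.masses, dtype=float)


def _chain_frame(rng: np.random.Generator, n: int, bond: float, flex: float) -> np.ndarray:
    """One chain conformation: bond directions random-walk with rms angle flex."""
    pos = np.zeros((n, 3))
    d = np.array([0.0, 0.0, 1.0])
    for i in range(1, n):
        if flex > 0:
            theta = rng.normal(0.0, flex)
            phi = rng.uniform(0.0, 2 * np.pi)
            # rotate d by theta about a random axis perpendicular to it
            perp = np.cross(d, [1.0, 0.0, 0.0])
            if np.linalg.norm(perp) < 1e-8:
                perp = np.cross(d, [0.0, 1.0, 0.0])
            perp /= np.linalg.norm(perp)
            perp2 = np.cross(d, perp)
            axis = np.cos(phi) * perp + np.sin(phi) * perp2
            d = d * np.cos(theta) + np.cross(axis, d) * np.sin(theta)
            d /= np.linalg.norm(d)
        pos[i] = pos[i - 1] + bond * d
    return pos


def gen_conformers(spec: MoleculeSpec) -> ConformerEnsemble:
    """Generate a conformer ensemble; deterministic for a fixed seed."""
    rng = np.random.default_rng(spec.seed)
    n, nf = spec.n_atoms, spec.n_frames
    if spec.template == "rod":
        base = np.zeros((n, 3))
        base[:, 2] = spec.bond_length * np.arange(n)
        frames = np.repeat(base[None], nf, axis=0)
    elif spec.template == "sphere_cluster":
        if n == 1:
            base = np.zeros((1, 3))
        else:
            r_cluster = spec.bond_length * max(1.0, n ** (1 / 3))
            pts = rng.normal(size=(n, 3))
            pts /= np.linalg.norm(pts, axis=1, keepdims=True)
            base = pts * (r_cluster * rng.uniform(0, 1, size=(n, 1)) ** (1 / 3))
        frames = np.repeat(base[None], nf, axis=0)
    else:  # flexible_chain
        frames = np.stack([_chain_frame(rng, n, spec.bond_length, spec.flexibility)
                           for _ in range(nf)])
    return ConformerEnsemble(
        frames=frames,
        charges=spec.charges.copy(),
        radii=np.full(n, spec.atom_radius),
        masses=spec.masses.copy(),
        elements=["C"] * n,
    )


@dataclass
class FesSpec:
    """Recipe for a synthetic 2D free-energy surface."""

    z_range: tuple[float, float] = (-25.0, 25.0)  # Å
    cv1_range: tuple[float, float] = (-1.0, 1.0)
    shape: tuple[int, int] = (41, 101)  # (n_cv1, n_z)
    bulk_width: float = 5.0  # Å of exact-zero plateau at each z end
    barrier_height: float = 3.0  # kcal/mol at z ≈ 0
    barrier_width: float = 3.0  # Gaussian σ, Å
    wells: list[tuple[float, float]] = field(default_factory=list)  # (depth kcal/mol, z Å)
    well_width: float = 2.0  # Å
    separable: bool = True
    cv1_confinement: float = 1.0  # kcal/mol · cv1² confinement term
    roughness_amplitude: float = 0.0  # kcal/mol
    seed: int = 0

    def __post_init__(self) -> None:
        if self.barrier_height < 0:
            raise ValueError("barrier_height must be ≥ 0")
        z0, z1 = self.z_range
        if z1 <= z0:
            raise ValueError("z_range must be increasing")
        inner = (z0 + self.bulk_width, z1 - self.bulk_width)
        for depth, zw in self.wells:
            if depth < 0:
                raise ValueError("well depths are positive magnitudes")
            if not (inner[0] < zw < inner[1]):
                raise ValueError(
                    f"well at z={zw} outside the non-bulk interval {inner}"
                )


@dataclass
class FesGroundTruth:
    """Analytic truth shipped with a generated surface."""

    marginal: FES1D | None  # exact bulk-referenced 1D marginal (separable only)
    barrier_height: float  # kcal/mol
    barrier_z: float
    well_positions: list[float]


def _smooth_mask(z: np.ndarray, z0: float, z1: float, bulk: float) -> np.ndarray:
    """Exactly 0 over [z0, z0+bulk] and [z1-bulk, z1], 1 in the core,
    C¹ smoothstep ramps of width `bulk` in between."""
    def ramp(t: np.ndarray) -> np.ndarray:
        t = np.clip(t, 0.0, 1.0)
        return t * t * (3 - 2 * t)

    up = ramp((z - (z0 + bulk)) / bulk)
    down = ramp(((z1 - bulk) - z) / bulk)
    return up * down


def _roughness_1d(rng: np.random.Generator, z: np.ndarray, amp: float) -> np.ndarray:
    """Seeded band-limited random field: a few low-frequency cosines."""
    span = z[-1] - z[0]
    out = np.zeros_like(z)
    for k in range(1, 5):
        a = rng.normal(0, amp / 2)
        phi = rng.uniform(0, 2 * np.pi)
        out += a * np.cos(2 * np.pi * k * (z - z[0]) / span + phi)
    return out


def gen_fes2d(spec: FesSpec) -> tuple[FES2D, FesGroundTruth]:
    """Generate a 2D surface and its analytic ground truth.

    For separable specs the ground truth carries the exact bulk-referenced
    1D marginal (the z-part of the surface; the CV1 confinement cancels).
    The value on both bulk plateaus is exactly 0 by construction.
    """
    rng = np.random.default_rng(spec.seed)
    n_cv, n_z = spec.shape
    cv1 = np.linspace(*spec.cv1_range, n_cv)
    z = np.linspace(*spec.z_range, n_z)
    mask = _smooth_mask(z, spec.z_range[0], spec.z_range[1], spec.bulk_width)

    fz = spec.barrier_height * np.exp(-z**2 / (2 * spec.barrier_width**2))
    for depth, zw in spec.wells:
        if spec.separable:
            fz -= depth * np.exp(-(z - zw) ** 2 / (2 * spec.well_width**2))
    if spec.roughness_amplitude > 0 and spec.separable:
        fz += _roughness_1d(rng, z, spec.roughness_amplitude)
    fz = fz * mask

    fcv = spec.cv1_confinement * cv1**2
    F = fz[None, :] + fcv[:, None]

    if not spec.separable:
        for depth, zw in spec.wells:
            cvw = rng.uniform(-0.5, 0.5)
            F -= (depth
                  * np.exp(-(z[None, :] - zw) ** 2 / (2 * spec.well_width**2))
                  * np.exp(-(cv1[:, None] - cvw) ** 2 / (2 * 0.3**2))
                  * mask[None, :])
        if spec.roughness_amplitude > 0:
            span_z, span_c = z[-1] - z[0], cv1[-1] - cv1[0]
            for _ in range(4):
                a = rng.normal(0, spec.roughness_amplitude / 2)
                kz, kc = rng.integers(1, 4, size=2)
                phi = rng.uniform(0, 2 * np.pi)
                F += (a * np.cos(2 * np.pi * (kz * (z[None, :] - z[0]) / span_z
                                              + kc * (cv1[:, None] - cv1[0]) / span_c) + phi)
                      * mask[None, :])

    fes = FES2D(cv1, z, F)
    marginal = None
    if spec.separable:
        from .fes import reference_to_bulk

        # exact marginal: the z-part (the CV1 confinement cancels); referenced
        # with the same default bulk-window convention as `marginalize`
        marginal = reference_to_bulk(FES1D(z, fz.copy(), temperature=fes.temperature))
    sel = np.abs(z) < 3 * spec.barrier_width
    truth = FesGroundTruth(
        marginal=marginal,
        barrier_height=float(fz[sel].max()) if spec.separable else float("nan"),
        barrier_z=float(z[sel][np.argmax(fz[sel])]) if spec.separable else 0.0,
        well_positions=[zw for _, zw in spec.wells],
    )
    return fes, truth


# ---------------------------------------------------------------------------
# Fixture round-trip helpers
# ---------------------------------------------------------------------------

def write_fixture(obj: ConformerEnsemble | FES2D, path: str | Path) -> None:
    """Write an ensemble (multi-frame XYZ + sidecar) or a FES2D (text grid)."""
    if isinstance(obj, ConformerEnsemble):
        write_ensemble(obj, path)
    elif isinstance(obj, FES2D):
        write_fes2d(obj, path)
    else:
        raise TypeError(f"cannot serialize {type(obj).__name__}")


def read_fixture(path: str | Path) -> ConformerEnsemble | FES2D:
    """Read a fixture by extension: .xyz/.pdb → ensemble, anything else → FES2D."""
    suffix = Path(path).suffix.lower()
    if suffix in (".xyz", ".pdb"):
        return read_ensemble(path)
    return read_fes2d(path)
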