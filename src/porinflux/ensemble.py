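"""Conformer ensembles: in-memory container and multi-frame XYZ + sidecar I/O.

An ensemble is a stack of frames of atom coordinates together with fixed
per-atom partial charges (e), van-der-Waals radii (Å) and masses (amu).
Coordinates travel as multi-frame XYZ (written/read through MDAnalysis);
the per-atom table travels as a whitespace sidecar
``index element charge vdw_radius mass``.  PDB files are accepted read-only.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


class FixtureParseError(ValueError):
    """Raised when an on-disk fixture cannot be parsed; names the line."""


@dataclass
class ConformerEnsemble:
    """Frames of atom coordinates with per-atom charge, vdW radius, mass.

    Attributes
    ----------
    frames : (n_frames, n_atoms, 3) float array, Å
    charges : (n_atoms,) float array, e
    radii : (n_atoms,) float array, Å (must be positive)
    masses : (n_atoms,) float array, amu
    elements : (n_atoms,) list of element labels
    """

    frames: np.ndarray
    charges: np.ndarray
    radii: np.ndarray
    masses: np.ndarray
    elements: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError(
                f"frames must have shape (n_frames, n_atoms, 3), got {self.frames.shape}"
            )
        n = self.frames.shape[1]
        for name in ("charges", "radii", "masses"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n,):
                raise ValueError(f"{name} must have length {n}, got {arr.shape}")
            setattr(self, name, arr)
        if np.any(self.radii <= 0):
            raise ValueError("all vdW radii must be positive")
        if not self.elements:
            self.elements = ["C"] * n
        if len(self.elements) != n:
            raise ValueError("elements must match atom count")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]

    @property
    def net_charge(self) -> float:
        return float(self.charges.sum())


def write_ensemble(ens: ConformerEnsemble, xyz_path: str | Path) -> None:
    """Write a multi-frame XYZ plus a ``.atoms`` sidecar next to it."""
    import MDAnalysis as mda

    xyz_path = Path(xyz_path)
    u = mda.Universe.empty(ens.n_atoms, trajectory=True)
    u.add_TopologyAttr("names", ens.elements)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(xyz_path), n_atoms=ens.n_atoms) as w:
            for frame in ens.frames:
                u.atoms.positions = frame
                w.write(u.atoms)
    sidecar = pd.DataFrame(
        {
            "index": np.arange(ens.n_atoms),
            "element": ens.elements,
            "charge": ens.charges,
            "vdw_radius": ens.radii,
            "mass": ens.masses,
        }
    )
    sidecar_path = xyz_path.with_suffix(".atoms")
    with open(sidecar_path, "w") as fh:
        fh.write("# index element charge vdw_radius mass\n")
        sidecar.to_csv(fh, sep=" ", index=False, header=False, float_format="%.9g")


def _read_sidecar(path: Path, n_atoms: int) -> pd.DataFrame:
    try:
        df = pd.read_csv(
            path,
            sep=r"\s+",
            comment="#",
            header=None,
            names=["index", "element", "charge", "vdw_radius", "mass"],
        )
    except Exception as exc:  # noqa: BLE001 - re-raise with file context
        raise FixtureParseError(f"{path}: cannot parse sidecar table: {exc}") from exc
    if len(df) != n_atoms:
        raise FixtureParseError(
            f"{path}: sidecar has {len(df)} atoms but trajectory has {n_atoms} "
            f"(first mismatch at line {min(len(df), n_atoms) + 2})"
        )
    return df


def read_ensemble(xyz_path: str | Path, sidecar_path: str | Path | None = None) -> ConformerEnsemble:
    """Read a multi-frame XYZ (or PDB, read-only) plus its atom sidecar.

    Without a sidecar the charges default to 0, radii to 1.7 Å and masses
    to 12 amu, with a warning.
    """
    import MDAnalysis as mda

    xyz_path = Path(xyz_path)
    if not xyz_path.exists():
        raise FileNotFoundError(xyz_path)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(xyz_path))
            frames = np.array([u.atoms.positions.copy() for _ in u.trajectory], dtype=float)
            try:
                elements = [str(n) for n in u.atoms.names]
            except mda.exceptions.NoDataError:
                elements = ["C"] * frames.shape[1]
    except FixtureParseError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise FixtureParseError(f"{xyz_path}: cannot parse coordinates: {exc}") from exc

    n_atoms = frames.shape[1]
    if sidecar_path is None:
        candidate = xyz_path.with_suffix(".atoms")
        sidecar_path = candidate if candidate.exists() else None
    if sidecar_path is not None:
        df = _read_sidecar(Path(sidecar_path), n_atoms)
        charges = df["charge"].to_numpy(float)
        radii = df["vdw_radius"].to_numpy(float)
        masses = df["mass"].to_numpy(float)
        elements = [str(e) for e in df["element"]]
    else:
        warnings.warn(f"{xyz_path}: no atom sidecar found; using default charges/radii/masses")
        charges = np.zeros(n_atoms)
        radii = np.full(n_atoms, 1.7)
        masses = np.full(n_atoms, 12.0)
    return ConformerEnsemble(frames, charges, radii, masses, elements)
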