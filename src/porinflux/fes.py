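"""Free-energy surfaces: text I/O, 2D→1D Boltzmann marginalization, features.

A 2D surface F(CV1, z) lives on a regular grid: CV1 is a dimensionless
orientation variable, z (Å) the position along the channel diffusion axis
(z = 0 at the constriction, increasing cis→trans).  The 1D profile used by
the transport stage is obtained by Boltzmann averaging over CV1,

    F₁D(z) = −kT ln [ Σ_cv1 exp(−F(cv1, z)/kT) Δcv1 ],

trapezoid weights, log-sum-exp stabilized, then shifted so that the
declared bulk windows (outer ends of the z range) average exactly zero.
Barrier heights downstream are therefore measured with respect to bulk.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import logsumexp

from .constants import DEFAULT_TEMPERATURE_K, kT


class FesParseError(ValueError):
    """Malformed FES text file; message names the offending line/block."""


@dataclass
class FES2D:
    """Free energy on a regular (CV1, z) grid.

    ``F[i, j]`` is the free energy (kcal/mol) at ``cv1[i], z[j]``.  Masked
    (non-finite) cells are tracked in ``mask`` and excluded from the CV1
    average with measure renormalization.
    """

    cv1: np.ndarray
    z: np.ndarray
    F: np.ndarray
    temperature: float = DEFAULT_TEMPERATURE_K

    def __post_init__(self) -> None:
        self.cv1 = np.asarray(self.cv1, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        if self.F.shape != (self.cv1.size, self.z.size):
            raise ValueError(
                f"F shape {self.F.shape} does not match grid "
                f"({self.cv1.size}, {self.z.size})"
            )
        for name, axis in (("cv1", self.cv1), ("z", self.z)):
            if axis.size < 2 or np.any(np.diff(axis) <= 0):
                raise ValueError(f"{name} axis must be strictly increasing with ≥2 points")

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True where F is masked (inf/nan)."""
        return ~np.isfinite(self.F)

    @property
    def n_masked(self) -> int:
        return int(self.mask.sum())


@dataclass
class Feature:
    """A well, barrier top or saddle on a profile/surface."""

    kind: str  # "minimum" | "barrier" | "saddle"
    z: float
    value: float
    cv1: float | None = None


@dataclass
class FES1D:
    """1D profile F(z) referenced so that the bulk windows average 0."""

    z: np.ndarray
    F: np.ndarray
    temperature: float = DEFAULT_TEMPERATURE_K
    bulk_windows: tuple[tuple[float, float], tuple[float, float]] | None = None
    channel: tuple[float, float] | None = None
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        if self.z.shape != self.F.shape or self.z.ndim != 1:
            raise ValueError("z and F must be 1D arrays of equal length")
        if np.any(np.diff(self.z) <= 0):
            raise ValueError("z axis must be strictly increasing")

    def interp(self, z: np.ndarray | float) -> np.ndarray | float:
        return np.interp(z, self.z, self.F)

    @property
    def barrier(self) -> Feature | None:
        for f in self.features:
            if f.kind == "barrier":
                return f
        return None

    @property
    def wells(self) -> list[Feature]:
        return [f for f in self.features if f.kind == "minimum"]


# ---------------------------------------------------------------------------
# Text dialect: '#' headers, rows "cv1 z F", cv1 varying fastest, optional
# blank lines between z-blocks.  A permissive variant allows any column
# order declared via `columns`.
# ---------------------------------------------------------------------------

def write_fes2d(fes: FES2D, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# porinflux FES2D\n")
        fh.write(f"# temperature_K {fes.temperature}\n")
        fh.write("# columns: cv1 z free_energy_kcal_mol\n")
        for j, zv in enumerate(fes.z):
            for i, cv in enumerate(fes.cv1):
                fh.write(f"{cv:.10g} {zv:.10g} {fes.F[i, j]:.10g}\n")
            fh.write("\n")


def read_fes2d(
    path: str | Path,
    columns: tuple[str, str, str] = ("cv1", "z", "F"),
    temperature: float | None = None,
) -> FES2D:
    """Read a whitespace (cv1, z, F) grid file.

    ``columns`` declares the on-file column order; any permutation of
    ``("cv1", "z", "F")`` is accepted.  Non-finite F cells are kept and
    flagged through :attr:`FES2D.mask`.  Ragged grids raise
    :class:`FesParseError` naming the offending z-block.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if sorted(columns) != ["F", "cv1", "z"]:
        raise ValueError(f"columns must be a permutation of ('cv1','z','F'), got {columns}")
    icv, iz, iF = columns.index("cv1"), columns.index("z"), columns.index("F")

    file_temp = None
    rows: list[tuple[float, float, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s:
                continue
            if s.startswith("#"):
                toks = s.lstrip("#").split()
                if len(toks) == 2 and toks[0] == "temperature_K":
                    file_temp = float(toks[1])
                continue
            parts = s.split()
            if len(parts) < 3:
                raise FesParseError(f"{path}:{lineno}: expected 3 columns, got {len(parts)}")
            try:
                vals = [float(p) for p in parts[:3]]
            except ValueError as exc:
                raise FesParseError(f"{path}:{lineno}: non-numeric value: {s!r}") from exc
            rows.append((vals[icv], vals[iz], vals[iF]))
    if not rows:
        raise FesParseError(f"{path}: no data rows")

    arr = np.asarray(rows)
    cv1_vals = np.unique(arr[:, 0])
    z_vals = np.unique(arr[:, 1])
    if cv1_vals.size * z_vals.size != arr.shape[0]:
        # locate the first short/long z-block for the error message
        counts = {zv: int(np.sum(arr[:, 1] == zv)) for zv in z_vals}
        bad = next((zv for zv, c in counts.items() if c != cv1_vals.size), None)
        raise FesParseError(
            f"{path}: ragged grid — z-block at z={bad} has {counts.get(bad)} rows, "
            f"expected {cv1_vals.size}"
        )
    F = np.full((cv1_vals.size, z_vals.size), np.nan)
    i = np.searchsorted(cv1_vals, arr[:, 0])
    j = np.searchsorted(z_vals, arr[:, 1])
    F[i, j] = arr[:, 2]
    temp = temperature if temperature is not None else (file_temp or DEFAULT_TEMPERATURE_K)
    return FES2D(cv1_vals, z_vals, F, temperature=temp)


def write_fes1d(fes: FES1D, path: str | Path) -> None:
    """Two-column text: z (Å), F (kcal/mol)."""
    with open(Path(path), "w") as fh:
        fh.write("# porinflux FES1D\n")
        fh.write(f"# temperature_K {fes.temperature}\n")
        if fes.channel is not None:
            fh.write(f"# channel {fes.channel[0]:.10g} {fes.channel[1]:.10g}\n")
        fh.write("# columns: z free_energy_kcal_mol\n")
        for zv, fv in zip(fes.z, fes.F):
            fh.write(f"{zv:.10g} {fv:.10g}\n")


def read_fes1d(path: str | Path, temperature: float | None = None) -> FES1D:
    path = Path(path)
    file_temp = None
    channel = None
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s:
                continue
            if s.startswith("#"):
                toks = s.lstrip("#").split()
                if len(toks) == 2 and toks[0] == "temperature_K":
                    file_temp = float(toks[1])
                if len(toks) == 3 and toks[0] == "channel":
                    channel = (float(toks[1]), float(toks[2]))
                continue
            parts = s.split()
            if len(parts) < 2:
                raise FesParseError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            rows.append((float(parts[0]), float(parts[1])))
    if not rows:
        raise FesParseError(f"{path}: no data rows")
    arr = np.asarray(rows)
    order = np.argsort(arr[:, 0])
    temp = temperature if temperature is not None else (file_temp or DEFAULT_TEMPERATURE_K)
    fes = FES1D(arr[order, 0], arr[order, 1], temperature=temp, channel=channel)
    return reference_to_bulk(fes) if channel is None else fes


# ---------------------------------------------------------------------------
# Marginalization and referencing
# ---------------------------------------------------------------------------

def _bulk_windows(z: np.ndarray, bulk_fraction: float) -> tuple[tuple[float, float], tuple[float, float]]:
    span = z[-1] - z[0]
    w = bulk_fraction * span
    return ((z[0], z[0] + w), (z[-1] - w, z[-1]))


def reference_to_bulk(
    fes: FES1D,
    bulk_fraction: float = 0.2,
    channel_threshold_kT: float = 0.5,
    asymmetry_warn_kcal: float = 0.5,
) -> FES1D:
    """Shift a profile so both bulk windows jointly average zero.

    Bulk windows default to the outer 20% of the z range at each end.  The
    channel interval [z_cis, z_trans] is the outermost pair of z values
    where |F| first exceeds ``channel_threshold_kT``·kT moving inward from
    the bulk windows.  A bulk-plateau mismatch beyond
    ``asymmetry_warn_kcal`` triggers a warning, not an error.
    """
    z, F = fes.z, fes.F.copy()
    (lo0, lo1), (hi0, hi1) = _bulk_windows(z, bulk_fraction)
    in_lo = (z >= lo0) & (z <= lo1)
    in_hi = (z >= hi0) & (z <= hi1)
    if not (in_lo.any() and in_hi.any()):
        raise ValueError("bulk windows contain no grid points")
    mean_lo, mean_hi = F[in_lo].mean(), F[in_hi].mean()
    if abs(mean_lo - mean_hi) > asymmetry_warn_kcal:
        warnings.warn(
            f"bulk plateaus differ by {abs(mean_lo - mean_hi):.3f} kcal/mol; "
            "referencing to their joint mean"
        )
    F -= np.concatenate([F[in_lo], F[in_hi]]).mean()

    thr = channel_threshold_kT * kT(fes.temperature)
    inner = (z > lo1) & (z < hi0)
    exceeds = np.abs(F) > thr
    cand = np.where(exceeds & inner)[0]
    if cand.size:
        channel = (float(z[cand[0]]), float(z[cand[-1]]))
    else:  # essentially flat: whole interior is "channel"
        interior = np.where(inner)[0]
        channel = (float(z[interior[0]]), float(z[interior[-1]]))
    out = FES1D(z, F, temperature=fes.temperature,
                bulk_windows=((lo0, lo1), (hi0, hi1)), channel=channel)
    out.features = find_features(out)
    return out


def marginalize(
    fes2d: FES2D,
    bulk_fraction: float = 0.2,
    channel_threshold_kT: float = 0.5,
    max_masked_fraction: float = 0.5,
) -> FES1D:
    """Boltzmann-average a 2D surface over CV1 into a bulk-referenced profile.

    Masked cells are dropped from the CV1 quadrature with renormalization of
    the integration measure; a z-column with more than
    ``max_masked_fraction`` masked cells is flagged with a warning, and an
    entirely masked column is an error.
    """
    kt = kT(fes2d.temperature)
    dcv = np.empty_like(fes2d.cv1)  # trapezoid weights on a (possibly uneven) grid
    dcv[1:-1] = (fes2d.cv1[2:] - fes2d.cv1[:-2]) / 2
    dcv[0] = (fes2d.cv1[1] - fes2d.cv1[0]) / 2
    dcv[-1] = (fes2d.cv1[-1] - fes2d.cv1[-2]) / 2
    n_cv = fes2d.cv1.size
    W = fes2d.cv1[-1] - fes2d.cv1[0]

    F1 = np.empty(fes2d.z.size)
    for j in range(fes2d.z.size):
        col = fes2d.F[:, j]
        ok = np.isfinite(col)
        if not ok.any():
            raise ValueError(f"z column {j} (z={fes2d.z[j]:g}) is entirely masked")
        n_bad = n_cv - int(ok.sum())
        if n_bad / n_cv > max_masked_fraction:
            warnings.warn(f"z={fes2d.z[j]:g}: {n_bad}/{n_cv} CV1 cells masked")
        w = dcv[ok]
        w = w * (W / w.sum())  # renormalize the measure over surviving cells
        F1[j] = -kt * logsumexp(-col[ok] / kt, b=w)

    prof = FES1D(fes2d.z, F1, temperature=fes2d.temperature)
    return reference_to_bulk(prof, bulk_fraction=bulk_fraction,
                             channel_threshold_kT=channel_threshold_kT)


# ---------------------------------------------------------------------------
# Feature extraction
# ---------------------------------------------------------------------------

def find_features(fes: FES1D, level_tol: float = 0.0) -> list[Feature]:
    """Wells and the channel barrier top of a referenced 1D profile.

    Local minima inside the channel interval are reported as wells if their
    prominence (depth below the lower of the two flanking maxima) exceeds
    ``level_tol`` (kcal/mol); the barrier is the global maximum inside the
    channel.  Sub-tolerance wiggles are suppressed.
    """
    from scipy.signal import argrelextrema

    z, F = fes.z, fes.F
    a, b = fes.channel if fes.channel is not None else (z[0], z[-1])
    if a >= b:
        raise ValueError(f"empty channel interval [{a}, {b}]")
    sel = (z >= a) & (z <= b)
    idx = np.where(sel)[0]
    feats: list[Feature] = []

    zi, Fi = z[idx], F[idx]
    jmax = int(np.argmax(Fi))
    feats.append(Feature("barrier", float(zi[jmax]), float(Fi[jmax])))

    minima = argrelextrema(Fi, np.less_equal, order=1)[0]
    for m in minima:
        if m == 0 or m == Fi.size - 1:
            continue
        left_max = Fi[:m].max()
        right_max = Fi[m + 1:].max()
        prominence = min(left_max, right_max) - Fi[m]
        if prominence > max(level_tol, 1e-12):
            if any(f.kind == "minimum" and abs(f.z - zi[m]) < 1e-9 for f in feats):
                continue
            feats.append(Feature("minimum", float(zi[m]), float(Fi[m])))
    return feats


def find_saddles_2d(fes2d: FES2D) -> list[Feature]:
    """Saddle points of a 2D surface by the 4-neighbor criterion.

    An interior cell is a saddle when it is a maximum along one grid axis
    and a minimum along the other.
    """
    F = fes2d.F
    feats: list[Feature] = []
    for i in range(1, F.shape[0] - 1):
        for j in range(1, F.shape[1] - 1):
            if not np.isfinite(F[i - 1:i + 2, j - 1:j + 2]).all():
                continue
            c = F[i, j]
            max_cv = F[i - 1, j] < c > F[i + 1, j]
            min_cv = F[i - 1, j] > c < F[i + 1, j]
            max_z = F[i, j - 1] < c > F[i, j + 1]
            min_z = F[i, j - 1] > c < F[i, j + 1]
            if (max_cv and min_z) or (min_cv and max_z):
                feats.append(Feature("saddle", float(fes2d.z[j]), float(c),
                                     cv1=float(fes2d.cv1[i])))
    return feats
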