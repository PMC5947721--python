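"""Unit cells, atomic models and Friedel-pair structure factors.

This module is the physical forward model for everything else in the
package: direct-summation structure factors with anomalous corrections
(f', f''), FFT-based map synthesis/inversion in P1, and equal-population
resolution binning.

Conventions
-----------
* Space group P1 only.  Every reflection is acentric and Bijvoet pairs
  carry independent information; no centric special cases exist.
* Phases are stored in degrees on [0, 360).  ``F_minus`` always means the
  structure factor evaluated at -h (not its conjugate); covariance algebra
  elsewhere conjugates the minus branch internally.
* Fractional coordinates, 0-based grids, x the fastest-varying map axis.
* Atomic form factors f0(s) come from the International Tables 4-Gaussian
  parameterization as tabulated by gemmi, with s = 1/d and
  (sin(theta)/lambda)^2 = 1/(4 d^2).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import gemmi
import numpy as np

__all__ = [
    "UnitCell",
    "AtomSite",
    "CrystalModel",
    "ReflectionSet",
    "ComplexSF",
    "RealMap",
    "build_reflection_set",
    "structure_factors",
    "scattering_vector_f0",
    "atom_scattering",
    "fourier_map",
    "map_to_coefficients",
    "resolution_bins",
    "default_grid_shape",
]


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class UnitCell:
    """Triclinic unit cell; lengths in Angstrom, angles in degrees."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("cell lengths must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise ValueError("cell angles must lie in (0, 180) degrees")
        if self.volume <= 0 or not np.isfinite(self.volume):
            raise ValueError("cell volume must be positive")

    @property
    def volume(self) -> float:
        ca, cb, cg = (np.cos(np.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        arg = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
        if arg <= 0:
            return -1.0
        return float(self.a * self.b * self.c * np.sqrt(arg))

    @property
    def orthogonalization_matrix(self) -> np.ndarray:
        """3x3 matrix mapping fractional to orthogonal (Angstrom) coordinates."""
        ca, cb, cg = (np.cos(np.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        sg = np.sin(np.radians(self.gamma))
        v = self.volume
        return np.array([
            [self.a, self.b * cg, self.c * cb],
            [0.0, self.b * sg, self.c * (ca - cb * cg) / sg],
            [0.0, 0.0, v / (self.a * self.b * sg)],
        ])

    @property
    def metric_tensor(self) -> np.ndarray:
        o = self.orthogonalization_matrix
        return o.T @ o

    @property
    def reciprocal_metric_tensor(self) -> np.ndarray:
        return np.linalg.inv(self.metric_tensor)

    def d_spacing(self, miller: np.ndarray) -> np.ndarray:
        """d-spacings (Angstrom) for an (N, 3) integer Miller array."""
        h = np.atleast_2d(np.asarray(miller, dtype=float))
        inv_d2 = np.einsum("ni,ij,nj->n", h, self.reciprocal_metric_tensor, h)
        return 1.0 / np.sqrt(inv_d2)

    def orthogonalize(self, frac: np.ndarray) -> np.ndarray:
        return np.asarray(frac) @ self.orthogonalization_matrix.T

    def fractionalize(self, xyz: np.ndarray) -> np.ndarray:
        return np.asarray(xyz) @ np.linalg.inv(self.orthogonalization_matrix).T

    def shortest_distance(self, frac_a: np.ndarray, frac_b: np.ndarray) -> np.ndarray:
        """Minimum-image distance (Angstrom) between fractional positions."""
        d = np.asarray(frac_a) - np.asarray(frac_b)
        d -= np.round(d)
        # minimum image in a triclinic cell: check the 27 neighbouring offsets
        offsets = np.array(np.meshgrid([-1, 0, 1], [-1, 0, 1], [-1, 0, 1])).T.reshape(-1, 3)
        cand = d[..., None, :] + offsets
        cart = cand @ self.orthogonalization_matrix.T
        return np.sqrt((cart ** 2).sum(axis=-1)).min(axis=-1)

    def to_gemmi(self) -> gemmi.UnitCell:
        return gemmi.UnitCell(self.a, self.b, self.c, self.alpha, self.beta, self.gamma)


@dataclass
class AtomSite:
    """One atom: element, fractional position, occupancy, B, anomalous terms."""

    element: str
    frac_xyz: np.ndarray
    occupancy: float = 1.0
    b_iso: float = 20.0
    f_prime: float = 0.0
    f_double_prime: float = 0.0
    role: str = "protein"  # "protein" | "anomalous"

    def __post_init__(self) -> None:
        self.frac_xyz = np.asarray(self.frac_xyz, dtype=float) % 1.0
        if not (0.0 <= self.occupancy <= 1.0):
            raise ValueError("occupancy must lie in [0, 1]")
        if self.b_iso < 0:
            raise ValueError("b_iso must be >= 0")
        if self.f_double_prime < 0:
            raise ValueError("f_double_prime must be >= 0")
        if self.role not in ("protein", "anomalous"):
            raise ValueError("role must be 'protein' or 'anomalous'")

    def copy(self) -> "AtomSite":
        return AtomSite(self.element, self.frac_xyz.copy(), self.occupancy,
                        self.b_iso, self.f_prime, self.f_double_prime, self.role)


@dataclass
class CrystalModel:
    """A unit cell plus atom list (P1)."""

    cell: UnitCell
    atoms: list
    spacegroup: str = "P1"

    def __post_init__(self) -> None:
        if len(self.atoms) == 0:
            raise ValueError("model must contain at least one atom")
        if self.spacegroup not in ("P1", "P 1"):
            raise ValueError("only space group P1 is supported")
        for a in self.atoms:
            if not np.all(np.isfinite(a.frac_xyz)):
                raise ValueError("non-finite fractional coordinates")

    @property
    def protein_atoms(self) -> list:
        return [a for a in self.atoms if a.role == "protein"]

    @property
    def anomalous_atoms(self) -> list:
        return [a for a in self.atoms if a.role == "anomalous"]

    def subset(self, atoms: Iterable[AtomSite]) -> "CrystalModel":
        return CrystalModel(self.cell, [a.copy() for a in atoms], self.spacegroup)

    def copy(self) -> "CrystalModel":
        return self.subset(self.atoms)


@dataclass
class ReflectionSet:
    """Friedel-unique Miller indices with d-spacings.

    Uniqueness convention: of each +-h pair the lexicographically greater
    triple (h, k, l) > (-h, -k, -l) is kept; (0,0,0) is excluded.
    """

    miller: np.ndarray
    d_spacing: np.ndarray
    cell: UnitCell

    def __post_init__(self) -> None:
        self.miller = np.asarray(self.miller, dtype=int).reshape(-1, 3)
        self.d_spacing = np.asarray(self.d_spacing, dtype=float)
        keys = {tuple(h) for h in self.miller}
        if len(keys) != len(self.miller):
            raise ValueError("duplicate Miller indices")
        for h in self.miller:
            if tuple(-h) in keys:
                raise ValueError("set contains a Friedel mate pair")
        ref = self.cell.d_spacing(self.miller)
        if np.any(np.abs(ref - self.d_spacing) > 1e-10 * ref):
            raise ValueError("d_spacing inconsistent with cell metric")

    def __len__(self) -> int:
        return len(self.miller)

    @property
    def s(self) -> np.ndarray:
        """|reciprocal vector| = 1/d per reflection."""
        return 1.0 / self.d_spacing


@dataclass
class ComplexSF:
    """Amplitude (electrons) and phase (degrees in [0, 360)) arrays."""

    amplitude: np.ndarray
    phase: np.ndarray

    def __post_init__(self) -> None:
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        self.phase = np.asarray(self.phase, dtype=float) % 360.0
        if np.any(self.amplitude < 0):
            raise ValueError("amplitudes must be >= 0")

    @classmethod
    def from_complex(cls, z: np.ndarray) -> "ComplexSF":
        z = np.asarray(z, dtype=complex)
        return cls(np.abs(z), np.degrees(np.angle(z)) % 360.0)

    def to_complex(self) -> np.ndarray:
        return self.amplitude * np.exp(1j * np.radians(self.phase))


@dataclass
class RealMap:
    """Electron-density samples on a fractional grid (x fastest)."""

    values: np.ndarray
    cell: UnitCell

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or min(self.values.shape) < 2:
            raise ValueError("map must be 3-D with >= 2 samples per axis")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("map values must be finite")

    @property
    def shape(self):
        return self.values.shape

    def sigma_normalized(self) -> "RealMap":
        v = self.values
        sd = v.std()
        if sd == 0:
            return RealMap(v - v.mean(), self.cell)
        return RealMap((v - v.mean()) / sd, self.cell)


# --------------------------------------------------------------------------
# operations
# --------------------------------------------------------------------------

def build_reflection_set(cell: UnitCell, d_min: float) -> ReflectionSet:
    """All Friedel-unique reflections with d >= d_min, sorted by (h, k, l)."""
    if d_min <= 0:
        raise ValueError("d_min must be positive")
    rec = cell.reciprocal_metric_tensor
    # |h_i| <= a_i / d_min is a safe box bound (generous for oblique cells);
    # exact filtering below via the reciprocal metric.
    hmax = np.ceil(np.array([cell.a, cell.b, cell.c]) / d_min).astype(int)
    ranges = [np.arange(-m, m + 1) for m in hmax]
    hh, kk, ll = np.meshgrid(*ranges, indexing="ij")
    miller = np.stack([hh.ravel(), kk.ravel(), ll.ravel()], axis=1)
    miller = miller[np.any(miller != 0, axis=1)]
    inv_d2 = np.einsum("ni,ij,nj->n", miller.astype(float), rec, miller.astype(float))
    keep = inv_d2 <= 1.0 / d_min ** 2 + 1e-12
    miller = miller[keep]
    # Friedel reduction: keep h > -h lexicographically
    neg = -miller
    gt = _lex_greater(miller, neg)
    miller = miller[gt]
    order = np.lexsort((miller[:, 2], miller[:, 1], miller[:, 0]))
    miller = miller[order]
    return ReflectionSet(miller, cell.d_spacing(miller), cell)


def _lex_greater(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    res = np.zeros(len(a), dtype=bool)
    undecided = np.ones(len(a), dtype=bool)
    for i in range(3):
        gt = undecided & (a[:, i] > b[:, i])
        lt = undecided & (a[:, i] < b[:, i])
        res[gt] = True
        undecided &= ~(gt | lt)
    return res


_F0_CACHE: dict = {}


def scattering_vector_f0(element: str, s: np.ndarray) -> np.ndarray:
    """IT 4-Gaussian f0 for ``element`` at s = 1/d (per-reflection array)."""
    el = gemmi.Element(element)
    stol2 = np.asarray(s, dtype=float) ** 2 / 4.0
    it92 = el.it92
    a = np.asarray(it92.a)
    b = np.asarray(it92.b)
    c = it92.c
    return (a[None, :] * np.exp(-b[None, :] * stol2[:, None])).sum(axis=1) + c


def atom_scattering(atom: AtomSite, s: np.ndarray) -> np.ndarray:
    """Complex per-reflection scattering g = f0(s) + f' + i f'' (no B, no occ)."""
    return scattering_vector_f0(atom.element, s) + atom.f_prime + 1j * atom.f_double_prime


def structure_factors(model: CrystalModel, refl: ReflectionSet,
                      atoms: Sequence[AtomSite] | None = None):
    """Direct-summation Friedel-pair structure factors.

    F(h) = sum_j occ_j (f0_j(s) + f'_j + i f''_j) exp(-B_j s^2/4) exp(2 pi i h.x_j)
    and F_minus = F(-h).  Returns a pair of :class:`ComplexSF`.
    """
    atoms = list(model.atoms if atoms is None else atoms)
    if len(atoms) == 0:
        z = np.zeros(len(refl), dtype=complex)
        return ComplexSF.from_complex(z), ComplexSF.from_complex(z)
    s = refl.s
    fplus = np.zeros(len(refl), dtype=complex)
    fminus = np.zeros(len(refl), dtype=complex)
    h = refl.miller.astype(float)
    # group atoms by (element, f', f'') so f0 is evaluated once per species
    groups: dict = {}
    for a in atoms:
        groups.setdefault((a.element, a.f_prime, a.f_double_prime), []).append(a)
    for (el, fp, fpp), members in groups.items():
        g = scattering_vector_f0(el, s) + fp + 1j * fpp
        xyz = np.array([a.frac_xyz for a in members])
        occ = np.array([a.occupancy for a in members])
        biso = np.array([a.b_iso for a in members])
        dw = np.exp(-biso[None, :] * (s ** 2)[:, None] / 4.0)  # (N, M)
        phase = 2.0 * np.pi * (h @ xyz.T)  # (N, M)
        w = occ[None, :] * dw
        fplus += g * (w * np.exp(1j * phase)).sum(axis=1)
        fminus += g * (w * np.exp(-1j * phase)).sum(axis=1)
    return ComplexSF.from_complex(fplus), ComplexSF.from_complex(fminus)


def default_grid_shape(cell: UnitCell, d_min: float, oversample: float = 3.0):
    """FFT-friendly grid with spacing <= d_min / oversample (>= Nyquist)."""
    def _round_up(n: int) -> int:
        while True:
            m = n
            for p in (2, 3, 5):
                while m % p == 0:
                    m //= p
            if m == 1:
                return n
            n += 1
    dims = []
    for length in (cell.a, cell.b, cell.c):
        n = int(np.ceil(oversample * length / d_min))
        dims.append(_round_up(max(n, 4)))
    return tuple(dims)


def _grid_indices(miller: np.ndarray, shape) -> tuple:
    return tuple(miller[:, i] % shape[i] for i in range(3))


def fourier_map(coeffs: ComplexSF, refl: ReflectionSet, cell: UnitCell,
                grid_shape=None, d_min: float | None = None) -> RealMap:
    """Synthesize rho(x) = (1/V) sum_h F(h) exp(-2 pi i h.x) on a real grid.

    The Friedel completion F(-h) = conj(F(h)) is applied internally, so the
    map is real for any coefficient set on the Friedel-unique indices.
    """
    if grid_shape is None:
        dmin = d_min if d_min is not None else float(refl.d_spacing.min())
        grid_shape = default_grid_shape(cell, dmin)
    shape = tuple(int(n) for n in grid_shape)
    hmax = np.abs(refl.miller).max(axis=0)
    if any(shape[i] < 2 * hmax[i] + 1 for i in range(3)):
        raise ValueError("grid undersampled for the coefficient set")
    f = np.asarray(coeffs.to_complex(), dtype=complex)
    grid = np.zeros(shape, dtype=complex)
    grid[_grid_indices(refl.miller, shape)] = f
    grid[_grid_indices(-refl.miller, shape)] = np.conj(f)
    # rho(x) = (1/V) sum_h F(h) e^{-2 pi i h.x}:  numpy fftn computes
    # sum_h A[h] e^{-2 pi i h.x/N} over grid frequencies, so fftn fits directly.
    rho = np.fft.fftn(grid).real / cell.volume
    return RealMap(rho, cell)


def map_to_coefficients(rmap: RealMap, refl: ReflectionSet) -> ComplexSF:
    """Inverse of :func:`fourier_map` on the in-set indices."""
    shape = rmap.values.shape
    hmax = np.abs(refl.miller).max(axis=0)
    if any(shape[i] < 2 * hmax[i] + 1 for i in range(3)):
        raise ValueError("grid undersampled for the reflection set")
    n = np.prod(shape)
    back = np.fft.ifftn(rmap.values) * rmap.cell.volume
    f = back[_grid_indices(refl.miller, shape)]
    return ComplexSF.from_complex(f)


def resolution_bins(refl: ReflectionSet, n_bins: int) -> np.ndarray:
    """Equal-population bin index per reflection, ordered by 1/d^2 ascending."""
    if not 1 <= n_bins <= len(refl):
        raise ValueError("n_bins out of range")
    inv_d2 = 1.0 / refl.d_spacing ** 2
    order = np.argsort(inv_d2, kind="stable")
    bins = np.empty(len(refl), dtype=int)
    splits = np.array_split(order, n_bins)
    for b, idx in enumerate(splits):
        bins[idx] = b
    return bins
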