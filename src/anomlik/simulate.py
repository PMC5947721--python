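"""Synthetic crystals, perturbed starting models and noisy Bijvoet data.

Stands in for real diffraction data: a protein-like chain (self-avoiding
random walk with 3.8 A steps, the C-alpha virtual bond length) plus planted
anomalous scatterers, perturbed along the three axes real starting models
degrade along — coordinate error, omission, and outright wrong placement —
and Gaussian measurement noise with a controllable anomalous signal level.

All generators are pure functions of their seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .crystal import (AtomSite, ComplexSF, CrystalModel, ReflectionSet,
                      UnitCell, structure_factors)

__all__ = [
    "PerturbationSpec",
    "NoiseSpec",
    "BijvoetPair",
    "ObservedData",
    "generate_ground_truth",
    "perturb_model",
    "simulate_observations",
    "anomalous_signal_profile",
    "solvent_fraction_of_model",
]

# default anomalous corrections per element (electrons), typical SAD values
DEFAULT_ANOMALOUS = {
    "Se": (-8.0, 3.8),
    "S": (0.3, 0.56),
    "I": (-0.5, 6.8),
    "P": (0.3, 0.43),
}

_PROTEIN_ELEMENTS = ("C", "C", "C", "N", "O")  # rough protein composition


@dataclass(frozen=True)
class PerturbationSpec:
    """Starting-model degradation: jitter, omission, wrong placement.

    ``coord_rms`` is the 3-D r.m.s. displacement; per-axis Gaussian sigma is
    coord_rms / sqrt(3).  ``omit_fraction`` removes round(f*n) protein atoms;
    ``wrong_fraction`` re-places round(f*n) of the survivors uniformly at
    random; ``omit_anomalous_count`` deletes that many anomalous atoms.
    """

    coord_rms: float = 0.0
    omit_fraction: float = 0.0
    wrong_fraction: float = 0.0
    omit_anomalous_count: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.omit_fraction <= 1.0 and 0.0 <= self.wrong_fraction <= 1.0):
            raise ValueError("fractions must lie in [0, 1]")
        if self.coord_rms < 0:
            raise ValueError("coord_rms must be >= 0")


@dataclass(frozen=True)
class NoiseSpec:
    """Measurement noise: per-reflection sigma = fraction * bin-mean |F|."""

    base_sigma_fraction: float = 0.04
    n_bins: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.base_sigma_fraction <= 0:
            raise ValueError("base_sigma_fraction must be > 0")


@dataclass(frozen=True)
class BijvoetPair:
    """One reflection's observed Friedel amplitudes and sigmas."""

    miller: tuple
    f_plus_obs: float
    sig_plus: float
    f_minus_obs: float
    sig_minus: float

    def __post_init__(self) -> None:
        if self.f_plus_obs < 0 or self.f_minus_obs < 0:
            raise ValueError("amplitudes must be >= 0")
        if self.sig_plus <= 0 or self.sig_minus <= 0:
            raise ValueError("sigmas must be > 0")


@dataclass
class ObservedData:
    """Vectorized container of Bijvoet-pair observations, aligned to a ReflectionSet."""

    refl: ReflectionSet
    f_plus: np.ndarray
    sig_plus: np.ndarray
    f_minus: np.ndarray
    sig_minus: np.ndarray
    truncated: np.ndarray = None  # type: ignore[assignment]  # flags for negative draws clipped at 0

    def __post_init__(self) -> None:
        n = len(self.refl)
        for name in ("f_plus", "sig_plus", "f_minus", "sig_minus"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n,):
                raise ValueError(f"{name} misaligned with reflection set")
            setattr(self, name, arr)
        if self.truncated is None:
            self.truncated = np.zeros(n, dtype=bool)
        if np.any(self.f_plus < 0) or np.any(self.f_minus < 0):
            raise ValueError("amplitudes must be >= 0")
        if np.any(self.sig_plus <= 0) or np.any(self.sig_minus <= 0):
            raise ValueError("sigmas must be > 0")

    def __len__(self) -> int:
        return len(self.refl)

    def pair(self, i: int) -> BijvoetPair:
        return BijvoetPair(tuple(self.refl.miller[i]), self.f_plus[i],
                           self.sig_plus[i], self.f_minus[i], self.sig_minus[i])

    @property
    def pairs(self) -> list:
        return [self.pair(i) for i in range(len(self))]


def generate_ground_truth(n_protein_atoms: int, n_anomalous: int, cell: UnitCell,
                          elements: str | Sequence[str] = "Se", seed: int = 0,
                          b_range=(15.0, 35.0), anomalous_occupancy: float = 1.0,
                          f_double_prime: float | None = None,
                          f_prime: float | None = None,
                          max_retries: int = 200) -> CrystalModel:
    """Protein-like chain plus anomalous scatterers, reproducible per seed.

    Protein atoms follow a self-avoiding random walk with 3.8 A steps and a
    1.0 A minimum clash distance (periodic images included); anomalous atoms
    are placed >= 3 A from every other atom.
    """
    if n_protein_atoms < 1 or n_anomalous < 1:
        raise ValueError("atom counts must be >= 1")
    rng = np.random.default_rng(seed)
    if isinstance(elements, str):
        elements = [elements] * n_anomalous
    if len(elements) != n_anomalous:
        raise ValueError("one element per anomalous atom required")

    orth = cell.orthogonalization_matrix
    inv = np.linalg.inv(orth)
    step = 3.8
    clash = 1.0

    def min_dist(frac_pt, frac_others):
        if len(frac_others) == 0:
            return np.inf
        return cell.shortest_distance(np.asarray(frac_others), frac_pt[None, :]).min()

    for attempt in range(max_retries):
        positions = [rng.random(3)]
        ok = True
        for _ in range(n_protein_atoms - 1):
            placed = False
            for _trial in range(60):
                direction = rng.normal(size=3)
                direction /= np.linalg.norm(direction)
                new_cart = cell.orthogonalize(positions[-1]) + step * direction
                new_frac = (inv @ new_cart) % 1.0
                if min_dist(new_frac, positions[:-1]) >= clash:
                    positions.append(new_frac)
                    placed = True
                    break
            if not placed:
                ok = False
                break
        if not ok:
            continue
        anom_pos = []
        for _ in range(n_anomalous):
            placed = False
            for _trial in range(400):
                p = rng.random(3)
                if min_dist(p, positions + anom_pos) >= 3.0:
                    anom_pos.append(p)
                    placed = True
                    break
            if not placed:
                ok = False
                break
        if ok:
            break
    else:
        raise RuntimeError("cell too small to place atoms at the required separations")

    atoms = []
    prot_els = [_PROTEIN_ELEMENTS[i % len(_PROTEIN_ELEMENTS)] for i in range(n_protein_atoms)]
    b_vals = rng.uniform(*b_range, size=n_protein_atoms + n_anomalous)
    for i, p in enumerate(positions):
        atoms.append(AtomSite(prot_els[i], p, 1.0, b_vals[i], 0.0, 0.0, "protein"))
    for j, p in enumerate(anom_pos):
        el = elements[j]
        fp, fpp = DEFAULT_ANOMALOUS.get(el, (0.0, 1.0))
        if f_prime is not None:
            fp = f_prime
        if f_double_prime is not None:
            fpp = f_double_prime
        atoms.append(AtomSite(el, p, anomalous_occupancy,
                              b_vals[n_protein_atoms + j], fp, fpp, "anomalous"))
    return CrystalModel(cell, atoms)


def perturb_model(truth: CrystalModel, spec: PerturbationSpec):
    """Degrade a ground-truth model per the spec; returns (model, realized_rms).

    Protein atoms: exactly round(omit_fraction * n) removed, then
    round(wrong_fraction * n_kept) re-placed uniformly at random, and the
    remaining "correct" atoms jittered with per-axis sigma coord_rms/sqrt(3).
    Anomalous atoms: omit_anomalous_count deleted (no jitter — substructure
    sites are treated as either known or absent).  realized_rms is the r.m.s.
    displacement over kept, non-re-placed protein atoms.
    """
    rng = np.random.default_rng(spec.seed)
    prot = truth.protein_atoms
    anom = truth.anomalous_atoms
    if spec.omit_anomalous_count > len(anom):
        raise ValueError("omit_anomalous_count exceeds substructure size")

    n = len(prot)
    n_omit = int(round(spec.omit_fraction * n))
    keep_idx = rng.permutation(n)[: n - n_omit]
    kept = [prot[i].copy() for i in sorted(keep_idx)]

    n_wrong = int(round(spec.wrong_fraction * len(kept)))
    wrong_idx = set(rng.permutation(len(kept))[:n_wrong].tolist())

    sigma_axis = spec.coord_rms / np.sqrt(3.0)
    inv = np.linalg.inv(truth.cell.orthogonalization_matrix)
    displacements = []
    out = []
    for i, atom in enumerate(kept):
        a = atom.copy()
        if i in wrong_idx:
            a.frac_xyz = rng.random(3)
        elif sigma_axis > 0:
            cart = truth.cell.orthogonalize(a.frac_xyz) + rng.normal(0, sigma_axis, 3)
            a.frac_xyz = (inv @ cart) % 1.0
            displacements.append(truth.cell.shortest_distance(
                a.frac_xyz[None, :], atom.frac_xyz[None, :])[0])
        else:
            displacements.append(0.0)
        out.append(a)

    omit_anom = set(rng.permutation(len(anom))[: spec.omit_anomalous_count].tolist())
    out.extend(anom[i].copy() for i in range(len(anom)) if i not in omit_anom)
    realized = float(np.sqrt(np.mean(np.square(displacements)))) if displacements else 0.0
    if len(out) == 0:
        raise ValueError("perturbation removed every atom")
    return truth.subset(out), realized


def simulate_observations(truth: CrystalModel, refl: ReflectionSet,
                          noise: NoiseSpec) -> ObservedData:
    """Noisy Bijvoet amplitudes: |F_true(+-h)| + N(0, sigma^2), sigma per bin.

    sigma is base_sigma_fraction times the bin-mean true amplitude (not the
    per-reflection amplitude, avoiding signal-dependent bias).  Negative
    draws are truncated at zero and flagged.
    """
    from .crystal import resolution_bins

    fp, fm = structure_factors(truth, refl)
    a_plus, a_minus = fp.amplitude, fm.amplitude
    n_bins = min(noise.n_bins, len(refl))
    bins = resolution_bins(refl, n_bins)
    sigma = np.empty(len(refl))
    for b in range(n_bins):
        m = bins == b
        mean_amp = 0.5 * (a_plus[m].mean() + a_minus[m].mean())
        sigma[m] = noise.base_sigma_fraction * max(mean_amp, 1e-12)
    rng = np.random.default_rng(noise.seed)
    obs_p = a_plus + rng.normal(0, 1, len(refl)) * sigma
    obs_m = a_minus + rng.normal(0, 1, len(refl)) * sigma
    truncated = (obs_p < 0) | (obs_m < 0)
    return ObservedData(refl, np.maximum(obs_p, 0.0), sigma.copy(),
                        np.maximum(obs_m, 0.0), sigma.copy(), truncated)


def anomalous_signal_profile(data: ObservedData, bins: np.ndarray):
    """Per-bin mean |dF| / sigma(dF) with dF = F+ - F- (empty bins dropped).

    Returns (bin_ids, profile); bins with no reflections are excluded.
    """
    d = data.f_plus - data.f_minus
    sd = np.sqrt(data.sig_plus ** 2 + data.sig_minus ** 2)
    ratio = np.abs(d) / sd
    out_bins, out_vals = [], []
    for b in np.unique(bins):
        m = bins == b
        if m.sum() == 0:
            continue
        out_bins.append(int(b))
        out_vals.append(float(ratio[m].mean()))
    return np.array(out_bins), np.array(out_vals)


def solvent_fraction_of_model(model: CrystalModel, probe_radius: float = 2.8,
                              grid_shape=(32, 32, 32)) -> float:
    """Fraction of cell volume farther than probe_radius from every atom.

    The Matthews-style prior a real experiment would supply; the synthetic
    scenario writer records it so the pipelines need not peek at the truth.
    """
    cell = model.cell
    nx, ny, nz = grid_shape
    fx, fy, fz = np.meshgrid(np.arange(nx) / nx, np.arange(ny) / ny,
                             np.arange(nz) / nz, indexing="ij")
    pts = np.stack([fx.ravel(), fy.ravel(), fz.ravel()], axis=1)
    xyz = np.array([a.frac_xyz for a in model.atoms])
    near = np.zeros(len(pts), dtype=bool)
    # chunked minimum-image distance to keep memory bounded
    for start in range(0, len(pts), 4096):
        chunk = pts[start:start + 4096]
        d = chunk[:, None, :] - xyz[None, :, :]
        d -= np.round(d)
        cart = d @ cell.orthogonalization_matrix.T
        dist2 = (cart ** 2).sum(axis=-1)
        near[start:start + 4096] = (dist2 <= probe_radius ** 2).any(axis=1)
    return float(1.0 - near.mean())
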