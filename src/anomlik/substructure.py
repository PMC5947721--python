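"""Anomalous-substructure detection and maintenance.

Two map types locate anomalous scatterers:

* the anomalous difference Fourier, coefficients
  (|F_o+| - |F_o-|) exp(i (phi_model - 90 deg)), used to bootstrap an
  empty substructure from partial-model phases, and
* the log-likelihood-gradient (LLG) map: the Fourier synthesis of the
  per-reflection gradients of the multivariate log-likelihood with respect
  to the substructure component, projected onto the anomalous species'
  scattering factor.  Peaks mark where adding an anomalous atom would
  increase the likelihood — this uses data, models, phasing and density
  modification together, and works at any stage.

Both maps are sigma-normalized before peak search.  Accepted peaks become
atoms (occupancy 0.5, Wilson-like B), parameters are refined, and atoms
whose occupancy refines below a threshold are pruned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .crystal import (AtomSite, ComplexSF, CrystalModel, RealMap, ReflectionSet,
                      UnitCell, atom_scattering, fourier_map)
from .errormodel import CovarianceModel
from .likelihood import (ModelSFTriple, QuadratureSpec, gradient_wrt_model_sf,
                         refine_parameters)

__all__ = [
    "PeakList",
    "SubstructureState",
    "anomalous_difference_map",
    "llg_map",
    "peak_search",
    "update_substructure",
    "wilson_b_estimate",
]

DEFAULT_PEAK_SIGMA = 4.75    # r.m.s. peak-acceptance threshold
LOW_RES_PEAK_SIGMA = 4.25    # relaxed threshold for very low-resolution data
DEFAULT_MIN_SEPARATION = 2.5  # Angstrom, peak merge radius


@dataclass
class PeakList:
    """Peaks (fractional position, height in map-sigma units), sorted descending."""

    positions: np.ndarray    # (n, 3) fractional
    heights: np.ndarray      # (n,) sigma units
    map_mean: float = 0.0
    map_sigma: float = 1.0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, float).reshape(-1, 3) % 1.0
        self.heights = np.asarray(self.heights, float)
        if len(self.heights) > 1 and np.any(np.diff(self.heights) > 1e-9):
            raise ValueError("peaks must be sorted by descending height")

    def __len__(self) -> int:
        return len(self.heights)


@dataclass
class SubstructureState:
    """Current anomalous substructure plus per-atom provenance."""

    atoms: list                      # AtomSite, role == "anomalous"
    provenance: list = field(default_factory=list)  # "initial"|"anom-diff"|"llg"|"refined"
    cycle: int = 0

    def __post_init__(self) -> None:
        if not self.provenance:
            self.provenance = ["initial"] * len(self.atoms)
        if len(self.provenance) != len(self.atoms):
            raise ValueError("provenance misaligned")
        for a in self.atoms:
            if a.role != "anomalous":
                raise ValueError("substructure atoms must have role='anomalous'")

    def copy(self) -> "SubstructureState":
        return SubstructureState([a.copy() for a in self.atoms],
                                 list(self.provenance), self.cycle)


def anomalous_difference_map(data, model_phases_deg: np.ndarray, refl: ReflectionSet,
                             cell: UnitCell, grid_shape=None) -> RealMap:
    """Sigma-normalized anomalous difference Fourier from model phases."""
    dano = data.f_plus - data.f_minus
    phases = (np.asarray(model_phases_deg, float) - 90.0) % 360.0
    coeffs = ComplexSF(np.abs(dano), np.where(dano >= 0, phases, (phases + 180.0) % 360.0))
    rmap = fourier_map(coeffs, refl, cell, grid_shape)
    return rmap.sigma_normalized()


def llg_map(data, triple: ModelSFTriple, cov: CovarianceModel,
            quad: QuadratureSpec, refl: ReflectionSet, cell: UnitCell,
            anomalous_scattering: np.ndarray, grid_shape=None) -> RealMap:
    """Sigma-normalized log-likelihood-gradient map for missing anomalous atoms.

    ``anomalous_scattering``: per-reflection complex g = f0(s) + f' + i f''
    of the anomalous species to be searched for.  An atom at fractional x
    would change the substructure SFs by dF+ = g e(h.x), dF- = conj(g
    e(h.x))*..., so the likelihood sensitivity is the Fourier synthesis of
    t_h = conj(G+) g + conj(G-) conj(g) evaluated with e^{+2 pi i h.x} —
    i.e. a map with coefficients conj(t_h) in the package's synthesis
    convention.
    """
    grads = gradient_wrt_model_sf(data, triple, cov, quad)
    name = "substructure" if "substructure" in grads.components else \
        next(iter(grads.components))
    gp, gm = grads.components[name]
    g = np.asarray(anomalous_scattering, dtype=complex)
    gmb = np.conj(gm)  # gradient w.r.t. conj(F-)
    t = np.conj(gp) * g + np.conj(gmb) * np.conj(g)
    if np.allclose(t, 0):
        shape = grid_shape or None
        zero = fourier_map(ComplexSF.from_complex(np.zeros(len(refl), complex)),
                           refl, cell, shape)
        return RealMap(zero.values, cell)
    coeffs = ComplexSF.from_complex(np.conj(t))
    rmap = fourier_map(coeffs, refl, cell, grid_shape)
    return rmap.sigma_normalized()


def peak_search(rmap: RealMap, threshold_sigma: float = DEFAULT_PEAK_SIGMA,
                min_separation: float = DEFAULT_MIN_SEPARATION,
                max_peaks: int = 50, exclude_positions=None,
                exclude_radius: float | None = None) -> PeakList:
    """Local maxima above threshold, greedily thinned by minimum separation.

    The map is sigma-normalized internally; sub-grid positions come from a
    per-axis quadratic (parabolic) interpolation through the maximum.
    ``exclude_positions`` (fractional) suppresses peaks within
    ``exclude_radius`` (default ``min_separation``) of known sites — used
    when searching for atoms *missing* from a model, whose own sites can
    carry residual gradient (e.g. an occupancy pinned at its bound).
    """
    norm = rmap.sigma_normalized()
    v = norm.values
    is_max = np.ones(v.shape, dtype=bool)
    for axis in range(3):
        for shift in (1, -1):
            is_max &= v >= np.roll(v, shift, axis=axis)
    cand = np.argwhere(is_max & (v > threshold_sigma))
    if len(cand) == 0:
        return PeakList(np.empty((0, 3)), np.empty(0), float(rmap.values.mean()),
                        float(rmap.values.std()))
    heights = v[tuple(cand.T)]
    order = np.argsort(-heights)
    cand, heights = cand[order], heights[order]

    shape = np.array(v.shape)
    accepted_pos = []
    accepted_h = []
    cell = rmap.cell
    excl = None if exclude_positions is None or len(exclude_positions) == 0 \
        else np.asarray(exclude_positions, float).reshape(-1, 3)
    excl_r = min_separation if exclude_radius is None else exclude_radius
    for idx, h in zip(cand, heights):
        frac = _parabolic_subgrid(v, idx) / shape
        if excl is not None and cell.shortest_distance(excl, frac[None, :]).min() < excl_r:
            continue
        if accepted_pos:
            d = cell.shortest_distance(np.array(accepted_pos), frac[None, :])
            if d.min() < min_separation:
                continue
        accepted_pos.append(frac)
        accepted_h.append(float(h))
        if len(accepted_pos) >= max_peaks:
            break
    return PeakList(np.array(accepted_pos), np.array(accepted_h),
                    float(rmap.values.mean()), float(rmap.values.std()))


def _parabolic_subgrid(v: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Refine a grid maximum by a 1-D parabola along each axis (periodic)."""
    out = idx.astype(float).copy()
    for axis in range(3):
        im = list(idx)
        ip = list(idx)
        im[axis] = (idx[axis] - 1) % v.shape[axis]
        ip[axis] = (idx[axis] + 1) % v.shape[axis]
        y0, y1, y2 = v[tuple(im)], v[tuple(idx)], v[tuple(ip)]
        denom = y0 - 2 * y1 + y2
        if denom < 0:
            out[axis] += 0.5 * (y0 - y2) / denom
    return out


def wilson_b_estimate(data, refl: ReflectionSet) -> float:
    """Wilson-like overall B from the slope of ln <|F|^2> vs 1/(2 d^2)."""
    inv_2d2 = 1.0 / (2.0 * refl.d_spacing ** 2)
    amp2 = 0.5 * (data.f_plus ** 2 + data.f_minus ** 2)
    nb = max(4, min(12, len(refl) // 50))
    qs = np.quantile(inv_2d2, np.linspace(0, 1, nb + 1))
    xs, ys = [], []
    for i in range(nb):
        m = (inv_2d2 >= qs[i]) & (inv_2d2 <= qs[i + 1])
        if m.sum() > 2:
            xs.append(inv_2d2[m].mean())
            ys.append(np.log(max(amp2[m].mean(), 1e-12)))
    if len(xs) < 2:
        return 20.0
    slope = np.polyfit(xs, ys, 1)[0]
    return float(np.clip(-slope, 5.0, 100.0))


def update_substructure(state: SubstructureState, peaks: PeakList, data,
                        refl: ReflectionSet, cov: CovarianceModel,
                        quad: QuadratureSpec = QuadratureSpec(),
                        element: str = "Se", f_prime: float = -8.0,
                        f_double_prime: float = 3.8,
                        prune_occ_threshold: float = 0.2,
                        merge_radius: float = DEFAULT_MIN_SEPARATION,
                        max_new_atoms: int = 4,
                        protein_sf=None, dm_sf=None,
                        cell: UnitCell | None = None) -> SubstructureState:
    """Accept peaks as new atoms, refine occupancies/B/D, prune weak atoms.

    New atoms start at occupancy 0.5 and a Wilson-like B; peaks closer than
    ``merge_radius`` to an existing atom are skipped.  After refinement,
    atoms with occupancy below ``prune_occ_threshold`` are removed.
    """
    cell = cell or refl.cell
    new_state = state.copy()
    added = 0
    for pos, h in zip(peaks.positions, peaks.heights):
        if added >= max_new_atoms:
            break
        if new_state.atoms:
            existing = np.array([a.frac_xyz for a in new_state.atoms])
            if cell.shortest_distance(existing, pos[None, :]).min() < merge_radius:
                continue
        b0 = wilson_b_estimate(data, refl)
        new_state.atoms.append(AtomSite(element, pos, 0.5, b0, f_prime,
                                        f_double_prime, "anomalous"))
        new_state.provenance.append("llg")
        added += 1

    if new_state.atoms:
        from .errormodel import component_sums
        sub = cov.component("substructure")
        sub.s2, sub.cg = component_sums(new_state.atoms, refl, cov.bins, cov.n_bins)
        cov._cond_cache = None
        res = refine_parameters(data, refl, new_state.atoms, cov, quad,
                                protein_sf=protein_sf, dm_sf=dm_sf,
                                d_components=("protein", "dm"), max_sweeps=2)
        # pure-SAD coordinate polish: positions refined against the
        # substructure alone so protein-model bias cannot drag them
        from .errormodel import build_covariance, estimate_sigma_n
        atoms_x = res.substructure
        if atoms_x:
            before = np.array([a.frac_xyz for a in atoms_x])
            sad_cov = build_covariance(
                refl, cov.bins, estimate_sigma_n(data, cov.bins, cov.n_bins),
                [("substructure", atoms_x, 0.98)])
            res_xyz = refine_parameters(data, refl, atoms_x, sad_cov, quad,
                                        refinable=("xyz",), d_components=(),
                                        max_sweeps=1)
            atoms_x = res_xyz.substructure
            # anchor the translation-flat P1 mode on the *pre-existing*
            # atoms: newly added atoms legitimately need large individual
            # corrections that must not be redistributed as a global shift
            after = np.array([a.frac_xyz for a in atoms_x])
            shift = after - before
            shift -= np.round(shift)
            n_old = len(state.atoms)
            anchor = shift[:n_old] if n_old > 0 else shift
            mean_shift = anchor.mean(axis=0)
            for j, a in enumerate(atoms_x):
                a.frac_xyz = (before[j] + shift[j] - mean_shift) % 1.0
        res.substructure = atoms_x
        new_state = SubstructureState(res.substructure,
                                      ["refined" if p == "initial" else p
                                       for p in new_state.provenance],
                                      state.cycle)
        keep = [i for i, a in enumerate(new_state.atoms)
                if a.occupancy >= prune_occ_threshold]
        new_state = SubstructureState([new_state.atoms[i] for i in keep],
                                      [new_state.provenance[i] for i in keep],
                                      state.cycle)
        sub.s2, sub.cg = component_sums(new_state.atoms, refl, cov.bins, cov.n_bins)
        cov._cond_cache = None
    new_state.cycle = state.cycle + 1
    return new_state
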