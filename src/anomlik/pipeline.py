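"""The two MR-SAD drivers: "substructure-only" and "rebuilding".

Both start from Bijvoet data plus a (possibly poor) partial protein model
and/or an anomalous substructure, and run

1. *refinement and substructure completion*: cycles of parameter
   refinement (substructure occupancies/B, per-bin Luzzati D), anomalous
   scatterer detection (anomalous-difference map while the substructure is
   empty, log-likelihood-gradient map once one exists), peak search,
   atom addition and occupancy pruning; then
2. *combined cycles*: phase posteriors from the multivariate likelihood,
   Blow-Crick best coefficients, crystal-space density modification, and
   re-estimation of the error parameters, iterated a fixed number of
   cycles with the best cycle chosen by total log-likelihood.

The pipelines differ in how much the protein model is trusted afterwards:
"substructure-only" discards it after step 1 (its first combined
iteration is exactly the pure-SAD code path); "rebuilding" keeps it as a
likelihood component whose per-bin D re-weights — and, for a wrong model,
suppresses — its contribution.  Model *rebuilding* proper (chain tracing)
is out of scope; the D-mediated re-weighting is what stands in for it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .crystal import (ComplexSF, CrystalModel, RealMap, ReflectionSet,
                      fourier_map, resolution_bins, structure_factors)
from .densitymod import dm_cycle
from .errormodel import (CovarianceModel, build_covariance, component_sums,
                         estimate_luzzati_d, estimate_sigma_n)
from .likelihood import (ModelSFTriple, QuadratureSpec, loglik_dataset,
                         reduce_to_sad, refine_parameters)
from .phasing import best_coefficients, mean_phase_error, phase_posterior
from .simulate import ObservedData
from .substructure import (DEFAULT_MIN_SEPARATION, SubstructureState,
                           anomalous_difference_map, llg_map, peak_search,
                           update_substructure)

__all__ = [
    "PipelineConfig",
    "MetricsReport",
    "PipelineResult",
    "run_refine_and_complete",
    "run_substructure_only",
    "run_rebuilding",
    "evaluate",
    "map_correlation",
]


@dataclass
class PipelineConfig:
    """Run configuration; defaults follow the package's standard protocol."""

    n_refine_cycles: int = 5
    n_combined_cycles: int = 15
    peak_threshold_sigma: float = 4.75
    substructure_resolution_cutoff: float | None = None   # Angstrom, or None
    prune_occ_threshold: float = 0.2
    min_separation: float = DEFAULT_MIN_SEPARATION
    n_quad: int = 64
    n_phase: int = 360
    n_bins: int = 8
    solvent_fraction: float = 0.5
    dm_inner_cycles: int = 1
    smoothing_radius: float = 4.0
    anomalous_element: str = "Se"
    f_prime: float = -8.0
    f_double_prime: float = 3.8
    max_new_atoms_per_cycle: int = 4
    refine_max_sweeps: int = 3
    histogram_matching: bool = True   # protein-region histogram matching in dm
    low_res_mode: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_refine_cycles < 1 or self.n_combined_cycles < 1:
            raise ValueError("cycle counts must be >= 1")
        if self.peak_threshold_sigma <= 0:
            raise ValueError("peak threshold must be positive")
        if self.low_res_mode:
            # bundled low-resolution adjustments: relaxed peak threshold and
            # a 7 A resolution cutoff for the substructure-completion maps
            self.peak_threshold_sigma = min(self.peak_threshold_sigma, 4.25)
            if self.substructure_resolution_cutoff is None:
                self.substructure_resolution_cutoff = 7.0

    @property
    def quad(self) -> QuadratureSpec:
        return QuadratureSpec(self.n_quad)


@dataclass
class MetricsReport:
    """Per-cycle evaluation against a known ground truth."""

    phase_error: list = field(default_factory=list)      # F-weighted, degrees
    map_cc: list = field(default_factory=list)
    fom_mean: list = field(default_factory=list)
    loglik: list = field(default_factory=list)
    substructure_recall: float = np.nan
    substructure_precision: float = np.nan
    r_factor: float = np.nan
    status: str = "ok"
    final_phase_error: float = np.nan
    final_map_cc: float = np.nan
    best_cycle: int = -1


@dataclass
class PipelineResult:
    """Outputs of one pipeline run."""

    best_coeffs: ComplexSF
    posteriors: object
    substructure: SubstructureState
    cov: CovarianceModel
    triple: ModelSFTriple
    metrics: MetricsReport
    iteration1_coeffs: ComplexSF | None = None
    status: str = "ok"


# --------------------------------------------------------------------------
# helpers
# --------------------------------------------------------------------------

def _subset_refl(refl: ReflectionSet, mask: np.ndarray) -> ReflectionSet:
    return ReflectionSet(refl.miller[mask], refl.d_spacing[mask], refl.cell)


def _subset_data(data: ObservedData, mask: np.ndarray) -> ObservedData:
    return ObservedData(_subset_refl(data.refl, mask), data.f_plus[mask],
                        data.sig_plus[mask], data.f_minus[mask],
                        data.sig_minus[mask], data.truncated[mask])


def _protein_sf(model: CrystalModel | None, refl: ReflectionSet):
    if model is None or not model.atoms:
        return None
    fp, fm = structure_factors(model, refl)
    return fp.to_complex(), fm.to_complex()


def _substructure_sf(atoms, refl: ReflectionSet, cell):
    if not atoms:
        n = len(refl)
        return np.zeros(n, complex), np.zeros(n, complex)
    model = CrystalModel(cell, [a.copy() for a in atoms])
    fp, fm = structure_factors(model, refl)
    return fp.to_complex(), fm.to_complex()


def _build_cov(data, refl, bins, n_bins, protein_atoms, sub_atoms,
               d_protein=0.5, d_sub=0.98, dm=None) -> CovarianceModel:
    sigma_n = estimate_sigma_n(data, bins, n_bins)
    comps = []
    if protein_atoms is not None:
        comps.append(("protein", protein_atoms, d_protein))
    comps.append(("substructure",
                  component_sums(sub_atoms, refl, bins, n_bins), d_sub))
    return build_covariance(refl, bins, sigma_n, comps, dm=dm)


def map_correlation(a: RealMap, b: RealMap) -> float:
    x, y = a.values.ravel(), b.values.ravel()
    x = x - x.mean()
    y = y - y.mean()
    denom = np.sqrt((x * x).sum() * (y * y).sum())
    return float((x * y).sum() / denom) if denom > 0 else 0.0


def _dm_coeffs(best: ComplexSF, refl, cell, config, reference_histogram=None):
    fdm = dm_cycle(best, refl, cell, config.solvent_fraction,
                   config.dm_inner_cycles, config.smoothing_radius,
                   reference_histogram=reference_histogram)
    return fdm.to_complex()


def _reference_histogram(refl, cell, config):
    """Protein-region density histogram of an unrelated synthetic crystal
    at the same cell and resolution (the shape reference for histogram
    matching)."""
    from .densitymod import solvent_mask
    from .simulate import generate_ground_truth

    n_prot = max(30, int(round(0.019 * (1.0 - config.solvent_fraction) * cell.volume)))
    ref = generate_ground_truth(n_prot, max(1, n_prot // 50), cell,
                                config.anomalous_element, seed=987654321)
    rp, _ = structure_factors(ref, refl)
    ref_map = fourier_map(rp, refl, cell)
    sm = solvent_mask(ref_map, config.solvent_fraction, config.smoothing_radius)
    return ref_map.values[~sm.mask]


def _dm_power(fdm: np.ndarray, bins: np.ndarray, n_bins: int) -> np.ndarray:
    out = np.zeros(n_bins)
    for b in range(n_bins):
        m = bins == b
        out[b] = max(np.mean(np.abs(fdm[m]) ** 2), 1e-12) if m.any() else 1e-12
    return out


# --------------------------------------------------------------------------
# stage 1: refinement and substructure completion
# --------------------------------------------------------------------------

def _refine_substructure(data, refl, bins, n_bins, prot_atoms, prot_sf, atoms,
                         quad, max_sweeps):
    """Two-step refinement: occ/B and D against the full model, then a
    pure-SAD coordinate polish against the substructure alone."""
    cov = _build_cov(data, refl, bins, n_bins, prot_atoms, atoms)
    res = refine_parameters(data, refl, atoms, cov, quad, protein_sf=prot_sf,
                            refinable=("occ", "b", "d"),
                            d_components=("protein",) if prot_sf is not None else (),
                            max_sweeps=max_sweeps)
    atoms = res.substructure
    if atoms:
        before = np.array([a.frac_xyz for a in atoms])
        cov_sad = _build_cov(data, refl, bins, n_bins, None, atoms)
        res_xyz = refine_parameters(data, refl, atoms, cov_sad, quad,
                                    refinable=("xyz",), d_components=(),
                                    max_sweeps=1)
        atoms = res_xyz.substructure
        # the substructure-only likelihood is invariant under a global
        # origin translation (P1); anchor the centroid so the polish only
        # applies relative corrections and stays in the protein's frame
        after = np.array([a.frac_xyz for a in atoms])
        shift = after - before
        shift -= np.round(shift)
        mean_shift = shift.mean(axis=0)
        for j, a in enumerate(atoms):
            a.frac_xyz = (before[j] + shift[j] - mean_shift) % 1.0
        # re-evaluate the full-model likelihood at the polished positions
        cov = _build_cov(data, refl, bins, n_bins, prot_atoms, atoms)
        for name in ("protein",) if prot_sf is not None else ():
            cov.set_d(name, res.cov.component(name).d)
        comps = {}
        if prot_sf is not None:
            comps["protein"] = prot_sf
        comps["substructure"] = _substructure_sf(atoms, refl, refl.cell)
        triple = ModelSFTriple(comps)
        ll, _ = loglik_dataset(data, triple, cov, quad)
        return atoms, cov, triple, ll
    return atoms, res.cov, res.triple, res.loglik


def run_refine_and_complete(data: ObservedData, protein_model: CrystalModel | None,
                            substructure: SubstructureState | None,
                            config: PipelineConfig):
    """Iterate parameter refinement, scatterer detection and pruning.

    Returns (substructure_state, cov, triple, status).  The cycle state
    with the best total log-likelihood is kept.
    """
    refl = data.refl
    cell = refl.cell
    state = substructure.copy() if substructure is not None else SubstructureState([])
    if protein_model is None and not state.atoms:
        raise ValueError("need at least one of protein model / substructure")
    bins = resolution_bins(refl, min(config.n_bins, len(refl)))
    n_bins = bins.max() + 1
    prot_sf = _protein_sf(protein_model, refl)
    prot_atoms = protein_model.atoms if protein_model is not None else None

    # optional resolution cutoff for the completion maps
    if config.substructure_resolution_cutoff is not None:
        map_mask = refl.d_spacing >= config.substructure_resolution_cutoff
        if map_mask.sum() < 10:
            map_mask = np.ones(len(refl), dtype=bool)
    else:
        map_mask = np.ones(len(refl), dtype=bool)
    map_refl = _subset_refl(refl, map_mask)
    map_data = _subset_data(data, map_mask)

    best = None
    for cycle in range(config.n_refine_cycles):
        atoms, cov, triple, ll = _refine_substructure(
            data, refl, bins, n_bins, prot_atoms, prot_sf, state.atoms,
            config.quad, config.refine_max_sweeps)
        state = SubstructureState(atoms, state.provenance, cycle)
        if best is None or ll > best[0]:
            best = (ll, state.copy(), cov, triple)

        if not state.atoms:
            if prot_sf is None:
                break
            phases = np.degrees(np.angle(prot_sf[0][map_mask])) % 360.0
            rmap = anomalous_difference_map(map_data, phases, map_refl, cell)
        else:
            map_bins = resolution_bins(map_refl, min(n_bins, len(map_refl)))
            map_cov = _build_cov(map_data, map_refl, map_bins, map_bins.max() + 1,
                                 prot_atoms, state.atoms)
            for comp in map_cov.components:
                full = cov.component(comp.name)
                comp.d = full.d.copy() if len(full.d) == len(comp.d) else comp.d
            map_cov._cond_cache = None
            comps = {}
            if prot_sf is not None:
                comps["protein"] = (prot_sf[0][map_mask], prot_sf[1][map_mask])
            comps["substructure"] = _substructure_sf(state.atoms, map_refl, cell)
            map_triple = ModelSFTriple(comps)
            from .crystal import atom_scattering as _asc
            from .crystal import AtomSite as _AS
            probe = _AS(config.anomalous_element, np.zeros(3), 1.0, 0.0,
                        config.f_prime, config.f_double_prime, "anomalous")
            g_anom = _asc(probe, map_refl.s)
            rmap = llg_map(map_data, map_triple, map_cov, config.quad,
                           map_refl, cell, g_anom)

        existing = [a.frac_xyz for a in state.atoms]
        peaks = peak_search(rmap, config.peak_threshold_sigma, config.min_separation,
                            exclude_positions=existing)
        state = update_substructure(state, peaks, data, refl, cov, config.quad,
                                    element=config.anomalous_element,
                                    f_prime=config.f_prime,
                                    f_double_prime=config.f_double_prime,
                                    prune_occ_threshold=config.prune_occ_threshold,
                                    merge_radius=config.min_separation,
                                    max_new_atoms=config.max_new_atoms_per_cycle,
                                    protein_sf=prot_sf, cell=cell)

    # final refinement of whatever survived
    atoms, cov, triple, ll = _refine_substructure(
        data, refl, bins, n_bins, prot_atoms, prot_sf, state.atoms,
        config.quad, config.refine_max_sweeps)
    state = SubstructureState(atoms, state.provenance, state.cycle)
    if best is None or ll >= best[0]:
        best = (ll, state.copy(), cov, triple)
    status = "ok" if best[1].atoms else "substructure-failure"
    return best[1], best[2], best[3], status


# --------------------------------------------------------------------------
# stage 2: combined cycles
# --------------------------------------------------------------------------

def _estimate_ddm_free(data, triple, cov, quad, free_mask, n_groups: int = 3):
    """d_dm in a few coarse resolution groups, fitted on the free set only.

    A per-bin fit on the small free set would be too noisy; coarse groups
    keep the resolution dependence while every estimate still comes from
    reflections the dm map has never seen, giving honest predictive
    weights.
    """
    from scipy.optimize import minimize_scalar

    if cov.dm is None or not free_mask.any():
        return np.zeros(cov.n_bins)

    values = cov.dm.d.copy()
    groups = np.array_split(np.arange(cov.n_bins), min(n_groups, cov.n_bins))
    for grp in groups:
        gmask = free_mask & np.isin(cov.bins, grp)
        if gmask.sum() < 15:
            continue

        def neg(x, _grp=grp, _gmask=gmask):
            vals = values.copy()
            vals[_grp] = x
            cov.set_d("dm", vals)
            return -loglik_dataset(data, triple, cov, quad, subset=_gmask)[0]

        res = minimize_scalar(neg, bounds=(0.0, 1.0 - 1e-6), method="bounded",
                              options={"xatol": 2e-3})
        values[grp] = float(np.clip(res.x, 0.0, 1.0 - 1e-6))
    cov.set_d("dm", values)
    return values


def _combined_cycles(data, refl, bins, n_bins, state, config,
                     prot_atoms=None, prot_sf=None, truth=None,
                     iteration1_coeffs=None, first_post=None, first_ll=None):
    """Shared combined-iteration loop; protein component optional."""
    cell = refl.cell
    metrics = MetricsReport()
    sub_sf = _substructure_sf(state.atoms, refl, cell)
    truth_phase, truth_map, weights = None, None, data.f_plus
    if truth is not None:
        tp, _ = structure_factors(truth, refl)
        truth_phase = tp.phase
        truth_map = fourier_map(tp, refl, cell)

    best_post, best_co, best_ll_cycle = first_post, iteration1_coeffs, -np.inf
    best_cov = best_triple = None
    ref_hist = (_reference_histogram(refl, cell, config)
                if config.histogram_matching else None)
    # cross-validation free set: excluded from the dm map synthesis; d_dm is
    # estimated on it alone.  The dm stream is built from the same data it
    # then informs, so a working-set d_dm measures self-consistency rather
    # than predictive value and makes the posteriors overconfident.
    rng = np.random.default_rng(config.seed + 17)
    free = rng.random(len(refl)) < max(0.12, 60.0 / len(refl))
    if free.sum() < 20:
        free[:] = False
    coeffs = iteration1_coeffs
    for cycle in range(config.n_combined_cycles):
        # two maps: the full map is used for phasing; a free-omitted map
        # provides genuinely predictive dm entries at the free reflections,
        # on which d_dm is estimated
        fdm = _dm_coeffs(coeffs, refl, cell, config, reference_histogram=ref_hist)
        dm_in = ComplexSF(np.where(free, 0.0, coeffs.amplitude), coeffs.phase)
        fdm_est = _dm_coeffs(dm_in, refl, cell, config,
                             reference_histogram=ref_hist)
        dm_spec = (_dm_power(fdm, bins, n_bins), 0.5)
        cov = _build_cov(data, refl, bins, n_bins, prot_atoms, state.atoms,
                         dm=dm_spec)
        comps = {}
        if prot_sf is not None:
            comps["protein"] = prot_sf
        comps["substructure"] = sub_sf
        triple = ModelSFTriple(comps, fdm)
        triple_est = ModelSFTriple(comps, np.where(free, fdm_est, fdm))
        if prot_sf is not None:
            estimate_luzzati_d(data, triple, cov, which="protein")
        _estimate_ddm_free(data, triple_est, cov, config.quad, free)
        ll, _ = loglik_dataset(data, triple, cov, config.quad)
        post = phase_posterior(data, triple, cov, config.quad, config.n_phase)
        coeffs = best_coefficients(post, data)

        metrics.loglik.append(ll)
        metrics.fom_mean.append(float(post.fom.mean()))
        if truth is not None:
            metrics.phase_error.append(
                mean_phase_error(post.phi_best, truth_phase, weights))
            bm = fourier_map(coeffs, refl, cell)
            metrics.map_cc.append(map_correlation(bm, truth_map))
        if ll > best_ll_cycle:
            best_ll_cycle = ll
            best_post, best_co = post, coeffs
            best_cov, best_triple = cov, triple
            metrics.best_cycle = cycle
    if truth is not None and metrics.phase_error:
        metrics.final_phase_error = metrics.phase_error[metrics.best_cycle]
        metrics.final_map_cc = metrics.map_cc[metrics.best_cycle]
    return best_post, best_co, best_cov, best_triple, metrics


def run_substructure_only(data: ObservedData, protein_model: CrystalModel | None,
                          substructure: SubstructureState | None,
                          config: PipelineConfig,
                          truth: CrystalModel | None = None) -> PipelineResult:
    """MR model used only to improve the substructure; phasing is model-free.

    Iteration 1 is the pure-SAD reduction: posterior from the substructure
    alone (the general function with protein and dm absent), density
    modification of its best map, then phase combination with the dm
    stream; later cycles iterate dm + combination.
    """
    refl = data.refl
    state, _, _, status = run_refine_and_complete(data, protein_model,
                                                  substructure, config)
    if status != "ok":
        return _failed_result(data, status)
    bins = resolution_bins(refl, min(config.n_bins, len(refl)))
    n_bins = bins.max() + 1
    sub_sf = _substructure_sf(state.atoms, refl, refl.cell)
    cov0 = _build_cov(data, refl, bins, n_bins, None, state.atoms)
    triple0 = ModelSFTriple({"substructure": sub_sf})
    post0, ll0 = reduce_to_sad(data, triple0, cov0, config.quad, config.n_phase)
    coeffs0 = best_coefficients(post0, data)

    post, coeffs, cov, triple, metrics = _combined_cycles(
        data, refl, bins, n_bins, state, config, truth=truth,
        iteration1_coeffs=coeffs0, first_post=post0, first_ll=ll0)
    metrics.status = status
    return PipelineResult(coeffs, post, state, cov, triple, metrics,
                          iteration1_coeffs=coeffs0, status=status)


def run_rebuilding(data: ObservedData, protein_model: CrystalModel,
                   substructure: SubstructureState | None,
                   config: PipelineConfig,
                   truth: CrystalModel | None = None) -> PipelineResult:
    """Keep the refined protein model as a likelihood component.

    The model's contribution is re-weighted every cycle through its
    refined per-bin D (a wrong model refines toward D = 0 and stops
    influencing the phases).
    """
    if protein_model is None or not protein_model.atoms:
        raise ValueError("rebuilding pipeline requires a protein model")
    refl = data.refl
    state, _, _, status = run_refine_and_complete(data, protein_model,
                                                  substructure, config)
    if status != "ok":
        return _failed_result(data, status)
    bins = resolution_bins(refl, min(config.n_bins, len(refl)))
    n_bins = bins.max() + 1
    prot_sf = _protein_sf(protein_model, refl)
    sub_sf = _substructure_sf(state.atoms, refl, refl.cell)
    cov0 = _build_cov(data, refl, bins, n_bins, protein_model.atoms, state.atoms)
    triple0 = ModelSFTriple({"protein": prot_sf, "substructure": sub_sf})
    estimate_luzzati_d(data, triple0, cov0, which="protein")
    post0 = phase_posterior(data, triple0, cov0, config.quad, config.n_phase)
    coeffs0 = best_coefficients(post0, data)

    post, coeffs, cov, triple, metrics = _combined_cycles(
        data, refl, bins, n_bins, state, config,
        prot_atoms=protein_model.atoms, prot_sf=prot_sf, truth=truth,
        iteration1_coeffs=coeffs0, first_post=post0)
    metrics.status = status
    return PipelineResult(coeffs, post, state, cov, triple, metrics,
                          iteration1_coeffs=coeffs0, status=status)


def _failed_result(data, status):
    n = len(data.refl)
    zeros = ComplexSF(np.zeros(n), np.zeros(n))
    metrics = MetricsReport(status=status)
    metrics.fom_mean = [0.0]
    return PipelineResult(zeros, None, SubstructureState([]), None, None,
                          metrics, status=status)


# --------------------------------------------------------------------------
# evaluation
# --------------------------------------------------------------------------

def evaluate(result: PipelineResult, truth: CrystalModel, data: ObservedData,
             starting_model: CrystalModel | None = None) -> MetricsReport:
    """Truth-based metrics: phase error, map CC, substructure recall/precision.

    Substructure matching allows the P1 phase ambiguities: a continuous
    permitted origin translation and the enantiomorph inversion are
    searched (candidate translations from found-to-true difference
    vectors) before 0.5 A bipartite matching.
    """
    refl = data.refl
    cell = refl.cell
    m = result.metrics if result.metrics is not None else MetricsReport()
    tp, _ = structure_factors(truth, refl)
    truth_map = fourier_map(tp, refl, cell)
    if result.status == "ok" and result.posteriors is not None:
        m.final_phase_error = mean_phase_error(result.posteriors.phi_best,
                                               tp.phase, data.f_plus)
        bm = fourier_map(result.best_coeffs, refl, cell)
        m.final_map_cc = map_correlation(bm, truth_map)
    true_sites = np.array([a.frac_xyz for a in truth.anomalous_atoms])
    found = np.array([a.frac_xyz for a in result.substructure.atoms]) \
        if result.substructure.atoms else np.empty((0, 3))
    rec, prec = substructure_match(found, true_sites, cell)
    m.substructure_recall, m.substructure_precision = rec, prec
    if starting_model is not None and starting_model.atoms:
        fp, _ = structure_factors(starting_model, refl)
        scale = (data.f_plus * fp.amplitude).sum() / max((fp.amplitude ** 2).sum(), 1e-30)
        m.r_factor = float(np.abs(data.f_plus - scale * fp.amplitude).sum()
                           / data.f_plus.sum())
    return m


def substructure_match(found: np.ndarray, true_sites: np.ndarray, cell,
                       tol: float = 0.5):
    """(recall, precision) after permitted-origin and enantiomorph search."""
    if len(true_sites) == 0:
        return np.nan, np.nan
    if len(found) == 0:
        return 0.0, np.nan
    best = (0, 0)
    for hand in (1.0, -1.0):
        f = (hand * found) % 1.0
        candidates = [np.zeros(3)]
        for i in range(len(f)):
            for j in range(len(true_sites)):
                candidates.append((true_sites[j] - f[i]) % 1.0)
        for t in candidates:
            shifted = (f + t) % 1.0
            matched_true: set = set()
            matched_found = 0
            d = np.empty((len(shifted), len(true_sites)))
            for i in range(len(shifted)):
                d[i] = cell.shortest_distance(true_sites, shifted[i][None, :])
            # greedy bipartite matching by increasing distance
            order = np.dstack(np.unravel_index(np.argsort(d, axis=None), d.shape))[0]
            used_f: set = set()
            for i, j in order:
                if d[i, j] > tol:
                    break
                if i in used_f or j in matched_true:
                    continue
                used_f.add(int(i))
                matched_true.add(int(j))
                matched_found += 1
            if matched_found > best[0] + best[1]:
                best = (len(matched_true), matched_found)
    recall = best[0] / len(true_sites)
    precision = best[1] / len(found)
    return float(recall), float(precision)
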