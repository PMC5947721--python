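"""Anomalous-difference maps, LLG maps, peak search, update/prune."""

import numpy as np
import pytest

from anomlik.crystal import (AtomSite, ComplexSF, CrystalModel, RealMap,
                             build_reflection_set, default_grid_shape, fourier_map,
                             resolution_bins, structure_factors, atom_scattering)
from anomlik.errormodel import build_covariance, estimate_sigma_n
from anomlik.likelihood import ModelSFTriple, QuadratureSpec, loglik_dataset
from anomlik.pipeline import _build_cov, _protein_sf, _substructure_sf
from anomlik.simulate import (NoiseSpec, PerturbationSpec, generate_ground_truth,
                              perturb_model, simulate_observations)
from anomlik.substructure import (PeakList, SubstructureState,
                                  anomalous_difference_map, llg_map, peak_search,
                                  update_substructure)


def _closest(cell, sites, pos):
    return cell.shortest_distance(np.asarray(sites), np.asarray(pos)[None, :]).min()


class TestAnomalousDifferenceMap:
    def test_truth_phases_locate_selenium(self, small_truth, small_refl):
        data = simulate_observations(small_truth, small_refl, NoiseSpec(1e-6, seed=1))
        tp, _ = structure_factors(small_truth, small_refl)
        rmap = anomalous_difference_map(data, tp.phase, small_refl, small_truth.cell)
        peaks = peak_search(rmap, 4.0, 2.5)
        assert len(peaks) > 0
        sites = [a.frac_xyz for a in small_truth.anomalous_atoms]
        assert _closest(small_truth.cell, sites, peaks.positions[0]) < 0.5

    def test_no_signal_is_noise_level(self, small_truth_no_anom, small_refl):
        hits = 0
        for seed in range(4):
            data = simulate_observations(small_truth_no_anom, small_refl,
                                         NoiseSpec(0.05, seed=seed))
            tp, _ = structure_factors(small_truth_no_anom, small_refl)
            rmap = anomalous_difference_map(data, tp.phase, small_refl,
                                            small_truth_no_anom.cell)
            hits += rmap.sigma_normalized().values.max() < 5.0
        assert hits >= 3

    def test_negating_differences_negates_map(self, small_truth, small_refl, small_data):
        from anomlik.simulate import ObservedData
        tp, _ = structure_factors(small_truth, small_refl)
        m1 = anomalous_difference_map(small_data, tp.phase, small_refl, small_truth.cell)
        flipped = ObservedData(small_refl, small_data.f_minus, small_data.sig_minus,
                               small_data.f_plus, small_data.sig_plus)
        m2 = anomalous_difference_map(flipped, tp.phase, small_refl, small_truth.cell)
        np.testing.assert_allclose(m2.values, -m1.values, atol=1e-9)


class TestLLGMap:
    def test_recovers_omitted_sites(self, small_truth, small_refl, small_bins, small_data):
        pert, _ = perturb_model(small_truth, PerturbationSpec(1.0, 0.3, 0.0, 1, seed=5))
        prot_sf = _protein_sf(CrystalModel(small_refl.cell, pert.protein_atoms),
                              small_refl)
        cov = _build_cov(small_data, small_refl, small_bins, 6,
                         pert.protein_atoms, pert.anomalous_atoms)
        tri = ModelSFTriple({
            "protein": prot_sf,
            "substructure": _substructure_sf(pert.anomalous_atoms, small_refl,
                                             small_refl.cell)})
        probe = AtomSite("Se", np.zeros(3), 1.0, 0.0, -8.0, 3.8, "anomalous")
        g = atom_scattering(probe, small_refl.s)
        rmap = llg_map(small_data, tri, cov, QuadratureSpec(64), small_refl,
                       small_refl.cell, g)
        peaks = peak_search(rmap, 3.5, 2.5)
        kept = np.array([a.frac_xyz for a in pert.anomalous_atoms])
        omitted = [a.frac_xyz for a in small_truth.anomalous_atoms
                   if _closest(small_refl.cell, kept, a.frac_xyz) > 0.1]
        assert len(omitted) == 1
        assert _closest(small_refl.cell, omitted, peaks.positions[0]) < 0.5

    def test_flat_when_gradients_vanish(self, small_truth, small_refl, small_bins,
                                        small_data):
        sn = estimate_sigma_n(small_data, small_bins, 6)
        cov = build_covariance(small_refl, small_bins, sn,
                               [("substructure", small_truth.anomalous_atoms, 0.0)])
        tri = ModelSFTriple({"substructure": _substructure_sf(
            small_truth.anomalous_atoms, small_refl, small_refl.cell)})
        probe = AtomSite("Se", np.zeros(3), 1.0, 0.0, -8.0, 3.8, "anomalous")
        g = atom_scattering(probe, small_refl.s)
        rmap = llg_map(small_data, tri, cov, QuadratureSpec(64), small_refl,
                       small_refl.cell, g)
        assert np.abs(rmap.values).max() < 1e-10


class TestPeakSearch:
    def _blob_map(self, cell, center, refl):
        model = CrystalModel(cell, [AtomSite("C", center, 1.0, 30.0)])
        fp, _ = structure_factors(model, refl)
        return fourier_map(fp, refl, cell)

    def test_single_blob_subgrid_position(self, small_cell):
        refl = build_reflection_set(small_cell, 3.0)
        center = np.array([0.31, 0.62, 0.17])
        rmap = self._blob_map(small_cell, center, refl)
        peaks = peak_search(rmap, 4.0, 2.0)
        assert len(peaks) == 1
        spacing = max(small_cell.a, small_cell.b, small_cell.c) / min(rmap.shape)
        assert _closest(small_cell, [center], peaks.positions[0]) < 0.25 * spacing

    def test_threshold_above_max_empty(self, small_cell):
        refl = build_reflection_set(small_cell, 3.0)
        rmap = self._blob_map(small_cell, np.array([0.5, 0.5, 0.5]), refl)
        assert len(peak_search(rmap, 1e6, 2.0)) == 0

    def test_close_blobs_suppressed(self, small_cell):
        refl = build_reflection_set(small_cell, 3.0)
        c1 = np.array([0.3, 0.3, 0.3])
        c2 = c1 + np.array([1.0 / small_cell.a, 0, 0])  # 1 A apart
        model = CrystalModel(small_cell, [AtomSite("C", c1, 1.0, 30.0),
                                          AtomSite("C", c2, 1.0, 30.0)])
        fp, _ = structure_factors(model, refl)
        rmap = fourier_map(fp, refl, small_cell)
        peaks = peak_search(rmap, 4.0, min_separation=3.0)
        assert len(peaks) == 1

    def test_sorted_heights_invariant(self):
        with pytest.raises(ValueError):
            PeakList(np.zeros((2, 3)), np.array([1.0, 2.0]))


class TestUpdateSubstructure:
    def test_no_peaks_no_prune_only_advances_cycle(self, small_truth, small_refl,
                                                   small_bins, small_data):
        state = SubstructureState([a.copy() for a in small_truth.anomalous_atoms])
        cov = _build_cov(small_data, small_refl, small_bins, 6, None, state.atoms)
        empty = PeakList(np.empty((0, 3)), np.empty(0))
        new = update_substructure(state, empty, small_data, small_refl, cov,
                                  QuadratureSpec(64), prune_occ_threshold=0.0)
        assert len(new.atoms) == len(state.atoms)
        assert new.cycle == state.cycle + 1

    def test_true_site_addition_increases_likelihood(self, small_truth, small_refl,
                                                     small_bins, small_data):
        anom = small_truth.anomalous_atoms
        partial = [a.copy() for a in anom[:-1]]
        cov = _build_cov(small_data, small_refl, small_bins, 6, None, partial)
        tri = ModelSFTriple({"substructure": _substructure_sf(
            partial, small_refl, small_refl.cell)})
        before, _ = loglik_dataset(small_data, tri, cov, QuadratureSpec(64))
        state = SubstructureState(partial)
        peaks = PeakList(anom[-1].frac_xyz[None, :], np.array([8.0]))
        new = update_substructure(state, peaks, small_data, small_refl, cov,
                                  QuadratureSpec(64))
        assert len(new.atoms) == len(partial) + 1
        tri2 = ModelSFTriple({"substructure": _substructure_sf(
            new.atoms, small_refl, small_refl.cell)})
        cov2 = _build_cov(small_data, small_refl, small_bins, 6, None, new.atoms)
        after, _ = loglik_dataset(small_data, tri2, cov2, QuadratureSpec(64))
        assert after > before

    def test_spurious_atom_pruned(self, small_truth, small_refl, small_bins,
                                  small_data):
        rng = np.random.default_rng(3)
        atoms = [a.copy() for a in small_truth.anomalous_atoms]
        atoms.append(AtomSite("Se", rng.random(3), 0.5, 25.0, -8.0, 3.8, "anomalous"))
        state = SubstructureState(atoms)
        cov = _build_cov(small_data, small_refl, small_bins, 6, None, state.atoms)
        empty = PeakList(np.empty((0, 3)), np.empty(0))
        new = update_substructure(state, empty, small_data, small_refl, cov,
                                  QuadratureSpec(64), prune_occ_threshold=0.2)
        assert len(new.atoms) == len(small_truth.anomalous_atoms)
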