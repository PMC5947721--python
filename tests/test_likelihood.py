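"""Multivariate likelihood: limits, quadrature, gradients, refinement."""

import numpy as np
import pytest

from anomlik.crystal import (AtomSite, CrystalModel, resolution_bins,
                             structure_factors)
from anomlik.errormodel import (build_covariance, component_sums,
                                condition_on_models, estimate_sigma_n)
from anomlik.likelihood import (ModelSFTriple, QuadratureSpec, gradient_wrt_model_sf,
                                loglik_dataset, loglik_reflection, reduce_to_sad,
                                refine_parameters, rice_logpdf)
from anomlik.simulate import NoiseSpec, PerturbationSpec, perturb_model, simulate_observations


@pytest.fixture(scope="module")
def battery(small_truth, small_refl, small_bins, small_data):
    """Partial model + substructure + covariance at testbed conditions."""
    pert, _ = perturb_model(small_truth, PerturbationSpec(1.0, 0.3, 0.0, 1, seed=5))
    fpp, fpm = structure_factors(CrystalModel(small_refl.cell, pert.protein_atoms),
                                 small_refl)
    fsp, fsm = structure_factors(CrystalModel(small_refl.cell, pert.anomalous_atoms),
                                 small_refl)
    sn = estimate_sigma_n(small_data, small_bins, 6)
    cov = build_covariance(small_refl, small_bins, sn,
                           [("protein", pert.protein_atoms, 0.45),
                            ("substructure", pert.anomalous_atoms, 0.95)])
    tri = ModelSFTriple({"protein": (fpp.to_complex(), fpm.to_complex()),
                         "substructure": (fsp.to_complex(), fsm.to_complex())})
    return cov, tri


class TestRiceLimits:
    def test_pair_reduces_to_noise_rices_at_exact_model(
            self, small_truth_no_anom, small_refl, small_bins):
        """f''=0, complete exact model, D=1: the conditional cross term is
        exactly zero and the pair likelihood is a product of two
        measurement-noise Rice densities."""
        data = simulate_observations(small_truth_no_anom, small_refl,
                                     NoiseSpec(0.25, seed=2))
        fp, fm = structure_factors(small_truth_no_anom, small_refl)
        s2, cg = component_sums(small_truth_no_anom.atoms, small_refl, small_bins, 6)
        cov = build_covariance(small_refl, small_bins, s2, [("model", (s2, cg), 1.0)])
        tri = ModelSFTriple({"model": (fp.to_complex(), fm.to_complex())})
        _, ll = loglik_dataset(data, tri, cov, QuadratureSpec(1024))
        oracle = (rice_logpdf(data.f_plus, fp.amplitude, 2 * data.sig_plus ** 2)
                  + rice_logpdf(data.f_minus, fm.amplitude, 2 * data.sig_minus ** 2))
        assert np.abs(ll - oracle).max() < 1e-8

    def test_marginal_is_luzzati_rice_at_any_d(
            self, small_truth_no_anom, small_refl, small_bins):
        """Single-amplitude marginal (missing Friedel mate) equals the
        acentric Luzzati Rice with variance (1-D^2) Sigma_N + sigma^2."""
        d = 0.7
        data = simulate_observations(small_truth_no_anom, small_refl,
                                     NoiseSpec(0.05, seed=2))
        pert, _ = perturb_model(small_truth_no_anom,
                                PerturbationSpec(coord_rms=0.8, seed=3))
        fp, fm = structure_factors(pert, small_refl)
        s2, cg = component_sums(small_truth_no_anom.atoms, small_refl, small_bins, 6)
        cov = build_covariance(small_refl, small_bins, s2, [("model", (s2, cg), d)])
        tri = ModelSFTriple({"model": (fp.to_complex(), fm.to_complex())})
        missing = np.ones(len(small_refl), dtype=bool)
        _, ll = loglik_dataset(data, tri, cov, QuadratureSpec(64),
                               missing_minus=missing)
        var = (1 - d * d) * s2[small_bins] + 2 * data.sig_plus ** 2
        oracle = rice_logpdf(data.f_plus, d * fp.amplitude, var)
        assert np.abs(ll - oracle).max() < 1e-8


class TestQuadrature:
    def test_convergence_at_64_nodes(self, small_data, battery):
        cov, tri = battery
        _, l64 = loglik_dataset(small_data, tri, cov, QuadratureSpec(64))
        _, l4096 = loglik_dataset(small_data, tri, cov, QuadratureSpec(4096))
        assert np.abs(l64 - l4096).max() < 1e-6

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            QuadratureSpec(4)
        with pytest.raises(ValueError):
            QuadratureSpec(64, rule="simpson")


class TestLimitsAndAdditivity:
    def test_d_zero_makes_models_irrelevant(self, small_truth, small_refl,
                                            small_bins, small_data):
        sn = estimate_sigma_n(small_data, small_bins, 6)
        cov = build_covariance(small_refl, small_bins, sn,
                               [("model", small_truth.atoms, 0.0)])
        fp, fm = structure_factors(small_truth, small_refl)
        t1 = ModelSFTriple({"model": (fp.to_complex(), fm.to_complex())})
        t2 = ModelSFTriple({"model": (fp.to_complex() * 1.7j, fm.to_complex() * 0.2)})
        a, _ = loglik_dataset(small_data, t1, cov, QuadratureSpec(64))
        b, _ = loglik_dataset(small_data, t2, cov, QuadratureSpec(64))
        assert abs(a - b) < 1e-12

    def test_total_is_sum_and_single_reflection_matches(self, small_data, battery):
        cov, tri = battery
        total, ll = loglik_dataset(small_data, tri, cov, QuadratureSpec(64))
        assert total == pytest.approx(ll.sum(), rel=1e-12)
        for i in (0, 17, 101):
            assert loglik_reflection(small_data.pair(i), tri, cov,
                                     QuadratureSpec(64), index=i) == \
                pytest.approx(ll[i], rel=1e-10)

    def test_proper_density_normalizes(self, small_data, battery):
        """2-D numeric integral of the two-amplitude density is ~1."""
        from anomlik.likelihood import _conditional_parts, _kernel
        cov, tri = battery
        a1, a2, mu1, mu2, c11, c22, c12 = _conditional_parts(small_data, tri, cov)
        i = 11
        g1 = np.linspace(1e-3, np.abs(mu1[i]) + 6 * np.sqrt(c11[i]), 160)
        g2 = np.linspace(1e-3, np.abs(mu2[i]) + 6 * np.sqrt(c22[i]), 160)
        aa1, aa2 = np.meshgrid(g1, g2, indexing="ij")
        n = aa1.size
        ll, _, _ = _kernel(aa1.ravel(), aa2.ravel(), np.full(n, mu1[i]),
                           np.full(n, mu2[i]), np.full(n, c11[i]),
                           np.full(n, c22[i]), np.full(n, c12[i]), 256)
        dens = np.exp(ll).reshape(aa1.shape)
        integral = np.trapezoid(np.trapezoid(dens, g2, axis=1), g1)
        assert integral == pytest.approx(1.0, abs=1e-3)


class TestGradients:
    def test_matches_finite_differences(self, small_data, battery):
        cov, tri = battery
        grads = gradient_wrt_model_sf(small_data, tri, cov, QuadratureSpec(64))
        fpp, fpm = tri.components["protein"]
        eps = 1e-4 * np.abs(fpp).mean()
        rng = np.random.default_rng(3)
        for i in rng.choice(len(small_data), 6, replace=False):
            for name in ("protein", "substructure"):
                gp, gm = grads.components[name]
                for branch, g in (("plus", gp), ("minus", gm)):
                    for dz in (eps, 1j * eps):
                        def ll_of(delta, _i=i, _name=name, _branch=branch):
                            comps = {k: (fp.copy(), fm.copy())
                                     for k, (fp, fm) in tri.components.items()}
                            fp, fm = comps[_name]
                            (fp if _branch == "plus" else fm)[_i] += delta
                            t = ModelSFTriple(comps)
                            return loglik_dataset(small_data, t, cov,
                                                  QuadratureSpec(64))[0]
                        fd = (ll_of(dz) - ll_of(-dz)) / (2 * abs(dz))
                        ana = 2 * (g[i].real if dz.imag == 0 else g[i].imag)
                        assert abs(fd - ana) <= 1e-5 * max(abs(fd), 1e-6)

    def test_zero_when_uninformative(self, small_truth, small_refl, small_bins,
                                     small_data):
        sn = estimate_sigma_n(small_data, small_bins, 6)
        cov = build_covariance(small_refl, small_bins, sn,
                               [("model", small_truth.atoms, 0.0)])
        fp, fm = structure_factors(small_truth, small_refl)
        tri = ModelSFTriple({"model": (fp.to_complex(), fm.to_complex())})
        grads = gradient_wrt_model_sf(small_data, tri, cov, QuadratureSpec(64))
        gp, gm = grads.components["model"]
        assert np.abs(gp).max() < 1e-12 and np.abs(gm).max() < 1e-12


class TestReduceToSad:
    def test_same_code_path_as_general_function(self, small_truth, small_refl,
                                                small_bins, small_data):
        from anomlik.phasing import phase_posterior
        sub = small_truth.anomalous_atoms
        sn = estimate_sigma_n(small_data, small_bins, 6)
        cov = build_covariance(small_refl, small_bins, sn,
                               [("substructure", sub, 0.98)])
        fsp, fsm = structure_factors(CrystalModel(small_refl.cell, sub), small_refl)
        tri = ModelSFTriple({"substructure": (fsp.to_complex(), fsm.to_complex())})
        post, total = reduce_to_sad(small_data, tri, cov, QuadratureSpec(64), 360)
        ref_total, _ = loglik_dataset(small_data, tri, cov, QuadratureSpec(64))
        ref_post = phase_posterior(small_data, tri, cov, QuadratureSpec(64), 360)
        assert total == pytest.approx(ref_total, abs=1e-10)
        np.testing.assert_allclose(post.prob, ref_post.prob, atol=1e-12)

    def test_full_truth_substructure_phases_well(self, small_truth, small_refl,
                                                 small_bins, small_data):
        from anomlik.phasing import mean_phase_error
        sub = small_truth.anomalous_atoms
        sn = estimate_sigma_n(small_data, small_bins, 6)
        cov = build_covariance(small_refl, small_bins, sn,
                               [("substructure", sub, 0.98)])
        fsp, fsm = structure_factors(CrystalModel(small_refl.cell, sub), small_refl)
        tri = ModelSFTriple({"substructure": (fsp.to_complex(), fsm.to_complex())})
        post, _ = reduce_to_sad(small_data, tri, cov, QuadratureSpec(64), 360)
        tp, _ = structure_factors(small_truth, small_refl)
        err = mean_phase_error(post.phi_best, tp.phase, small_data.f_plus)
        assert err < 30.0


class TestRefinement:
    def test_truth_start_is_fixed_point(self, small_truth, small_refl, small_bins,
                                        small_data):
        from anomlik.pipeline import _build_cov, _protein_sf
        sub = [a.copy() for a in small_truth.anomalous_atoms]
        prot_sf = _protein_sf(CrystalModel(small_refl.cell, small_truth.protein_atoms),
                              small_refl)
        cov = _build_cov(small_data, small_refl, small_bins, 6,
                         small_truth.protein_atoms, sub)
        res = refine_parameters(small_data, small_refl, sub, cov, QuadratureSpec(64),
                                protein_sf=prot_sf, d_components=("protein",),
                                max_sweeps=2)
        for a, t in zip(res.substructure, small_truth.anomalous_atoms):
            assert abs(a.occupancy - t.occupancy) < 0.05

    def test_halved_occupancy_recovered(self, small_truth, small_refl, small_bins,
                                        small_data):
        from anomlik.pipeline import _build_cov, _protein_sf
        sub = [a.copy() for a in small_truth.anomalous_atoms]
        for a in sub:
            a.occupancy = 0.5
        prot_sf = _protein_sf(CrystalModel(small_refl.cell, small_truth.protein_atoms),
                              small_refl)
        cov = _build_cov(small_data, small_refl, small_bins, 6,
                         small_truth.protein_atoms, sub)
        res = refine_parameters(small_data, small_refl, sub, cov, QuadratureSpec(64),
                                protein_sf=prot_sf, d_components=("protein",),
                                max_sweeps=3)
        for a, t in zip(res.substructure, small_truth.anomalous_atoms):
            assert abs(a.occupancy - t.occupancy) < 0.15

    def test_likelihood_never_decreases(self, small_truth, small_refl, small_bins,
                                        small_data):
        from anomlik.pipeline import _build_cov
        sub = [a.copy() for a in small_truth.anomalous_atoms]
        cov = _build_cov(small_data, small_refl, small_bins, 6, None, sub)
        fsp, fsm = structure_factors(CrystalModel(small_refl.cell, sub), small_refl)
        tri = ModelSFTriple({"substructure": (fsp.to_complex(), fsm.to_complex())})
        before, _ = loglik_dataset(small_data, tri, cov, QuadratureSpec(64))
        res = refine_parameters(small_data, small_refl, sub, cov, QuadratureSpec(64),
                                d_components=(), max_sweeps=2)
        assert res.loglik >= before - 1e-6
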