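"""Covariance assembly, Schur conditioning, Luzzati-D estimation."""

import numpy as np
import pytest

from anomlik.crystal import (AtomSite, CrystalModel, build_reflection_set,
                             resolution_bins, structure_factors)
from anomlik.errormodel import (build_covariance, component_sums,
                                condition_on_models, estimate_luzzati_d,
                                estimate_sigma_n)
from anomlik.likelihood import ModelSFTriple, QuadratureSpec, loglik_dataset
from anomlik.simulate import NoiseSpec, PerturbationSpec, perturb_model, simulate_observations


@pytest.fixture(scope="module")
def se_cov(small_truth, small_refl, small_bins):
    """Single-component (substructure, f'' > 0) covariance with dm stream."""
    sub = small_truth.anomalous_atoms
    s2, cg = component_sums(small_truth.atoms, small_refl, small_bins, 6)
    sdm = 0.8 * s2
    return build_covariance(small_refl, small_bins, s2,
                            [("model", sub, 0.7)], dm=(sdm, 0.6))


class TestAssembly:
    def test_hermitian_psd_over_random_parameters(self, small_truth, small_refl, small_bins):
        rng = np.random.default_rng(0)
        s2, _ = component_sums(small_truth.atoms, small_refl, small_bins, 6)
        for _ in range(25):
            d1, d2 = rng.uniform(0.01, 0.99, 2)
            ddm = rng.uniform(0.0, 0.95)
            cov = build_covariance(
                small_refl, small_bins, s2,
                [("protein", small_truth.protein_atoms, d1),
                 ("substructure", small_truth.anomalous_atoms, d2)],
                dm=(rng.uniform(0.2, 2.0) * s2, ddm))
            for b in range(cov.n_bins):
                sig = cov.sigma_full(b, 1.0, 1.0)
                np.testing.assert_allclose(sig, sig.conj().T, atol=1e-8)
                evals = np.linalg.eigvalsh(sig)
                assert evals.min() > -1e-8 * evals.max()

    def test_classical_luzzati_two_by_two(self, small_truth_no_anom, small_refl, small_bins):
        """Complete f''=0 model: marginal of F_o+ given F_m+ is the textbook
        N(D F_m, (1-D^2) Sigma_N + sigma^2)."""
        d = 0.65
        s2, cg = component_sums(small_truth_no_anom.atoms, small_refl, small_bins, 6)
        cov = build_covariance(small_refl, small_bins, s2, [("model", (s2, cg), d)])
        fp, fm = structure_factors(small_truth_no_anom, small_refl)
        tri = ModelSFTriple({"model": (fp.to_complex(), fm.to_complex())})
        sig = np.full(len(small_refl), 2.0)
        cg_cond = condition_on_models(cov, tri.stack(cov), sig, sig)
        np.testing.assert_allclose(cg_cond.mean_plus, d * fp.to_complex(), rtol=1e-8)
        expect_var = (1 - d * d) * s2[small_bins] + 8.0  # 2 sigma^2 convention
        np.testing.assert_allclose(cg_cond.cov[:, 0, 0].real, expect_var, rtol=1e-8)

    def test_d_zero_uninformative(self, se_cov, small_truth, small_refl):
        se_cov.set_d("model", 0.0)
        se_cov.set_d("dm", 0.0)
        sub = CrystalModel(small_refl.cell, [a.copy() for a in small_truth.anomalous_atoms])
        fp, fm = structure_factors(sub, small_refl)
        tri = ModelSFTriple({"model": (fp.to_complex(), fm.to_complex())},
                            fdm=fp.to_complex())
        cond = condition_on_models(se_cov, tri.stack(se_cov))
        assert np.abs(cond.mean).max() < 1e-10
        for b in range(se_cov.n_bins):
            sig = se_cov.sigma_full(b)
            mask = se_cov.bins == b
            np.testing.assert_allclose(cond.cov[mask][0], sig[:2, :2], atol=1e-8)
        se_cov.set_d("model", 0.7)
        se_cov.set_d("dm", 0.6)

    def test_non_psd_assembly_rejected(self, small_refl, small_bins):
        s2 = np.full(6, 100.0)
        cg = np.full(6, 150.0 + 0j)  # |Cg| > S2 is unphysical
        with pytest.raises(ValueError, match="bin"):
            build_covariance(small_refl, small_bins, s2, [("model", (s2, cg), 0.5)])


class TestConditioning:
    def test_schur_matches_full_inverse_elements(self, se_cov, small_truth, small_refl):
        """Conditional from Schur complement vs direct use of the Sigma5 inverse:
        C = (Sigma5^-1[obs,obs])^-1 and mean = -C Sigma5inv[obs,mod] m."""
        sub = CrystalModel(small_refl.cell, [a.copy() for a in small_truth.anomalous_atoms])
        fp, fm = structure_factors(sub, small_refl)
        tri = ModelSFTriple({"model": (fp.to_complex(), fm.to_complex())},
                            fdm=0.9 * fp.to_complex())
        m = tri.stack(se_cov)
        sig_p = np.full(len(small_refl), 1.5)
        cond = condition_on_models(se_cov, m, sig_p, sig_p)
        rng = np.random.default_rng(2)
        for i in rng.choice(len(small_refl), 10, replace=False):
            b = se_cov.bins[i]
            sig5 = se_cov.sigma_full(b, 1.5, 1.5)
            inv = np.linalg.inv(sig5)
            c_direct = np.linalg.inv(inv[:2, :2])
            mean_direct = -c_direct @ inv[:2, 2:] @ m[i]
            np.testing.assert_allclose(cond.mean[i], mean_direct, atol=1e-8)
            np.testing.assert_allclose(cond.cov[i], c_direct, atol=1e-8)

    def test_component_order_invariance(self, small_truth, small_refl, small_bins):
        s2, _ = component_sums(small_truth.atoms, small_refl, small_bins, 6)
        prot = small_truth.protein_atoms
        sub = small_truth.anomalous_atoms
        fpp, fpm = structure_factors(CrystalModel(small_refl.cell, prot), small_refl)
        fsp, fsm = structure_factors(CrystalModel(small_refl.cell, sub), small_refl)
        comps = {"protein": (fpp.to_complex(), fpm.to_complex()),
                 "substructure": (fsp.to_complex(), fsm.to_complex())}
        means = []
        for order in (("protein", "substructure"), ("substructure", "protein")):
            cov = build_covariance(small_refl, small_bins, s2,
                                   [(n, prot if n == "protein" else sub,
                                     0.5 if n == "protein" else 0.9) for n in order])
            tri = ModelSFTriple(comps)
            means.append(condition_on_models(cov, tri.stack(cov)).mean)
        np.testing.assert_allclose(means[0], means[1], atol=1e-8)

    def test_perfect_model_degenerate_guard(self, small_truth_no_anom, small_refl, small_bins):
        """D=1 complete model: conditional variance hits the floor, stays finite."""
        s2, cg = component_sums(small_truth_no_anom.atoms, small_refl, small_bins, 6)
        cov = build_covariance(small_refl, small_bins, s2, [("model", (s2, cg), 1.0)])
        fp, fm = structure_factors(small_truth_no_anom, small_refl)
        tri = ModelSFTriple({"model": (fp.to_complex(), fm.to_complex())})
        cond = condition_on_models(cov, tri.stack(cov))
        assert np.all(cond.cov[:, 0, 0].real > 0)
        np.testing.assert_allclose(cond.mean_plus, fp.to_complex(), rtol=1e-6)


class TestLuzzatiD:
    def test_perfect_model_estimates_near_one(self, small_truth, small_refl, small_bins, small_data):
        s2, cg = component_sums(small_truth.atoms, small_refl, small_bins, 6)
        cov = build_covariance(small_refl, small_bins, s2, [("model", (s2, cg), 0.5)])
        fp, fm = structure_factors(small_truth, small_refl)
        tri = ModelSFTriple({"model": (fp.to_complex(), fm.to_complex())})
        dhat = estimate_luzzati_d(small_data, tri, cov, "model")
        assert dhat.min() >= 0.99

    def test_random_model_estimates_near_zero(self, small_truth, small_refl, small_bins, small_data):
        """A fully wrong protein model refines to D ~ 0 (the correct anomalous
        substructure anchors the conditional mean, which is what makes small
        D identifiable in the package's own usage)."""
        wrong, _ = perturb_model(small_truth, PerturbationSpec(0.0, 0.0, 1.0, 0, seed=77))
        bins3 = resolution_bins(small_refl, 3)
        sn = estimate_sigma_n(small_data, bins3, 3)
        cov = build_covariance(
            small_refl, bins3, sn,
            [("protein", wrong.protein_atoms, 0.5),
             ("substructure", small_truth.anomalous_atoms, 0.98)])
        fpp, fpm = structure_factors(CrystalModel(small_refl.cell, wrong.protein_atoms),
                                     small_refl)
        fsp, fsm = structure_factors(
            CrystalModel(small_refl.cell, small_truth.anomalous_atoms), small_refl)
        tri = ModelSFTriple({"protein": (fpp.to_complex(), fpm.to_complex()),
                             "substructure": (fsp.to_complex(), fsm.to_complex())})
        dhat = estimate_luzzati_d(small_data, tri, cov, "protein")
        assert dhat.max() <= 0.15

    def test_estimate_improves_likelihood(self, small_truth, small_refl, small_bins, small_data):
        pert, _ = perturb_model(small_truth, PerturbationSpec(1.0, 0.2, seed=5))
        sn = estimate_sigma_n(small_data, small_bins, 6)
        cov = build_covariance(small_refl, small_bins, sn, [("model", pert.atoms, 0.3)])
        fp, fm = structure_factors(pert, small_refl)
        tri = ModelSFTriple({"model": (fp.to_complex(), fm.to_complex())})
        before, _ = loglik_dataset(small_data, tri, cov, QuadratureSpec(64))
        estimate_luzzati_d(small_data, tri, cov, "model")
        after, _ = loglik_dataset(small_data, tri, cov, QuadratureSpec(64))
        assert after >= before - 1e-6
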