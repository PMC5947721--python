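"""Posterior phase distributions, figures of merit and centroid map terms.

For each reflection the posterior of the unknown phase alpha_o+ is the
joint conditional density evaluated at the observed amplitudes,
marginalized over the minus-branch phase and normalized on the circle.
Internally phase information lives as these full gridded posteriors;
Hendrickson-Lattman coefficients are an *export* representation only.

The Blow-Crick centroid ("best") coefficient m |F_o+| exp(i phi_best)
minimizes the expected squared density error under the posterior; the
figure of merit m is the modulus of the posterior's circular mean, i.e.
the expected cosine of the phase error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .crystal import ComplexSF
from .errormodel import CovarianceModel
from scipy.special import i0e

from .likelihood import ModelSFTriple, QuadratureSpec, _conditional_parts

__all__ = [
    "PhasePosterior",
    "HLCoefficients",
    "phase_posterior",
    "best_coefficients",
    "hl_export",
    "mean_phase_error",
]


@dataclass
class PhasePosterior:
    """Gridded posteriors of alpha_o+ for a reflection set."""

    phi: np.ndarray        # (P,) phase nodes, radians
    prob: np.ndarray       # (N, P) density over radians: sum * dphi = 1
    fom: np.ndarray        # (N,)
    phi_best: np.ndarray   # (N,) degrees in [0, 360)
    flat: np.ndarray       # (N,) bool: posterior fell back to uniform

    def __len__(self) -> int:
        return self.prob.shape[0]


@dataclass
class HLCoefficients:
    """Per-reflection A, B, C, D of exp(A cos a + B sin a + C cos 2a + D sin 2a)."""

    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    d: np.ndarray
    kl: np.ndarray   # KL divergence of the gridded posterior from the fit
    degenerate: np.ndarray


def phase_posterior(data, triple: ModelSFTriple, cov: CovarianceModel,
                    quad: QuadratureSpec = QuadratureSpec(), n_phase: int = 180,
                    chunk: int = 2048) -> PhasePosterior:
    """Posterior of alpha_o+ on ``n_phase`` uniform nodes per reflection.

    At each alpha_o+ node the joint conditional density is evaluated with
    the minus-branch phase integrated *analytically*: the psi-dependent
    part of the exponent is 2 Re(e^{-i psi} u) with
    u(phi) = A- v2 - A+ A- conj(P12) e^{i phi}, whose circle integral is
    2 pi I0(2|u|).  This stays exact even in the strongly coupled regime
    where the two Friedel branches are nearly perfectly correlated and a
    gridded psi integral would need thousands of nodes.
    """
    n = max(n_phase, quad.n_points)
    a1, a2, mu1, mu2, c11, c22, c12 = _conditional_parts(data, triple, cov)
    det = np.maximum(c11 * c22 - np.abs(c12) ** 2, 1e-30)
    p11, p22, p12 = c22 / det, c11 / det, -c12 / det
    v1 = p11 * mu1 + p12 * mu2
    v2 = np.conj(p12) * mu1 + p22 * mu2

    phi = 2.0 * np.pi * np.arange(n) / n
    eiphi = np.exp(1j * phi)
    nref = len(a1)
    prob = np.empty((nref, n))
    flat = np.zeros(nref, dtype=bool)
    for lo in range(0, nref, chunk):
        hi = min(lo + chunk, nref)
        f = 2.0 * (a1[lo:hi, None] * np.conj(v1)[lo:hi, None] * eiphi[None, :]).real
        u = (a2[lo:hi, None] * v2[lo:hi, None]
             - (a1 * a2)[lo:hi, None] * np.conj(p12)[lo:hi, None] * eiphi[None, :])
        x = 2.0 * np.abs(u)
        logp = f + x + np.log(i0e(x))
        logp -= logp.max(axis=1, keepdims=True)
        p = np.exp(logp)
        tot = p.sum(axis=1)
        bad = (tot <= 0) | ~np.isfinite(tot)
        if bad.any():
            p[bad] = 1.0
            tot[bad] = float(n)
            flat[lo:hi][bad] = True
        prob[lo:hi] = p / (tot[:, None] * (2.0 * np.pi / n))
    z = (prob * np.exp(1j * phi)[None, :]).sum(axis=1) * (2.0 * np.pi / n)
    fom = np.clip(np.abs(z), 0.0, 1.0)
    phi_best = np.degrees(np.angle(z)) % 360.0
    return PhasePosterior(phi, prob, fom, phi_best, flat)


def best_coefficients(post: PhasePosterior, data) -> ComplexSF:
    """Blow-Crick centroid coefficients m |F_o+| exp(i phi_best)."""
    return ComplexSF(post.fom * data.f_plus, post.phi_best)


def hl_export(post: PhasePosterior) -> HLCoefficients:
    """Least-squares fit of log-posterior to the 4-coefficient HL basis."""
    phi = post.phi
    design = np.stack([np.ones_like(phi), np.cos(phi), np.sin(phi),
                       np.cos(2 * phi), np.sin(2 * phi)], axis=1)   # (P, 5)
    pinv = np.linalg.pinv(design)                                    # (5, P)
    logp = np.log(np.maximum(post.prob, 1e-300))
    coef = logp @ pinv.T                                             # (N, 5)
    degenerate = post.flat | ~np.isfinite(coef).all(axis=1)
    coef[degenerate] = 0.0
    a, b, c, d = coef[:, 1], coef[:, 2], coef[:, 3], coef[:, 4]
    # KL(post || fitted) with the fit renormalized on the grid
    fit = design @ coef.T  # (P, N)
    fit = np.exp(fit - fit.max(axis=0, keepdims=True)).T
    fit /= fit.sum(axis=1, keepdims=True) * (2 * np.pi / len(phi))
    p = np.maximum(post.prob, 1e-300)
    q = np.maximum(fit, 1e-300)
    kl = ((p * (np.log(p) - np.log(q))).sum(axis=1) * (2 * np.pi / len(phi)))
    return HLCoefficients(a, b, c, d, kl, degenerate)


def mean_phase_error(phases_deg, truth_deg, weights=None) -> float:
    """Weight-averaged absolute circular phase difference, in [0, 180] degrees."""
    p = np.radians(np.asarray(phases_deg, float))
    t = np.radians(np.asarray(truth_deg, float))
    d = np.angle(np.exp(1j * (p - t)))
    err = np.degrees(np.abs(d))
    if weights is None:
        return float(err.mean())
    w = np.asarray(weights, float)
    return float((err * w).sum() / w.sum())
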