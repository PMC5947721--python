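"""Multivariate likelihood of Bijvoet observations given models and maps.

The per-reflection probability P(|F_o+|, |F_o-| | models) is obtained from
the conditional complex Gaussian of (F_o+, conj(F_o-)) given the model
entries (partial model, substructure, density-modified map):

* the unknown phase of F_o+ integrates analytically to a modified-Bessel
  I0 (Rice) factor;
* the unknown minus-branch phase has no analytic integral and is handled
  by a periodic trapezoid rule (spectrally accurate for smooth periodic
  integrands), 64 nodes by default.

With no anomalous signal and a complete *exact* model (D = 1) the
conditional cross term vanishes and the function collapses to the product
of two measurement-noise Rice densities, and every single-amplitude
marginal is the classical acentric Luzzati Rice at any D — both used as
hard correctness checks.  All heavy arithmetic is vectorized over
reflections.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import i0e, i1e

from .crystal import AtomSite, CrystalModel, ReflectionSet, atom_scattering, structure_factors
from .errormodel import CovarianceModel, condition_on_models

__all__ = [
    "ModelSFTriple",
    "QuadratureSpec",
    "loglik_reflection",
    "loglik_dataset",
    "gradient_wrt_model_sf",
    "SFGradients",
    "reduce_to_sad",
    "refine_parameters",
    "RefinementResult",
    "rice_logpdf",
]

_AMP_FLOOR = 1e-12


@dataclass(frozen=True)
class QuadratureSpec:
    """Uniform nodes on [0, 2pi) for the minus-branch phase integral."""

    n_points: int = 64
    rule: str = "trapezoid"

    def __post_init__(self) -> None:
        if self.n_points < 8:
            raise ValueError("n_points must be >= 8")
        if self.rule != "trapezoid":
            raise ValueError("only the periodic trapezoid rule is supported")

    @property
    def nodes(self) -> np.ndarray:
        return 2.0 * np.pi * np.arange(self.n_points) / self.n_points


@dataclass
class ModelSFTriple:
    """Per-reflection model structure factors: components plus dm stream.

    ``components`` maps a component name ('model', or 'protein'/
    'substructure') to (F_plus, F_minus) complex arrays — F_minus is the
    structure factor at -h, *not* its conjugate.  ``fdm`` is the
    density-modified coefficient (None when no dm map exists).
    """

    components: dict
    fdm: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = None
        comps = {}
        for name, (fp, fm) in self.components.items():
            fp = np.asarray(fp, dtype=complex)
            fm = np.asarray(fm, dtype=complex)
            if fp.shape != fm.shape or fp.ndim != 1:
                raise ValueError("component arrays must be matching 1-D")
            if n is None:
                n = len(fp)
            elif len(fp) != n:
                raise ValueError("component lengths disagree")
            comps[name] = (fp, fm)
        self.components = comps
        if self.fdm is not None:
            self.fdm = np.asarray(self.fdm, dtype=complex)
            if n is not None and len(self.fdm) != n:
                raise ValueError("fdm length disagrees")
            if n is None:
                n = len(self.fdm)
        if n is None:
            raise ValueError("empty triple")
        self._n = n

    def __len__(self) -> int:
        return self._n

    @property
    def has_dm(self) -> bool:
        return self.fdm is not None

    @property
    def fm_plus(self) -> np.ndarray:
        """Summed model structure factor F_m+ (all components)."""
        if not self.components:
            return np.zeros(self._n, dtype=complex)
        return np.sum([fp for fp, _ in self.components.values()], axis=0)

    @property
    def fm_minus(self) -> np.ndarray:
        if not self.components:
            return np.zeros(self._n, dtype=complex)
        return np.sum([fm for _, fm in self.components.values()], axis=0)

    def stack(self, cov: CovarianceModel) -> np.ndarray:
        """(N, k) model vector in the covariance ordering, minus branch conjugated."""
        cols = []
        for c in cov.components:
            if c.name not in self.components:
                raise KeyError(f"triple lacks component '{c.name}' expected by covariance")
            fp, fm = self.components[c.name]
            cols.extend([fp, np.conj(fm)])
        if cov.dm is not None:
            if self.fdm is None:
                raise KeyError("covariance expects a dm entry but triple has none")
            cols.append(self.fdm)
        if not cols:
            return np.zeros((self._n, 0), dtype=complex)
        return np.stack(cols, axis=1)

    def take(self, idx) -> "ModelSFTriple":
        comps = {k: (fp[idx], fm[idx]) for k, (fp, fm) in self.components.items()}
        fdm = self.fdm[idx] if self.fdm is not None else None
        return ModelSFTriple(comps, fdm)


def rice_logpdf(a: np.ndarray, nu: np.ndarray, var: np.ndarray) -> np.ndarray:
    """Acentric Rice log-density: P(A) = (2A/V) exp(-(A^2+nu^2)/V) I0(2 A nu / V)."""
    a = np.maximum(np.asarray(a, float), _AMP_FLOOR)
    x = 2.0 * a * np.abs(nu) / var
    return (np.log(2.0 * a / var) - (a ** 2 + np.abs(nu) ** 2) / var
            + x + np.log(i0e(x)))


# --------------------------------------------------------------------------
# core kernel
# --------------------------------------------------------------------------

def _conditional_parts(data, triple: ModelSFTriple, cov: CovarianceModel, subset=None):
    m = triple.stack(cov)
    ws, c0s = cov.conditioners()
    bins = cov.bins
    a1, a2 = data.f_plus, data.f_minus
    sp, sm = data.sig_plus, data.sig_minus
    if subset is not None:
        sel = np.asarray(subset)
        m, bins = m[sel], bins[sel]
        a1, a2, sp, sm = a1[sel], a2[sel], sp[sel], sm[sel]
    wsel = ws[bins]
    mean = np.einsum("nij,nj->ni", wsel, m)
    c0 = c0s[bins]
    a1 = np.maximum(a1, _AMP_FLOOR)
    a2 = np.maximum(a2, _AMP_FLOOR)
    # amplitude sigma -> complex variance 2 sigma^2 (radial variance v/2)
    c11 = c0[:, 0, 0].real + 2.0 * sp ** 2
    c22 = c0[:, 1, 1].real + 2.0 * sm ** 2
    c12 = c0[:, 0, 1]
    return a1, a2, mean[:, 0], mean[:, 1], c11, c22, c12


def _kernel(a1, a2, mu1, mu2, c11, c22, c12, n_quad, want_grad=False):
    """Vectorized log-likelihood (and posterior moments for gradients).

    Returns (loglik, E1, E2) where E1 = E[F_o+], E2 = E[conj(F_o-)] under the
    per-reflection phase posterior (E1/E2 are None unless want_grad).
    """
    det = c11 * c22 - np.abs(c12) ** 2
    det = np.maximum(det, 1e-30)
    p11 = c22 / det
    p22 = c11 / det
    p12 = -c12 / det
    v1 = p11 * mu1 + p12 * mu2
    v2 = np.conj(p12) * mu1 + p22 * mu2
    mu_p_mu = (np.conj(mu1) * v1 + np.conj(mu2) * v2).real
    base = -(p11 * a1 ** 2 + p22 * a2 ** 2 + mu_p_mu)

    psi = 2.0 * np.pi * np.arange(n_quad) / n_quad
    eipsi = np.exp(1j * psi)  # (Q,)
    # w_k = A1 (v1 - P12 A2 e^{i psi})   -> (N, Q)
    w = a1[:, None] * (v1[:, None] - p12[:, None] * a2[:, None] * eipsi[None, :])
    absw = np.abs(w)
    x = 2.0 * absw
    log_i0 = x + np.log(i0e(x))
    g = (base[:, None]
         + 2.0 * (a2[:, None] * (np.conj(v2)[:, None] * eipsi[None, :])).real
         + log_i0)
    mx = g.max(axis=1)
    lse = mx + np.log(np.exp(g - mx[:, None]).sum(axis=1))
    loglik = (np.log(a1) + np.log(a2) - 2.0 * np.log(np.pi) - np.log(det)
              + np.log(2.0 * np.pi) + np.log(2.0 * np.pi / n_quad) + lse)
    if not want_grad:
        return loglik, None, None
    p = np.exp(g - lse[:, None])            # posterior over psi nodes (sums to ~n/2pi scale)
    p /= p.sum(axis=1, keepdims=True)
    ratio = i1e(x) / i0e(x)
    dirw = np.where(absw > 0, w / np.maximum(absw, 1e-300), 0.0)
    e1 = a1 * (p * dirw * ratio).sum(axis=1)
    e2 = a2 * (p * eipsi[None, :]).sum(axis=1)
    return loglik, e1, e2


# --------------------------------------------------------------------------
# public operations
# --------------------------------------------------------------------------

def loglik_dataset(data, triple: ModelSFTriple, cov: CovarianceModel,
                   quad: QuadratureSpec = QuadratureSpec(), subset=None,
                   missing_minus=None):
    """Total log-likelihood and the per-reflection vector.

    ``missing_minus``: optional boolean mask; flagged reflections contribute
    the single-amplitude Rice marginal of |F_o+| instead of the pair term.
    """
    a1, a2, mu1, mu2, c11, c22, c12 = _conditional_parts(data, triple, cov, subset)
    ll, _, _ = _kernel(a1, a2, mu1, mu2, c11, c22, c12, quad.n_points)
    if missing_minus is not None:
        mm = np.asarray(missing_minus)
        if subset is not None:
            mm = mm[np.asarray(subset)]
        if mm.any():
            ll = np.where(mm, rice_logpdf(a1, np.abs(mu1), c11), ll)
    if not np.all(np.isfinite(ll)):
        bad = int(np.flatnonzero(~np.isfinite(ll))[0])
        raise FloatingPointError(f"non-finite log-likelihood at reflection {bad}")
    return float(ll.sum()), ll


def loglik_reflection(pair, triple: ModelSFTriple, cov: CovarianceModel,
                      quad: QuadratureSpec = QuadratureSpec(), index: int = 0):
    """Log-likelihood of a single Bijvoet pair (reflection ``index``)."""
    b = int(cov.bins[index])
    m = triple.stack(cov)[index:index + 1]
    ws, c0s = cov.conditioners()
    mean = (ws[b] @ m[0])
    c = c0s[b].copy()
    c[0, 0] += 2.0 * pair.sig_plus ** 2
    c[1, 1] += 2.0 * pair.sig_minus ** 2
    ll, _, _ = _kernel(np.array([max(pair.f_plus_obs, _AMP_FLOOR)]),
                       np.array([max(pair.f_minus_obs, _AMP_FLOOR)]),
                       np.array([mean[0]]), np.array([mean[1]]),
                       np.array([c[0, 0].real]), np.array([c[1, 1].real]),
                       np.array([c[0, 1]]), quad.n_points)
    if not np.isfinite(ll[0]):
        raise FloatingPointError(f"non-finite log-likelihood at reflection {index}")
    return float(ll[0])


@dataclass
class SFGradients:
    """Complex Wirtinger gradients d logL / d conj(F) per reflection.

    Convention: for a perturbation dF of the (unconjugated) structure
    factor, d logL = 2 Re(conj(G) dF); equivalently d logL / d Re(F) =
    2 Re(G) and d logL / d Im(F) = 2 Im(G).
    """

    components: dict   # name -> (g_plus, g_minus) arrays, unconjugated convention
    dm: np.ndarray | None

    def for_component(self, name: str):
        return self.components[name]


def loglik_and_gradients(data, triple: ModelSFTriple, cov: CovarianceModel,
                         quad: QuadratureSpec = QuadratureSpec(), subset=None):
    """(total log-likelihood, SFGradients) from a single kernel pass."""
    ll, grads = _loglik_grad_impl(data, triple, cov, quad, subset)
    return float(ll.sum()), grads


def gradient_wrt_model_sf(data, triple: ModelSFTriple, cov: CovarianceModel,
                          quad: QuadratureSpec = QuadratureSpec(),
                          subset=None) -> SFGradients:
    """Analytic gradients of the total log-likelihood w.r.t. every model SF.

    Differentiation under the quadrature: with conditional precision P and
    posterior moments E[x], the gradient w.r.t. the conditional mean is
    G_mu = P (E[x] - mu); the chain through mu = W m gives G_m = W^H G_mu
    per reflection, split back into components and the dm entry.  The
    minus-branch gradients are returned in the unconjugated F_m- convention.
    """
    return _loglik_grad_impl(data, triple, cov, quad, subset)[1]


def _loglik_grad_impl(data, triple, cov, quad, subset=None):
    a1, a2, mu1, mu2, c11, c22, c12 = _conditional_parts(data, triple, cov, subset)
    ll, e1, e2 = _kernel(a1, a2, mu1, mu2, c11, c22, c12, quad.n_points, want_grad=True)
    det = np.maximum(c11 * c22 - np.abs(c12) ** 2, 1e-30)
    p11, p22, p12 = c22 / det, c11 / det, -c12 / det
    r1, r2 = e1 - mu1, e2 - mu2
    gmu1 = p11 * r1 + p12 * r2
    gmu2 = np.conj(p12) * r1 + p22 * r2
    ws, _ = cov.conditioners()
    b = cov.bins if subset is None else cov.bins[np.asarray(subset)]
    wsel = ws[b]                       # (N, 2, k)
    gm = (np.conj(wsel[:, 0, :]) * gmu1[:, None]
          + np.conj(wsel[:, 1, :]) * gmu2[:, None])  # (N, k)
    comps = {}
    col = 0
    for c in cov.components:
        gp = gm[:, col]
        gmin = np.conj(gm[:, col + 1])  # entry is conj(F-): chain back to F-
        comps[c.name] = (gp, gmin)
        col += 2
    gdm = gm[:, col] if cov.dm is not None else None
    return ll, SFGradients(comps, gdm)


def reduce_to_sad(data, substructure_triple: ModelSFTriple, cov: CovarianceModel,
                  quad: QuadratureSpec = QuadratureSpec(), n_phase: int = 180):
    """Pure-SAD phasing: the general path with protein and dm absent.

    Returns (posteriors, total_loglik).  This *is* the general code path —
    the covariance simply carries a single substructure component — so the
    equivalence contract with the full function is structural.
    """
    from .phasing import phase_posterior

    total, _ = loglik_dataset(data, substructure_triple, cov, quad)
    post = phase_posterior(data, substructure_triple, cov, quad, n_phase)
    return post, total


# --------------------------------------------------------------------------
# parameter refinement
# --------------------------------------------------------------------------

@dataclass
class RefinementResult:
    substructure: list            # refined AtomSite list
    cov: CovarianceModel
    triple: ModelSFTriple
    loglik: float
    n_sweeps: int
    converged: bool
    warning: str | None = None


def refine_parameters(data, refl: ReflectionSet, substructure: Sequence[AtomSite],
                      cov: CovarianceModel, quad: QuadratureSpec = QuadratureSpec(),
                      protein_sf: tuple | None = None, dm_sf: np.ndarray | None = None,
                      refinable=("occ", "b", "d"),
                      d_components: tuple | None = None,
                      max_sweeps: int = 10,
                      tol: float = 1e-3, b_bounds=(2.0, 200.0)) -> RefinementResult:
    """Alternating maximization of the total log-likelihood.

    Sweeps alternate (substructure occupancies, B — and fractional
    coordinates when "xyz" is requested — jointly, bounded L-BFGS-B with
    analytic gradients) and (per-bin Luzzati D, bounded 1-D search, for
    the components named in ``d_components`` — default all).  Coordinate
    refinement matters (atoms placed from interpolated map peaks sit a few
    tenths of an Angstrom off their sites), but it should be run against a
    substructure-only covariance: with a biased partial protein model in
    the conditional mean, the positions drift to compensate the model's
    phase errors.  The pipelines therefore refine occupancies/B/D with the
    full model and polish coordinates in a separate pure-SAD pass.
    Substructure occupancies and the substructure D scale the same
    amplitudes and are nearly degenerate; callers refining occupancies
    normally pin the substructure D and list only "protein"/"dm" here.
    Substructure covariance sums are held fixed within each inner solve
    and refreshed between sweeps.
    Occupancies stay in [0, 1], B in ``b_bounds``; on optimizer failure the
    best parameters seen so far are returned with a warning flag.
    """
    from scipy.optimize import minimize

    from .errormodel import component_sums, estimate_luzzati_d

    atoms = [a.copy() for a in substructure]
    s = refl.s
    h = refl.miller.astype(float)
    s2q = s ** 2 / 4.0
    gs = [atom_scattering(a, s) for a in atoms]
    na = len(atoms)

    def sub_sf(occ, b, frac):
        n = len(refl)
        fp = np.zeros(n, dtype=complex)
        fmb = np.zeros(n, dtype=complex)
        for j in range(na):
            e = np.exp(2j * np.pi * (h @ frac[j]))
            dw = np.exp(-b[j] * s2q)
            fp += occ[j] * gs[j] * dw * e
            fmb += occ[j] * np.conj(gs[j]) * dw * e
        return fp, np.conj(fmb)

    def build_triple(occ, b, frac):
        comps = {}
        if protein_sf is not None:
            comps["protein"] = protein_sf
        if na:
            comps["substructure"] = sub_sf(occ, b, frac)
        else:
            zero = np.zeros(len(refl), dtype=complex)
            comps["substructure"] = (zero, zero.copy())
        return ModelSFTriple(comps, dm_sf)

    def refresh_cov_sums(occ, b, frac):
        if not na:
            return
        for j, a in enumerate(atoms):
            a.occupancy, a.b_iso = float(occ[j]), float(b[j])
            a.frac_xyz = frac[j] % 1.0
        sub = cov.component("substructure")
        s2, cgx = component_sums(atoms, refl, cov.bins, cov.n_bins)
        sub.s2, sub.cg = s2, cgx
        cov._cond_cache = None

    occ = np.array([a.occupancy for a in atoms])
    bfac = np.array([a.b_iso for a in atoms])
    frac = np.array([a.frac_xyz for a in atoms]).reshape(na, 3)
    triple = build_triple(occ, bfac, frac)
    ll0, _ = loglik_dataset(data, triple, cov, quad)
    best_ll = ll0
    warning = None
    sweeps_done = 0
    do_occ = "occ" in refinable
    do_b = "b" in refinable
    do_xyz = "xyz" in refinable

    for sweep in range(max_sweeps):
        ll_start = best_ll
        if "d" in refinable:
            for comp in cov.components:
                if d_components is not None and comp.name not in d_components:
                    continue
                estimate_luzzati_d(data, triple, cov, which=comp.name)
            if cov.dm is not None and (d_components is None or "dm" in d_components):
                estimate_luzzati_d(data, triple, cov, which="dm")
            best_ll, _ = loglik_dataset(data, triple, cov, quad)
        if na and (do_occ or do_b or do_xyz):

            def pack(o, bb, fx):
                parts = []
                if do_occ:
                    parts.append(o)
                if do_b:
                    parts.append(bb)
                if do_xyz:
                    parts.append(fx.ravel())
                return np.concatenate(parts)

            def unpack(p):
                o, bb, fx = occ.copy(), bfac.copy(), frac.copy()
                i = 0
                if do_occ:
                    o = p[i:i + na]
                    i += na
                if do_b:
                    bb = p[i:i + na]
                    i += na
                if do_xyz:
                    fx = p[i:i + 3 * na].reshape(na, 3)
                return o, bb, fx

            def negloglik(p):
                o, bb, fx = unpack(p)
                tri = build_triple(o, bb, fx)
                ll, grads = loglik_and_gradients(data, tri, cov, quad)
                gp, gm = grads.for_component("substructure")
                gmb = np.conj(gm)  # gradient w.r.t. conj(F-) entries
                docc = np.empty(na)
                dbf = np.empty(na)
                dxyz = np.empty((na, 3))
                for j in range(na):
                    e = np.exp(2j * np.pi * (h @ fx[j]))
                    dw = np.exp(-bb[j] * s2q)
                    common = (np.conj(gp) * gs[j] + np.conj(gmb) * np.conj(gs[j])) * e
                    docc[j] = 2.0 * (common * dw).real.sum()
                    dbf[j] = 2.0 * o[j] * (common * dw * (-s2q)).real.sum()
                    if do_xyz:
                        cw = common * dw * (2j * np.pi) * o[j]
                        dxyz[j] = 2.0 * (cw[:, None] * h).real.sum(axis=0)
                grad = []
                if do_occ:
                    grad.append(docc)
                if do_b:
                    grad.append(dbf)
                if do_xyz:
                    grad.append(dxyz.ravel())
                return -ll, -np.concatenate(grad)

            # positions move within a 0.75 A trust region per sweep: the
            # likelihood is multimodal in the coordinates with period ~d_min
            # and unconstrained steps hop atoms onto aliased false optima
            lengths = np.array([refl.cell.a, refl.cell.b, refl.cell.c])
            delta = 0.75 / lengths
            xyz_bounds = [(frac[j, i] - delta[i], frac[j, i] + delta[i])
                          for j in range(na) for i in range(3)]
            bounds = ([(0.0, 1.0)] * na if do_occ else []) + \
                     ([b_bounds] * na if do_b else []) + \
                     (xyz_bounds if do_xyz else [])
            try:
                res = minimize(negloglik, pack(occ, bfac, frac), jac=True,
                               method="L-BFGS-B", bounds=bounds,
                               options={"maxiter": 40, "ftol": 1e-9})
                occ_new, b_new, f_new = unpack(res.x)
                tri = build_triple(occ_new, b_new, f_new)
                ll_new, _ = loglik_dataset(data, tri, cov, quad)
                if ll_new >= best_ll - 1e-9:
                    occ, bfac = np.clip(occ_new, 0, 1), np.clip(b_new, *b_bounds)
                    frac = f_new
                    best_ll = max(best_ll, ll_new)
            except Exception as exc:  # pragma: no cover - optimizer failure path
                warning = f"substructure parameter optimization failed: {exc}"
            refresh_cov_sums(occ, bfac, frac)
            triple = build_triple(occ, bfac, frac)
            best_ll, _ = loglik_dataset(data, triple, cov, quad)

        sweeps_done = sweep + 1
        if abs(best_ll - ll_start) < tol:
            break

    for j, a in enumerate(atoms):
        a.occupancy, a.b_iso = float(occ[j]), float(bfac[j])
        a.frac_xyz = frac[j] % 1.0
    if best_ll < ll0 - 1e-6:  # never return something worse than the input
        warning = warning or "refinement failed to improve the likelihood"
    return RefinementResult(atoms, cov, triple, float(best_ll), sweeps_done,
                            converged=sweeps_done < max_sweeps, warning=warning)
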