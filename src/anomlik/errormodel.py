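"""Structure-factor covariance model for the multivariate SAD likelihood.

The joint distribution of (F_o+, conj(F_o-), model components, F_dm) per
reflection is a zero-mean circular complex Gaussian.  Working with the
*conjugate* of every minus-Friedel branch makes the f''->0 limit render the
plus/minus entries perfectly correlated (rather than anti-correlated), so
all covariances are ordinary Hermitian entries.

Per resolution bin the model carries, for each model component c (the
partial protein model, the anomalous substructure, or a single combined
model):

* ``S2_c = <sum_j occ_j^2 |g_j|^2 DW_j^2>_bin`` — scattering power of the
  component, with g_j = f0_j(s) + f'_j + i f''_j and DW the Debye-Waller
  factor, and
* ``Cg_c = <sum_j occ_j^2 g_j^2 DW_j^2>_bin`` — the complex Friedel-cross
  sum whose imaginary part (2 sum f'' (f0+f')) carries the anomalous
  phase information, and
* a refinable Luzzati parameter ``D_c`` in [0, 1].

Cross-branch structure: because a coordinate error displaces an atom
identically in F(h) and F(-h), its phase-error factors are complex
conjugates and the inter-branch covariance of the *content* is
<F+ F-> = sum_j g_j^2 regardless of the Luzzati damping — the plus/minus
cross entry therefore carries the full Sigma g^2 (unknown content treated
as non-anomalous, so its g^2 equals |g|^2).  After conditioning on the
models this leaves an inter-branch residual correlation
SU + sum_c (1-D_c^2) Cg_c: large and real when the model is a small
substructure (the source of the bimodal SAD phase posterior), exactly
zero for a complete exact model (D = 1), where the likelihood collapses
to two independent measurement-noise Rice densities.  Each single
amplitude's marginal is an acentric Luzzati Rice with noncentrality
D |F_m| and variance (1 - D^2)-damped power plus noise at any D.

The density-modified map enters as a fifth variable F_dm with its own
empirical power per bin and a Luzzati-like refinable correlation ``d_dm``;
being derived from a real map it correlates identically with both Friedel
branches.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.linalg

from .crystal import ReflectionSet, atom_scattering

__all__ = [
    "ComponentCov",
    "DmCov",
    "CovarianceModel",
    "ConditionalGaussian",
    "component_sums",
    "estimate_sigma_n",
    "build_covariance",
    "condition_on_models",
    "estimate_luzzati_d",
]

# relative floor for conditional variances (degenerate perfect-model guard)
COND_VAR_FLOOR = 1e-12


@dataclass
class ComponentCov:
    """Per-bin second moments and Luzzati D for one model component."""

    name: str
    s2: np.ndarray          # (B,) real
    cg: np.ndarray          # (B,) complex
    d: np.ndarray           # (B,) in [0, 1]

    def __post_init__(self) -> None:
        self.s2 = np.asarray(self.s2, dtype=float)
        self.cg = np.asarray(self.cg, dtype=complex)
        self.d = np.atleast_1d(np.asarray(self.d, dtype=float)) * np.ones(len(self.s2))
        if np.any((self.d < 0) | (self.d > 1)):
            raise ValueError("Luzzati D must lie in [0, 1]")


@dataclass
class DmCov:
    """Per-bin empirical power and correlation parameter of the dm map."""

    s_dm: np.ndarray        # (B,) real
    d: np.ndarray           # (B,) in [0, 1)

    def __post_init__(self) -> None:
        self.s_dm = np.asarray(self.s_dm, dtype=float)
        self.d = np.atleast_1d(np.asarray(self.d, dtype=float)) * np.ones(len(self.s_dm))
        if np.any((self.d < 0) | (self.d >= 1)):
            raise ValueError("d_dm must lie in [0, 1)")


@dataclass
class CovarianceModel:
    """Binned Hermitian covariance of (F_o+, F_o-bar, model entries, F_dm)."""

    bins: np.ndarray               # (N,) bin index per reflection
    bin_d: np.ndarray              # (B,) mean d-spacing per bin
    sigma_n: np.ndarray            # (B,) total scattering power Sigma_N
    components: list               # list[ComponentCov], order fixes the m-vector
    dm: DmCov | None = None

    def __post_init__(self) -> None:
        self.bins = np.asarray(self.bins, dtype=int)
        self.sigma_n = np.asarray(self.sigma_n, dtype=float)
        if np.any(self.sigma_n <= 0):
            raise ValueError("sigma_n must be positive in every bin")
        self._cond_cache = None

    @property
    def n_bins(self) -> int:
        return len(self.sigma_n)

    @property
    def model_dim(self) -> int:
        """Length of the model vector m = (c1+, c1-bar, ..., F_dm)."""
        return 2 * len(self.components) + (1 if self.dm is not None else 0)

    def component(self, name: str) -> ComponentCov:
        for c in self.components:
            if c.name == name:
                return c
        raise KeyError(name)

    def set_d(self, name: str, values) -> None:
        new = np.atleast_1d(np.asarray(values, float)) * np.ones(self.n_bins)
        if name == "dm":
            if self.dm is None:
                raise KeyError("no dm component")
            old, self.dm.d = self.dm.d, new
        else:
            c = self.component(name)
            old, c.d = c.d, new
        if self._cond_cache is not None:
            changed = np.flatnonzero(old != new)
            for b in changed:
                self._condition_bin(int(b))

    # -- full-matrix assembly ------------------------------------------------

    def _unknown_terms(self, b: int):
        su = self.sigma_n[b] - sum(c.s2[b] for c in self.components)
        su = max(su, 0.0)
        # unknown content treated as non-anomalous: Sigma g^2 = Sigma |g|^2
        return su, su + 0.0j

    def _obs_cross(self, b: int) -> complex:
        """<F_o+ conj(F_o-bar)> = Sigma_all g^2; D-independent (conjugate
        phase errors cancel in the inter-branch product)."""
        su, cgu = self._unknown_terms(b)
        return cgu + sum(c.cg[b] for c in self.components)

    def sigma_full(self, b: int, sig_plus: float = 0.0, sig_minus: float = 0.0) -> np.ndarray:
        """Assembled Hermitian covariance for bin ``b``.

        Ordering: (F_o+, F_o-bar, c1+, c1-bar, c2+, c2-bar, ..., F_dm);
        with a single model component plus dm this is the 5x5 matrix.
        Amplitude measurement sigmas enter the complex diagonal as
        2 sigma^2: a circular complex variance v has radial (amplitude)
        variance v/2, so matching the stated amplitude error needs the
        factor of two.
        """
        ncomp = len(self.components)
        k = 2 + 2 * ncomp + (1 if self.dm is not None else 0)
        sn = self.sigma_n[b]
        xt = self._obs_cross(b)
        sig = np.zeros((k, k), dtype=complex)
        sig[0, 0] = sn + 2.0 * sig_plus ** 2
        sig[1, 1] = sn + 2.0 * sig_minus ** 2
        sig[0, 1] = xt
        sig[1, 0] = np.conj(xt)
        for i, c in enumerate(self.components):
            r = 2 + 2 * i
            d, s2, cg = c.d[b], c.s2[b], c.cg[b]
            sig[0, r], sig[0, r + 1] = d * s2, d * cg
            sig[1, r], sig[1, r + 1] = d * np.conj(cg), d * s2
            sig[r, 0], sig[r + 1, 0] = d * s2, d * np.conj(cg)
            sig[r, 1], sig[r + 1, 1] = d * cg, d * s2
            sig[r, r] = sig[r + 1, r + 1] = s2
            sig[r, r + 1] = cg
            sig[r + 1, r] = np.conj(cg)
        if self.dm is not None:
            jdm = k - 1
            sdm, ddm = self.dm.s_dm[b], self.dm.d[b]
            st = max(0.5 * (sn + xt.real), 1e-30)
            beta = ddm * np.sqrt(max(sdm, 0.0) / st)
            odm_p = beta * 0.5 * (sn + xt)
            odm_m = beta * 0.5 * (sn + np.conj(xt))
            sig[0, jdm], sig[jdm, 0] = odm_p, np.conj(odm_p)
            sig[1, jdm], sig[jdm, 1] = odm_m, np.conj(odm_m)
            for i, c in enumerate(self.components):
                r = 2 + 2 * i
                cdm_p = beta * c.d[b] * 0.5 * (c.s2[b] + c.cg[b])
                cdm_m = beta * c.d[b] * 0.5 * (c.s2[b] + np.conj(c.cg[b]))
                sig[r, jdm], sig[jdm, r] = cdm_p, np.conj(cdm_p)
                sig[r + 1, jdm], sig[jdm, r + 1] = cdm_m, np.conj(cdm_m)
            sig[jdm, jdm] = max(sdm, 1e-30)
        return sig

    def conditioners(self):
        """Per-bin (W, C0): mean weights (2, k) and noise-free conditional 2x2.

        W = Sigma_om Sigma_mm^+ (Hermitian pseudo-inverse; the model block is
        legitimately singular in the f''->0 limit), C0 = Sigma_oo - W Sigma_mo
        with conditional variances floored at 1e-8 Sigma_N.
        """
        if self._cond_cache is not None:
            return self._cond_cache
        kmod = self.model_dim
        ws = np.zeros((self.n_bins, 2, kmod), dtype=complex)
        c0s = np.zeros((self.n_bins, 2, 2), dtype=complex)
        self._cond_cache = (ws, c0s)
        for b in range(self.n_bins):
            self._condition_bin(b)
        return self._cond_cache

    def _condition_bin(self, b: int) -> None:
        ws, c0s = self._cond_cache
        kmod = self.model_dim
        sig = self.sigma_full(b)
        soo = sig[:2, :2]
        if kmod == 0:
            c0 = soo.copy()
            w = np.zeros((2, 0), dtype=complex)
        else:
            som = sig[:2, 2:]
            smm = sig[2:, 2:]
            evals = np.linalg.eigvalsh(smm)
            if evals.min() < -1e-8 * max(evals.max(), 1e-30):
                raise ValueError(f"covariance bin {b}: model block not PSD")
            w = som @ scipy.linalg.pinvh(smm, rtol=1e-10)
            c0 = soo - w @ som.conj().T
        floor = COND_VAR_FLOOR * self.sigma_n[b]
        for i in range(2):
            c0[i, i] = max(c0[i, i].real, floor)
        # keep the 2x2 positive definite after flooring
        r11, r22 = c0[0, 0].real, c0[1, 1].real
        off = c0[0, 1]
        lim = np.sqrt(r11 * r22) * (1.0 - 1e-12)
        if abs(off) > lim:
            off *= lim / abs(off)
            c0[0, 1], c0[1, 0] = off, np.conj(off)
        ws[b], c0s[b] = w, c0


@dataclass
class ConditionalGaussian:
    """Per-reflection conditional law of (F_o+, F_o-bar) given the models."""

    mean: np.ndarray   # (N, 2) complex
    cov: np.ndarray    # (N, 2, 2) complex Hermitian, measurement noise included

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=complex)
        self.cov = np.asarray(self.cov, dtype=complex)

    @property
    def mean_plus(self) -> np.ndarray:
        return self.mean[:, 0]

    @property
    def mean_minus(self) -> np.ndarray:
        """Conditional mean of conj(F_o-)."""
        return self.mean[:, 1]


# --------------------------------------------------------------------------
# builders
# --------------------------------------------------------------------------

def component_sums(atoms, refl: ReflectionSet, bins: np.ndarray, n_bins: int):
    """Bin-averaged (S2, Cg) sums for a list of atoms.

    S2 = sum_j occ_j^2 |g_j(s)|^2 exp(-B_j s^2 / 2) averaged within bins,
    Cg the same with g^2 in place of |g|^2 (complex).
    """
    s = refl.s
    s2_r = np.zeros(len(refl))
    cg_r = np.zeros(len(refl), dtype=complex)
    for a in atoms:
        g = atom_scattering(a, s)
        dw2 = np.exp(-a.b_iso * s ** 2 / 2.0)
        w = a.occupancy ** 2 * dw2
        s2_r += w * np.abs(g) ** 2
        cg_r += w * g ** 2
    s2 = np.zeros(n_bins)
    cg = np.zeros(n_bins, dtype=complex)
    for b in range(n_bins):
        m = bins == b
        if m.any():
            s2[b] = s2_r[m].mean()
            cg[b] = cg_r[m].mean()
    return s2, cg


def estimate_sigma_n(data, bins: np.ndarray, n_bins: int) -> np.ndarray:
    """Empirical Sigma_N per bin: mean (|F_o|^2) minus measurement variance."""
    amp2 = 0.5 * (data.f_plus ** 2 + data.f_minus ** 2)
    var = 0.5 * (data.sig_plus ** 2 + data.sig_minus ** 2)
    out = np.zeros(n_bins)
    for b in range(n_bins):
        m = bins == b
        val = amp2[m].mean() - var[m].mean()
        out[b] = max(val, 0.05 * amp2[m].mean())
    return out


def build_covariance(refl: ReflectionSet, bins: np.ndarray, sigma_n: np.ndarray,
                     components: Sequence[tuple] = (), dm: tuple | None = None) -> CovarianceModel:
    """Assemble a :class:`CovarianceModel`.

    ``components``: sequence of (name, atoms_or_sums, D) where
    atoms_or_sums is either a list of :class:`~anomlik.crystal.AtomSite`
    or a precomputed (s2, cg) pair; D is a scalar or per-bin array.
    ``dm``: optional (s_dm_per_bin, d_dm).
    """
    n_bins = len(sigma_n)
    comp_objs = []
    for name, spec, d in components:
        if isinstance(spec, tuple):
            s2, cg = spec
        else:
            s2, cg = component_sums(spec, refl, bins, n_bins)
        comp_objs.append(ComponentCov(name, s2, cg, np.asarray(d, dtype=float)))
    dm_obj = None
    if dm is not None:
        s_dm, d_dm = dm
        dm_obj = DmCov(np.asarray(s_dm, dtype=float), np.asarray(d_dm, dtype=float))
    cov = CovarianceModel(bins, _bin_d(refl, bins, n_bins), sigma_n, comp_objs, dm_obj)
    cov.conditioners()  # fail fast on a bad assembly, naming the bin
    return cov


def _bin_d(refl: ReflectionSet, bins: np.ndarray, n_bins: int) -> np.ndarray:
    out = np.zeros(n_bins)
    for b in range(n_bins):
        m = bins == b
        out[b] = refl.d_spacing[m].mean() if m.any() else np.nan
    return out


def condition_on_models(cov: CovarianceModel, m: np.ndarray,
                        sig_plus: np.ndarray | None = None,
                        sig_minus: np.ndarray | None = None) -> ConditionalGaussian:
    """Condition the joint Gaussian on the model vector per reflection.

    ``m``: (N, k) complex model entries in the covariance's ordering
    (c1+, c1-bar, ..., F_dm).  Measurement variances (if given) are added to
    the conditional diagonal; they never enter the mean weights.
    """
    m = np.asarray(m, dtype=complex)
    n = len(cov.bins)
    if m.shape != (n, cov.model_dim):
        raise ValueError("model vector shape mismatch")
    ws, c0s = cov.conditioners()
    b = cov.bins
    mean = np.einsum("nij,nj->ni", ws[b], m)
    covar = c0s[b].copy()
    if sig_plus is not None:
        covar[:, 0, 0] += 2.0 * np.asarray(sig_plus) ** 2
    if sig_minus is not None:
        covar[:, 1, 1] += 2.0 * np.asarray(sig_minus) ** 2
    return ConditionalGaussian(mean, covar)


def estimate_luzzati_d(data, triple, cov: CovarianceModel, which: str = "model",
                       min_refl: int = 20) -> np.ndarray:
    """Per-bin maximum-likelihood Luzzati parameter for one component.

    Each bin's D maximizes the multivariate likelihood restricted to the
    bin's reflections, by bounded 1-D optimization on [0, 1] (for ``which ==
    'dm'`` on [0, 1)).  Bins with fewer than ``min_refl`` reflections keep
    their current value.  The returned estimates are also stored in ``cov``.
    """
    from scipy.optimize import minimize_scalar

    from .likelihood import loglik_dataset

    upper = 1.0 - 1e-6 if which == "dm" else 1.0
    current = (cov.dm.d if which == "dm" else cov.component(which).d).copy()
    est = current.copy()
    for b in range(cov.n_bins):
        mask = cov.bins == b
        if mask.sum() < min_refl:
            continue

        def neg(dval, _b=b, _mask=mask):
            vals = current.copy()
            vals[_b] = dval
            cov.set_d(which, vals)
            ll = loglik_dataset(data, triple, cov, subset=_mask)[0]
            return -ll

        res = minimize_scalar(neg, bounds=(0.0, upper), method="bounded",
                              options={"xatol": 2e-3})
        est[b] = float(np.clip(res.x, 0.0, upper))
        current[b] = est[b]
    cov.set_d(which, est)
    return est
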