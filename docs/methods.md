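# Methods

`anomlik` implements joint ("combined") MR-SAD phasing: a multivariate
likelihood of Bijvoet-pair amplitude observations conditional on a partial
protein model, an anomalous substructure and a density-modified map, with
log-likelihood-gradient substructure completion, solvent-flattening density
modification, and Blow–Crick phase combination.  Everything runs on a
synthetic micro-crystal testbed, so every component is verifiable against a
known ground truth without external diffraction data.

## The statistical model

Per Friedel-unique reflection h, the package works with the complex vector

    z = ( F_o+, conj(F_o-), F_c1+, conj(F_c1-), ..., F_dm )

— the observed pair, one or more model components c (partial protein model,
anomalous substructure, or a single combined model), and the
density-modified coefficient — under a zero-mean circular complex Gaussian
with a per-resolution-bin Hermitian covariance.  Conjugating every
minus-branch entry makes the f″→0 limit render plus/minus entries
*perfectly correlated* rather than anti-correlated, so all covariances are
ordinary Hermitian entries.  With a single model component plus the dm
stream this is the classical 5×5 structure-factor covariance of
(F_o⁺, F_o⁻, F_m⁺, F_m⁻, F_dm).

Per bin and model component c the covariance carries

* `S2_c = ⟨Σ_j occ_j² |g_j|² DW_j²⟩`, the component's scattering power,
  with `g_j = f0_j(s) + f′_j + i f″_j` and DW the Debye–Waller factor;
* `Cg_c = ⟨Σ_j occ_j² g_j² DW_j²⟩` (complex) — its imaginary part,
  `2 Σ f″ (f0+f′)`, carries the anomalous phase information;
* a refinable Luzzati parameter `D_c ∈ [0,1]` down-weighting the
  component's contribution according to its coordinate errors and bias.

Cross-branch structure (derived, not assumed): a coordinate error displaces
an atom identically in F(h) and F(−h), so its phase-error factors are
complex conjugates and they *cancel* in the inter-branch product.  The
observation cross term is therefore `⟨F_o⁺ conj(F_o⁻-bar)⟩ = Σ_all g²`,
independent of D.  After conditioning on the models the residual
inter-branch correlation is `SU + Σ_c (1−D_c²) Cg_c` (`SU` = unknown-atom
power, treated as non-anomalous so its `Σ g² = Σ |g|²`):

* large and real when the model is a small substructure — the source of
  the bimodal SAD phase posterior;
* exactly zero for a complete exact model (D = 1), where the pair
  likelihood collapses to two independent measurement-noise Rice
  densities; and
* each single-amplitude *marginal* is the acentric Luzzati Rice
  `Rice(A; D|F_m|, (1−D²)Σ_N + σ²)` at any D.

The last two bullets are the package's hard exact-limit tests (1e−8).
Note that for D < 1 the *pair* likelihood is not a product of independent
Rice terms: the shared content keeps the mates correlated, and that
correlation is precisely the SAD signal.  An alternative convention with
independent per-branch model errors makes the D < 1 pair factorize, but it
predicts spurious Bijvoet-difference variance ~(1−D²)S2 and drives the ML
Luzzati estimates to 1 on physically simulated data; it was measured and
rejected.

The density-modified map enters as a fifth variable with empirical power
per bin and a refinable Luzzati-like correlation `d_dm`; being derived from
a real map it correlates identically with both Friedel branches.  An
amplitude measurement error σ enters the complex diagonal as 2σ² — a
circular complex variance v has radial (amplitude) variance v/2, so
matching the stated amplitude error needs the factor of two.  (The
simulator adds Gaussian noise to amplitudes; the likelihood's complex-
noise embedding reproduces its variance exactly and its density to the
usual Rice-vs-Gaussian accuracy at the testbed's signal-to-noise.)  The full
covariance is assembled from an explicit latent-variable construction, so
it is positive semi-definite by construction; the f″→0 model block is
legitimately singular and is conditioned through a Hermitian pseudo-inverse.
Conditional variances are floored at `1e−12 Σ_N` (a degenerate-model guard;
a larger floor measurably contaminates the D = 1 Rice limit).

## Likelihood evaluation

Conditioning on the model entries leaves a bivariate complex Gaussian for
(F_o⁺, conj(F_o⁻)).  The unknown plus phase integrates analytically to a
modified-Bessel I₀ (Rice) factor; the minus-branch phase has no analytic
integral and is evaluated by the periodic trapezoid rule (64 uniform nodes
by default).  The trapezoid integrand is tempered by the log-I₀ factor and
converges to ~1e−12 per reflection at the testbed conditions; near the
degenerate perfect-model/low-noise corner the integrand sharpens and the
exact-limit tests use 1024 nodes.

The *phase posterior* over α_o⁺ reverses the order: at each α_o⁺ grid node
(360 by default in the pipelines) the minus phase is integrated
analytically — its exponent is `2 Re(e^{−iψ} u)` with
`u(φ) = A⁻ v₂ − A⁺A⁻ conj(P₁₂) e^{iφ}`, a circle integral equal to
`2π I₀(2|u|)`.  This matters: when the branches are nearly perfectly
correlated the ψ-integrand is ~1° wide and a gridded ψ integral at a few
hundred nodes collapses the posterior onto the midpoint of the two SAD
modes (verified against a 200 000-node brute-force integral).  FOM and the
centroid phase are the modulus and argument of the posterior's circular
mean; Blow–Crick coefficients are `m |F_o⁺| e^{iφ_best}`.
Hendrickson–Lattman coefficients are fitted to the log-posterior by linear
least squares for export only; internal phase information is always the
full gridded posterior.

Gradients of the log-likelihood with respect to every model structure
factor are analytic (differentiation under the quadrature): with
conditional precision P and posterior moments E[x], the gradient w.r.t. the
conditional mean is `P (E[x] − μ)`, chained through the conditioning
weights.  They match central finite differences to better than 1e−5
relative and drive both the LLG maps and parameter refinement.

## Parameter refinement

Alternating sweeps: substructure occupancies, B values and (optionally)
fractional coordinates jointly by bounded L-BFGS-B with analytic gradients;
then per-bin Luzzati D by bounded 1-D likelihood maximization.  Two
identifiability facts shape the defaults:

* substructure occupancies and the substructure D scale the same
  amplitudes; the pipelines therefore pin `D_substructure = 0.98` and let
  occupancies absorb scale, refining D only for the protein component and
  the dm stream;
* coordinates must be refined against a substructure-only covariance: with
  a biased partial protein model in the conditional mean, ML positions
  drift by several tenths of an Å to compensate the model's phase errors.
  The pure-SAD likelihood is in turn exactly invariant under a global P1
  origin translation, so the coordinate polish anchors that flat mode on
  the pre-existing atoms and restricts each sweep to a 0.75 Å trust region
  (the coordinate likelihood is multimodal with period ~d_min).

The per-bin ML estimator of D has the classic acentric-Rice score
degeneracy at small noncentrality: near D = 0 the first two derivatives of
the expected log-likelihood vanish and D is estimable only at an n^(−1/4)
rate.  Recovery against the analytic Luzzati factor exp(−2π²σ²/d²) is
therefore validated in resolution shells where the expected D stays in
[~0.45, 0.95], on a uniform random-gas crystal — the regime in which the
closed form holds at all; a chain-like structure adds low-resolution
envelope correlations that genuinely exceed the per-atom Luzzati factor.

## Substructure completion

While the substructure is empty, anomalous scatterers are bootstrapped from
the anomalous difference Fourier, coefficients
`(|F_o⁺|−|F_o⁻|) exp(i(φ_model − 90°))`, with partial-model phases.  Once
any anomalous atoms exist, log-likelihood-gradient (LLG) maps take over:
per-reflection gradients w.r.t. the substructure component, projected onto
the anomalous species' scattering factor and Fourier-synthesized.  Peaks
above 4.75σ (4.25σ in low-resolution mode) and farther than 2.5 Å from any
existing atom become trial atoms at occupancy 0.5 and a Wilson-like B; the
search excludes existing sites because an occupancy pinned at its bound
leaves residual gradient there.  After refinement, atoms with occupancy
below 0.2 are pruned.  Single-pass LLG maps at the testbed's anomalous
signal-to-noise (~1.5) contain noise and model-error peaks of comparable
height to real sites; it is the iterated detect–refine–prune loop that
separates them, and the completion contract is tested at that level.

## Density modification

Wang-style solvent mask: the local density variance is computed with a
periodic Gaussian (σ = radius/2, radius 4 Å default) and the
lowest-variance fraction of voxels becomes solvent, flattened to its own
mean (not zero).  One inner pass per combined cycle — more passes
over-flatten and measurably degrade map correlation.  The pipeline drivers
additionally histogram-match the protein region to a reference histogram
taken from an unrelated synthetic crystal at matching resolution (z-scored
rank mapping, so only the distribution shape transfers); `dm_cycle` itself
leaves matching off unless given a reference.  Amplitude conservation is
*not* imposed: `F_dm` re-enters the likelihood with its own refinable
`d_dm`, which is what decides how much the modified map is trusted.
Because the modified map is built from the same data it then informs, a
working-set ML fit of `d_dm` measures self-consistency rather than
predictive value and makes the phase posteriors overconfident (measured:
binned FOM exceeded the realized cos Δφ by ~0.2).  The drivers therefore
hold out a seeded ~12% cross-validation free set: a second, free-omitted
dm synthesis provides genuinely predictive entries at the free
reflections, `d_dm` is fitted on those alone (three coarse resolution
groups), and the full map is used for phasing with the honest weights.
With this scheme the binned FOM tracks cos Δφ to ~0.05.  The
solvent fraction is supplied by configuration (the synthetic scenario
records the true envelope fraction, the stand-in for a Matthews estimate).

## Pipelines

Both drivers start with refinement-and-substructure-completion cycles
(default 5), then iterate combined cycles (default 15): density
modification of the current best map, re-estimation of the error
parameters, phase posterior, new Blow–Crick coefficients; the best cycle by
total log-likelihood is reported.  "Substructure-only" discards the protein
model after completion — its first combined iteration is numerically the
pure-SAD code path — while "rebuilding" keeps the protein model as a
likelihood component whose refined per-bin D re-weights (and, for a wrong
model, suppresses) its contribution.  Chain rebuilding proper is out of
scope; the D-mediated re-weighting stands in for it, which is the one
deliberate reduction relative to a production pipeline.  Evaluation against
the synthetic truth reports F-weighted mean phase error, truth-map
correlation, and substructure recall/precision at 0.5 Å after a permitted
P1 origin translation and enantiomorph search.

## The synthetic testbed and its limits

The standard battery (`anomlik.scenarios`) is a 27×30×33 Å (β = 100°) P1
cell with a 200-atom C/N/O chain (self-avoiding walk, 3.8 Å steps — the
Cα virtual bond), 4 Se (f′ = −8, f″ = 3.8), data to 3.5 Å (~1290 Bijvoet
pairs), Gaussian noise at 4% of the bin-mean amplitude giving
|ΔF|/σ(ΔF) ≈ 1.4–2.3, and a starting model with 40% of protein atoms
omitted, the rest jittered to 1.5 Å r.m.s., and 2 of 4 Se missing.  These
are fixed study conditions chosen to mimic the weak-signal low-resolution
regime the method targets, scaled down so a full 20-seed battery runs in
minutes on one CPU.

What the testbed does *not* emulate: space-group symmetry (P1 only — no
centric reflections, no symmetry-related sites), bulk solvent scattering,
radiation damage, translational NCS, multi-crystal merging, anisotropic
displacement, and real protein folds (the likelihood only sees structure
factors, so chain realism beyond atomic clustering is unnecessary — but
low-resolution envelope statistics of real proteins are only coarsely
reproduced).  Passing tests demonstrate the correctness and internal
consistency of the statistical machinery under these conditions, not
performance on deposited diffraction data.

## Conventions and numerical choices

* Phases in degrees [0, 360); `F_minus` always means F(−h), not its
  conjugate; fractional coordinates; x fastest-varying map axis;
  ρ(x) = (1/V) Σ F(h) e^{−2πi h·x} with Friedel completion internal.
* Atomic f0(s) from the International Tables 4-Gaussian parameterization
  (via gemmi), `(sinθ/λ)² = 1/(4d²)`; f′/f″ supplied per element by
  configuration (PDB has no field for them).
* Σ_N per bin is estimated from the data (Wilson-style, measurement
  variance subtracted); exact-limit tests supply it from the known model
  composition, as the limits require.
* Amplitudes are floored at 1e−12 in log terms; negative simulated
  amplitude draws are truncated at zero and flagged (no French–Wilson
  treatment).
* Equal-population resolution binning in 1/d², 8 bins by default;
  per-bin constant error parameters (no spline smoothing).
* Stopping is by fixed cycle counts with the best cycle chosen by total
  log-likelihood, not by convergence detection.
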