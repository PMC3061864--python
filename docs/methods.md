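# Methods

This note documents the models implemented in `pulsedyn`, the choices made
where the design was genuinely open, and what the synthetic benchmarks do and
do not demonstrate.

## Kinetic model and solver

A connectivity scheme is a directed graph of species with first-order rate
constants; sinks may be other species or "loss" (decay out of the observed
system). The scheme defines the linear system dc/dt = K·c with
K[j,i] = k(i→j) off-diagonal and K[i,i] = −Σ outgoing rates. A rate constant
of exactly 0 encodes a long-lived ("infinite") component that does not decay
on the observed time base.

The default solution path diagonalises K and evaluates
c(t) = V·exp(Λt)·V⁻¹·c₀ vectorised over the time grid — exact up to round-off
and fast enough to sit inside a fitting loop. When V is ill-conditioned
(condition number above 1e8, e.g. an equal-rate sequential chain whose K is
defective) the solver falls back to a Padé matrix exponential per time point,
which handles defective matrices exactly; a confluent chain A→B→loss with
equal rates therefore reproduces c_B(t) = t·e^(−kt) without special-casing.
An LSODA integrator (`solver="ivp"`) is available as an independent
cross-check and for imported schemes; its relative tolerance defaults to
1e−6 and may be tightened to 1e−12.

SBML import is restricted to irreversible first-order mass action with one
reactant (reversible reactions are expanded into a forward/backward pair
using `kf`/`kr`); anything outside that subset raises an error naming the
offending reaction. Compartments and volumes are ignored by design.

## Instrument response and chirp

The IRF is a unit-area Gaussian parameterised by FWHM Δ, with
σ = Δ/(2√(2 ln 2)). The convolution with exp(−k(t−μ)) is evaluated in two
algebraically equivalent, overflow-safe branches around z = (kσ² − (t−μ))/(σ√2):
for z ≥ 0 as ½·erfcx(z)·e^(−u²) (both factors bounded) and for z < 0 as
½·erfc(z)·e^(k²σ²/2 − k(t−μ)) (the exponent is then provably negative). This
matters: the naive single-expression form produces inf·0 = NaN a few IRF
widths after time zero.

Chirp is modelled as μ(λ) = t₀ + Σ_{j=1..n} a_j (λ−λ_c)^j. The wavelength
offset is taken in the data's native channel units, unnormalised, and λ_c
defaults to the midpoint of the channel axis; the same convention is used in
simulation, estimation and fitting. Estimation locates each channel's onset
as the extremal time gradient of the trace — the discrete equivalent of the
maximum-gradient point of its cross-correlation with an instantaneous unit
step — with parabolic sub-grid refinement and ties broken towards the
earliest time, then least-squares fits the polynomial to the per-channel
onsets. All-zero channels are excluded with a warning. The onset of an
IRF-convolved decay sits at μ − O(kσ²), so recovery is guaranteed to one
grid step only while the IRF width is small against the fastest lifetime;
this is the regime the round-trip tests exercise.

## SVD and rank

`svd_decompose` wraps a thin SVD with a deterministic sign convention (the
largest-magnitude element of each right vector is made positive — the sign
itself is physically meaningless). `significant_rank` implements the visual
scree-gap rule as a formula: the smallest r with s_r/s_{r+1} ≥ gap_factor
(default 10) whose tail contains no further gap of that size; singular values
at the numerical floor (eps·s₁) are clamped before ratios so junk-level
fluctuation cannot masquerade as a gap. Pure white noise has no qualifying
gap and yields 0 with a warning — structureless data give no objective
component count, and the CLI always prints the scree for human confirmation.

## Variable-projection fitting

Rates (and optionally the IRF centre and width) are shared across channels;
spectra and per-channel offsets are linear and eliminated at every objective
evaluation by QR least squares. Two deliberate behaviours of the projection:

- a genuinely rank-deficient design (duplicated rates) warns and returns the
  minimum-norm solution, flagged on the result;
- a closed (mass-conserving) scheme makes the offset column an exact linear
  combination of the concentration columns (species sum to a constant). The
  offset is then unidentifiable, and the projection drops it in favour of the
  physical spectra rather than smearing amplitude across both.

Rates are fitted as log k, which enforces positivity and evens out the
conditioning between fast and slow components; bounds default to
[1e−12, 1e6] 1/time and a rate that ends at the lower bound is reported as
long-lived. The gradient engine is trust-region-reflective least squares
(ftol/xtol 1e−12); the pattern-search engine is a compass search with
initial mesh 25% of the log-parameter range, expansion 2, contraction 0.5,
stopping at mesh < 1e−6. Standard errors come from the linearised covariance
(JᵀJ)⁻¹·SS/dof at the optimum, mapped from log-space by the chain rule, and
lifetimes are reported sorted ascending with σ_τ = σ_k/k².

These standard errors assume independent residuals. The benchmark's noise
recipe (below) violates that assumption for full-matrix fits — the temporal
noise is coherent across all channels — so quoted lifetime uncertainties
should come from the SVD-trace fit (the first n left singular vectors), where
the error model is closer to honest; the package tests its 3-s.e. coverage
there.

With an IRF the concentration design becomes channel-dependent (each channel
has its own time zero), and the projection runs per channel; this path
requires a diagonalisable, non-oscillatory rate matrix.

Model comparison reports component count, sum of squares and relative
improvement, and flags compensating amplitudes: two spectra with one or more
shared channels of opposite sign where each exceeds 30% of that spectrum's
own maximum. On sequential-mechanism data fitted with a parallel model this
flags the fast/intermediate DAS pair (amplitude poured into one component and
subtracted from the other); the correct sequential fit, whose species spectra
are non-negative, raises nothing.

## Photoselection

All ensemble averages are over p = cos θ uniform on [0, 1] (isotropy plus
up/down symmetry). Every numeric factor of the saturation model lives in one
constants table (`photoselection.CONSTANTS`):

- linear absorber, f(p, x) = 1 − exp(−3xp²): the 3 normalises the
  orientational cross-section 3σcos²θ to σ over the isotropic ensemble;
- circular (in-plane degenerate) absorber, f = 1 − exp(−(3/2)x(1−p²));
- Gaussian peak photon density = ln 2 × the equal-energy top-hat value when
  the Gaussian FWHM equals the top-hat diameter (two-dimensional integral
  equality: N/(2πs²) vs N/(π D²/4) with s = D/(2√(2 ln 2))).

Excitation strength x = I·σ·Φ with σ in cm²/molecule and the photon flux I
in photons/cm² (energy / (hc/λ) / beam area); SI beam dimensions are
converted internally. The reference working point used throughout the tests
is a phytochrome-style experiment (1.65 µJ, 640 nm, 120 µm beam,
σ = 1.08e−16 cm², Φ = 0.1), giving x ≈ 0.51 — consistent with roughly five
times that power saturating the favourable orientations.

Closed forms via erf are used for ⟨f⟩ and ⟨f·P₂⟩ (with small-argument series
to avoid cancellation); the `quadrature` method paths integrate adaptively
and agree with the closed forms to better than 1e−10. The `taylor` method
sums the analytic power series — coefficients from term-wise integration,
with the quotient series for r_opt = ⟨fP₂⟩/⟨f⟩ built by the Cauchy rule
(leading terms 2/5 − (27/175)x + (57/1750)x²) — to machine convergence by
default within a documented radius x ≤ 1, warning and falling back to
quadrature beyond. A three-term truncation (`order=3`) reproduces the
familiar low-power approximation but is only good to ~3e−5 at x = 0.1, which
is why the default sums the series fully.

The measured anisotropy is r = (ΔA∥ − ΔA⊥)/(ΔA∥ + 2ΔA⊥) with magic-angle
signal (ΔA∥ + 2ΔA⊥)/3; the dipole angle is the principal solution of
r = r_opt·P₂(cos β) in [0°, 90°] (the cos² degeneracy makes ±β and 180°−β
indistinguishable). For degenerate in-plane transitions probed by a linear
one at angle α from the plane, r(α) = (3cos²α − 2)/10, spanning 0.1 (in
plane) to −0.2 (perpendicular), rotational relaxation ignored.

The pump/probe beam-ratio correction is the probe-weighted average of the
pump profile along a transverse axis of the product of the two centred
Gaussians, R/√(1+R²). Depth averaging attenuates the pump flux decadically,
x(z) = x₀·10^(−A·z/d), and averages the local anisotropy weighted by the
local photolysed fraction (polarised signals add in proportion to the locally
excited population): r̄ = ∫⟨fP₂⟩dz / ∫⟨f⟩dz. The depth integral uses uniform
slicing with composite-Simpson weights; the default 200 layers agree with a
10⁴-layer reference to better than 1e−6 for A ≤ 2.

Two-pulse experiments compose per orientation first and average second — the
pulse-II ground state is not isotropic, so the order matters. With
ground-state recovery G, f_II(p) = [1 − (1−G)f₁(p)]·(1 − e^(−3x₂p²)); the
ensemble average reduces to G·F(x₂) + (1−G)(F(x₁+x₂) − F(x₁)) with F the
single-pulse closed form, which makes the two printed identities exact: G = 1
returns the single-pulse expressions, and a zero-delay equal-power pair
equals one pulse at doubled power. The pulse-II anisotropy
r_II = ⟨f_II·P₂⟩/⟨f_II⟩ can drop below the single-pulse bound of −0.2 at
strong first-pulse bleach with little recovery — pulse II then addresses a
hole-burned, perpendicular-leaning distribution and the bound is the Legendre
extreme −0.5 instead; the property tests encode that wider bound.

Pure-intermediate extraction models the pump-dump-probe matrix as
S_pdp = S_pp + w_gs·S_dp + w_int·I, where w_gs = ⟨f_II⟩/F(x₂) rescales the
dump-probe ground-state response to the actual pulse-II excitation and
w_int = (1−G)·F(x₁) is the pumped population still in the transient phase at
the dump. Solving for I gives the intermediate-only signal ready for global
fitting. The synthetic generator builds S_pdp by the same linear model, so
extraction inverts it exactly; validity assumes no rotational diffusion
between pulses and no pulse-II resonance with higher excited states.

## Synthetic benchmark

The reference dataset is a sequential three-species scheme with lifetimes
1.87 s and 34.8 s feeding a long-lived product, sampled at 91 logarithmic
delays from 0.1 s to 300 s over 100 channels. The spectra are fixed sums of
Gaussian bands chosen once, with strong overlap near pixel 50 so that model
mismatch shows up as compensating amplitudes there. Noise (when enabled, 10%)
is white, added to each basis spectrum at 10% of that spectrum's maximum and
to each concentration profile at 10% of that profile's maximum, before the
factors are multiplied.

Consequences worth knowing:

- the noiseless matrix is an exact rank-3 product, so its fourth singular
  value sits at the float floor (≲1e−15 relative) — far below the 1e−8
  solver-precision floor a numerically integrated construction would show;
- the noisy matrix is also exactly rank 3 (a product of rank-3 factors), and
  its temporal noise is coherent across channels. Full-matrix fits therefore
  chase that shared structure: point estimates shift by several nominal
  standard errors, and an extra (fourth) exponential component buys a
  one-to-several-percent sum-of-squares improvement by partially absorbing
  the noise traces. The qualitative model-selection signal survives — adding
  the third component gains more than two-fold, the fourth gains a couple of
  percent at most — but the fourth-component gain does not shrink below 1%
  under this noise model;
- none of this emulates detector-specific artefacts (pointing jumps, 1/f
  drift, wavelength-correlated noise), so passing tests demonstrate correct
  mathematics and a sound workflow, not robustness to every real-world
  pathology.

## Problem sizes and tolerances

Default test and acceptance runs use the 91×100 benchmark, 25 noisy repeats
for the stochastic statistics, 51 channels × 241 delays for chirp round
trips, and 200 depth layers — all chosen so the full suite completes in well
under a minute on one core while leaving each check's numerical margin
(1e−6 to 1e−10, as stated per test) comfortably wide. Solver tolerances are
user-raisable to 1e−12 throughout.
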