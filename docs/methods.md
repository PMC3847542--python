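# Methods

## Model

A single symmetric EPR line broadened by dipole–dipole interaction between
randomly distributed electron spins takes one of three limiting shapes,
depending on spin concentration and on the dimensionality d of the spatial
distribution:

* **Gaussian** (high concentration, or unresolved hyperfine broadening).
  The recorded derivative is F_G(u) = −A_pp·u·exp(½ − 2u²),
  u = (B − B_res)/ΔB_pp, with extrema ±A_pp/2 at u = ∓½.
* **Lorentzian** (dilute, d = 3):
  F₃(u) = −(16/9)·A_pp·u/(1 + (4/3)u²)², equivalently
  −A_pp·ΔB_pp³·(B − B_res)/((¾)ΔB_pp² + (B − B_res)²)².
* **Stretched Lorentzian** (dilute, d = 1 or 2).  The transverse
  magnetization after an ideal pulse decays as G(d, t) = exp(−a·t^(d/3)),
  with a proportional to spin concentration.  The absorption is the Fourier
  transform of G and the recorded derivative line is

      F_d(δ) = ℜ ∫₀^∞ G(d,t)·(−i·t·κ)·e^(−i·δ·t·κ) dt
             = −κ ∫₀^∞ t·G(d,t)·sin(κδt) dt,

  δ = B − B_res, κ = gβ/ħ.  For d = 3 this closes to the Lorentzian above
  (the quadrature oracle); for d < 3 it is evaluated numerically and its
  wings decay more slowly than u⁻³.

Exchange interaction (very concentrated spin systems), hyperfine structure,
anisotropy and Voigt profiles are outside the model, as is non-integer d.

Two conventions are deliberate simplifications, possible because R₁₀ depends
on shape only: the prefactor of G is unity (amplitude is removed by
normalization), and κ defaults to 1 (it rescales the field axis, also
removed).  Tests assert that the final normalized shape is independent of a.

## The Benc transform and R₁₀

With the measured (A_pp, ΔB_pp, B_res), each side of the line maps to
x = u², y = √(−A_pp·u/F).  This is the unique form of that family under
which the Lorentzian image is exactly f_L(x) = x + ¾ and the Gaussian image
exp(x − ¼) — both anchors are verified to 1e−6 in the tests.  Points where F
vanishes (|F| < 1e−12·A_pp) or where noise flips the sign of F (negative
radicand) are dropped, not clipped, and reported via `n_dropped`; the sample
at B = B_res itself always drops.  Left-side points are reversed so x
ascends; no interpolation onto a uniform x grid is performed.

R₁₀ = (1/10)·Σ [y(xᵢ) − f_L(xᵢ)]·(xᵢ₊₁ − xᵢ), summed over consecutive
retained points whose right endpoint lies strictly below the cap x = 10, and
averaged over the two sides.  The top-left rectangle rule is the defining
computation (it reproduces the original manual procedure); a higher-order
rule on the same points serves only as a convergence oracle in tests.  The
cap exists because the integral may diverge as x → ∞ and real spectra are
noise-dominated beyond; when a spectrum does not reach x = 10 the sum is
still normalized by 10 and the shortfall is surfaced as `x_max_used` plus a
warning, never absorbed silently.

On dense grids the rectangle rule converges to R₁₀ = −1.862 (d = 2) and
−2.978 (d = 1); the 4096-point default grids used throughout report −1.856
and −2.969.  Values commonly quoted for these regimes from coarser,
manually-processed data are a few hundredths closer to zero, consistent with
the O(h) bias of the rectangle rule; the package reports what its own
integration actually produces.

## Numerical choices

* **Fourier quadrature.**  The time integral is truncated where
  G < 1e−10, i.e. t_max = (ln 10¹⁰/a)^(3/d) (≈ 23 for d = 3, ≈ 1.2·10⁴ for
  d = 1); passing a smaller t_max raises an error with the cutoff
  diagnostic.  The default path evaluates each field point with scipy's
  adaptive oscillatory (Fourier-weight) quadrature, which handles the slowly
  decaying d = 1 tail at machine accuracy; a log-spaced trapezoid path is
  retained (`method="trapezoid"`) and cross-checked against it to 1e−6.
  The d = 3 result matches the analytic Lorentzian to ~1e−8, far inside the
  1% oracle tolerance.
* **Simulation grids.**  `simulate_stretched_lorentzian` builds an exactly
  antisymmetric uniform grid spanning |u| ≤ √x_max·1.05 (default x_max 10,
  n = 4096), so the output is antisymmetric to quadrature tolerance and the
  Benc abscissa reaches the integration cap with margin.  The raw curve is
  rescaled to the requested (A_pp, ΔB_pp, B_res) using its continuum
  extremum located by root polishing; `normalize_lineshape` provides the
  same affine rescaling for arbitrary curves via the grid-measured
  parameters.
* **Baseline.**  Degree-3 polynomial, least squares on the first and last
  `tail_fraction` (default 10%, each tail ≥ 4 points) of the sweep, fitted
  in a scaled variable for conditioning and stored in the raw field basis.
  The sweep should be wide relative to the line: Lorentzian wings decay only
  as u⁻³, and tails at |u| ≈ 4 still hold ~2% of A_pp, which biases the fit.
* **Parameter extraction.**  Global argmax/argmin of the ordinates, no
  smoothing, first occurrence winning ties; maximum must precede minimum.
  B_res is the midpoint of the two consecutive fields bracketing the zero
  crossing between the extrema (an exact-zero sample is its own candidate);
  with several noise-induced crossings the one nearest the midpoint of the
  extrema fields wins.  The extrema search spans the full corrected
  spectrum.
* **Tie-breaks and degenerate inputs** are deterministic throughout;
  spectra are validated (equal lengths, strictly increasing field, finite
  values) and never silently re-sorted.

## Monte Carlo error propagation

Stage 1 clones the corrected spectrum `n_iterations` (default 1000) times,
perturbing every ordinate by N(yᵢ, max(√|yᵢ|, noise_floor)) — the
Poisson-counting noise model customary for EPR absorption measurements,
extended with |·| because derivative ordinates are signed — and re-extracts
the parameters per clone.  Failed clones are redrawn (the sample count
always equals `n_iterations`); more than 10% failures aborts.  Stage 2 draws
parameter triples from independent normals with the stage-1 means/sds and
recomputes R₁₀ on the fixed spectrum.  Normality of every distribution is
reported (D'Agostino–Pearson plus histogram counts) but never enforced.
All randomness derives from `MCConfig.seed` with separated substreams, so
identical inputs give bit-identical reports.  Clones are not re-baselined;
the alternative (refit per clone) would fold baseline uncertainty into the
parameter spread and is left out to match the staged procedure.

**Known bias.**  Because extraction takes the raw global extrema, the
amplitude of a noisy clone is the maximum over the effectively-tied samples
near each peak: an extreme-value draw, biased upward by ~2–3 per-point noise
sds while the MC spread of A_pp is smaller than one.  A_pp is therefore
accurate to a couple of percent but *not* unbiased at the 3-sd level on
dense grids, at any signal level (the bias/sd ratio is amplitude-
independent under the √|y| model).  ΔB_pp and B_res are position estimates
with locally symmetric noise and show no such bias.  At high SNR, B_res can
be exactly degenerate (the zero crossing never leaves one grid interval);
this is flagged rather than tested for normality.

## Synthetic data

Real kerogen spectra are not redistributable at test scale, so all test
inputs come from `synthetic_fixtures`: a model line, a cubic background and
constant-sd i.i.d. Gaussian noise on a uniform grid (default 4096 points
over |u| ≤ 4, line at B_res = 3480 G with ΔB_pp = 4 G), written in the same
text dialect with a metadata-bearing filename.  The constant noise is
deliberate — it lets the √|y| assumption of the Monte Carlo be tested as a
model rather than baked into the data.  What the fixtures do not emulate:
field-sweep nonlinearity, saturation, modulation broadening, multi-line
spectra, drift between scans.  Passing tests therefore demonstrate
correctness of the algorithmic chain under the stated noise model, not
robustness to every instrumental artifact.

## Problem sizes

Defaults were chosen so the full suite and the benchmark script each run in
well under a minute on one core: 4096-point simulation grids (doubling them
changes R₁₀ by < 0.01), 120–300 Monte Carlo iterations in tests versus the
1000 default in production use.
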