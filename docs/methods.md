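# Methods

This note documents the statistical model behind `magbird`, the choices
made where the design was genuinely open, the numerical details, and what
the synthetic-data validation does and does not establish.

## The analysis question and its data model

Given timed geographic fixes of a migrating bird, the response variable is
the circular series of per-segment travel directions, and the covariates
are the local geomagnetic declination D and inclination I (or their
changes along the route). The pipeline asks, per species:

1. are the directions compatible with a von Mises law (Watson U²)?
2. do they correlate with a magnetic covariate (circular correlation and
   its asymptotic test of H₀: ρ_c = 0)?
3. how well does a circular-circular regression of directions on the
   covariate fit (circular association ρ between observed and fitted
   directions)?

### Direction extraction

The central angle between fixes is the spherical law of cosines,
evaluated in haversine form (identical analytically, far better
conditioned at small separations — repeated fixes give exactly zero,
which the degenerate-segment filter relies on). A central angle, however,
is a *distance*, not a direction; to obtain a circular direction per
segment the package uses the standard forward azimuth (initial
great-circle bearing, clockwise from north)

    atan2( sin ΔL cos φ_B , cos φ_A sin φ_B − sin φ_A cos φ_B cos ΔL ),

with ΔL wrapped to (−π, π] so antimeridian crossings take the short way.
Per-segment bearings are the default "direction change" (each segment has
a well-defined circular direction); the turn angle (wrapped difference of
consecutive bearings) is available as `mode="turn_angle"`. Geometry is on
the unit sphere — angles do not depend on the radius and tracking data
carry no usable altitude — and no ellipsoidal correction is applied.
Bearings are undefined at the exact poles and for coincident points
(central angle < 1e−12 rad); both raise typed errors.

### Geomagnetic covariates

The main field is synthesized from Gauss coefficients g_n^m, h_n^m (nT)
with Schmidt semi-normalized associated Legendre functions (no
Condon–Shortley phase), reference radius a = 6 371 200 m, and linear
(optionally quadratic) secular variation about the file epoch. The
components follow the standard spherical-harmonic synthesis

    X = −Σ (a/r)^{n+2} Σ_m (g cos mλ + h sin mλ) dP̆/dφ
    Y = (1/cos φ) Σ (a/r)^{n+2} Σ_m m (g sin mλ − h cos mλ) P̆
    Z = −Σ (n+1)(a/r)^{n+2} Σ_m (g cos mλ + h sin mλ) P̆

with D = atan2(Y, X), I = atan2(Z, √(X²+Y²)). Two deliberate
simplifications: latitudes are treated as geocentric on the sphere r = a
(no geodetic conversion; altitude 0), and only the internal main field is
modeled — no crustal biases or external fields, and no fitting of
coefficients to observations. The truncation degree defaults to the
coefficient file's own n_max (12 for standard main-field files).

The Legendre functions are computed by a stable three-term recursion
directly in the Schmidt-normalized values, with derivatives taken with
respect to latitude; the factorial (closed-form) formula is retained only
as a test oracle, since it loses accuracy at high degree.

Covariates come in two modes. `point` evaluates D or I at each segment's
anchor fix and time; `delta` (the pipeline default, since the hypothesis
concerns field *changes*) takes the wrapped change of the angle from the
segment's start fix to its end fix, which telescopes to zero around a
closed loop in a static field. Both are reported in radians internally;
degrees appear only at I/O boundaries.

### von Mises machinery

Density f(θ; μ, κ) = e^{κ cos(θ−μ)} / (2π I₀(κ)); κ = 0 is the circular
uniform. The cdf uses the Fourier–Bessel series of the antiderivative,

    F(θ) = A(θ) − A(0),
    A(θ) = (1/2π) [ θ + (2/I₀(κ)) Σ_p I_p(κ) sin(p(θ−μ)) / p ],

anchored at 0 so that F(0) = 0 and F(2π) = 1, truncated when the term
bound 2I_p/(p I₀) drops below 1e−14. Internally all Bessel evaluations
use exponentially scaled routines so density, cdf and MLE stay finite at
very large κ; the plain power series Σ_r (κ/2)^{2r+p} / (r!(r+p)!) is
exposed separately because several oracle checks are stated in terms of
it. Sampling is Best–Fisher rejection sampling via numpy's generator.

The MLE sets μ̂ to the circular mean and solves A₁(κ̂) = R̄ (the Bessel
ratio I₁/I₀ equals the mean resultant length) by a safeguarded Newton
iteration polished to ~1e−10, capped at κ = 1e4 — beyond the cap A₁ is
within 5e−5 of 1 and the data are numerically degenerate (e.g. all angles
equal). A zero resultant (R̄ < 1e−12) leaves the mean direction, and
hence the fit, undefined and raises.

### Watson U²

With order statistics U_(1) ≤ … ≤ U_(n) of the probability-integral
transforms U_i = F₀(θ_i),

    U² = Σ_i [ (U_(i) − (2i−1)/(2n)) − (Ū − ½) ]² + 1/(12n),

the rotation-invariant Cramér–von Mises-type statistic; its minimum
1/(12n) is attained exactly at the midpoints, which the tests use as an
analytic identity. Ties are kept (stable sort, no jitter). Two variants:
`uniformity` (F₀ uniform) and `vonmises_estimated` (F₀ the von Mises cdf
at the sample MLE). Critical values are *computed*, not tabulated: plain
Monte Carlo for uniformity, and a parametric bootstrap for the estimated
variant (simulate from the fitted law, re-estimate parameters in each
replicate, take the 1−α quantile of the resulting statistics). This
keeps the test honest about the estimated-parameter effect without
committing to any published table, at the price of a seeded Monte-Carlo
step; the bootstrap loop is vectorized row-wise so a 500-replicate
critical value at n = 100 costs ~30 ms.

### Circular correlation and its test

The sine-moment correlation

    r = Σ sin(θᵢ−θ̄) sin(Mᵢ−M̄) / √(Σ sin²(θᵢ−θ̄) Σ sin²(Mᵢ−M̄))

is invariant to each variable's zero direction. The test studentizes by
the sample sine moments λ̂_ij = mean(sin^i(θ−θ̄) sin^j(M−M̄)):
z = √(n λ̂₂₀ λ̂₀₂ / λ̂₂₂) · r is asymptotically standard normal under
independence; p-values are two-sided. The implementation warns below
n = 25 and the pipeline's default minimum of 30 segments per species
keeps the asymptotics defensible. Rather than trusting the constant
structure of the studentization, its calibration is verified by
simulation: the empirical type-I error at α = 0.05 (n = 200, 2000
replicates) sits within ±0.02 of nominal. No multiple-testing correction
is applied across species or covariates; all tests are two-sided. A
series with (numerically) no dispersion about its mean — e.g. declination
under an axial dipole, which is identically zero — raises a typed error
that the pipeline records as a per-covariate skip reason rather than a
failure.

### Circular-circular regression

The conditional expectation of the unit response vector,
E[e^{iβ}|α] = g₁(α) + i g₂(α), is approximated by degree-m trigonometric
polynomials and fitted by two ordinary least-squares problems (for cos β
and sin β) on the shared design [1, cos α, sin α, …, cos mα, sin mα];
the identically-zero sin(0·α) column is dropped. The error vector
(ε₁, ε₂) has its 2×2 cross-moment matrix Σ stored as the residual
dispersion; predictions are the quadrant-aware β̂ = atan2(g₂, g₁). No
weighting or robust loss: two homoscedastic linear models on one design.

Degree m defaults to 1 — the smallest model in which a covariate shift
acts like a rotation — and can be chosen by `select_degree`, which
minimizes mean squared residual of both models plus a BIC-like penalty
2(2m+1) ln(n)/n per model with ties to the smaller degree. The penalty is
on the mean-residual scale (residuals of sines/cosines are bounded by 1),
which simulation shows is consistent: degree-1 data select m = 1 in
≥ 90% of seeds at n = 300, and noiseless degree-2 data always select 2.

The scalar fit summary per covariate ("ρ") is the circular correlation
between observed and fitted response directions — 1 for a noiseless
deterministic relation, ≈ 0 for independence. One known property of the
chord-space least squares: when β = μ(α) + von Mises(0, κ) noise, the
population coefficients are attenuated by A₁(κ) relative to the
noise-free ones (E cos ε = A₁(κ)); at κ = 5 this is ≈ 0.893, and the
recovery check below accounts for it implicitly by its tolerance.

## Synthetic data: what it emulates, what it does not

The generator produces the study conditions under which the method stack
is validated. Headings are i.i.d. von Mises(μ, κ) — or, in the coupled
variant, von Mises(μ + c·M, κ) where M is the local covariate angle (its
value or per-step change) and c ∈ [0, 1] the planted coupling — and each
fix advances along the great circle at the drawn azimuth by a fixed
central angle (spherical dead-reckoning), so the geodesy module's bearing
extraction inverts the construction to floating-point accuracy.
Defaults: 500 fixes, 0.002 rad (~13 km) steps, κ = 4, northward μ,
starting at 10°N — a plausible northward spring migration leg that stays
clear of the pole. Coefficient sets are either an Earth-like axial dipole
(g₁⁰ = −30 000 nT, giving the closed-form identities D ≡ 0 and
tan I = 2 tan φ) or a randomized multipole with degree spectrum decaying
as 30 000·(0.3)^n nT, roughly mimicking the real main-field spectrum at
low degree. Seeding: one master seed, child generators spawned via
`SeedSequence`, per-species streams keyed by a hash of the species name
so results are invariant to input ordering.

Deliberately *not* modeled: stopovers, wind drift, diel cycles,
per-individual heterogeneity, measurement error in fixes, and temporal
field change during a track (synthetic fields are static). Passing the
validation therefore shows the estimators and tests recover known signal
under the stated generative model — it does not certify behavior on real
tracking data, whose autocorrelation and heterogeneity violate the
i.i.d.-heading assumption to an unknown degree.

## Validation problem sizes

The acceptance script and test suite recompute, from scratch:

* dipole identities on a 181-point latitude grid (|error| ~1e−13);
* field-vs-potential-gradient consistency at 100 random points for a
  degree-8 randomized set (relative error ~1e−10 against 1e−5 required);
* the Watson midpoint identity at n = 10 (exact);
* von Mises density normalization (quadrature, 1e−10) for
  κ ∈ {0, 0.5, 2, 10, 50} and MLE recovery of (μ = 1, κ = 2) over 200
  replicates of n = 2000;
* type-I error of the correlation test (n = 200, 2000 replicates) and of
  the estimated-parameter Watson variant (1000 outer replicates × 500
  bootstrap draws at n = 100, κ = 2), both within ±0.02 of 0.05;
* degree-1 regression coefficient recovery (median RMSE over 100 seeds of
  n = 500 at κ = 5; observed ≈ 0.065 against 0.1 required) and exact
  recovery on noiseless data;
* full-pipeline planted-signal recovery: coupling 0.8 at n = 500 yields
  the planted positive correlation sign with significance in ≥ 95/100
  seeds, and coupling 0 stays non-significant in ≈ 95% of seeds;
* byte-identical JSON from rerunning `analyze` with the same seed.

## Known limitations

* Spherical (not ellipsoidal) geodesy and geocentric-on-sphere field
  evaluation introduce sub-degree angular discrepancies relative to a
  full WMM implementation at altitude; a config hook for an ellipsoid is
  a natural extension.
* Bootstrap critical values make Watson decisions Monte-Carlo-seeded;
  rerunning with a different master seed can flip marginal decisions.
* The correlation test is asymptotic; with fewer than ~30 segments per
  species its level is not guaranteed (hence the pipeline's skip
  threshold).
* Tracks are treated as a single sequence per species; individuals are
  not modeled separately.
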