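# Methods

## Model and scope

The package works with centered, homogeneous, isotropic complex Gaussian
random fields on the plane — the standard idealization of an
orientation-preference map at the earliest developmental stage, with
orientation `½·arg z` and pinwheels at zeros of `z`.  Invariance reduces the
model to a probability measure `P` on radial wavenumbers; everything
computed here (wavelength statistics, crossing counts along lines, pinwheel
densities, exact crossing variance) is a functional of `P`.  Non-Gaussian
mature-map ensembles, anisotropic or non-centered covariances, and the
estimation of `P` from experimental correlation data are out of scope.

## Spectral measures

Two families are implemented: finite atom sets `{(Rᵢ, wᵢ)}` and uniform
densities on an annulus `[r_lo, r_hi]`.  Moments of orders 0–2 use closed
forms; annuli are discretized, for every downstream oscillatory integral, by
a fixed Gauss–Legendre rule (default 2049 nodes on the support) so results
are deterministic given the configuration.  Weight renormalization is
silent, but an all-zero weight vector is an error.  The 2N+1-ring family
`R_mean + hw·i/N` with equal weights converges to the uniform annulus
`[R_mean − hw, R_mean + hw]`; because both endpoints carry full weight the
moment error is O(1/N) (an endpoint-weighted Riemann sum), not O(1/N²).

### The thin-annulus gap bound

For measures supported in `[a, b]`, `k²` is convex, so at any fixed first
moment the second moment is maximized by a two-point measure at the
endpoints; the worst-case ratio `Λ_mean/Λ_sq` therefore reduces to a
one-dimensional optimization over the endpoint weight, with the closed-form
stationary point `p = b/(a+b)` giving `Λ_mean/Λ_sq = (a+b)/(2√(ab))`.  The
implementation optimizes numerically and cross-checks on a weight grid; the
closed form is kept as an independent test oracle.  "Width a fifth of its
radius" is read against the *central* radius (`[1−w/2, 1+w/2]`), which is
the conservative (larger) worst case — 0.504 % at `w = 1/5`; the
inner-radius reading (0.416 %) is computed and reported alongside.

## Covariance conventions

The line-restricted covariance is `G(τ) = s·∫ J₀(Rτ) dP(R)` with `s = 1`
("unit" normalization, `G(0)=1`) or `s = ½` ("paper" normalization, the
covariance of the real part of a field with `E|z|² = 1`).  Both exist
because the literature mixes them: the two-point variance matrix presumes a
unit-variance process while the real-part process carries variance ½.  All
counting statistics are scale-invariant, so the package's canonical internal
convention is unit normalization, with paper normalization as a reporting
option (`−G″(0) = π²/Λ_sq²` holds in the latter).  Derivatives are analytic
(`J₀′ = −J₁`, `J₁′(x) = J₀(x) − J₁(x)/x`), never finite differences; the
`τ→0` limit of `G″` is evaluated explicitly as `−s·∫R²dP/2`.

## Crossing statistics

### Expectation: two candidates, simulation decides

For the zeros of the projection `Re(e^{−2iθ₀}z)` along a segment, the
Kac–Rice formula gives `E[N] = (ℓ/π)·√(λ₂/λ₀) = √2·ℓ/Λ_sq`.  The value
`ℓ/Λ_sq` — one repetition per column spacing — circulates in the literature
but follows only from mixing `λ₀ = 1` with the half-variance `λ₂`; the two
cannot hold simultaneously for one process.  Both candidates are exposed
(`mode="kac-rice"` and `mode="paper"`), and the Monte Carlo ensembles select
the Kac–Rice value decisively (empirical rate × Λ_sq = 1.414 within half a
percent across spectra).  Note the counting convention: zeros of the
projection carry `arg z = 2θ₀ ± π/2`, i.e. two orientation values per cycle;
a strict single-orientation count (roots with positive conjugate component,
half the projection count on average) is offered separately, and neither is
asserted to be "the" definition — the constants for one convention convert
to the other by a factor 2.

### Variance: the two-point integral

The exact variance uses the 4×4 covariance of `(X(0), X(τ), X′(0), X′(τ))`
for the unit-variance line process.  Its (3,3) and (3,4) cofactors reduce to

    M33 = λ₂(1−G²) − G′²,      M34 = G″(1−G²) + G·G′²,

(verified against generic determinant expansion to 1e-12), and the pair
intensity of zeros is

    μ(τ) = [√(M33²−M34²) + M34·arctan(M34/√(M33²−M34²))] / (π²(1−G²)^{3/2}).

The variance is assembled as `V = E[N] − E[N]² + 2∫₀^ℓ (ℓ−τ) μ(τ) dτ` — the
standard factorial-moment decomposition ("corrected" mode).  An "as-printed"
mode replaces the leading terms with `πℓ/Λ_sq − (πℓ/Λ_sq)²`, a published
variant that is dimensionally a count but goes strongly negative for
`ℓ ≳ Λ_sq/2` (≈ −185 at `ℓ = 5Λ_sq`, monochromatic); it is retained
unclipped, flagged in the diagnostics, and excluded by the Monte Carlo
arbitration, which matches the corrected mode within one standard error
(2.924 predicted vs 2.924 ± 0.039 measured at `ℓ = 5Λ_sq`, n = 10⁴ fields).

Numerics: the integrand is evaluated on composite Gauss–Legendre panels no
longer than `Λ_sq/8` (order 16), starting at `τ_min = 10⁻⁴·Λ_sq`.  Zeros of
a smooth Gaussian process repel, so `μ(τ) ∝ τ` near zero; the `[0, τ_min]`
tail is added from that linear model and its deviation goes into the error
budget, together with a re-evaluation at doubled panel density.  Both
cofactors vanish like `τ⁴` while being assembled from O(τ²) terms, so the
discriminant `M33²−M34²` is clipped at zero when within floating noise of
the *pre-cancellation* magnitude `(λ₂(1−G²)+G′²)²`; a violation beyond that
tolerance raises.  Replicate evaluations at perturbed settings (panels
`Λ_sq/12`, order 24, 1025 annulus nodes) agree to ~1e-9 relative.

### Pinwheel density

`E[#zeros in A] = π|A|/Λ_sq²` for every `P`; the package treats this theorem
as ground truth (it reduces to the classic monochromatic random-wave density
`R²/4π`) and the identity `η·Λ_sq² = π` is asserted exactly.  The variance
of the pinwheel count is deliberately not computed.

## Field synthesis

`z(x) = Σⱼ aⱼ e^{i kⱼ·x}` with `aⱼ` i.i.d. circular complex Gaussian of
variance `1/n` (so `E|z|² = 1` and the field is centered by construction).
Radii are stratified: atoms receive wave blocks by largest remainder,
annuli the mid-quantiles; directions sit at regular n-gon vertices plus one
uniform random global rotation.  Compared with i.i.d. wave vectors this has
an exactly known spectrum at finite n and lower Monte Carlo variance; the
deviation from true Gaussianity vanishes as n grows and is not detectable in
any statistic used here at the default n = 256 (a 100-wave preset mirrors
the classic demonstration figure).  One finite-n artifact worth knowing:
opposite-direction wave pairs leave a spatially constant component in `z²`
of magnitude ~n^{-1/2} per realization, so the Re/Im variance split
fluctuates at that scale realization by realization (ensemble means are
exact).  Grids must resolve `Λ_sq/12`; segments `Λ_sq/50` (default 64
samples per wavelength).  Synthesis is deterministic given seed, and grid
rows coincide with segment samples bit-for-bit under the same seed.

## Empirical statistics

Crossing counts localize sign changes of the projection by linear
interpolation, with half-open endpoints (a root at the start counts, at the
end does not; an exact-zero sample belongs to the following interval).
Pinwheels are detected by plaquette winding (four phase increments wrapped
to `(−π, π]`; totals of ±2π give charge ±1); an increment at exactly π is
re-evaluated on a locally refined subgrid using the sample's stored wave
decomposition.  Densities use the area actually tiled by the counted
plaquettes rather than the nominal window area — window edges cut plaquette
rows differently at different resolutions, and the nominal area biases the
density by several percent.  The default counting window trims one `Λ_sq`
margin to suppress boundary effects.  Fourfold grid refinement moves the
ensemble density by well under 2 %; individual near-coincident zero pairs
can still blur across one coarse plaquette (observed for ~0.4 % of
detections at `Λ_sq/12`).

## Experiment defaults and the probe length

The variance experiments default to uniform annuli centered at wavenumber
10.95 (an arbitrary unit), widths 0–30 % of the center in 2.5 % steps, the
2N+1-ring family with half-width 0.95, and a probe of length `ℓ = Λ_sq` —
one column spacing, i.e. the side of one hypercolumn, which is the natural
scale for asking how variable hypercolumn content is.  This choice matters
more than it may appear: the *ordering* of variances across spectra depends
on `ℓ`.  For short probes (`ℓ ≲ 2Λ_sq`) the normalized variance is minimal
for the monochromatic field, rises monotonically with annulus width (with a
flat slope at zero width), and decreases along the ring family toward the
annulus limit.  For long probes the orderings invert: the monochromatic line
process has slowly decaying (τ^{-1/2}) Bessel correlations, and its count
variance overtakes that of broad spectra, whose line correlations decay
faster.  Both regimes are exact consequences of the same two-point integral
and both are confirmed by simulation; the monotone-rise regime reported by
the experiment drivers is a statement about hypercolumn-scale probes, not
about arbitrarily long segments.  `ℓ/Λ_sq` is recorded in every output row
and is freely configurable.

Monte Carlo defaults: 3-standard-error gates for acceptance-style checks,
50 fields × 256 waves with a `(10Λ_sq)²` interior window for density tests,
and ensembles of 2.5–20 × 10³ segments for crossing moments (sizes chosen to
put Monte Carlo error well below the effects under test while keeping the
full suite in minutes on one CPU).  All ensembles are seeded and
reproducible; standard errors use the sample variance (delta method for the
normalized variance).

## Known limitations

* The synthesized fields are exactly Gaussian only as `n_waves → ∞`;
  finite-n residuals are below the Monte Carlo noise used here but would
  matter for per-mille-level tests.
* Plaquette winding cannot separate zero pairs closer than a grid cell;
  densities are unbiased at the stated resolutions but individual detections
  near such pairs carry one-cell position uncertainty.
* The quadrature assumes compactly supported spectra (all implemented
  families are); heavy-tailed spectral measures with divergent second moment
  have no column spacing and are rejected by construction.
* Passing tests here validate the mathematics of invariant Gaussian fields,
  not the biology of mature cortical maps: real orientation maps are known
  to deviate from Gaussian statistics (e.g. their pinwheel density scaled by
  the experimentally defined column spacing differs from the `Λ_sq`-scaled
  one), and no synthetic ensemble in this package emulates those deviations.
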