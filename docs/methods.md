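# Methods

## Scope and model

The package classifies labelled NIR absorbance spectra (rows over a strictly
increasing wavelength grid) into c varieties with a five-stage pipeline:
stratified split → pretreatment → PCA → discriminant extraction → KNN.
Every stage with learnable state (MSC reference, mean-centering means, PCA
model, discriminant projection, KNN references, fuzzy partition) is fit on
the training split only; the test split is transformed with the trained
state.  All randomness flows from one master seed through
`numpy.random.SeedSequence` children (child 0: the split shuffle; further
children where the caller derives data seeds), so a run is bit-reproducible.

## Pretreatments

- **SNV** centres and scales each spectrum to unit spread; the divisor is
  the sample standard deviation (n−1), the common chemometrics convention
  (a `ddof` flag selects the population form).  Constant spectra are
  rejected by sample id.
- **MSC** regresses each spectrum on a reference (training-set column mean
  by default) and inverts the fitted affine model, (x − a)/b.  A near-zero
  slope is an error, not a silent division.
- **Mean centering** is column-wise (per wavelength), the standard
  chemometric meaning; per-row centering would duplicate what SNV already
  does.
- **Savitzky–Golay** smoothing is one operator with two conventional
  parameterisations: a narrow window (order 2, window 11) for light
  smoothing and a wide window (order 2, window 53) for aggressive noise
  filtering.  Edges are handled by evaluating the polynomial fit over the
  first/last full window (scipy's `mode="interp"`), not by padding.  The
  filter reproduces polynomials up to its order exactly, and the
  interpolating order (window − 1) is the identity.

## PCA

Sample-covariance eigendecomposition via thin SVD of the centred training
matrix; k = 7 components by default (on spectra of this kind the first
seven carry essentially all variance).  Loadings carry a deterministic
sign (largest-magnitude entry of each column positive); eigenvalues use
ddof = 1.

## Discriminant extractors

Crisp scatter matrices follow the printed definitions, including the
**between-class scatter unweighted by class size**; `class_weighted_sb=True`
selects the conventional nⱼ-weighted form (for balanced classes the two
differ by the constant factor nⱼ, which classical LDA is invariant to but
the exponential variants are not — see "benchmark behaviour" below).

The exponential eigenproblem B = exp(S_w)⁻¹exp(S_b) is solved as the
equivalent symmetric-definite problem exp(S_b) w = λ exp(S_w) w.  B itself
is non-symmetric; the generalized form has real eigenpairs and a stable
solver.  Implementation detail that matters: a Cholesky-based generalized
solver fails outright once exp(S_w) has condition ≳ 1e15, which is routine
for scatter eigenvalues in the tens.  We therefore whiten explicitly with
M = exp(−S_w/2) computed spectrally and eigendecompose the symmetric
M exp(S_b) M; directions with huge within-class spread underflow smoothly
to zero, matching the analytic limit.  If the largest scatter eigenvalue
exceeds 300, both matrices are rescaled by a common factor before
exponentiation (configurable off) so the exponentials stay finite.

Fuzzy memberships use the FCM formula with exponent η (default 4) against
centers initialised to the labelled class means.  The default
`supervised_oneshot` mode evaluates the formula once: it is deterministic
and label-faithful.  An `fcm_iterative` mode runs the standard FCM
alternating updates (tol 1e−6, max 300 sweeps) from that initialisation;
note that at η = 4 on strongly overlapping data unsupervised FCM can
collapse all centers to the grand mean, which the code reports as a
duplicate-center error — one reason the one-shot mode is the default.
A sample coinciding with a center receives membership one there.

**Projection scale.**  Eigenvector scale is arbitrary in all three
eigenproblems, and the solvers' natural normalisations differ (wᵀS_w w = 1
for LDA, wᵀexp(S_fw) w = 1 for the exponential variants), which would hand
the downstream Euclidean KNN incomparably scaled spaces.  All three
extractors therefore rescale each discriminant vector to unit pooled
within-class variance on the training scores.  Sign convention: the
largest-magnitude entry of each column is positive.  Eigenvalue ties keep
the underlying solver's order.

## Classification

KNN with Euclidean distance in DV space.  Determinism: neighbours sort by
(distance, sample id) — stable under any permutation of the training
set — and vote ties fall back to the single nearest neighbour's label.
K defaults to leave-one-out cross-validation on the training projections
over odd K ∈ {1, 3, 5, 7, 9, 11}, smallest K on ties.  The
max-membership rule (assign to the class of largest fuzzy membership) is
provided as an alternative decision rule.

## Synthetic data generator

Each class has a smooth quadratic baseline and Gaussian absorption bands
near 1180 nm (C–H) and 1430 nm (O–H/water) on a 228-point 900–1700 nm
grid.  Class identity enters as per-class offsets: full strength on the
baseline intercept (varieties of one fruit differ most visibly in overall
absorbance level — this also makes the class centers spread along PC1,
which the membership formula needs to be informative), quarter strength on
baseline slope/curvature, and full strength on each band height, all drawn
once per class as Normal(0, class_effect_scale).  Each sample is then
distorted by x ← m·x + a with m ~ N(1, scatter_mult_sd),
a ~ N(0, scatter_add_sd), plus i.i.d. N(0, noise_sd) per point.  Draw
order is fixed (class-level draws first, then sample-level in class-major
order), so output is bit-identical for a given config and seed.

Defaults (the benchmark conditions): 5 classes × 60 samples,
class_effect_scale 0.08 AU, scatter 2% multiplicative / 0.01 AU additive,
noise 0.08 AU per point.  The within-class variation is deliberately
noise-dominated rather than scatter-dominated: the benchmark probes the
claimed noise robustness of the fuzzy discriminant, and light scatter is
what careful presentation of intact fruit to a portable instrument
produces.  What the generator does **not** emulate: non-Gaussian or
sample-specific noise (bad-contact outliers), wavelength-correlated
instrument drift, or physically modelled tissue optics.  Passing tests on
this generator therefore validate the algebra and the pipeline mechanics,
not field performance on real spectra.

## Benchmark behaviour and limitations

On the default benchmark (20 seeds, S-G filter, PCA(7), η = 4, K auto)
the fuzzy exponential discriminant is consistently the stronger of the two
exponential methods — mean accuracy ≈ 0.95–0.97 versus ≈ 0.90–0.92 for the
crisp one, a stable 3–5 point margin.  The mechanism is the printed
formula asymmetry noted above: the crisp between-class scatter is
unweighted by class size, so its exponential stays near I + S_b and the
crisp method's exponential within-class suppression deletes high-variance
directions even when they separate classes; the fuzzy between-class
scatter carries the membership mass (≈ class size in the crisp limit) and
re-amplifies those directions.

Classical LDA, however, is the strongest of the three on this generator
(≈ 0.97–0.98), and we found no honest setting of the generator in which
the exponential variants beat it while accuracy stays high: with
light-tailed Gaussian class-conditionals and 175 training samples in 7
dimensions, the pooled-covariance whitening that LDA performs is close to
statistically optimal, and the exponential map's advantages (singular or
unreliable S_w, null-space information, outlier-heavy within-class
estimates) have nothing to bite on.  The exponential variants do pull
ahead of LDA under heavy noise after MSC, but only at accuracies around
0.7.  Reported advantages of the fuzzy exponential method over LDA on real
spectra plausibly rest on within-class structure — sample-specific
artifacts, heteroscedastic and heavy-tailed deviations — that this
generator intentionally excludes.  This is a documented limitation of the
synthetic benchmark, not of the implementations, which are verified
against brute-force oracles independently of any accuracy claim.

Numerical notes: oracle comparisons of the exponential eigenproblem are
made on instances with scatter eigenvalues ≲ 10, because once the
exponentiated eigenvalue spread approaches 1/eps both the implementation
and the dense oracle lose the trailing eigenvectors to round-off and no
float64 route can resolve the subspace.  Tolerances: scatter identities at
1e−12 (exact algebra), subspace agreement at 1e−7, S-G polynomial
reproduction at 1e−9.
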