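# Methods

## The optimizer

The fruit fly algorithm maintains, per problem dimension, an (X, Y) axis
pair — the swarm center. Each of the `population` flies perturbs both
axes per coordinate ("olfactory search"), and the candidate is decoded
coordinate-wise as the reciprocal distance to the origin:

    Dist_j = sqrt(X_j² + Y_j²),   S_j = 1 / Dist_j.

Candidates are therefore strictly positive. The fly with the lowest
objective value attracts the swarm ("visual search"): the axes jump to
its position, but only when it improves on the incumbent best (global
elitism), so the best-value trace is non-increasing by construction.
Ties keep the incumbent, and within an iteration the lowest fly index
wins a tie. One run performs `1 + population × max_iterations` objective
evaluations (the decoded initial axis point seeds the incumbent).

The classic FOA perturbs by U(−1, 1) per coordinate. The variable-step
variant multiplies fly i's draw at iteration t by |lv(i, t)|,

    lv(i, t) = e^(i/t) − w · i · e^(−i/t),   w ∈ [0, 1] (default 0.8).

`lv` can be negative; since the perturbation U(−1, 1) is symmetric, only
the magnitude matters and the absolute value is used. At t = 1 with 50
flies the amplitudes span from ~2.4 to e⁵⁰ ≈ 5·10²¹ — about 21 orders of
magnitude — and the schedule contracts as t grows. This has a decisive
interaction with the reciprocal decoding: a huge step makes `Dist`
huge and the decoded candidate S ≈ 10⁻²⁰ or smaller. For objectives
whose minimum sits at the origin, terms like x²/4000 or 10·cos(2πx)
then round to their limiting values in double precision, and functions
such as Griewank, Rastrigin, Schaffer N.2, Bohachevsky and Drop-Wave
evaluate to their *exact* floating-point optimum (0 or −1). The exact
zeros reported for the benchmark suite are this mechanism at work, not
an accident of seeding; Matyas, whose minimum is approached but never
hit exactly off the diagonal, bottoms out around 10⁻⁴⁵.

Choices left open by the method's usual description, fixed here:

* Axes initialize uniformly in [0, 1] per dimension (the conventional
  choice; the scale is forgotten within a few iterations).
* The random perturbation is U(−1, 1), symmetric about the axis.
* A zero decoded distance (measure-zero event) is replaced by the
  smallest positive normal double before taking the reciprocal.
* Benchmark bounds are metadata only — the algorithm never
  box-constrains candidates on test functions, which is what lets the
  reciprocal decoding underflow to the optimum. For the image
  application, decoded candidates are clipped into [ε, 10 − ε],
  ε = 10⁻³, honoring the transfer curve's open (0, 10) domain.
* One PCG64 generator per run, seeded from the config; every stochastic
  draw flows through it, making runs bit-reproducible.

## Benchmark protocol

Six classic minimization functions in their standard published forms
(Griewank d = 30, Drop-Wave d = 2, Rastrigin d = 30, Schaffer N.2,
rotated Bohachevsky, Matyas). The rotated Bohachevsky family has three
conventional variants; the headline suite reports the first (N.1) under
the id `F5`, with `F5.2`/`F5.3` addressable separately. Repeated-run
summaries use best = min, worst = max, arithmetic mean, and the sample
standard deviation (n − 1 denominator; immaterial at n = 30, zero for a
single run). The standard protocol is 30 independent runs at population
50, 500 iterations, w = 0.8.

## The transfer curve and fitness

`beta_cdf` is the regularized incomplete Beta function (scipy's
`betainc`); tests cross-check it against adaptive quadrature of the
integrand, an independent algorithm. Gray values are normalized by the
image's own min/max (Ib = gmin + F(n)·(gmax − gmin) on the way back), so
the output occupies the same span as the input. Denormalization rounds
half away from zero and clips to [0, 255]; the fixed rule makes
normalize → identity curve → denormalize a bit-exact round trip.

The fitness is the negative gray-level variance E[x²] − (E[x])² of the
*denormalized* enhanced image, computed over all pixels. Because the
enhanced value of a pixel depends only on its original gray level, the
optimizer evaluates fitness from the image's level histogram and the
tabulated curve — algebraically identical to materializing the enhanced
image (a unit test asserts exact agreement) at a fraction of the cost.
Evaluating the fitness on the 0–255 scale rather than the normalized
[0, 1] scale only rescales the objective by (gmax − gmin)²; it cannot
change the argmax.

## Pipeline

1. Convert to grayscale (luma weights 0.299/0.587/0.114, rounded);
   grayscale inputs pass through.
2. Normalize by min/max. A constant image is returned unchanged with
   identity parameters and a degenerate flag.
3. Optimize (α, β) with the variable-step optimizer at the standard
   image budget: population 30, 50 iterations, w = 0.8, candidates
   clipped into [10⁻³, 10 − 10⁻³].
4. If the optimized curve scores worse than the identity curve (possible
   only at tiny budgets), fall back to the identity — the enhanced
   variance therefore never drops below the original.
5. Apply the curve and denormalize. For color inputs the curve is fitted
   on the luma image and then applied either to each RGB channel with
   that channel's own span (`per_channel`, the default — the simplest
   rule that turns gray-optimized parameters into a color output) or to
   the HSV value channel (`luminance`). `gray` returns the enhanced luma
   image itself.

Reported variances (original vs enhanced) are measured on the
optimization channel.

## What the synthetic scenes emulate — and what they do not

The generators stand in for the photographs such methods are usually
demonstrated on. `gamma_dark` raises a smooth blob-textured base scene
to a power (default γ = 2.5), compressing the histogram into the dark
end; the base is capped at 0.78 of full scale (dark scenes have no
saturated whites), which keeps occupancy below 60 % of the gray levels
and leaves the pipeline headroom to demonstrate brightening. `blobs`
gives a bright-structures-on-dark-field scene reminiscent of endoscopic
frames — a qualitative resemblance only, with no claim of clinical
realism. `checker` and `gradient` are exact patterns for metric tests.
What passing tests on these fixtures show is that the method behaves as
designed on controlled low-contrast inputs; they cannot show how
enhanced real photographs look, and no photograph-level quality numbers
are claimed.

A structural note on histograms: the transfer curve is a monotone map
applied to discrete gray levels inside the image's own span, so it can
merge occupied levels but never create new ones — the occupied-level
*count* never increases under enhancement. What the method actually
does to the histogram is move mass out of the dark bins and spread it
across the span (the mean gray level of dark fixtures roughly triples);
variance maximization tends toward bimodal histograms, and on some
seeds it selects a near-binarizing corner (α ≈ 10⁻³) rather than a
smooth S-curve. Both behaviors are tested at the level that is true:
variance and mean rise, counts do not grow.

## Quality metrics

MSE/PSNR are standard (PSNR = +∞ sentinel for identical images; MAX =
255). SSIM is the single-window, whole-image form with c1 = (0.01·255)²,
c2 = (0.03·255)² and population moments; a sliding-window mean-SSIM is
deliberately not the default since the global form is what the rest of
the package reports. MSCN coefficients use a 7×7 Gaussian window with
σ = 7/6 (the convention of the BRISQUE/NIQE literature), symmetric
boundary extension, and stabilizer C = 1. The AGGD fit is the standard
moment-matching estimator with the shape read off a ρ(ν) grid over
[0.2, 10] at step 0.001. The NIQE distance is the Mahalanobis form
sqrt((v₁−v₂)ᵀ((Σ₁+Σ₂)/2)⁻¹(v₁−v₂)); a singular pooled covariance falls
back to the pseudo-inverse with a warning. Fitting the pristine-corpus
Gaussian model (full NIQE scoring) and BRISQUE's SVM regression are out
of scope: the operations here make the formulas testable without
trained models.

## Problem sizes

The test and acceptance runs use: the full benchmark protocol (6
functions × 2 variants × 30 runs × 500 iterations × 50 flies,
vectorized per iteration — tens of seconds), ten 256×256 dark fixtures
through the full pipeline (histogram-path fitness makes each run a
fraction of a second), and 10⁵-sample AGGD fits. These sizes were chosen
to match the method's standard settings exactly where they are defined
(benchmark and pipeline budgets) and to keep statistical estimates
(AGGD shape within 10 %) comfortably stable.

## Known limitations

* Variance is a proxy for "content richness"; it rewards bimodal
  histograms, and on some inputs the optimum is a near-thresholding
  curve. No perceptual term restrains it.
* The color recombination rule (per-channel application of a
  luma-fitted curve) can shift hue on strongly colored inputs; the
  `luminance` mode preserves hue at the cost of saturation artifacts
  after value-channel stretching.
* The pipeline is 8-bit end to end; deeper images are rejected rather
  than rescaled.
* Enhanced output occupies the same gray span as the input (min/max
  round trip); the method increases spread within the span, it does not
  extend the span.
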