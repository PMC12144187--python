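# Methods

## The PSHG forward model

Each pixel is modeled as an assembly of SHG-active harmonophores with
cylindrical symmetry about an in-plane fiber axis at angle α (degrees,
counterclockwise from the image x-axis, defined modulo 180°). With incident
linear polarization at angle φ, the detected second-harmonic intensity is

    I(φ) = C² sin² 2(φ−α) + [A sin²(φ−α) + B cos²(φ−α)]²,

where A = I₀χ31, B = I₀χ33, C = I₀χ15 fold the illumination intensity I₀
into the three independent susceptibility tensor elements. The model assumes
the fiber axis lies in the image plane, neglects birefringence and
phase-retardation effects that accumulate in thick tissue, and ignores the
forward/backward emission ratio; these are deliberate scope limits, not
oversights.

Amplitude signs are unobservable in an intensity measurement, so A, B, C are
reported as magnitudes, and all ratios derived from them are non-negative.

## Exact Fourier representation and inversion

Writing S = A+B, D = B−A, the profile in ψ = φ−α is
c₀ + c₂cos2ψ + c₄cos4ψ with

    c₀ = C²/2 + S²/4 + D²/8,   c₂ = SD/2,   c₄ = D²/8 − C²/2,

which rotates into the five-coefficient series
a₀ + a₂cos2φ + b₂sin2φ + a₄cos4φ + b₄sin4φ. The signal is band-limited, so
for P ≥ 5 equally spaced angles covering [0°, 180°) the discrete means

    a₀ = mean(I),  aₙ = 2·mean(cos nφ · I),  bₙ = 2·mean(sin nφ · I)

recover the coefficients exactly (discrete orthogonality); irregular grids
fall back to linear least squares on the five basis functions. The algebraic
inversion is

    α  = ½·atan2(b₂, a₂)             (mod 180°)
    c₂ = √(a₂²+b₂²)
    c₄ = a₄cos4α + b₄sin4α           (signed projection)
    B  = √(a₀+c₄+c₂),  A = √(a₀+c₄−c₂),  C = √((B−A)²/4 − 2c₄).

### Numerical choices

- **Branch convention.** The 2φ harmonic fixes α only modulo 90° jointly
  with the sign of c₂. The package adopts c₂ ≥ 0 ⇔ B ≥ A (χ33 ≥ χ31), the
  regime of every collagen measurement this pipeline addresses. The algebra
  makes the two branches yield the identical amplitude pair
  {a₀+c₄±|c₂|} = {((S±|D|)/2)²}, so the convention only decides which
  amplitude is labeled χ33 and the corresponding α; no pixel can be rescued
  by the alternate branch that the main branch rejects.
- **Signed c₄ projection** (rather than the magnitude √(a₄²+b₄²)): the sign
  of c₄ distinguishes the C-dominated from the D-dominated regime and is
  required for a correct C.
- **Noise clamps.** Shot noise can drive the A² or C² estimates slightly
  negative. Values above −0.05·a₀² are clamped to zero; larger violations
  flag the pixel invalid (unphysical under the model).
- **Isotropic pixels.** Where both harmonic magnitudes fall below 1e−9·a₀
  the orientation is genuinely undefined; α is reported as 0 with an
  isotropy flag and such pixels are excluded from orientation statistics.
- **Neighbor averaging.** Optional smoothing mean-filters the five
  coefficient maps over a (2r+1)² window *before* inversion (default radius
  1 in the pipeline configuration). Coefficients are linear in the data, so
  averaging them is statistically cleaner than averaging derived angles or
  ratios. Smoothing mixes adjacent fibers in dense fields and mildly shrinks
  the apparent orientation dispersion; the shrinkage is common to conditions
  being compared and largely cancels in dispersion ratios.

## Pitch angle

The effective α-helix pitch angle of the peptide-bond harmonophores is

    tan²θᵖ = 2 / (χ33/χ31 − χ15/χ31 + 1),

defined for a positive denominator, strictly decreasing in
χ33/χ31 − χ15/χ31, and approaching 90° as the denominator vanishes. Pixels
with a non-positive denominator carry a NaN pitch and are excluded from the
pitch statistics.

## Peak classification

Profiles are classified single- or double-peaked by counting strict local
maxima of the analytic profile on a 0.1° grid over one 180° period, with
plateau runs merged. χ33 = χ31 with C > 0 gives two equal maxima at
ψ = 45°, 135° (the myofibril signature); B > A with small C gives a single
maximum at ψ = 0. A flat profile (A = B, C = 0) raises a degenerate-profile
error.

## Image-level statistics

- **Segmentation.** The polarization-mean image is normalized by its 99.9th
  percentile (not the maximum, to resist hot pixels — the normalization
  reference was an open choice) and thresholded at 0.2 by default; the
  threshold is a configuration knob because it was an empirical choice in
  the underlying protocol.
- **Mode values.** Histogram modes with fixed bin widths — 0.01 for
  dimensionless ratios, 0.25° for angles — chosen so two-decimal reporting
  of ratios is resolvable; ties break toward the lower bin; bins are
  anchored at integer multiples of the width.
- **Orientation dispersion.** The α histogram (1° bins, 180°-periodic) is
  recentered at its circular mode so the peak sits mid-axis, then fitted
  with y = y₀ + a·exp(−(x−μ)²/2σ²). The offset y₀ absorbs the isotropic
  floor of the distribution (and most of the wrapped tail mass for broad
  distributions). On non-convergence or a near-degenerate histogram the
  circular standard deviation of the doubled angles is returned, flagged as
  a fallback.
- **Fiber density.** mask = image ≥ 0.45·mean(image); density is the masked
  fraction of *all* image pixels (the per-section reading; the denominator
  is configurable).

All statistics are invariant under multiplying the stack by any positive
constant: ratios cancel I₀, segmentation normalizes, the fiber mask
threshold is mean-relative.

## Phantom generator

The generator emulates the two specimen classes at the level needed to
exercise the pipeline; it renders the same forward model the fitter assumes
(plus noise), so recovery tests validate the estimation chain, not the
realism of the optics. Not emulated: the optical PSF, birefringence and
depth effects, detector saturation, spatially varying illumination, and
out-of-plane fiber tilt. Passing tests therefore certify correctness of
estimation and statistics under the model, not performance on real
microscope data.

- **Gel scenario** (`scenario("gel", col1_fraction=f)`, f ∈ {1.0 … 0.6}):
  straight fibril segments, uniformly random orientations, integer-pixel
  centers. Ground-truth pitch angle interpolates linearly from 47.72° at
  pure Col I to 48.19° at 60:40 Col I/III; χ33/χ31 is pinned at 1.13
  (mid-range) and χ15/χ31 is solved from the target θᵖ, since one equation
  cannot fix two ratios. Fibril length rises linearly from 6 µm to 16 µm
  over f = 0.6 → 1.0 (the increasing trend is the anchor; absolute lengths
  are a realism choice), thickness is 1.55 µm (mid of the observed
  1.3–1.8 µm band), pixel size 0.3 µm. The per-fibril brightness law is
  linear in f and constrained so the 80:20 / 60:40 mean-intensity ratio is
  1.7; because the model is quadratic in the amplitudes, brightness factors
  enter the amplitudes as square roots.
- **Skin scenario** (`scenario("skin", condition=...)`): curved strokes —
  unit-pixel steps whose heading performs a 1°-per-step random walk around a
  wrapped-normal base orientation (σ = 31° healthy, 25° scar; ratio 1.24).
  Both conditions share θᵖ = 46.7° via χ33/χ31 = 1.1 and the implied
  χ15/χ31 = 0.3239. 300 fibers of length 60 px, thickness 3 px on a 256²
  field by default.
- **Noise.** Poisson sampling after scaling the clean stack so its
  brightest pixel equals `peak_count` expected counts, plus optional
  Gaussian read noise, clipped at zero. All randomness flows from explicit
  integer seeds; identical seeds give bit-identical phantoms and stacks.

## Problem sizes and tolerances in the test suite

Recovery tests use 128² homogeneous phantoms at 1000 peak counts (mode θᵖ
within 0.5°, mode χ33/χ31 within 0.02) and 256² skin phantoms at 2000 peak
counts for the healthy/scar dispersion comparison (fitted SD ratio within
10% of the 1.24 design value). These sizes give stable histogram modes and
keep the orientation-sampling error of a few hundred fibers well inside the
tolerance; across seeds the measured SD ratio ranges ≈1.16–1.24. Exact
algebraic round-trips are asserted at 1e−8 or tighter; the noise-free
residual bound is 1e−12 relative.

## Known limitations

- The orientation Gaussian SD underestimates very broad wrapped
  distributions (σ ≳ 30°) because wrap-around mass is absorbed by the
  offset term; comparisons between conditions remain valid because the bias
  is shared.
- Dense fiber fields plus coefficient smoothing mix orientations at fiber
  crossings; per-pixel α there is an intensity-weighted compromise.
- The inversion assumes χ33 ≥ χ31; specimens genuinely in the opposite
  regime would have α systematically offset by 90° and the two χ ratios
  exchanged.
- Depth-dependent birefringence and phase retardation are not modeled;
  results from thick, strongly birefringent samples should be read as
  effective, not molecular, parameters.
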