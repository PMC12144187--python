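# pshglab

Pixel-based analysis of polarization-resolved second harmonic generation
(PSHG) microscopy. Given a stack of SHG images acquired at a series of
incident linear-polarization angles (typically 18 angles, 0°–170° in 10°
steps), the package recovers at every pixel:

- the in-plane fiber orientation α (degrees, modulo 180°),
- the second-order susceptibility ratios χ15/χ31 and χ33/χ31 of the
  cylindrically symmetric tissue tensor,
- the effective α-helix pitch angle θᵖ of the peptide-bond harmonophores,

and reduces the maps to the statistics used to compare specimens: histogram
mode values, the Gaussian width of the fiber-orientation distribution, and
fiber density. It targets fibrillar-collagen applications (gels of varying
Col I/III composition, healthy versus scarred dermis) but applies to any
SHG-active fibrous specimen (starch, myosin).

## Model

The per-pixel intensity as a function of polarization angle φ is

```
I(φ) = χ15² sin²2(φ−α) + [χ31 sin²(φ−α) + χ33 cos²(φ−α)]² · I₀²-scaled
     = C² sin²2(φ−α) + [A sin²(φ−α) + B cos²(φ−α)]²
```

with A = I₀χ31, B = I₀χ33, C = I₀χ15. This profile is exactly a five-term
Fourier series a₀ + a₂cos2φ + b₂sin2φ + a₄cos4φ + b₄sin4φ, so for P ≥ 5
equally spaced angles the coefficients are obtained by discrete means
(a₀ = mean I, aₙ = 2·mean(cos nφ·I), bₙ = 2·mean(sin nφ·I)) — no iterative
fitting — and inverted in closed form back to (α, A, B, C). The pitch angle
follows from

```
tan²θᵖ = 2 / (χ33/χ31 − χ15/χ31 + 1).
```

Because no public PSHG stacks accompany this problem, a phantom generator
renders fibril fields with known per-pixel ground truth (straight segments
for gels, curved strokes for dermis) through the same forward model, with
Poisson shot noise and Gaussian read noise, so every pipeline stage is
testable end to end.

## Worked example

```sh
pshg pipeline --scenario gel --col1-fraction 0.8 --size 128 --seed 42 --outdir run
```

prints (values from this exact command):

```
mode chi15/chi31 = 0.505  mode chi33/chi31 = 1.125  mode theta_p = 47.88 deg
orientation sd = 42.67 deg  fiber density = 0.751  foreground = 0.751
```

The 80:20 Col I/III gel phantom carries ground truth χ33/χ31 = 1.13 and
θᵖ = 47.955°; the recovered modes land within one histogram bin of the truth
despite shot noise at 2000 peak counts. The large orientation SD reflects the
gel scenario's uniformly random fibril orientations (dermis scenarios have
wrapped-normal orientations and give SDs near their design values of
25°/31°). `run/` contains float-TIFF maps (`alpha`, `chi15`, `chi33`,
`theta`, `residual`, NaN = invalid pixel), the masks, `summary.csv`, and a
plain-text run report.

The same stages are available as a library:

```python
import numpy as np, pshglab as pl

ph = pl.scenario("skin", size=(256, 256), seed=4, condition="healthy")
stack = pl.render_stack(ph, np.arange(0, 180, 10),
                        noise=pl.NoiseModel(peak_count=2000, seed=104))
result = pl.analyze_stack(stack, pl.RunConfig(smooth_radius=1))
print(result.stats.orientation_sd)   # Gaussian SD of fiber orientation, degrees
```

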