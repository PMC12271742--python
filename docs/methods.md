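# Methods

## The similarity model

An image `s` is compared with a reference `s_GT` through a panel of
global no-reference quality markers rather than pixel differences. The
default panel of eight covers complementary degradations:

| marker | meaning | sensitive to |
|---|---|---|
| `FRC_res` | resolution from the single-image Fourier ring correlation | blur, noise |
| `FRC_sum` | sum of the FRC curve (spectral SNR mass) | noise, blur |
| `SNR_sigma` | `20 log10((s_max − μ)/σ)` dB, μ/σ of background or full image | noise |
| `SNR_mu` | `20 log10((s_max − μ)/μ)` dB | offsets, background level |
| `HF_sum` | mass of the sum-normalised power spectrum beyond `(3/8)·min(n_rows, n_cols)` | blur |
| `SC` | mean gradient magnitude `(1/N)Σ√((∂x s)²+(∂y s)²)/√2` | smoothing, noise |
| `E_edge` | intensity fraction beyond radius `(3/8)·min(n_rows, n_cols)` | vignetting |
| `C_RMS` | standard deviation of the [0,1]-rescaled image | contrast, noise |

Every image is min–max rescaled to [0, 1] per image before marker
extraction (the degenerate constant image maps to all zeros and the
markers take their regularised branches; negative or undefined values
are replaced by `ε = 1e−6`).

Marker columns are prepared dataset-wide: values are clamped to the
0.005/0.995 percentiles (linear-interpolation quantiles; recommended
for large batches, skippable for small ones) and divided by the column
maximum, so every marker has data range 1. A marker pair then yields

```
SMSim(m1, m2) = (2 m1 m2 + k) / (m1² + m2² + k),    k = 0.01
```

— symmetric, equal to 1 iff `m1 = m2`, decreasing towards 0 as the
values diverge, with `k` stabilising near-zero markers. If max
normalisation is disabled, `k` becomes 0.01 × the fitted data range of
each marker. MMSim is the weighted arithmetic mean of the SMSim values;
uniform weights are the default and the headline score.

`MMSimScorer` freezes the clamp bounds and column maxima at `fit` time.
Scoring an image that arrives later reuses that state; it is never
renormalised against a new batch, which would silently change all
previous scores.

## Single-image FRC

Two half-images are built by checkerboard splitting: pixels with even
`x + y` go to one half, odd to the other, and the two pixels of each
parity class inside every 2×2 block are averaged onto a half-resolution
grid. Under pixel-wise independent noise the halves share the signal
but not the noise. The ring correlation

```
FRC(r) = Re(Σ_ring F_A conj(F_B)) / sqrt(Σ_ring |F_A|² · Σ_ring |F_B|²)
```

is evaluated over unit-width rings of the centred Fourier plane (zero
frequency at index `n//2`; radii Euclidean in index units, rounded to
the nearest ring). The resolution frequency is the first outward
crossing of the fixed 1/7 threshold, linearly interpolated between the
bracketing rings; `FRC_res = 1/resolution_freq` in pixels of the split
grid. The frequency axis is normalised to (0, 0.5], so a curve that
never crosses — a noise-free or extremely clean image, whose halves
correlate at every radius — is assigned the Nyquist-limit resolution of
2 px rather than an undefined value. The constant factor of 2 between
split-grid and original-sampling units cancels in the symmetric SMSim
and is therefore not applied. `FRC_sum` is the sum of the curve,
floored at `ε` if negative.

Note that the single-image FRC is a *spectral SNR* estimate: it needs
noise to decorrelate the halves. On a strictly noise-free image the
correlation stays near 1 at all radii regardless of blur, and the
resolution marker saturates at its 2 px fallback.

## Baseline metrics and ranking normalisation

SSIM (single-factor form, `k1 = 0.01`, `k2 = 0.03`, `L` = data range),
MSE, MAE, PSNR (peak from the reference) and PCC are implemented
directly from their defining formulas. SSIM defaults to the
conventional sliding-window evaluation (7×7 uniform window, population
moments, reflective borders, mean-aggregated); a whole-image global
mode is available behind the same flag, and the windowed map's centre
equals the global value when the window covers the image. PCC of a
constant image is undefined and returns 0 with a warning.

For joint rankings every metric is standardised to increase towards 1:
MMSim, SSIM and PCC pass through; PSNR's infinity (perfect match) is
replaced by 110% of the highest finite score, then the scores are
clipped to the [0.05, 0.95] quantiles and min–max rescaled (nPSNR);
MSE and MAE are quantile-clipped and inverted as `x_inv = x_min/x`
(nMSE, nMAE), which maps the reference through the clipped minimum to
exactly 1. Rankings sort by descending normalised score with the
reference pinned at rank 1 and score 1; ties break lexicographically by
image id so output is reproducible.

## PCA marker reduction

To cut computation for a specific evaluation problem, the panel is
reduced using only a quality series of the *reference* field of view
(≥ 3 variants), so the captured variability comes from the degradation
and not from differing content. A full PCA is fitted to the marker
matrix and each marker's relevance is `Σ_c |loading_c,m| · EVR_c` (EVR:
explained variance ratio); the 4 most relevant markers are kept by
default and their renormalised relevances are usable as MMSim weights.

Column scaling before the PCA is the one genuinely open design choice.
The default divides each column by its maximum — the same scaling the
similarity itself uses — so markers that respond strongly to the
degradation keep a proportionally larger variance and dominate the
leading components. Z-scoring (available as `scaling="zscore"`) forces
*every* column to unit variance, which hands noise-realisation jitter
the same weight as the degradation signal; on the synthetic defocus
series this made the selected set flip between seeds and degraded the
agreement between reduced and full-panel focus selection, so it is not
the default. On the defocus fixtures the default selection is stable
across seeds and lands on the physically expected markers
(`FRC_res`, `FRC_sum`, `HF_sum`, plus one of `SNR_mu`/`SC`/`C_RMS`).

## Denoising optimisation

The early-stopping loop filters the *original* noisy image with a 2-D
Gaussian of standard deviation `σ_t = σ1 + (t−1)·δσ`
(`σ1 = δσ = 0.05 px`; reflective borders, truncated at 4σ) — filters
are not compounded, so the reported σ is the filter actually applied.
After each iteration the monitored metric (MMSim, SSIM, PSNR, PCC:
increase; MSE, MAE: decrease) is evaluated against the reference; the
unfiltered input's score is the iteration-0 baseline. The loop stops
when the improvement over the previous iteration is ≤ `1e−5` of the
previous value (guarding against small metric oscillations) or after
100 iterations. An iterate whose improvement is positive but below the
tolerance is still the best iterate; a first step that worsens the
metric leaves the unfiltered input as the result. With `metric="MMSIM"`
the reference may be a bare marker vector (reduced-reference mode).

The sweep harness runs average, median and Gaussian filters
(scipy.ndimage) and total-variation and wavelet denoising
(scikit-image) over user-given hyperparameter grids and scores every
output with MMSim and the five baselines for ranking.

## Validation against known degradations

When the true degradation level of each image is known, a metric is
validated by Pearson correlation (PLCC), Kendall rank correlation
(KRCC, tau-b — integer quality scores create heavy ties) and RMSE.
Because a bounded similarity and an integer score live on incompatible
scales, the RMSE is computed on the residuals of the least-squares line
mapping metric scores onto the degradation scale, the standard
practice in quality-assessment validation. Defocus series are scored
`3 − |offset|`; averaging series either ordinally (1…L) or by the
averaging count itself.

## Synthetic fixtures: what they emulate and what they do not

The generator emulates the structure of public denoising and defocus
benchmarks so all experiments run without downloads:

* **Noise series** (`make_fov_series`): distinct structure seeds per
  FOV (filaments by default, 96×96), each measured at averaging levels
  n ∈ {1, 2, 4, 8, 16, 50}. Noise is mixed Poisson–Gaussian: each raw
  realisation draws `Poisson(peak·s)/peak + N(0, σ_read)` with
  peak = 50 photons and σ_read = 0.02 — visibly grainy at n = 1,
  near-clean at n = 50 — and the image is the mean of n realisations,
  so noise variance scales as 1/n. The highest level of FOV 1 is the
  reduced-reference ground truth. An optional saturation clip emulates
  a bounded detector range.
* **Defocus series** (`make_defocus_series`): 11 FOVs × focal offsets
  −3…+3, blur σ = 1 px per step (symmetric defocus model), each
  position an independent acquisition. The emulated regime is a
  high-SNR confocal stack of one homogeneous stained sample: nuclei
  with narrow size and amplitude ranges and chromatin-like fine
  texture (the high-frequency content that defocus physically
  removes), acquired at peak 200 photons with 16 averaged frames at
  128×128. Without that homogeneity and texture the FOV-to-FOV content
  variance would exceed the blur signal, which is not how the real
  benchmark behaves.

Everything is bit-reproducible under `(seed, parameters)`; no global
random state is used. Not emulated: a physical point-spread function,
optical sectioning, detector fixed-pattern artefacts, sample motion,
or 3-D aberrations. Passing the synthetic experiments therefore shows
that the method ranks *these* controlled degradations correctly at
desk scale; it does not certify behaviour on artefacts outside the
modelled families.

## Numerical choices and edge cases

* `ε = 1e−6` for all regularised degenerate/negative marker values.
* Quantiles use linear interpolation everywhere (clamping, ranking
  normalisation), so independent oracle implementations agree exactly.
* Radial thresholds use `min(n_rows, n_cols)` for rectangular images;
  spatial radii are measured from the geometric centre `(n−1)/2`,
  spectral radii from the FFT centre bin `n//2`.
* Markers are computed per channel for multichannel data; a
  multichannel MMSim is the unweighted mean of per-channel scores.
* Per-image min–max rescaling has two consequences worth knowing:
  blurring a *noise-free* structure can slightly raise the rescaled
  gradient marker (the lower maximum re-amplifies contrast), while on
  measured noisy images blur lowers `SC` and `HF_sum` monotonically;
  and unbounded noise can *lower* `C_RMS` because hot pixels inflate
  the min–max range faster than the variance grows — with a bounded
  (saturating) detector range noise raises `C_RMS` as expected.
* Tie-breaks: report columns follow the fixed canonical marker order;
  ranking ties break by image id; marker-relevance ties break by panel
  order.

## Known limitations

Scores are only comparable within one scored batch (one normalisation
state). The FRC marker needs noise to estimate resolution and
saturates on clean images. The method compares global statistics: a
processing artefact that preserves global markers while corrupting
local structure (e.g. hallucinated texture) is invisible to it, so
pixel-wise baselines remain a useful complement.
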