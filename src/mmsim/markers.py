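"""No-reference quality markers.

Eight global markers summarise complementary aspects of a microscopy
image: two Fourier-ring-correlation markers (estimated resolution and
correlation sum), two logarithmic signal ratios (dynamic range over
background standard deviation and over background mean), the
high-frequency mass of the power spectrum, the structural complexity
(mean gradient magnitude), the edge energy ratio and the RMS contrast.

Markers are computed on the image rescaled to [0, 1].  They are always
non-negative: degenerate or negative values (e.g. a logarithmic SNR of a
flat image) are regularised to the small constant :data:`EPSILON`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from mmsim.image import Image, as_image, require_min_size, rescale_unit

#: Regularisation constant replacing negative or undefined marker values.
EPSILON = 1e-6

#: Fixed FRC resolution threshold (the conventional 1/7 criterion).
FRC_THRESHOLD = 1.0 / 7.0

#: Canonical marker order used in every table and report.
DEFAULT_MARKERS = (
    "FRC_res",
    "FRC_sum",
    "SNR_sigma",
    "SNR_mu",
    "HF_sum",
    "SC",
    "E_edge",
    "C_RMS",
)


@dataclass(frozen=True)
class FRCCurve:
    """A Fourier ring correlation curve with its threshold crossing.

    Attributes
    ----------
    ring_frequency
        Normalised spatial frequencies of the ring centres, strictly
        increasing, in (0, 0.5] cycles per pixel of the split grid.
    correlation
        FRC value per ring, in [-1, 1] up to floating tolerance.
    resolution_freq
        Frequency where the curve first falls below the 1/7 threshold
        (linearly interpolated), or ``None`` if it never does.
    threshold
        The resolution criterion applied.
    """

    ring_frequency: np.ndarray
    correlation: np.ndarray
    resolution_freq: float | None
    threshold: float = FRC_THRESHOLD


def _checkerboard_split(px: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split one image into two statistically independent half-images.

    Pixels with even ``x + y`` form one sub-image, odd ``x + y`` the
    other; each parity class contributes two interleaved lattices that
    are averaged onto a common half-resolution grid.  Under pixel-wise
    independent noise the two halves share the signal but not the noise,
    which is what the ring correlation requires.
    """
    nr, nc = px.shape
    nr -= nr % 2
    nc -= nc % 2
    p = px[:nr, :nc]
    even = 0.5 * (p[0::2, 0::2] + p[1::2, 1::2])
    odd = 0.5 * (p[0::2, 1::2] + p[1::2, 0::2])
    return even, odd


def _ring_index(shape: tuple[int, int]) -> np.ndarray:
    """Integer ring index (rounded Euclidean radius) of each spectrum bin.

    The zero-frequency bin sits at ``(n // 2, n // 2)`` of the shifted
    spectrum; radii are Euclidean in index units.
    """
    nr, nc = shape
    fy = np.arange(nr) - nr // 2
    fx = np.arange(nc) - nc // 2
    r = np.hypot(fy[:, None], fx[None, :])
    return np.rint(r).astype(int)


def compute_frc(img: Image | np.ndarray) -> FRCCurve:
    """Single-image Fourier ring correlation.

    The image is checkerboard-split into two half-images, and the ring
    correlation ``Re(sum F_A conj(F_B)) / sqrt(sum |F_A|^2 sum |F_B|^2)``
    is evaluated over unit-width rings of the centred Fourier plane.  The
    resolution frequency is the first outward crossing of the fixed 1/7
    threshold, linearly interpolated between the bracketing rings.
    """
    img = as_image(img)
    require_min_size(img)
    a, b = _checkerboard_split(img.pixels)
    fa = np.fft.fftshift(np.fft.fft2(a))
    fb = np.fft.fftshift(np.fft.fft2(b))
    ring = _ring_index(fa.shape)
    n_rings = min(fa.shape) // 2
    radii = np.arange(1, n_rings + 1)

    num = np.bincount(ring.ravel(), weights=(fa * np.conj(fb)).real.ravel())
    den_a = np.bincount(ring.ravel(), weights=(np.abs(fa) ** 2).ravel())
    den_b = np.bincount(ring.ravel(), weights=(np.abs(fb) ** 2).ravel())
    num = num[radii]
    den = np.sqrt(den_a[radii] * den_b[radii])
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)

    freq = radii / (2.0 * n_rings)  # normalised to (0, 0.5]
    res_freq = _threshold_crossing(freq, corr, FRC_THRESHOLD)
    return FRCCurve(ring_frequency=freq, correlation=corr, resolution_freq=res_freq)


def _threshold_crossing(
    freq: np.ndarray, corr: np.ndarray, threshold: float
) -> float | None:
    """First outward crossing of ``corr`` below ``threshold``, interpolated."""
    below = np.nonzero(corr < threshold)[0]
    if below.size == 0:
        return None
    i = below[0]
    if i == 0:
        return float(freq[0])
    f0, f1 = freq[i - 1], freq[i]
    c0, c1 = corr[i - 1], corr[i]
    t = (c0 - threshold) / (c0 - c1)
    return float(f0 + t * (f1 - f0))


def frc_markers(curve: FRCCurve) -> tuple[float, float]:
    """Derive ``(FRC_res, FRC_sum)`` from an FRC curve.

    ``FRC_res`` is the reciprocal of the crossing frequency, expressed in
    pixels of the split grid; a curve that never crosses the threshold is
    assigned the Nyquist-limit resolution of 2 px.  ``FRC_sum`` is the sum
    of the correlation curve, floored at :data:`EPSILON` if negative.
    """
    if curve.resolution_freq is None:
        frc_res = 2.0
    else:
        frc_res = 1.0 / curve.resolution_freq
    frc_sum = float(np.sum(curve.correlation))
    if frc_sum < 0:
        frc_sum = EPSILON
    return frc_res, frc_sum


def _background_stats(img: Image) -> tuple[float, float]:
    """Mean and standard deviation of the background region (or full image)."""
    if img.background_mask is not None:
        vals = img.pixels[img.background_mask]
    else:
        vals = img.pixels
    return float(vals.mean()), float(vals.std())


def snr_sigma(img: Image | np.ndarray) -> float:
    """Logarithmic ratio of dynamic range to background standard deviation.

    ``20 log10((s_max - mu) / sigma)`` in dB, where ``mu`` and ``sigma``
    come from the background mask when one is set and from the full image
    otherwise, while ``s_max`` is always the global maximum.  Negative or
    undefined values are regularised to :data:`EPSILON`.
    """
    img = as_image(img)
    mu, sigma = _background_stats(img)
    s_max = float(img.pixels.max())
    if sigma <= 0 or s_max - mu <= 0:
        return EPSILON
    value = 20.0 * math.log10((s_max - mu) / sigma)
    return value if value >= 0 else EPSILON


def snr_mu(img: Image | np.ndarray) -> float:
    """Logarithmic ratio of dynamic range to background mean, in dB.

    ``20 log10((s_max - mu) / mu)``; an additive intensity offset raises
    ``mu`` without raising ``s_max - mu``, so offsets lower this marker.
    """
    img = as_image(img)
    mu, _ = _background_stats(img)
    s_max = float(img.pixels.max())
    if mu <= 0 or s_max - mu <= 0:
        return EPSILON
    value = 20.0 * math.log10((s_max - mu) / mu)
    return value if value >= 0 else EPSILON


def _radial_threshold(shape: tuple[int, int]) -> float:
    # "three-eighths the full size"; min(n_rows, n_cols) for rectangles
    return 0.375 * min(shape)


def hf_sum(img: Image | np.ndarray) -> float:
    """High-frequency mass of the sum-normalised power spectrum, in [0, 1].

    The centred power spectrum ``|F(s)|^2`` is normalised to unit sum and
    the mass at radii beyond the threshold ``f_th = (3/8) min(n_rows,
    n_cols)`` (integer frequency indices from the spectrum centre) is
    returned.  Blur removes high frequencies and lowers this marker.
    """
    img = as_image(img)
    ps = np.abs(np.fft.fftshift(np.fft.fft2(img.pixels))) ** 2
    total = ps.sum()
    if total <= 0:
        return 0.0
    nr, nc = ps.shape
    fy = np.arange(nr) - nr // 2
    fx = np.arange(nc) - nc // 2
    r = np.hypot(fy[:, None], fx[None, :])
    f_th = _radial_threshold(ps.shape)
    return float(ps[r > f_th].sum() / total)


def structural_complexity(img: Image | np.ndarray) -> float:
    """Average gradient magnitude ``(1/N) sum sqrt((dx^2 + dy^2) / 2)``.

    Gradients are central differences with replicated borders, so an
    isotropic ramp of slope ``d`` scores exactly ``|d|`` on interior
    pixels.  Sharp structure and noise raise it; smoothing lowers it.
    """
    img = as_image(img)
    p = np.pad(img.pixels, 1, mode="edge")
    gx = 0.5 * (p[1:-1, 2:] - p[1:-1, :-2])
    gy = 0.5 * (p[2:, 1:-1] - p[:-2, 1:-1])
    return float(np.mean(np.sqrt(0.5 * (gx**2 + gy**2))))


def edge_energy_ratio(img: Image | np.ndarray) -> float:
    """Fraction of intensity outside the radial threshold, in [0, 1].

    Radii are measured from the geometric image centre in pixel units with
    ``r_th = (3/8) min(n_rows, n_cols)``.  Vignetting suppresses the image
    periphery and lowers this marker.  A zero-sum image returns
    :data:`EPSILON`.
    """
    img = as_image(img)
    total = img.pixels.sum()
    if total <= 0:
        return EPSILON
    nr, nc = img.pixels.shape
    y = np.arange(nr) - (nr - 1) / 2.0
    x = np.arange(nc) - (nc - 1) / 2.0
    r = np.hypot(y[:, None], x[None, :])
    r_th = _radial_threshold(img.pixels.shape)
    return float(img.pixels[r > r_th].sum() / total)


def rms_contrast(img: Image | np.ndarray) -> float:
    """Root-mean-square contrast: the standard deviation of the image.

    Computed on the [0, 1]-rescaled image with the full-image mean, so the
    value lies in [0, 0.5].
    """
    img = as_image(img)
    return float(img.pixels.std())


_MARKER_FUNCS = {
    "SNR_sigma": snr_sigma,
    "SNR_mu": snr_mu,
    "HF_sum": hf_sum,
    "SC": structural_complexity,
    "E_edge": edge_energy_ratio,
    "C_RMS": rms_contrast,
}


def compute_markers(
    img: Image | np.ndarray,
    marker_set: tuple[str, ...] | list[str] | None = None,
) -> pd.Series:
    """Compute the requested quality markers for one image.

    The image is rescaled to [0, 1] once, each marker in ``marker_set``
    (default: all eight) is evaluated, and the values are returned as a
    Series in canonical marker order, named after ``image_id``.
    """
    img = as_image(img)
    require_min_size(img)
    if marker_set is None:
        marker_set = DEFAULT_MARKERS
    unknown = set(marker_set) - set(DEFAULT_MARKERS)
    if unknown:
        raise ValueError(f"unknown marker ids: {sorted(unknown)}")
    ordered = [m for m in DEFAULT_MARKERS if m in set(marker_set)]

    scaled = rescale_unit(img)
    values: dict[str, float] = {}
    if "FRC_res" in ordered or "FRC_sum" in ordered:
        frc_res, frc_sum = frc_markers(compute_frc(scaled))
        values["FRC_res"] = frc_res
        values["FRC_sum"] = frc_sum
    for name in ordered:
        if name not in values:
            values[name] = _MARKER_FUNCS[name](scaled)
    return pd.Series([values[m] for m in ordered], index=ordered, name=img.image_id)


class MarkerExtractor(BaseEstimator, TransformerMixin):
    """Transformer mapping a list of images to a marker table.

    ``transform`` accepts a sequence of :class:`~mmsim.image.Image` (or
    bare 2-D arrays) and returns a DataFrame with one row per image and
    one column per marker, rows indexed by ``image_id``.

    Parameters
    ----------
    marker_set
        Marker ids to compute; ``None`` selects the default eight.
    """

    def __init__(self, marker_set: tuple[str, ...] | None = None):
        self.marker_set = marker_set

    def fit(self, X, y=None):  # noqa: D102 — stateless
        return self

    def transform(self, X) -> pd.DataFrame:
        rows = []
        for i, item in enumerate(X):
            img = as_image(item)
            if not img.image_id:
                img = Image(img.pixels, img.background_mask, img.pixel_size, f"img{i:04d}")
            rows.append(compute_markers(img, self.marker_set))
        return pd.DataFrame(rows)
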