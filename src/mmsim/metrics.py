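"""Benchmark full-reference metrics and their ranking normalisation.

SSIM, MSE, PSNR, MAE and PCC are the pixel-wise baselines MMSim is
compared against.  ``normalize_for_ranking`` standardises every metric to
the same convention — increasing towards 1 for improving similarity — so
scores from different metrics can share one ranking and one plot:

* MMSim, SSIM and PCC already satisfy the convention and pass through.
* PSNR is infinite for a perfect match; the infinity is replaced by 110%
  of the highest finite score, the scores are clipped to the
  [0.05, 0.95] quantiles and min-max rescaled to [0, 1] (nPSNR).
* MSE and MAE decrease with similarity and reach 0 at a perfect match;
  after the same quantile clip their trend is inverted as
  ``x_inv = x_min / x`` (nMSE, nMAE).
"""

from __future__ import annotations

import math
import warnings
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter

from mmsim.image import Image, as_image

#: Metrics whose raw scores already increase towards 1 for similarity.
INCREASING_METRICS = frozenset({"MMSIM", "SSIM", "PCC"})
#: Standard SSIM stabiliser constants.
SSIM_K1 = 0.01
SSIM_K2 = 0.03
#: Default SSIM sliding-window size, in pixels.
SSIM_WINDOW = 7


def _pair(a: Image | np.ndarray, b: Image | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pa, pb = as_image(a).pixels, as_image(b).pixels
    if pa.shape != pb.shape:
        raise ValueError(f"image shapes differ: {pa.shape} vs {pb.shape}")
    return pa, pb


def ssim(
    a: Image | np.ndarray,
    b: Image | np.ndarray,
    mode: str = "windowed",
    data_range: float = 1.0,
    window: int = SSIM_WINDOW,
    full: bool = False,
) -> float | tuple[float, np.ndarray]:
    """Structural similarity index, global or uniform-windowed.

    The single-factor form combines luminance, contrast and structure::

        (2 mu_a mu_b + C1)(2 cov + C2)
        ------------------------------
        (mu_a^2 + mu_b^2 + C1)(var_a + var_b + C2)

    with ``C1 = (k1 L)^2``, ``C2 = (k2 L)^2``, ``k1 = 0.01``,
    ``k2 = 0.03`` and ``L`` the pixel value range.  ``mode='global'``
    evaluates it once with whole-image moments; ``mode='windowed'``
    (default) evaluates it per uniform sliding window and returns the
    mean, the form SSIM is conventionally reported in.  ``full=True``
    additionally returns the per-window similarity map (windowed mode).
    """
    pa, pb = _pair(a, b)
    c1 = (SSIM_K1 * data_range) ** 2
    c2 = (SSIM_K2 * data_range) ** 2
    if mode == "global":
        mu_a, mu_b = pa.mean(), pb.mean()
        var_a, var_b = pa.var(), pb.var()
        cov = ((pa - mu_a) * (pb - mu_b)).mean()
        return float(
            (2 * mu_a * mu_b + c1)
            * (2 * cov + c2)
            / ((mu_a**2 + mu_b**2 + c1) * (var_a + var_b + c2))
        )
    if mode != "windowed":
        raise ValueError(f"unknown ssim mode {mode!r}")
    # population moments per uniform window; borders handled by reflection
    mu_a = uniform_filter(pa, window)
    mu_b = uniform_filter(pb, window)
    var_a = uniform_filter(pa * pa, window) - mu_a**2
    var_b = uniform_filter(pb * pb, window) - mu_b**2
    cov = uniform_filter(pa * pb, window) - mu_a * mu_b
    smap = ((2 * mu_a * mu_b + c1) * (2 * cov + c2)) / (
        (mu_a**2 + mu_b**2 + c1) * (var_a + var_b + c2)
    )
    if full:
        return float(smap.mean()), smap
    return float(smap.mean())


def mse(a: Image | np.ndarray, b: Image | np.ndarray) -> float:
    """Mean squared error ``(1/N) sum (s_i - s_GT,i)^2``."""
    pa, pb = _pair(a, b)
    return float(np.mean((pa - pb) ** 2))


def mae(a: Image | np.ndarray, b: Image | np.ndarray) -> float:
    """Mean absolute error ``(1/N) sum |s_i - s_GT,i|``."""
    pa, pb = _pair(a, b)
    return float(np.mean(np.abs(pa - pb)))


def psnr(a: Image | np.ndarray, reference: Image | np.ndarray) -> float:
    """Peak signal-to-noise ratio ``20 log10(s_GT,max / sqrt(MSE))`` in dB.

    Asymmetric by definition: the peak is the reference's maximum.
    Identical images return ``+inf``.
    """
    pa, pref = _pair(a, reference)
    err = float(np.mean((pa - pref) ** 2))
    if err == 0:
        return math.inf
    return float(20.0 * math.log10(pref.max() / math.sqrt(err)))


def pcc(a: Image | np.ndarray, b: Image | np.ndarray) -> float:
    """Pearson correlation of pixel intensities, in [-1, 1].

    A constant image has no definable linear association; 0 is returned
    with a warning so batch scoring stays alive.
    """
    pa, pb = _pair(a, b)
    da = pa - pa.mean()
    db = pb - pb.mean()
    denom = math.sqrt((da**2).sum() * (db**2).sum())
    if denom == 0:
        warnings.warn("PCC undefined for a constant image; returning 0")
        return 0.0
    return float((da * db).sum() / denom)


def normalize_for_ranking(
    metric_id: str,
    scores: Mapping[str, float] | pd.Series,
    low_q: float = 0.05,
    high_q: float = 0.95,
) -> pd.Series:
    """Standardise raw metric scores to increase towards 1 for similarity.

    See the module docstring for the per-metric rules.  All-equal scores
    map to 1 everywhere.  Returned series are named ``nPSNR``/``nMSE``/
    ``nMAE`` for the transformed metrics and keep the raw name otherwise.
    """
    s = pd.Series(scores, dtype=float)
    mid = metric_id.upper()
    if mid in INCREASING_METRICS:
        return s.rename(metric_id)
    if mid == "PSNR":
        finite = s[np.isfinite(s)]
        if len(finite) == 0:
            raise ValueError("PSNR scores are all infinite")
        s = s.replace(math.inf, 1.10 * finite.max())
        lo, hi = s.quantile(low_q), s.quantile(high_q)
        s = s.clip(lo, hi)
        if hi == lo:
            return pd.Series(1.0, index=s.index, name="nPSNR")
        return ((s - lo) / (hi - lo)).rename("nPSNR")
    if mid in ("MSE", "MAE"):
        lo, hi = s.quantile(low_q), s.quantile(high_q)
        s = s.clip(lo, hi)
        x_min = s.min()
        if x_min == 0:
            # whole clipped column at zero: perfect similarity everywhere
            return pd.Series(1.0, index=s.index, name=f"n{mid}")
        return (x_min / s).rename(f"n{mid}")
    raise ValueError(f"unknown metric id {metric_id!r}")


def score_images(
    images: dict[str, Image | np.ndarray],
    reference_id: str,
    ssim_mode: str = "windowed",
) -> pd.DataFrame:
    """Score every image against the reference with all five baselines.

    Returns a table indexed by image id with columns SSIM, PSNR, MSE,
    MAE, PCC (raw values; normalise with :func:`normalize_for_ranking`).
    """
    if reference_id not in images:
        raise ValueError(f"reference id {reference_id!r} not in dataset")
    ref = as_image(images[reference_id])
    rows = {}
    for iid, img in images.items():
        img = as_image(img)
        rows[iid] = {
            "SSIM": ssim(img, ref, mode=ssim_mode),
            "PSNR": psnr(img, ref),
            "MSE": mse(img, ref),
            "MAE": mae(img, ref),
            "PCC": pcc(img, ref),
        }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "image_id"
    return df
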