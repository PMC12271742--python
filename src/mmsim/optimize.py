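"""Denoising hyperparameter optimisation and the denoiser sweep harness.

``optimize_gaussian`` implements an early-stopping scan over the standard
deviation of a 2-D Gaussian filter: starting at 0.05 px and stepping by
0.05 px, each iteration smooths the *original* noisy image (filters are
not compounded, so the reported sigma is the actual filter applied),
scores the result against the reference with the monitored metric, and
stops when the relative improvement over the previous iteration falls
within a tolerance of 1e-5 — or after 100 iterations.

``sweep_denoisers`` runs five standard denoisers (average, median,
Gaussian, total-variation, wavelet — all delegated to scipy /
scikit-image) over hyperparameter grids and scores every output with
MMSim and the five baseline metrics, feeding the ranking workflow.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, median_filter, uniform_filter
from skimage.restoration import denoise_tv_chambolle, denoise_wavelet

from mmsim.image import Image, as_image, rescale_unit
from mmsim.markers import MarkerExtractor
from mmsim.metrics import mae, mse, pcc, psnr, ssim
from mmsim.similarity import MMSimScorer, score_dataset

#: Metrics monitored for an increase; MSE and MAE are monitored for a decrease.
_INCREASE = {"MMSIM", "SSIM", "PSNR", "PCC"}
_DECREASE = {"MSE", "MAE"}


@dataclass
class OptimizationTrace:
    """Record of one early-stopping optimisation run.

    ``entries`` holds one row per filtering iteration (iteration, sigma,
    score); the unfiltered input's score is kept separately as
    ``baseline_score`` (conceptually iteration 0 at sigma 0).
    ``best_sigma`` is 0.0 when no filtering improved on the input.
    """

    metric_id: str
    entries: pd.DataFrame
    baseline_score: float
    stop_reason: str
    best_sigma: float
    best_score: float

    @property
    def n_iterations(self) -> int:
        return len(self.entries)


def _gaussian(img: Image, sigma: float) -> Image:
    return img.with_pixels(
        gaussian_filter(img.pixels, sigma=sigma, mode="reflect", truncate=4.0)
    )


def _make_evaluator(
    metric: str, reference: Image | pd.Series, marker_set=None
) -> Callable[[Image], float]:
    """Build a score function image -> metric value vs. the reference."""
    if isinstance(reference, pd.Series):
        if metric != "MMSIM":
            raise ValueError("a reference marker vector is only valid with MMSim")
        ref_vec = reference.copy()
        if ref_vec.name is None:
            ref_vec.name = "reference"

        def evaluate(img: Image) -> float:
            reports = score_dataset(
                [img], ref_vec, marker_set=marker_set, clamp=False
            )
            return reports[0].mmsim

        return evaluate

    ref_img = as_image(reference)
    if metric == "MMSIM":
        extractor = MarkerExtractor(marker_set=marker_set)
        ref_markers = extractor.transform([ref_img]).iloc[0]

        def evaluate(img: Image) -> float:
            m = extractor.transform([img])
            mat = pd.concat([m, ref_markers.to_frame().T])
            scorer = MMSimScorer(clamp=False).fit(mat)
            return scorer.score_reports(mat, reference=str(ref_markers.name))[0].mmsim

        return evaluate

    pixel_metrics = {
        "SSIM": lambda img: ssim(img, ref_img),
        "PSNR": lambda img: psnr(img, ref_img),
        "MSE": lambda img: mse(img, ref_img),
        "MAE": lambda img: mae(img, ref_img),
        "PCC": lambda img: pcc(img, ref_img),
    }
    if metric not in pixel_metrics:
        raise ValueError(f"unknown metric {metric!r}")
    return pixel_metrics[metric]


def optimize_gaussian(
    noisy: Image | np.ndarray,
    reference: Image | np.ndarray | pd.Series | None = None,
    metric: str | Callable[[Image], float] = "MMSIM",
    sigma1: float = 0.05,
    delta_sigma: float = 0.05,
    tol: float = 1e-5,
    max_iter: int = 100,
    marker_set: Sequence[str] | None = None,
) -> tuple[OptimizationTrace, Image]:
    """Early-stopping Gaussian-denoising hyperparameter optimisation.

    Parameters
    ----------
    noisy
        The image to denoise.
    reference
        Ground-truth image, or — with ``metric='MMSIM'`` only — a raw
        reference marker vector (reduced-reference mode).
    metric
        Metric id (``MMSIM``/``SSIM``/``PSNR``/``MSE``/``MAE``/``PCC``)
        or a callable ``image -> score`` monitored for an increase.
    sigma1, delta_sigma
        Standard deviation of the first iteration and per-iteration
        increment, in pixels.
    tol
        Relative-improvement tolerance: the loop stops once the gain over
        the previous iteration is at most ``tol`` times the previous
        value, guarding against small oscillations of the metric.
    max_iter
        Hard iteration cap.

    Returns
    -------
    (trace, best)
        The iteration trace and the best image — the last iterate whose
        score strictly improved, or the unfiltered input if the very
        first filtering step already made the metric worse.
    """
    noisy = as_image(noisy)
    if callable(metric):
        evaluate = metric
        direction = 1.0
        metric_id = getattr(metric, "__name__", "custom")
    else:
        metric_id = metric.upper()
        if metric_id not in _INCREASE | _DECREASE:
            raise ValueError(f"unknown metric {metric!r}")
        if reference is None:
            raise ValueError("a reference is required for built-in metrics")
        evaluate = _make_evaluator(metric_id, reference, marker_set)
        direction = 1.0 if metric_id in _INCREASE else -1.0

    baseline = float(evaluate(noisy))
    prev = baseline
    best_img, best_sigma, best_score = noisy, 0.0, baseline
    rows: list[tuple[int, float, float]] = []
    stop_reason = "max_iterations"
    for t in range(1, max_iter + 1):
        sigma = sigma1 + (t - 1) * delta_sigma
        candidate = _gaussian(noisy, sigma)
        score = float(evaluate(candidate))
        rows.append((t, sigma, score))
        improvement = (score - prev) * direction
        if improvement > 0:
            best_img, best_sigma, best_score = candidate, sigma, score
        if improvement <= tol * abs(prev):
            stop_reason = "converged"
            break
        prev = score
    entries = pd.DataFrame(rows, columns=["iteration", "sigma", "score"])
    trace = OptimizationTrace(
        metric_id=metric_id,
        entries=entries,
        baseline_score=baseline,
        stop_reason=stop_reason,
        best_sigma=best_sigma,
        best_score=best_score,
    )
    return trace, best_img


_DENOISERS: dict[str, Callable[[np.ndarray, float], np.ndarray]] = {
    "average": lambda px, w: uniform_filter(px, size=int(w), mode="reflect"),
    "median": lambda px, w: median_filter(px, size=int(w), mode="reflect"),
    "gaussian": lambda px, s: gaussian_filter(px, sigma=s, mode="reflect", truncate=4.0),
    "total_variation": lambda px, w: denoise_tv_chambolle(px, weight=w),
    "wavelet": lambda px, s: denoise_wavelet(px, sigma=s, rescale_sigma=True),
}


def sweep_denoisers(
    noisy: Image | np.ndarray,
    reference: Image | np.ndarray,
    methods: Mapping[str, Sequence[float]],
    marker_set: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, dict[str, Image]]:
    """Denoise with several methods x hyperparameters and score everything.

    ``methods`` maps a method id (``average``, ``median``, ``gaussian``,
    ``total_variation``, ``wavelet``) to its hyperparameter list: window
    size for average/median, Gaussian sigma, total-variation weight,
    wavelet noise sigma.  Each output is scored against the reference
    with MMSim and the five baselines.

    Returns a score table (rows: denoised outputs plus the reference's
    self-scores; columns: MMSIM, SSIM, PSNR, MSE, MAE, PCC) and the
    denoised images keyed by id ``<method>_<parameter>``.
    """
    unknown = set(methods) - set(_DENOISERS)
    if unknown:
        raise ValueError(f"unknown denoising methods: {sorted(unknown)}")
    noisy = rescale_unit(as_image(noisy))
    ref = rescale_unit(as_image(reference))
    ref_id = ref.image_id or "reference"

    outputs: dict[str, Image] = {}
    for method, params in methods.items():
        for p in params:
            iid = f"{method}_{p:g}"
            px = _DENOISERS[method](noisy.pixels, p)
            outputs[iid] = Image(px, image_id=iid)
    if not outputs:
        return (
            pd.DataFrame(columns=["MMSIM", "SSIM", "PSNR", "MSE", "MAE", "PCC"]),
            outputs,
        )

    all_images = list(outputs.values()) + [
        Image(ref.pixels, ref.background_mask, ref.pixel_size, ref_id)
    ]
    reports = score_dataset(all_images, ref_id, marker_set=marker_set, clamp=False)
    table = pd.DataFrame(index=[img.image_id for img in all_images])
    table["MMSIM"] = [r.mmsim for r in reports]
    for iid in table.index:
        img = outputs.get(iid, ref)
        table.loc[iid, "SSIM"] = ssim(img, ref)
        table.loc[iid, "PSNR"] = psnr(img, ref)
        table.loc[iid, "MSE"] = mse(img, ref)
        table.loc[iid, "MAE"] = mae(img, ref)
        table.loc[iid, "PCC"] = pcc(img, ref)
    table.index.name = "image_id"
    return table, outputs
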