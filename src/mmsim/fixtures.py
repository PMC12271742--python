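"""Synthetic fluorescence-microscopy fixtures with labelled degradations.

Real benchmark data for this problem comes as repeated raw acquisitions
of the same field of view (FOV): noisy images are averages of 1, 2, 4, 8
or 16 raw frames and the ground truth is the average of 50, while
defocus series sample several focal positions around the optimal plane.
This module emulates those constructions so every part of the package is
testable without downloads: structured fluorescence-like content
(filaments, blobs, nuclei), mixed Poisson-Gaussian noise whose level is
controlled by the number of averaged realisations, Gaussian defocus
blur, additive intensity offsets, and radial vignetting.

Everything is fully deterministic under ``(seed, parameters)``; no global
random state is touched.  What the generator does *not* emulate: a
physical point-spread function, optical sectioning, detector artefacts
beyond additive read noise, or sample motion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from mmsim.image import Image, as_image, save_image

#: Default peak photon count of the brightest structure at n_averaged=1.
DEFAULT_PEAK_PHOTONS = 50.0
#: Default additive Gaussian read-noise standard deviation (intensity units).
DEFAULT_READ_SIGMA = 0.02
#: Averaging levels of the emulated noise-series construction.
DEFAULT_LEVELS = (1, 2, 4, 8, 16, 50)
#: Blur magnitudes (px) standing in for focal steps of 0, 1, 2, 3 units.
DEFOCUS_SIGMA_PER_STEP = 1.0


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one synthetic image: structure plus ordered degradations.

    ``degradations`` is a list of ``(kind, params)`` pairs with kind in
    ``{"poisson_gaussian", "defocus_blur", "offset", "vignetting"}``.
    Identical specs produce bit-identical images.
    """

    structure: str = "blobs"
    size: tuple[int, int] = (128, 128)
    seed: int = 0
    degradations: tuple[tuple[str, dict], ...] = ()


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def _blobs(size, rng, n_objects) -> np.ndarray:
    nr, nc = size
    img = np.zeros(size)
    y, x = np.mgrid[0:nr, 0:nc]
    for _ in range(n_objects):
        cy, cx = rng.uniform(0, nr), rng.uniform(0, nc)
        sig = rng.uniform(2.0, 0.08 * min(size))
        amp = rng.uniform(0.3, 1.0)
        img += amp * np.exp(-((y - cy) ** 2 + (x - cx) ** 2) / (2 * sig**2))
    return img


def _filaments(size, rng, n_objects) -> np.ndarray:
    nr, nc = size
    img = np.zeros(size)
    n_steps = 4 * max(size)
    for _ in range(n_objects):
        py, px = rng.uniform(0, nr), rng.uniform(0, nc)
        angle = rng.uniform(0, 2 * np.pi)
        amp = rng.uniform(0.4, 1.0)
        for _ in range(n_steps):
            angle += rng.normal(0, 0.15)
            py += np.sin(angle)
            px += np.cos(angle)
            iy, ix = int(round(py)), int(round(px))
            if 0 <= iy < nr and 0 <= ix < nc:
                img[iy, ix] += amp
    return gaussian_filter(img, 1.2)  # Gaussian cross-section


def _nuclei(size, rng, n_objects) -> np.ndarray:
    # narrow size/amplitude ranges: FOVs of one stained sample are
    # morphologically homogeneous, which reduced-reference scoring relies on
    nr, nc = size
    img = np.zeros(size)
    y, x = np.mgrid[0:nr, 0:nc]
    for _ in range(n_objects):
        cy, cx = rng.uniform(0.1 * nr, 0.9 * nr), rng.uniform(0.1 * nc, 0.9 * nc)
        a = rng.uniform(0.08, 0.12) * min(size)
        b = a * rng.uniform(0.75, 1.0)
        theta = rng.uniform(0, np.pi)
        amp = rng.uniform(0.7, 1.0)
        dy, dx = y - cy, x - cx
        u = dy * np.cos(theta) + dx * np.sin(theta)
        v = -dy * np.sin(theta) + dx * np.cos(theta)
        d2 = (u / a) ** 2 + (v / b) ** 2
        img += amp * np.clip(1.0 - d2, 0.0, None) ** 0.5
    # chromatin-like fine texture; defocus blur is what removes it
    tex = gaussian_filter(rng.normal(0.0, 1.0, size), 0.8)
    tex = tex / np.abs(tex).max()
    return np.clip(img * (1.0 + 0.4 * tex), 0.0, None)


_STRUCTURES = {"blobs": _blobs, "filaments": _filaments, "nuclei": _nuclei}


def generate_structure(
    spec: FixtureSpec | None = None,
    structure: str = "blobs",
    size: tuple[int, int] = (128, 128),
    seed: int = 0,
    n_objects: int | None = None,
) -> Image:
    """Generate a clean, noise-free structure image with values in [0, 1]."""
    if spec is not None:
        structure, size, seed = spec.structure, spec.size, spec.seed
    if structure not in _STRUCTURES:
        raise ValueError(f"unknown structure kind {structure!r}")
    rng = _rng(seed)
    if n_objects is None:
        # object density scales with area; fixed per structure family
        area = size[0] * size[1]
        n_objects = {"blobs": max(1, area // 1300), "filaments": max(1, area // 2700), "nuclei": max(1, area // 2000)}[structure]
    img = _STRUCTURES[structure](size, rng, n_objects)
    peak = img.max()
    if peak > 0:
        img = img / peak
    return Image(img, image_id=f"{structure}_s{seed}")


def apply_poisson_gaussian(
    img: Image | np.ndarray,
    peak_photons: float = DEFAULT_PEAK_PHOTONS,
    read_sigma: float = DEFAULT_READ_SIGMA,
    n_averaged: int = 1,
    seed: int = 0,
    clip: bool = False,
) -> Image:
    """Mixed Poisson-Gaussian noise, averaged over independent realisations.

    Each realisation draws ``Poisson(peak_photons * s) / peak_photons``
    shot noise plus additive ``Normal(0, read_sigma)`` read noise; the
    returned image is the mean of ``n_averaged`` realisations, so its
    noise variance scales as ``1 / n_averaged`` — the construction used
    to produce graded noise levels from repeated raw acquisitions.
    ``clip=True`` additionally saturates each realisation to [0, 1],
    emulating a detector with a bounded dynamic range.
    """
    img = as_image(img)
    if peak_photons <= 0:
        raise ValueError("peak_photons must be positive")
    if n_averaged < 1:
        raise ValueError("n_averaged must be >= 1")
    rng = _rng(seed)
    clean = np.clip(img.pixels, 0.0, None)
    acc = np.zeros_like(clean)
    for _ in range(n_averaged):
        shot = rng.poisson(peak_photons * clean) / peak_photons
        real = shot + rng.normal(0.0, read_sigma, size=clean.shape)
        if clip:
            real = np.clip(real, 0.0, 1.0)
        acc += real
    return img.with_pixels(acc / n_averaged)


def apply_defocus(img: Image | np.ndarray, blur_sigma: float) -> Image:
    """Symmetric defocus model: isotropic Gaussian blur of ``blur_sigma`` px."""
    img = as_image(img)
    if blur_sigma < 0:
        raise ValueError("blur_sigma must be non-negative")
    if blur_sigma == 0:
        return img
    return img.with_pixels(gaussian_filter(img.pixels, blur_sigma, mode="reflect"))


def apply_offset(img: Image | np.ndarray, offset: float) -> Image:
    """Constant additive intensity offset."""
    img = as_image(img)
    return img.with_pixels(img.pixels + offset)


def apply_vignetting(img: Image | np.ndarray, strength: float) -> Image:
    """Radial multiplicative falloff ``1 - strength * (r / r_max)^2``."""
    img = as_image(img)
    if strength < 0:
        raise ValueError("strength must be non-negative")
    nr, nc = img.pixels.shape
    y = np.arange(nr) - (nr - 1) / 2.0
    x = np.arange(nc) - (nc - 1) / 2.0
    r = np.hypot(y[:, None], x[None, :])
    r_max = r.max()
    falloff = 1.0 - strength * (r / r_max) ** 2
    return img.with_pixels(img.pixels * falloff)


def generate(spec: FixtureSpec) -> Image:
    """Generate a structure and apply the spec's degradations in order."""
    img = generate_structure(spec)
    for kind, params in spec.degradations:
        if kind == "poisson_gaussian":
            img = apply_poisson_gaussian(img, **params)
        elif kind == "defocus_blur":
            img = apply_defocus(img, **params)
        elif kind == "offset":
            img = apply_offset(img, **params)
        elif kind == "vignetting":
            img = apply_vignetting(img, **params)
        else:
            raise ValueError(f"unknown degradation kind {kind!r}")
    return img


def make_fov_series(
    n_fovs: int = 5,
    levels: Sequence[int] = DEFAULT_LEVELS,
    base_seed: int = 0,
    size: tuple[int, int] = (96, 96),
    structure: str = "filaments",
    peak_photons: float = DEFAULT_PEAK_PHOTONS,
    read_sigma: float = DEFAULT_READ_SIGMA,
) -> tuple[list[Image], pd.DataFrame]:
    """Noise series: ``n_fovs`` structures x ``levels`` averaging counts.

    Emulates a denoising benchmark layout: each FOV is a distinct
    structure (different seed, same morphology family) measured at every
    averaging level.  The highest level of FOV 1 is flagged as the
    reduced-reference ground truth.

    Returns the images and a manifest with columns ``fov``,
    ``n_averaged``, ``seed`` and ``is_reference``, indexed by image id.
    """
    if n_fovs < 2:
        raise ValueError("need at least 2 FOVs")
    images: list[Image] = []
    records = []
    ref_level = max(levels)
    for fov in range(1, n_fovs + 1):
        clean = generate_structure(
            structure=structure, size=size, seed=base_seed + 7919 * fov
        )
        for li, n in enumerate(levels):
            noise_seed = base_seed + 104729 * fov + 13 * li + 1
            noisy = apply_poisson_gaussian(
                clean,
                peak_photons=peak_photons,
                read_sigma=read_sigma,
                n_averaged=int(n),
                seed=noise_seed,
            )
            iid = f"fov{fov:02d}_n{int(n):03d}"
            images.append(Image(noisy.pixels, image_id=iid))
            records.append(
                {
                    "image_id": iid,
                    "fov": fov,
                    "n_averaged": int(n),
                    "seed": noise_seed,
                    "is_reference": fov == 1 and n == ref_level,
                }
            )
    manifest = pd.DataFrame(records).set_index("image_id")
    return images, manifest


def make_defocus_series(
    n_fovs: int = 11,
    offsets: Sequence[int] = (-3, -2, -1, 0, 1, 2, 3),
    base_seed: int = 0,
    size: tuple[int, int] = (128, 128),
    structure: str = "nuclei",
    sigma_per_step: float = DEFOCUS_SIGMA_PER_STEP,
    n_averaged: int = 16,
    peak_photons: float = 200.0,
    read_sigma: float = DEFAULT_READ_SIGMA,
) -> tuple[list[Image], pd.DataFrame]:
    """Defocus grid: ``n_fovs`` structures x signed focal offsets.

    Each focal position is an independent acquisition of the FOV blurred
    by ``sigma_per_step * |offset|`` px (a symmetric defocus model) with
    its own noise realisation.  Position 0 of FOV 1 is flagged as the
    reduced-reference ground truth.
    """
    images: list[Image] = []
    records = []
    for fov in range(1, n_fovs + 1):
        clean = generate_structure(
            structure=structure, size=size, seed=base_seed + 6133 * fov
        )
        for oi, off in enumerate(offsets):
            blurred = apply_defocus(clean, sigma_per_step * abs(off))
            noise_seed = base_seed + 15485863 * fov + 101 * oi + 3
            noisy = apply_poisson_gaussian(
                blurred,
                peak_photons=peak_photons,
                read_sigma=read_sigma,
                n_averaged=n_averaged,
                seed=noise_seed,
            )
            iid = f"fov{fov:02d}_z{off:+d}"
            images.append(Image(noisy.pixels, image_id=iid))
            records.append(
                {
                    "image_id": iid,
                    "fov": fov,
                    "defocus_offset": int(off),
                    "seed": noise_seed,
                    "is_reference": fov == 1 and off == 0,
                }
            )
    manifest = pd.DataFrame(records).set_index("image_id")
    return images, manifest


def write_dataset(
    images: Sequence[Image], manifest: pd.DataFrame, out_dir: str | Path
) -> Path:
    """Write a fixture dataset as TIFFs plus a CSV manifest; returns the CSV path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for img in images:
        save_image(img, out / f"{img.image_id}.tif")
    manifest_path = out / "manifest.csv"
    manifest.to_csv(manifest_path)
    return manifest_path
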