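"""Parametric grayscale stimulus families and luminance equalization.

Real action photographs cannot ship with the package, so each "action"
is a parametric texture family: a Gabor-like windowed grating whose
orientation, spatial frequency and window position identify the family.
Exemplars are jittered instances (phase, position, orientation). At low
jitter the families are separable by C1 features — the property the
image-based control model needs — while sharing global luminance
statistics, which the equalization step then matches exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["ImageFamilyParams", "make_synthetic_images", "normalize_luminance"]


@dataclass(frozen=True)
class ImageFamilyParams:
    contrast: float = 60.0          # grating amplitude in intensity units
    freq_lo: float = 0.05           # cycles / pixel across families
    freq_hi: float = 0.15
    window_sd_frac: float = 0.25    # Gaussian window sd as fraction of min(h, w)
    jitter: float = 0.05            # exemplar jitter scale (0 = identical)


def make_synthetic_images(
    n_actions: int = 28,
    n_exemplars: int = 12,
    size: tuple[int, int] = (96, 128),
    family_params: ImageFamilyParams | None = None,
    seed: int = 0,
) -> np.ndarray:
    """(n_actions, n_exemplars, h, w) float stack with values in [0, 255].

    Family k has orientation ``k * 180 / n_actions`` degrees, a frequency
    on a fixed grid, and a family-specific window center. Exemplar jitter
    perturbs orientation (radians), phase and window position in
    proportion to ``family_params.jitter``.
    """
    h, w = size
    if h < 64 or w < 64:
        raise ValueError("image size must be at least 64x64")
    p = family_params or ImageFamilyParams()
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    thetas = np.pi * np.arange(n_actions) / n_actions
    freqs = np.linspace(p.freq_lo, p.freq_hi, n_actions)[rng.permutation(n_actions)]
    centers = np.stack([
        h * (0.3 + 0.4 * rng.random(n_actions)),
        w * (0.3 + 0.4 * rng.random(n_actions)),
    ], axis=1)
    win_sd = p.window_sd_frac * min(h, w)

    stack = np.empty((n_actions, n_exemplars, h, w))
    for a in range(n_actions):
        for e in range(n_exemplars):
            th = thetas[a] + p.jitter * rng.normal()
            phase = 2 * np.pi * p.jitter * rng.normal()
            cy = centers[a, 0] + p.jitter * win_sd * rng.normal()
            cx = centers[a, 1] + p.jitter * win_sd * rng.normal()
            carrier = np.sin(
                2 * np.pi * freqs[a] * (xx * np.cos(th) + yy * np.sin(th)) + phase
            )
            window = np.exp(-(((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * win_sd ** 2)))
            img = 127.5 + p.contrast * window * carrier
            stack[a, e] = np.clip(img, 0.0, 255.0)
    return stack


def normalize_luminance(
    images: np.ndarray,
    target_mean: float = 115.80,
    tol: float = 0.5,
    max_iter: int = 50,
) -> tuple[np.ndarray, dict]:
    """Shift each image additively so its mean intensity hits the target.

    Clipping to [0, 255] can eat part of the shift, so the shift is
    iterated until the clipped mean is within ``tol`` of the target or no
    further progress is possible (then a warning is raised). Returns the
    adjusted stack and a report with achieved means and per-image clipped
    pixel fractions.
    """
    imgs = np.asarray(images, dtype=float)
    flat = imgs.reshape(-1, *imgs.shape[-2:])
    out = np.empty_like(flat)
    means = np.empty(len(flat))
    clip_frac = np.empty(len(flat))
    unattained = []
    for i, img in enumerate(flat):
        cur = img.copy()
        for _ in range(max_iter):
            delta = target_mean - cur.mean()
            if abs(delta) <= tol:
                break
            cur = np.clip(cur + delta, 0.0, 255.0)
        achieved = cur.mean()
        if abs(achieved - target_mean) > tol:
            unattained.append(i)
        out[i] = cur
        means[i] = achieved
        clip_frac[i] = np.mean((cur <= 0.0) | (cur >= 255.0))
    if unattained:
        warnings.warn(
            f"luminance target {target_mean} unattainable for "
            f"{len(unattained)} image(s) (saturation)", RuntimeWarning
        )
    report = {
        "target_mean": target_mean,
        "means": means.reshape(imgs.shape[:-2]),
        "mean_of_means": float(means.mean()),
        "sd_of_means": float(means.std(ddof=1)) if len(means) > 1 else 0.0,
        "clip_fraction": clip_frac.reshape(imgs.shape[:-2]),
        "unattained": unattained,
    }
    return out.reshape(imgs.shape), report
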