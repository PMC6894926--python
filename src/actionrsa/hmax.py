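"""HMAX C1 features: Gabor filtering with local max pooling.

The C1 layer of the HMAX vision model serves as a low-level image
control model for RSA: S1 units are zero-mean, unit-norm Gabor filters
at several orientations and scales; C1 units take the maximum S1
response over a local spatial pool and over the two adjacent scales of a
band, giving tolerance to small shifts and scalings. The default
configuration is a reduced two-band version (Gabor sizes 7/9 and 11/13,
pooling grids 8 and 10 with 50% overlap) suitable for 128x96 images.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import correlate

from .rdm import RDM, normalize_rdm, squared_euclidean_rdm

__all__ = ["C1Params", "gabor_filter", "c1_features", "hmax_rdm"]


@dataclass(frozen=True)
class C1Params:
    n_orientations: int = 4
    #: per band, the two Gabor side lengths whose responses are max-pooled
    gabor_sizes: tuple[tuple[int, int], ...] = ((7, 9), (11, 13))
    #: per band, the side of the spatial max pool (stride = half the side)
    pool_sizes: tuple[int, ...] = (8, 10)
    aspect_ratio: float = 0.3

    def __post_init__(self):
        if len(self.gabor_sizes) != len(self.pool_sizes):
            raise ValueError("one pool size per band required")
        if len(self.gabor_sizes) < 1:
            raise ValueError("need at least one band")
        for pool, sizes in zip(self.pool_sizes, self.gabor_sizes):
            if pool <= 1:
                raise ValueError("pooling size must exceed the unit stride")

    @property
    def n_bands(self) -> int:
        return len(self.gabor_sizes)

    @property
    def orientations_rad(self) -> np.ndarray:
        return np.pi * np.arange(self.n_orientations) / self.n_orientations


def gabor_filter(size: int, theta: float, aspect_ratio: float = 0.3) -> np.ndarray:
    """Zero-mean, unit-norm Gabor of the given side length and orientation.

    Sigma and wavelength follow the standard HMAX size-dependent
    parameterization: sigma = 0.0036 s^2 + 0.35 s + 0.18, lambda = sigma / 0.8.
    """
    sigma = 0.0036 * size ** 2 + 0.35 * size + 0.18
    lam = sigma / 0.8
    half = size // 2
    y, x = np.mgrid[-half:half + 1, -half:half + 1].astype(float)
    xr = x * np.cos(theta) + y * np.sin(theta)
    yr = -x * np.sin(theta) + y * np.cos(theta)
    g = np.exp(-(xr ** 2 + (aspect_ratio * yr) ** 2) / (2 * sigma ** 2)) \
        * np.cos(2 * np.pi * xr / lam)
    g -= g.mean()
    norm = np.linalg.norm(g)
    return g / norm if norm > 0 else g


def _pool_grid(resp: np.ndarray, pool: int) -> np.ndarray:
    """Local max over pool x pool windows with 50% overlap (stride pool//2)."""
    stride = max(pool // 2, 1)
    h, w = resp.shape
    rows = range(0, max(h - pool, 0) + 1, stride)
    cols = range(0, max(w - pool, 0) + 1, stride)
    out = np.empty((len(list(rows)), len(list(cols))))
    for i, r in enumerate(range(0, max(h - pool, 0) + 1, stride)):
        for j, c in enumerate(range(0, max(w - pool, 0) + 1, stride)):
            out[i, j] = resp[r:r + pool, c:c + pool].max()
    return out


def c1_features(image: np.ndarray, params: C1Params | None = None) -> np.ndarray:
    """Flattened C1 vector in (band, orientation, grid-row, grid-col) order.

    S1 responses are the absolute values of the Gabor correlations
    (half-wave rectified magnitude); C1 takes the max over the two scales
    within a band and over the local spatial pool.
    """
    p = params or C1Params()
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("c1_features expects a single grayscale image")
    max_size = max(s for band in p.gabor_sizes for s in band)
    if min(img.shape) < max_size:
        raise ValueError(f"image smaller than the largest Gabor ({max_size})")
    chunks = []
    for band_sizes, pool in zip(p.gabor_sizes, p.pool_sizes):
        for theta in p.orientations_rad:
            scale_resp = []
            for size in band_sizes:
                g = gabor_filter(size, theta, p.aspect_ratio)
                # reflect boundary keeps zero-mean filters blind to constants
                resp = np.abs(correlate(img, g, mode="reflect"))
                scale_resp.append(resp)
            band_max = np.maximum(*scale_resp) if len(scale_resp) > 1 \
                else scale_resp[0]
            chunks.append(_pool_grid(band_max, pool).ravel())
    return np.concatenate(chunks)


def hmax_rdm(
    action_images: np.ndarray | dict[str, np.ndarray],
    params: C1Params | None = None,
    metric: str = "correlation",
) -> RDM:
    """Model RDM from per-action mean C1 vectors.

    action_images : (n_actions, n_exemplars, h, w) array or mapping
        label -> (n_exemplars, h, w) stack.
    metric : {'correlation', 'sqeuclidean'}
        'correlation' (default) uses 1 - Pearson between action vectors.
    The result is max-normalized like every other model RDM.
    """
    if isinstance(action_images, dict):
        labels = tuple(action_images)
        stacks = [np.asarray(action_images[k], dtype=float) for k in labels]
    else:
        arr = np.asarray(action_images, dtype=float)
        labels = tuple(f"action{i:02d}" for i in range(arr.shape[0]))
        stacks = [arr[i] for i in range(arr.shape[0])]
    vecs = []
    for label, stack in zip(labels, stacks):
        if stack.ndim != 3 or stack.shape[0] < 1:
            raise ValueError(f"{label}: need a (n_exemplars, h, w) stack")
        feats = np.stack([c1_features(img, params) for img in stack])
        vecs.append(feats.mean(axis=0))
    v = np.stack(vecs)
    meta = {"model": "hmax_c1", "metric": metric}
    if metric == "sqeuclidean":
        return normalize_rdm(squared_euclidean_rdm(v, labels, meta))
    if metric != "correlation":
        raise ValueError(f"unknown metric {metric!r}")
    sd = v.std(axis=1)
    if np.any(sd == 0):
        bad = [labels[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"zero-variance C1 vector for {bad} (degenerate image)")
    d = 1.0 - np.corrcoef(v)
    np.fill_diagonal(d, 0.0)
    d[d < 0] = 0.0  # guard tiny negative rounding on near-identical actions
    return normalize_rdm(RDM(labels, (d + d.T) / 2, meta))
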