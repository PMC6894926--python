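"""Plant representational structure into synthetic cortical data.

For each labeled region of a toy surface, condition patterns are
constructed so that the region's squared-Euclidean RDM equals a chosen
non-negative linear mixture of model RDMs exactly at zero noise. Each
model gets a disjoint block of the region's vertices carrying a
coordinate embedding of (weight x model RDM) read as squared distances;
because squared Euclidean distance is additive over disjoint feature
blocks, the blocks sum to the planted mixture. Background vertices carry
pure noise. This is the ground-truth generator the whole searchlight /
group-inference stack is validated against.
"""

from __future__ import annotations

import numpy as np

from .models import ModelSet
from .rdm import RDM
from .searchlight import BetaDataset
from .surface import SurfaceMesh

__all__ = ["embed_rdm_as_patterns", "plant_brain_patterns"]


def embed_rdm_as_patterns(rdm: RDM, weight: float = 1.0,
                          tol: float = 1e-8,
                          on_negative: str = "error") -> np.ndarray:
    """Coordinates whose squared-Euclidean RDM equals ``weight * rdm``.

    Torgerson embedding of the entries read as squared distances. Model
    RDMs built from Euclidean, absolute-difference, binary or
    correlation distances are all of negative type, so the embedding is
    exact up to numerical tolerance. Substantial negative eigenvalue
    mass means the RDM cannot be realized exactly; with
    ``on_negative='error'`` (default) that is raised, with ``'clip'``
    the negative part is dropped and the embedding is the closest
    realizable approximation.
    """
    s = weight * rdm.values
    n = len(s)
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ s @ j
    vals, vecs = np.linalg.eigh(b)
    neg = vals[vals < 0]
    if neg.size and -neg.min() > tol * max(vals.max(), 1.0) * 100:
        if on_negative == "error":
            raise ValueError(
                f"RDM is not embeddable as squared distances "
                f"(negative eigenvalue {neg.min():.3g}); pass "
                f"on_negative='clip' to accept the nearest embeddable RDM"
            )
        if on_negative != "clip":
            raise ValueError(f"unknown on_negative mode {on_negative!r}")
    keep = vals > tol * max(vals.max(), 1.0)
    coords = vecs[:, keep] * np.sqrt(vals[keep])
    return coords[:, ::-1]  # largest component first


def plant_brain_patterns(
    surface: SurfaceMesh,
    model_set: ModelSet,
    region_weights: dict[int, dict[str, float]],
    n_subjects: int = 20,
    n_runs: int = 12,
    noise_sd: float = 0.0,
    seed: int = 0,
    on_negative: str = "error",
) -> list[BetaDataset]:
    """Per-subject BetaDatasets with planted model mixtures per region.

    region_weights maps a region id (>=1 in the surface's region_map) to
    ``{model_name: weight}`` with non-negative weights. The planted
    signal is identical across runs and subjects; measurement noise is
    i.i.d. Gaussian per run, subject and vertex with sd ``noise_sd``.
    """
    n_cond = len(model_set.items)
    m = surface.n_vertices
    rng = np.random.default_rng(seed)
    base = np.zeros((n_cond, m))
    for region, weights in region_weights.items():
        verts = surface.region_vertices(region)
        if len(verts) == 0:
            raise ValueError(f"region {region} not present on the surface")
        blocks = []
        for name, w in weights.items():
            if w < 0:
                raise ValueError(f"negative weight for model {name!r}")
            if name not in model_set.names:
                raise ValueError(f"unknown model {name!r} in region_weights")
            if w == 0:
                continue
            blocks.append(embed_rdm_as_patterns(model_set[name], w,
                                                on_negative=on_negative))
        total = sum(b.shape[1] for b in blocks)
        if total > len(verts):
            raise ValueError(
                f"region {region} has {len(verts)} vertices but the "
                f"requested mixture needs {total} feature columns"
            )
        # share the region's vertices among the blocks proportionally to
        # their embedding dimensions, then spread each block's energy over
        # its whole vertex share with a random orthonormal map (squared
        # Euclidean distances are invariant to it), so every region vertex
        # carries signal
        dims = np.array([b.shape[1] for b in blocks])
        shares = dims.copy()
        spare = len(verts) - dims.sum()
        while spare > 0:
            for i in range(len(shares)):
                if spare == 0:
                    break
                shares[i] += 1
                spare -= 1
        col = 0
        for b, share in zip(blocks, shares):
            q, _ = np.linalg.qr(rng.normal(size=(share, b.shape[1])))
            base[:, verts[col:col + share]] = b @ q.T
            col += share
    datasets = []
    for s in range(n_subjects):
        noise = rng.normal(0.0, noise_sd, size=(n_runs, n_cond, m)) \
            if noise_sd > 0 else 0.0
        betas = np.broadcast_to(base, (n_runs, n_cond, m)).copy() + noise
        datasets.append(BetaDataset(f"sub{s + 1:02d}", betas,
                                    model_set.items, surface))
    return datasets
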