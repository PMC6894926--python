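"""Planted latent semantic structure for synthetic cohorts.

The behavioral finding this emulates is a clustered organization of
action concepts: items fall into a small number of semantic clusters
(six, for 28 actions, in the reference design). Ground truth is a latent
coordinate configuration with isotropic Gaussian cluster centers and
within-cluster scatter; its normalized Euclidean RDM is the quantity all
recovery experiments are scored against.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .rdm import RDM, euclidean_rdm, normalize_rdm

__all__ = ["GroundTruth", "make_ground_truth"]


@dataclass(frozen=True)
class GroundTruth:
    n_items: int
    latent_coords: np.ndarray        # (n, dim)
    cluster_labels: np.ndarray       # (n,) int in 0..n_clusters-1
    true_rdm: RDM                    # normalized euclidean RDM of latent_coords

    @property
    def n_clusters(self) -> int:
        return int(self.cluster_labels.max()) + 1

    @property
    def items(self) -> tuple[str, ...]:
        return self.true_rdm.items


def _draw_separated_centers(rng: np.random.Generator, n_clusters: int,
                            spread: float, dim: int, min_dist: float,
                            max_tries: int = 10_000) -> np.ndarray:
    """Isotropic-normal centers, redrawn until pairwise >= min_dist apart."""
    for _ in range(max_tries):
        centers = rng.normal(0.0, spread, size=(n_clusters, dim))
        if n_clusters == 1:
            return centers
        d = np.linalg.norm(centers[:, None] - centers[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        if d.min() >= min_dist:
            return centers
    raise ValueError(
        "could not place cluster centers with the requested separation; "
        "increase cluster_spread or lower min_separation"
    )


def make_ground_truth(
    n_items: int = 28,
    n_clusters: int = 6,
    cluster_spread: float = 5.0,
    within_spread: float = 1.0,
    dim: int = 2,
    seed: int = 0,
    min_separation: float = 5.0,
) -> GroundTruth:
    """Draw clustered latent coordinates and their true RDM.

    Cluster centers are isotropic-normal with sd ``cluster_spread``,
    redrawn until every pair of centers is at least
    ``min_separation * within_spread`` apart (the separation ratio that
    controls how recoverable the planted K is); items scatter around
    their center with sd ``within_spread`` and are assigned to clusters
    round-robin, so every cluster is non-empty.
    """
    if n_clusters > n_items:
        raise ValueError("n_clusters cannot exceed n_items")
    if n_clusters < 1 or cluster_spread <= 0 or within_spread < 0:
        raise ValueError("need n_clusters >= 1 and positive spreads")
    rng = np.random.default_rng(seed)
    centers = _draw_separated_centers(rng, n_clusters, cluster_spread, dim,
                                      min_separation * within_spread)
    labels = np.arange(n_items) % n_clusters
    coords = centers[labels] + rng.normal(0.0, within_spread, size=(n_items, dim))
    items = tuple(f"action{i:02d}" for i in range(n_items))
    true = normalize_rdm(euclidean_rdm(coords, items, {"task": "ground_truth"}))
    return GroundTruth(n_items, coords, labels, true)
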