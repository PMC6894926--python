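"""End-to-end validation experiments on synthetic cohorts.

These are the package's own benchmark experiments: exact recovery of
planted regression mixtures, detection of a planted semantic region
through the full searchlight + cluster-permutation stack, family-wise
error calibration on null cohorts, and recovery of the planted cluster
count by silhouette analysis. They are what passing results do and do
not show about real data — see the methods note for that discussion.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .ground_truth import make_ground_truth
from .inference import cluster_permutation
from .models import ModelSet
from .patterns import plant_brain_patterns
from .searchlight import (Searchlight, StatMap, build_searchlights,
                          regression_rsa_map, standard_rsa_map)
from .characterize import silhouette_select_k
from .surface import make_toy_surface

__all__ = ["regression_mixture_recovery", "region_recovery_experiment",
           "fwer_experiment", "clustering_recovery_experiment"]


def regression_mixture_recovery(weights=(2.0, 3.0), seed: int = 0) -> dict:
    """Plant a noiseless two-model mixture; recover weights by OLS.

    Returns the recovered coefficients and their maximum relative error
    against the planted weights — the oracle for the whole
    multiple-regression RSA stack (exact because squared Euclidean
    distance is additive over disjoint feature blocks).
    """
    gt1 = make_ground_truth(seed=seed + 1)
    gt2 = make_ground_truth(seed=seed + 2)
    models = ModelSet({"semantic": gt1.true_rdm.copy(model="semantic"),
                       "body": gt2.true_rdm.copy(model="body")})
    mesh = make_toy_surface(3, n_regions=1, region_size=80, seed=seed)
    ds = plant_brain_patterns(mesh, models,
                              {1: {"semantic": weights[0],
                                   "body": weights[1]}},
                              n_subjects=1, n_runs=2, noise_sd=0.0,
                              seed=seed)[0]
    verts = mesh.region_vertices(1)
    roi = Searchlight(int(verts[0]), tuple(int(v) for v in verts))
    maps = regression_rsa_map(ds, models, [roi], mode="raw")
    got = np.array([maps["semantic"].values[roi.center],
                    maps["body"].values[roi.center]])
    rel_err = np.max(np.abs(got - np.asarray(weights)) / np.asarray(weights))
    return {"planted": tuple(weights), "recovered": tuple(got),
            "max_rel_error": float(rel_err)}


def region_recovery_experiment(
    n_seeds: int = 20,
    n_subjects: int = 20,
    noise_sd: float = 0.4,
    n_perm: int = 1000,
    subdivisions: int = 3,
    region_size: int = 80,
    searchlight_features: int = 10,
    n_runs: int = 12,
    base_seed: int = 0,
) -> pd.DataFrame:
    """Detect a planted semantic region with cluster-corrected group RSA.

    Per seed: plant the semantic geometry in one region, simulate a
    cohort at a noise level giving per-subject in-region map r of about
    0.1-0.3, run the standard searchlight RSA and the cluster-based
    permutation correction, and score the significant clusters against
    the planted region (Dice overlap of region-overlapping clusters;
    count of significant clusters touching no region vertex).
    """
    gt = make_ground_truth(seed=base_seed + 1)
    models = ModelSet({"semantic": gt.true_rdm.copy(model="semantic")})
    rows = []
    for k in range(n_seeds):
        seed = base_seed + k
        mesh = make_toy_surface(subdivisions, n_regions=1,
                                region_size=region_size, seed=seed)
        region = set(mesh.region_vertices(1).tolist())
        sls = build_searchlights(mesh, searchlight_features)
        cohort = plant_brain_patterns(mesh, models, {1: {"semantic": 1.0}},
                                      n_subjects=n_subjects, n_runs=n_runs,
                                      noise_sd=noise_sd, seed=seed * 7 + 1)
        maps = [standard_rsa_map(d, models["semantic"], sls) for d in cohort]
        r_in = float(np.mean([np.nanmean([m.values[v] for v in region])
                              for m in maps]))
        result = cluster_permutation(maps, mesh, n_perm=n_perm,
                                     seed=seed + 3)
        sig = result.significant_clusters
        true_pos = [c for c in sig if set(c.vertices.tolist()) & region]
        false_pos = [c for c in sig if not set(c.vertices.tolist()) & region]
        if true_pos:
            covered = set(np.concatenate([c.vertices for c in true_pos])
                          .tolist())
            dice = 2 * len(covered & region) / (len(covered) + len(region))
        else:
            dice = 0.0
        rows.append({"seed": seed, "mean_in_region_r": r_in, "dice": dice,
                     "n_false_positive_clusters": len(false_pos)})
    return pd.DataFrame(rows)


def fwer_experiment(
    n_cohorts: int = 200,
    n_subjects: int = 12,
    n_perm: int = 500,
    subdivisions: int = 2,
    seed: int = 0,
) -> float:
    """Family-wise error rate of the cluster permutation test under the null.

    Each cohort's subject maps are i.i.d. standard normal per vertex; a
    family-wise error is any significant cluster (z > 1.65). With the
    test calibrated at 5%, the returned rate should sit inside the
    binomial confidence band around 0.05.
    """
    mesh = make_toy_surface(subdivisions, n_regions=1, region_size=10,
                            seed=seed)
    rng = np.random.default_rng(seed)
    n_fp = 0
    for c in range(n_cohorts):
        maps = [StatMap(rng.normal(size=mesh.n_vertices))
                for _ in range(n_subjects)]
        res = cluster_permutation(maps, mesh, n_perm=n_perm,
                                  transform="none", seed=seed + 1000 + c)
        n_fp += bool(res.significant_clusters)
    return n_fp / n_cohorts


def clustering_recovery_experiment(
    n_seeds: int = 50,
    n_items: int = 28,
    n_clusters: int = 6,
    separation: float = 8.0,
    n_restarts: int = 100,
    base_seed: int = 0,
) -> float:
    """Fraction of high-separation cohorts whose silhouette-optimal K
    equals the planted cluster count."""
    hits = 0
    for k in range(n_seeds):
        gt = make_ground_truth(n_items, n_clusters, cluster_spread=5.0,
                               within_spread=0.6, seed=base_seed + k,
                               min_separation=separation)
        best, _, _ = silhouette_select_k(gt.latent_coords, (2, 10),
                                         n_restarts=n_restarts,
                                         seed=base_seed + k)
        hits += (best == n_clusters)
    return hits / n_seeds
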