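"""Group-level inference on vertex maps.

Subject maps (correlations or regression coefficients) are optionally
Fisher transformed, tested against zero with a one-tailed one-sample
t-test per vertex, and corrected for multiple comparisons with a
cluster-based Monte-Carlo permutation test: supra-threshold vertices
(uncorrected p below an initial threshold, default 0.001) are grouped
into edge-connected clusters scored by their mass (sum of t, the
"max sum" statistic); the null distribution of the maximum cluster mass
is built by randomly sign-flipping each subject's map; corrected
p-values are converted to z, and z > 1.65 (one-tailed 0.05) is the
significance criterion. Benjamini-Hochberg FDR is provided for the
behavioral tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse, stats
from statsmodels.stats.multitest import multipletests

from .searchlight import StatMap
from .surface import SurfaceMesh
from .rdm import fisher_z

__all__ = ["GroupResult", "group_t_map", "cluster_permutation", "fdr_bh",
           "Z_THRESHOLD"]

#: one-tailed significance cut-off on the corrected-p z score
Z_THRESHOLD = 1.65

#: replacement for infinite t at zero-variance vertices (guarded, not raised)
_T_CAP = 1e6


@dataclass
class Cluster:
    cluster_id: int
    vertices: np.ndarray
    mass: float
    peak_vertex: int
    p_corrected: float = np.nan
    z: float = np.nan


@dataclass
class GroupResult:
    t_map: StatMap
    z_map: StatMap
    clusters: list[Cluster]
    params: dict = field(default_factory=dict)

    def cluster_table(self) -> pd.DataFrame:
        rows = [{
            "cluster_id": c.cluster_id, "n_vertices": len(c.vertices),
            "peak_vertex": c.peak_vertex, "mass": c.mass,
            "p_corr": c.p_corrected, "z": c.z,
            "significant": c.z > self.params.get("z_threshold", Z_THRESHOLD),
        } for c in self.clusters]
        return pd.DataFrame(rows, columns=["cluster_id", "n_vertices",
                                           "peak_vertex", "mass", "p_corr",
                                           "z", "significant"])

    @property
    def significant_clusters(self) -> list[Cluster]:
        zt = self.params.get("z_threshold", Z_THRESHOLD)
        return [c for c in self.clusters if c.z > zt]


def _stack_subject_maps(subject_maps: list[StatMap],
                        transform: str) -> tuple[np.ndarray, np.ndarray]:
    data = np.stack([m.values for m in subject_maps])
    if transform == "fisher":
        clipped = np.clip(data, -1 + 1e-12, 1 - 1e-12)
        data = np.where(np.isnan(data), np.nan, np.arctanh(clipped))
    elif transform != "none":
        raise ValueError(f"unknown transform {transform!r}")
    valid = np.isfinite(data).all(axis=0)
    return data, valid


def _t_stats(data: np.ndarray) -> np.ndarray:
    """One-sample t along axis 0 with a zero-variance guard."""
    n = data.shape[0]
    mean = data.mean(axis=0)
    sd = data.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    zero_var = sd == 0
    t = np.where(zero_var, np.sign(mean) * _T_CAP, t)
    return t


def group_t_map(subject_maps: list[StatMap],
                transform: str = "fisher") -> StatMap:
    """Per-vertex one-sample t of (optionally Fisher-transformed) maps.

    Vertices where any subject is NaN are masked to NaN; constant
    nonzero maps get a large finite t rather than a crash.
    """
    if len(subject_maps) < 3:
        raise ValueError("need at least 3 subjects")
    data, valid = _stack_subject_maps(subject_maps, transform)
    t = np.full(data.shape[1], np.nan)
    t[valid] = _t_stats(data[:, valid])
    return StatMap(t, {"statistic": "t", "df": data.shape[0] - 1,
                       "transform": transform,
                       "n_masked": int((~valid).sum())})


def _components(mask: np.ndarray, adjacency: sparse.csr_matrix) -> list[np.ndarray]:
    """Edge-connected components of the True vertices in ``mask``."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    sub = adjacency[idx][:, idx]
    n_comp, labels = sparse.csgraph.connected_components(sub, directed=False)
    return [idx[labels == c] for c in range(n_comp)]


def cluster_permutation(
    subject_maps: list[StatMap],
    mesh: SurfaceMesh,
    n_perm: int = 5000,
    p0: float = 0.001,
    transform: str = "fisher",
    z_threshold: float = Z_THRESHOLD,
    seed: int = 0,
) -> GroupResult:
    """Cluster-based Monte-Carlo permutation correction (max-sum, one-tailed).

    The initial threshold ``p0`` is converted to a t cut-off with
    n_subjects - 1 df. Null iterations multiply each subject's whole map
    by a random sign and take the maximum supra-threshold cluster mass;
    the corrected p for an observed cluster is
    ``(1 + #{null >= observed}) / (1 + n_perm)`` (never zero), and its z
    is the one-tailed normal quantile of that p. Vertices of clusters
    with z above ``z_threshold`` carry their cluster's z in the z-map.
    """
    n_subj = len(subject_maps)
    if n_subj < 3:
        raise ValueError("need at least 3 subjects")
    if n_subj < 8:
        warnings.warn(f"only {n_subj} subjects: sign-flip null has "
                      f"{2 ** n_subj} distinct states", RuntimeWarning)
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a very coarse null", RuntimeWarning)
    data, valid = _stack_subject_maps(subject_maps, transform)
    m = data.shape[1]
    if m != mesh.n_vertices:
        raise ValueError("maps and mesh vertex counts differ")
    df = n_subj - 1
    t_crit = stats.t.isf(p0, df)
    work = np.nan_to_num(data[:, valid])
    adjacency = mesh.adjacency[np.flatnonzero(valid)][:, np.flatnonzero(valid)]

    t_obs_v = _t_stats(work)
    observed = _components(t_obs_v > t_crit, adjacency.tocsr())
    clusters = [
        Cluster(i + 1, np.flatnonzero(valid)[comp],
                float(t_obs_v[comp].sum()),
                int(np.flatnonzero(valid)[comp[np.argmax(t_obs_v[comp])]]))
        for i, comp in enumerate(
            sorted(observed, key=lambda c: -t_obs_v[c].sum()))
    ]

    rng = np.random.default_rng(seed)
    flips = rng.choice([-1.0, 1.0], size=(n_perm, n_subj))
    # t for all flips at once: sum of squares is flip-invariant
    ss = (work ** 2).sum(axis=0)
    means = flips @ work / n_subj
    with np.errstate(divide="ignore", invalid="ignore"):
        var = (ss - n_subj * means ** 2) / df
        var[var < 0] = 0.0
        t_null = means / np.sqrt(var / n_subj)
    t_null = np.nan_to_num(t_null, posinf=_T_CAP, neginf=-_T_CAP)

    null_max = np.zeros(n_perm)
    adj_csr = adjacency.tocsr()
    for p in range(n_perm):
        comps = _components(t_null[p] > t_crit, adj_csr)
        if comps:
            null_max[p] = max(t_null[p][c].sum() for c in comps)

    t_map_full = np.full(m, np.nan)
    t_map_full[valid] = t_obs_v
    z_map = np.zeros(m)
    for c in clusters:
        c.p_corrected = (1.0 + np.sum(null_max >= c.mass)) / (1.0 + n_perm)
        c.z = float(stats.norm.isf(c.p_corrected))
        if c.z > z_threshold:
            z_map[c.vertices] = c.z
    params = {"n_perm": n_perm, "p0": p0, "t_crit": float(t_crit),
              "transform": transform, "z_threshold": z_threshold,
              "seed": seed, "stat": "max_sum", "tail": "one"}
    return GroupResult(
        StatMap(t_map_full, {"statistic": "t", "df": df, "level": "group"}),
        StatMap(z_map, {"statistic": "z_corrected", "level": "group"}),
        clusters, params)


def fdr_bh(pvalues: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (rejection mask, adjusted p-values)."""
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, p_adj
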