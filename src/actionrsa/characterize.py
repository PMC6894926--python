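"""Representational-geometry characterization.

Tools to describe the structure an RDM carries: classical (Torgerson)
MDS for low-dimensional visualization, PCA variance decomposition of
the item configuration, k-means with silhouette-based selection of the
number of clusters, agglomerative hierarchical clustering, and the
peak-ROI analysis that extracts the neighborhood around the strongest
group-map vertex and reports its neural RDM against every model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_samples, silhouette_score

from .inference import fdr_bh
from .models import ModelSet
from .rdm import RDM, rank_rescale_rdm, rdm_correlation
from .searchlight import (BetaDataset, Searchlight, StatMap,
                          build_searchlights, neural_rdm)
from .surface import SurfaceMesh

__all__ = ["Embedding", "ClusterSolution", "classical_mds", "pca_variance",
           "silhouette_select_k", "hierarchical_cluster", "dendrogram_newick",
           "roi_geometry"]


@dataclass
class Embedding:
    items: tuple[str, ...]
    coords: np.ndarray               # (n, k), columns by decreasing eigenvalue
    eigenvalues: np.ndarray          # all n eigenvalues, decreasing
    variance_explained: np.ndarray   # fractions for the returned components

    @property
    def negative_eigenvalue_mass(self) -> float:
        neg = self.eigenvalues[self.eigenvalues < 0]
        return float(-neg.sum())

    def to_frame(self) -> pd.DataFrame:
        cols = {f"dim{i + 1}": self.coords[:, i]
                for i in range(self.coords.shape[1])}
        return pd.DataFrame(cols, index=list(self.items))


@dataclass
class ClusterSolution:
    k: int
    labels: np.ndarray
    silhouette_per_item: np.ndarray
    mean_silhouette: float
    inertia: float
    seed: int
    n_restarts: int


def classical_mds(rdm: RDM, k: int = 2) -> Embedding:
    """Torgerson MDS: double-center squared dissimilarities, eigendecompose.

    Returns the top-k real coordinates (columns ordered by decreasing
    eigenvalue). If fewer than k eigenvalues are positive the embedding
    is truncated with a warning; negative-eigenvalue mass (the
    non-Euclidean part of the RDM) is available on the result.
    """
    if k >= rdm.n_items:
        raise ValueError("k must be smaller than the number of items")
    d2 = rdm.values ** 2
    n = rdm.n_items
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    n_pos = int((vals > 1e-12 * max(vals.max(), 1.0)).sum())
    k_eff = min(k, n_pos)
    if k_eff < k:
        import warnings
        warnings.warn(f"only {n_pos} positive eigenvalues; truncating "
                      f"embedding to {k_eff} dims", RuntimeWarning)
    coords = vecs[:, :k_eff] * np.sqrt(vals[:k_eff])
    pos_total = vals[vals > 0].sum()
    frac = vals[:k_eff] / pos_total if pos_total > 0 else np.zeros(k_eff)
    return Embedding(rdm.items, coords, vals, frac)


def pca_variance(coords: np.ndarray | Embedding) -> tuple[np.ndarray, np.ndarray]:
    """Principal components of an item configuration.

    Returns (loadings, variance_fractions); fractions sum to 1 over all
    components. Input may be raw coordinates or an Embedding.
    """
    x = coords.coords if isinstance(coords, Embedding) else np.asarray(coords, float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need at least 2 items of coordinates")
    xc = x - x.mean(axis=0)
    total = np.sum(xc ** 2)
    if total == 0:
        raise ValueError("zero-variance configuration")
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    fractions = s ** 2 / np.sum(s ** 2)
    return vt.T, fractions


def silhouette_select_k(
    coords: np.ndarray,
    k_range: range | tuple[int, int] = (2, 10),
    n_restarts: int = 100,
    seed: int = 0,
) -> tuple[int, pd.Series, ClusterSolution]:
    """Pick the number of clusters by maximal mean silhouette width.

    For each k, k-means (k-means++ seeding, best of ``n_restarts``) is
    fit and the mean silhouette width recorded; the returned k is the
    argmax (ties to the smaller k). Returns (best_k, silhouette curve,
    ClusterSolution at best_k).
    """
    x = np.asarray(coords, dtype=float)
    n = len(x)
    if isinstance(k_range, tuple):
        ks = range(k_range[0], min(k_range[1], n - 1) + 1)
    else:
        ks = k_range
    ks = [k for k in ks if 2 <= k <= n - 1]
    if not ks:
        raise ValueError("empty k range")
    curve = {}
    fits = {}
    for k in ks:
        km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
        labels = km.fit_predict(x)
        curve[k] = float(silhouette_score(x, labels))
        fits[k] = km
    series = pd.Series(curve, name="mean_silhouette")
    best_k = int(series.idxmax())
    km = fits[best_k]
    labels = km.labels_
    per_item = silhouette_samples(x, labels)
    solution = ClusterSolution(best_k, labels, per_item,
                               float(series[best_k]), float(km.inertia_),
                               seed, n_restarts)
    return best_k, series, solution


def hierarchical_cluster(rdm: RDM, linkage: str = "average") -> np.ndarray:
    """Agglomerative merge tree (scipy linkage matrix) of an RDM.

    linkage : {'average', 'complete', 'ward'}. Merge heights are
    non-decreasing for average and complete linkage.
    """
    if rdm.n_items < 2:
        raise ValueError("need at least 2 items")
    if linkage not in ("average", "complete", "ward"):
        raise ValueError(f"unsupported linkage {linkage!r}")
    return hierarchy.linkage(rdm.vector(), method=linkage)


def dendrogram_newick(merge_tree: np.ndarray, items: tuple[str, ...]) -> str:
    """Serialize a scipy linkage matrix as a Newick string with branch lengths."""
    tree = hierarchy.to_tree(merge_tree)

    def recurse(node, parent_height) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{items[node.id]}:{length:.6g}"
        left = recurse(node.left, node.dist)
        right = recurse(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return recurse(tree, tree.dist) + ";"


@dataclass
class ROIReport:
    roi: Searchlight
    model_tau: pd.DataFrame          # subjects x models Kendall tau-a
    mean_tau: pd.Series
    t_stats: pd.Series
    p_one_tailed: pd.Series
    p_fdr: pd.Series
    significant: pd.Series
    group_rdm: RDM                   # mean neural RDM across subjects
    display_rdm: RDM                 # rank-rescaled to 0..100
    embedding: Embedding
    merge_tree: np.ndarray
    newick: str


def roi_geometry(
    subject_betas: list[BetaDataset],
    mesh: SurfaceMesh,
    group_stat_map: StatMap,
    models: ModelSet,
    roi_size: int = 100,
) -> ROIReport:
    """Representational geometry of the peak-statistic ROI.

    The ROI is the searchlight of ``roi_size`` vertices around the argmax
    vertex of the group map (ties -> lowest index). Per subject, the
    standard-RSA neural RDM of the ROI is compared with every model by
    Kendall tau-a; taus are tested against zero with one-tailed t-tests
    and BH-FDR across models. The group-mean RDM is returned along with
    its rank-rescaled display version, classical MDS embedding, and
    average-linkage dendrogram.
    """
    vals = np.nan_to_num(group_stat_map.values, nan=-np.inf)
    peak = int(np.argmax(vals))  # argmax takes the lowest index on ties
    sls = build_searchlights(mesh, n_features=roi_size)
    roi = sls[peak]
    taus = {}
    rdms = []
    for ds in subject_betas:
        nr = neural_rdm(ds, roi, mode="standard")
        rdms.append(nr)
        taus[ds.subject] = {name: rdm_correlation(nr, models[name],
                                                  "kendall_tau_a")
                            for name in models.names}
    tau_df = pd.DataFrame(taus).T[list(models.names)]
    n = len(tau_df)
    mean_tau = tau_df.mean()
    sd = tau_df.std(ddof=1)
    t = mean_tau / (sd / np.sqrt(n))
    from scipy import stats as _st
    p = pd.Series(_st.t.sf(t, df=n - 1), index=t.index)
    reject, p_adj = fdr_bh(p.to_numpy())
    group_vals = np.mean([r.values for r in rdms], axis=0)
    group_rdm = RDM(models.items, group_vals, {"level": "group", "roi": peak})
    display = rank_rescale_rdm(group_rdm)
    emb = classical_mds(group_rdm, k=2)
    tree = hierarchical_cluster(group_rdm, "average")
    return ROIReport(roi, tau_df, mean_tau, t, p,
                     pd.Series(p_adj, index=p.index),
                     pd.Series(reject, index=p.index),
                     group_rdm, display, emb, tree,
                     dendrogram_newick(tree, models.items))
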