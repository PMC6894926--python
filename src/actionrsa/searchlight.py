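"""Surface searchlight RSA: neighborhoods, GLM, neural RDMs, and maps.

A searchlight is the set of the 100 mesh vertices nearest a center
vertex by edge-hop distance (one central vertex + 99 neighbors). Within
each searchlight the condition patterns give a neural RDM (squared
Euclidean distance, with normalizations depending on the analysis), and
either a single-model correlation (standard RSA) or a multiple
regression of the neural RDM vector on a set of model RDM vectors
(multiple-regression RSA) is evaluated; the statistic lands at the
center vertex, producing one map per subject (and per model).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform
from scipy.linalg import qr

from .design import DesignConfig, TrialEvent
from .models import ModelSet, vif
from .rdm import RDM, DegenerateRDMError, normalize_rdm
from .surface import SurfaceMesh
from .timeseries import HRFParams, condition_design_matrix

__all__ = ["BetaDataset", "Searchlight", "StatMap", "glm_betas",
           "build_searchlights", "neural_rdm", "standard_rsa_map",
           "regression_rsa_map"]


@dataclass
class BetaDataset:
    """Per-subject condition-by-vertex activation estimates, per run."""

    subject: str
    betas: np.ndarray                  # (n_runs, n_conditions, n_vertices)
    condition_labels: tuple[str, ...]
    mesh: SurfaceMesh

    def __post_init__(self) -> None:
        self.betas = np.asarray(self.betas, dtype=float)
        if self.betas.ndim != 3:
            raise ValueError("betas must be (n_runs, n_conditions, n_vertices)")
        if self.betas.shape[1] != len(self.condition_labels):
            raise ValueError("condition label count mismatch")
        if self.betas.shape[2] != self.mesh.n_vertices:
            raise ValueError("vertex count does not match the mesh")

    @property
    def n_runs(self) -> int:
        return self.betas.shape[0]

    # -- single-file container (HDF5); the mesh travels separately --------
    def to_hdf5(self, path) -> None:
        import h5py
        with h5py.File(path, "w") as f:
            f.create_dataset("betas", data=self.betas)
            f.attrs["subject"] = self.subject
            f.attrs["condition_labels"] = list(self.condition_labels)

    @classmethod
    def from_hdf5(cls, path, mesh: SurfaceMesh) -> "BetaDataset":
        import h5py
        with h5py.File(path, "r") as f:
            return cls(str(f.attrs["subject"]), f["betas"][()],
                       tuple(str(c) for c in f.attrs["condition_labels"]),
                       mesh)


@dataclass(frozen=True)
class Searchlight:
    center: int
    members: tuple[int, ...]
    complete: bool = True  # False when the mesh could not supply n_features

    def __post_init__(self):
        if self.center not in self.members:
            raise ValueError("searchlight center must be a member")


@dataclass
class StatMap:
    """One scalar per mesh vertex; NaN marks undefined vertices."""

    values: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("StatMap values must be a vector")


def glm_betas(
    timeseries: Sequence[np.ndarray],
    events: Sequence[Sequence[TrialEvent]],
    config: DesignConfig | None = None,
    nuisance_regressors: Sequence[np.ndarray] | None = None,
    hrf_params: HRFParams | None = None,
) -> np.ndarray:
    """Per-run OLS condition betas from vertex time series.

    The design matrix per run is [condition boxcars convolved with the
    HRF | pooled catch regressor | nuisance columns | constant]; only the
    condition betas are returned, shaped (n_runs, n_conditions, n_vertices).
    """
    cfg = config or DesignConfig()
    out = []
    for r, (series, run_events) in enumerate(zip(timeseries, events)):
        series = np.asarray(series, dtype=float)
        x, names = condition_design_matrix(run_events, cfg, hrf_params)
        cols = [x]
        if nuisance_regressors is not None:
            nr = np.asarray(nuisance_regressors[r], dtype=float)
            cols.append(nr.reshape(len(series), -1))
            names = names + [f"nuisance{i}" for i in range(cols[-1].shape[1])]
        cols.append(np.ones((len(series), 1)))
        names = names + ["constant"]
        design = np.hstack(cols)
        rank = np.linalg.matrix_rank(design)
        if rank < design.shape[1]:
            _, rdiag, piv = qr(design, mode="economic", pivoting=True)
            d = np.abs(np.diag(rdiag))
            bad = [names[piv[i]] for i in range(len(d))
                   if d[i] < 1e-10 * d.max()] or [names[piv[rank]]]
            raise np.linalg.LinAlgError(
                f"run {r}: rank-deficient design; collinear columns {bad}"
            )
        coef, *_ = np.linalg.lstsq(design, series, rcond=None)
        out.append(coef[: cfg.n_actions])
    return np.stack(out)


def build_searchlights(mesh: SurfaceMesh, n_features: int = 100) -> list[Searchlight]:
    """One searchlight per vertex: the n_features nearest by edge hops.

    Vertices are taken ring by ring in breadth-first order; within the
    last (partial) ring, ties are broken by Euclidean distance to the
    center and then by vertex index, so construction is deterministic and
    independent of traversal order.
    """
    m = mesh.n_vertices
    if n_features > m:
        raise ValueError(f"n_features={n_features} exceeds {m} vertices")
    neighbors = mesh.neighbors
    coords = mesh.vertices
    out: list[Searchlight] = []
    for center in range(m):
        members: list[int] = [center]
        visited = {center}
        ring = [center]
        complete = True
        while len(members) < n_features:
            nxt = sorted({int(nb) for v in ring for nb in neighbors[v]} - visited)
            if not nxt:
                complete = False
                break
            need = n_features - len(members)
            if len(nxt) > need:
                # distances rounded so symmetric vertices tie exactly and
                # the index tie-break is reproducible across platforms
                d = np.round(np.linalg.norm(coords[nxt] - coords[center],
                                            axis=1), 9)
                order = np.lexsort((nxt, d))
                nxt = [nxt[i] for i in order[:need]]
            members.extend(nxt)
            visited.update(nxt)
            ring = nxt
        out.append(Searchlight(center, tuple(members), complete))
    return out


def _zscore(a: np.ndarray, axis: int) -> tuple[np.ndarray, np.ndarray]:
    mu = a.mean(axis=axis, keepdims=True)
    sd = a.std(axis=axis, keepdims=True)
    ok = np.broadcast_to(sd > 0, a.shape).all(axis=axis) if axis is not None else sd > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (a - mu) / sd
    return z, ok


def _searchlight_patterns(betas: np.ndarray, mode: str) -> np.ndarray:
    """(n_conditions, n_members) patterns after the mode's normalizations."""
    if mode in ("standard", "raw"):
        return betas.mean(axis=0)
    if mode != "regression":
        raise ValueError(f"unknown neural RDM mode {mode!r}")
    # normalize across images: z-score each vertex over conditions, per run
    z, _ = _zscore(betas, axis=1)
    zero_var = ~np.isfinite(z).all(axis=(0, 1))
    if zero_var.any():
        warnings.warn(f"dropping {int(zero_var.sum())} zero-variance vertices "
                      "from searchlight", RuntimeWarning)
        z = z[:, :, ~zero_var]
        if z.shape[2] < 2:
            raise DegenerateRDMError("searchlight has <2 usable vertices")
    mean = z.mean(axis=0)  # average across runs
    # normalize across features: z-score each condition's member vector
    zf, ok = _zscore(mean, axis=1)
    if not np.all(ok):
        raise DegenerateRDMError("zero-variance condition pattern after averaging")
    return zf


def neural_rdm(
    betas: BetaDataset,
    searchlight: Searchlight,
    mode: str = "standard",
) -> RDM:
    """Neural RDM of one searchlight.

    standard : run-averaged betas -> squared Euclidean -> max-normalized.
    raw : as standard but without the final max-normalization (used when
        coefficients must stay on the planted scale).
    regression : betas z-scored per vertex across conditions within run
        ("across images"), averaged across runs, z-scored per condition
        across searchlight members ("across features"), then squared
        Euclidean (left on its native scale for the linear model).
    A geometrically degenerate searchlight (all conditions identical)
    yields a zero RDM flagged ``degenerate`` in meta.
    """
    sub = betas.betas[:, :, list(searchlight.members)]
    patterns = _searchlight_patterns(sub, mode)
    d = squareform(pdist(patterns, metric="sqeuclidean"), checks=False)
    meta = {"mode": mode, "subject": betas.subject,
            "center": searchlight.center}
    raw = RDM(betas.condition_labels, d, meta)
    if mode == "standard":
        try:
            return normalize_rdm(raw)
        except DegenerateRDMError:
            raw.meta["degenerate"] = True
            return raw
    return raw


def standard_rsa_map(
    betas: BetaDataset,
    model: RDM,
    searchlights: list[Searchlight] | None = None,
    method: str = "pearson",
) -> StatMap:
    """Per-subject correlation map of searchlight RDMs against one model.

    The correlation type is a parameter; Pearson is the default because
    the maps are subsequently Fisher transformed.
    """
    if model.items != betas.condition_labels:
        raise ValueError("model items do not match condition labels")
    sls = searchlights or build_searchlights(betas.mesh)
    mvec = model.vector()
    msd = mvec.std()
    if msd == 0:
        raise DegenerateRDMError("zero-variance model RDM")
    values = np.full(betas.mesh.n_vertices, np.nan)
    from .rdm import rdm_correlation  # local import to keep module surface flat
    for sl in sls:
        nr = neural_rdm(betas, sl, mode="standard")
        if nr.meta.get("degenerate"):
            continue
        try:
            values[sl.center] = rdm_correlation(nr, model, method)
        except DegenerateRDMError:
            continue
    return StatMap(values, {"statistic": f"{method}_r", "model":
                            model.meta.get("model", "model"),
                            "subject": betas.subject, "level": "subject"})


def regression_rsa_map(
    betas: BetaDataset,
    models: ModelSet,
    searchlights: list[Searchlight] | None = None,
    mode: str = "regression",
) -> dict[str, StatMap]:
    """Multiple-regression RSA: one coefficient map per model.

    Per searchlight, the neural RDM vector (regression normalization) is
    regressed on the model RDM vectors plus an intercept by OLS; each
    model's coefficient is written at the center vertex of its map.
    """
    if models.items != betas.condition_labels:
        raise ValueError("model items do not match condition labels")
    if len(models) >= 2:
        v = vif(models)
        if np.isinf(v).any():
            raise ValueError(f"collinear model set, infinite VIF: "
                             f"{list(v[np.isinf(v)].index)}")
    sls = searchlights or build_searchlights(betas.mesh)
    x = np.column_stack([np.ones(models.matrix().shape[1]), models.matrix().T])
    pinv = np.linalg.pinv(x)
    k = len(models)
    coef_maps = np.full((k, betas.mesh.n_vertices), np.nan)
    for sl in sls:
        try:
            nr = neural_rdm(betas, sl, mode=mode)
        except DegenerateRDMError:
            continue
        coefs = pinv @ nr.vector()
        coef_maps[:, sl.center] = coefs[1:]
    return {
        name: StatMap(coef_maps[i], {"statistic": "beta", "model": name,
                                     "subject": betas.subject,
                                     "level": "subject"})
        for i, name in enumerate(models.names)
    }
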