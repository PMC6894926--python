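"""Representational dissimilarity matrices (RDMs) and their primitives.

An RDM holds the pairwise dissimilarities between a set of experimental
conditions (here, observed actions). Every downstream stage — behavioral
aggregation, model construction, searchlight RSA, group statistics and
geometry characterization — consumes and produces this type, so the
invariants (symmetry, zero diagonal, non-negativity) are enforced at
construction and the comparison primitives (correlations on the
off-diagonal upper triangle, Fisher transform, rank rescaling) live here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

__all__ = [
    "RDM",
    "squared_euclidean_rdm",
    "euclidean_rdm",
    "normalize_rdm",
    "rdm_correlation",
    "fisher_z",
    "rank_rescale_rdm",
    "pair_index",
]

#: relative tolerance for symmetry checking on ingest
SYMMETRY_RTOL = 1e-8


class DegenerateRDMError(ValueError):
    """Raised when an operation receives an RDM with no usable variation."""


def _default_items(n: int) -> tuple[str, ...]:
    return tuple(f"item{i:02d}" for i in range(n))


@dataclass
class RDM:
    """Square symmetric dissimilarity matrix with condition labels.

    Parameters
    ----------
    items : sequence of str
        Ordered condition labels (length n).
    values : (n, n) array
        Pairwise dissimilarities. Must be symmetric (within a relative
        tolerance of 1e-8, in which case it is symmetrized as
        ``(M + M.T) / 2``), have a zero diagonal and non-negative finite
        entries. NaN entries are allowed only when ``meta['allow_missing']``
        is true (pre-aggregation partial RDMs).
    meta : dict
        Provenance tags (task name, subject id, normalization applied, ...).
    """

    items: tuple[str, ...]
    values: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.items = tuple(str(i) for i in self.items)
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError(f"RDM values must be square, got shape {v.shape}")
        if v.shape[0] != len(self.items):
            raise ValueError(
                f"{len(self.items)} items but values of shape {v.shape}"
            )
        allow_missing = bool(self.meta.get("allow_missing", False))
        finite = np.isfinite(v)
        if not allow_missing and not finite.all():
            bad = np.argwhere(~finite)
            raise ValueError(f"non-finite RDM entries at indices {bad[:5].tolist()}")
        scale = np.nanmax(np.abs(v)) or 1.0
        asym = np.nanmax(np.abs(v - v.T))
        if asym > SYMMETRY_RTOL * scale:
            raise ValueError(
                f"asymmetric input (max |M - M.T| = {asym:.3g}, scale {scale:.3g})"
            )
        v = (v + v.T) / 2.0
        if np.nanmax(np.abs(np.diag(v))) > SYMMETRY_RTOL * scale:
            raise ValueError("RDM diagonal must be zero")
        np.fill_diagonal(v, 0.0)
        with np.errstate(invalid="ignore"):
            if np.nanmin(v) < -SYMMETRY_RTOL * scale:
                raise ValueError("RDM entries must be non-negative")
        v[v < 0] = 0.0
        self.values = v

    # -- basic protocol ---------------------------------------------------
    @property
    def n_items(self) -> int:
        return len(self.items)

    def __len__(self) -> int:
        return self.n_items

    def copy(self, **meta_updates) -> "RDM":
        meta = dict(self.meta)
        meta.update(meta_updates)
        return RDM(self.items, self.values.copy(), meta)

    # -- vectorization ----------------------------------------------------
    def vector(self) -> np.ndarray:
        """Off-diagonal upper triangle in row-major (i<j) pair order."""
        iu = np.triu_indices(self.n_items, k=1)
        return self.values[iu]

    @classmethod
    def from_vector(
        cls,
        vec: np.ndarray,
        items: Sequence[str],
        meta: dict | None = None,
    ) -> "RDM":
        """Inverse of :meth:`vector`; validates the n(n-1)/2 length."""
        items = tuple(items)
        n = len(items)
        vec = np.asarray(vec, dtype=float)
        expected = n * (n - 1) // 2
        if vec.shape != (expected,):
            raise ValueError(f"expected vector of length {expected}, got {vec.shape}")
        mat = squareform(vec, checks=False)
        return cls(items, mat, meta or {})

    # -- file format: TSV matrix + JSON sidecar ---------------------------
    def to_tsv(self, path: str | Path) -> None:
        path = Path(path)
        df = pd.DataFrame(self.values, index=list(self.items), columns=list(self.items))
        df.to_csv(path, sep="\t")
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(json.dumps(self.meta, indent=2, default=str))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "RDM":
        path = Path(path)
        df = pd.read_csv(path, sep="\t", index_col=0)
        if list(df.index) != list(df.columns):
            raise ValueError(f"{path}: row and column labels differ")
        sidecar = path.with_suffix(path.suffix + ".json")
        meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
        return cls(tuple(df.index), df.to_numpy(dtype=float), meta)


def pair_index(items: Sequence[str]) -> list[tuple[str, str]]:
    """Ordered (i, j) label pairs, i < j in item order, matching RDM.vector()."""
    items = list(items)
    return [(a, b) for k, a in enumerate(items) for b in items[k + 1:]]


def _check_patterns(patterns: np.ndarray, min_rows: int = 2) -> np.ndarray:
    x = np.asarray(patterns, dtype=float)
    if x.ndim != 2:
        raise ValueError(f"expected 2-D pattern matrix, got shape {x.shape}")
    if x.shape[0] < min_rows:
        raise ValueError(f"need at least {min_rows} rows, got {x.shape[0]}")
    finite_cols = np.isfinite(x).all(axis=0)
    if not finite_cols.all():
        bad = np.flatnonzero(~finite_cols)
        raise ValueError(f"non-finite values in feature columns {bad[:10].tolist()}")
    return x


def squared_euclidean_rdm(
    patterns: np.ndarray,
    items: Sequence[str] | None = None,
    meta: dict | None = None,
) -> RDM:
    """RDM of squared Euclidean distances between condition patterns.

    Entry (i, j) is ``sum_f (x_if - x_jf)**2``. Squared Euclidean distance
    is additive over disjoint feature blocks, which is what licenses
    modeling a neural RDM as a linear combination of model RDMs.
    """
    x = _check_patterns(patterns)
    d = squareform(pdist(x, metric="sqeuclidean"), checks=False)
    items = tuple(items) if items is not None else _default_items(x.shape[0])
    return RDM(items, d, dict(meta or {}, metric="sqeuclidean"))


def euclidean_rdm(
    points: np.ndarray,
    items: Sequence[str] | None = None,
    meta: dict | None = None,
) -> RDM:
    """RDM of Euclidean distances between coordinate rows (k >= 1 dims)."""
    x = _check_patterns(points)
    if x.shape[1] < 1:
        raise ValueError("points need at least one coordinate dimension")
    d = squareform(pdist(x, metric="euclidean"), checks=False)
    items = tuple(items) if items is not None else _default_items(x.shape[0])
    return RDM(items, d, dict(meta or {}, metric="euclidean"))


def normalize_rdm(rdm: RDM) -> RDM:
    """Divide every entry by the maximum off-diagonal entry.

    After normalization the largest dissimilarity is exactly 1 and the
    ordering of entries is preserved. An all-zero RDM has no scale and is
    rejected rather than silently producing NaN.
    """
    vec = rdm.vector()
    vmax = np.nanmax(vec) if vec.size else 0.0
    if not np.isfinite(vmax) or vmax <= 0:
        raise DegenerateRDMError(
            "cannot normalize an all-zero RDM (no off-diagonal entry > 0)"
        )
    out = rdm.copy(normalization="max")
    out.values = rdm.values / vmax
    return out


def _kendall_tau_a(x: np.ndarray, y: np.ndarray) -> float:
    # tau-a: (concordant - discordant) / [m(m-1)/2]; ties contribute zero.
    sx = np.sign(x[:, None] - x[None, :])
    sy = np.sign(y[:, None] - y[None, :])
    iu = np.triu_indices(len(x), k=1)
    s = sx[iu] * sy[iu]
    m = len(x)
    return float(s.sum() / (m * (m - 1) / 2))


def rdm_correlation(a: RDM, b: RDM, method: str = "pearson") -> float:
    """Correlation between two RDMs over the same items.

    Computed on the off-diagonal upper-triangle vectors only, so the
    forced zero diagonal never inflates the estimate.

    method : {'pearson', 'spearman', 'kendall_tau_a'}
        ``kendall_tau_a`` uses the tau-a denominator m(m-1)/2 (ties in
        either vector reduce |tau|), the conservative choice for model
        RDMs with tied predictions.
    """
    if a.items != b.items:
        diff = set(a.items).symmetric_difference(b.items) or {"(ordering differs)"}
        raise ValueError(f"RDM item mismatch: {sorted(diff)}")
    if a.n_items < 3:
        raise ValueError("need at least 3 items to correlate RDMs")
    x, y = a.vector(), b.vector()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateRDMError("zero-variance RDM vector in correlation")
    if method == "pearson":
        return float(np.corrcoef(x, y)[0, 1])
    if method == "spearman":
        return float(np.corrcoef(rankdata(x), rankdata(y))[0, 1])
    if method == "kendall_tau_a":
        return _kendall_tau_a(x, y)
    raise ValueError(f"unknown correlation method {method!r}")


def fisher_z(r: float | np.ndarray) -> float | np.ndarray:
    """Fisher transform atanh(r); variance-stabilizes correlation maps."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1):
        raise ValueError("Fisher transform requires |r| < 1")
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


def rank_rescale_rdm(rdm: RDM) -> RDM:
    """Rank-transform off-diagonal entries and rescale to [0, 100].

    Ties share their average rank; an all-tied RDM maps to a constant 50.
    Used for display of group RDMs.
    """
    if rdm.n_items < 2:
        raise ValueError("need at least 2 items")
    vec = rdm.vector()
    ranks = rankdata(vec)  # average ranks, 1..m
    m = len(vec)
    if m == 1 or np.ptp(ranks) == 0:
        scaled = np.full(m, 50.0)
    else:
        scaled = (ranks - 1) / (m - 1) * 100.0
    return RDM.from_vector(scaled, rdm.items, dict(rdm.meta, rank_rescaled=True))
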