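"""Predictor model RDMs and their collinearity diagnostics.

The multiple-regression RSA uses ten predictors: five RDMs estimated
from multi-arrangement behavior (semantic, body, scene, movement,
object), three from Likert ratings (sociality, transitivity, distance),
a binary one-vs-two-people model, and the HMAX-C1 image model. This
module builds the rating-based and binary models, bundles any collection
of normalized RDMs into a ModelSet with a canonical order, and computes
model intercorrelations and variance inflation factors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .rdm import RDM, DegenerateRDMError, normalize_rdm, rdm_correlation

__all__ = ["RatingSet", "ModelSet", "rating_rdm", "binary_feature_rdm",
           "model_intercorrelation", "vif", "CANONICAL_MODEL_ORDER"]

CANONICAL_MODEL_ORDER = (
    "semantic", "body", "scene", "movement", "object",
    "sociality", "transitivity", "distance", "people", "hmax_c1",
)


@dataclass
class RatingSet:
    """Likert scores, subjects x items, with declared scale bounds."""

    scores: pd.DataFrame  # index = subject ids, columns = item labels
    scale: tuple[float, float] = (1, 7)
    name: str = "rating"

    def __post_init__(self) -> None:
        lo, hi = self.scale
        vals = self.scores.to_numpy(dtype=float)
        if np.isnan(vals).any():
            raise ValueError(f"{self.name}: missing rating values")
        bad = (vals < lo) | (vals > hi)
        if bad.any():
            subj, item = np.argwhere(bad)[0]
            raise ValueError(
                f"{self.name}: score {vals[subj, item]} outside [{lo}, {hi}] "
                f"for subject {self.scores.index[subj]!r}, "
                f"item {self.scores.columns[item]!r}"
            )

    @property
    def items(self) -> tuple[str, ...]:
        return tuple(self.scores.columns)

    @classmethod
    def from_tsv(cls, path: str | Path, scale: tuple[float, float] = (1, 7),
                 name: str = "rating") -> "RatingSet":
        """Long-format TSV with columns subject, item, score."""
        df = pd.read_csv(path, sep="\t")
        missing = {"subject", "item", "score"} - set(df.columns)
        if missing:
            raise ValueError(f"{path}: missing columns {sorted(missing)}")
        wide = df.pivot(index="subject", columns="item", values="score")
        return cls(wide, scale=scale, name=name)


def rating_rdm(ratings: RatingSet) -> tuple[list[RDM], RDM]:
    """Per-subject |score difference| RDMs and their renormalized mean.

    Each subject's RDM entry (i, j) is |score_i - score_j|, then
    max-normalized; the group RDM averages the normalized per-subject
    RDMs and renormalizes, weighting every subject equally.
    """
    items = ratings.items
    per_subject: list[RDM] = []
    for subj, row in ratings.scores.iterrows():
        s = row.to_numpy(dtype=float)
        mat = np.abs(s[:, None] - s[None, :])
        raw = RDM(items, mat, {"model": ratings.name, "subject": str(subj)})
        try:
            per_subject.append(normalize_rdm(raw))
        except DegenerateRDMError as exc:
            raise DegenerateRDMError(
                f"{ratings.name}: subject {subj!r} rated all items "
                f"identically ({exc})"
            ) from exc
    mean = np.mean([r.values for r in per_subject], axis=0)
    group = normalize_rdm(RDM(items, mean, {"model": ratings.name,
                                            "level": "group"}))
    return per_subject, group


def binary_feature_rdm(labels: Mapping[str, int], name: str = "people") -> RDM:
    """0/1 feature RDM: distance 0 for same label, 1 otherwise."""
    items = tuple(labels)
    vals = np.array([labels[i] for i in items], dtype=float)
    if not set(np.unique(vals)) <= {0.0, 1.0}:
        raise ValueError(f"{name}: labels must be binary 0/1")
    mat = np.abs(vals[:, None] - vals[None, :])
    meta = {"model": name}
    if mat.max() == 0:
        meta["degenerate"] = True
    return RDM(items, mat, meta)


class ModelSet:
    """Named, ordered collection of normalized predictor RDMs.

    Models whose names appear in :data:`CANONICAL_MODEL_ORDER` are kept
    in that order; any others follow in insertion order. All members must
    share the same items in the same order, and each is max-normalized
    on ingest (no-op if already normalized).
    """

    def __init__(self, models: Mapping[str, RDM]):
        if len(models) == 0:
            raise ValueError("empty ModelSet")
        names = list(models)
        if len(set(names)) != len(names):
            raise ValueError("duplicate model names")
        canonical = [n for n in CANONICAL_MODEL_ORDER if n in names]
        extra = [n for n in names if n not in CANONICAL_MODEL_ORDER]
        self.names: tuple[str, ...] = tuple(canonical + extra)
        first = models[self.names[0]]
        self.items = first.items
        self._models: dict[str, RDM] = {}
        for n in self.names:
            m = models[n]
            if m.items != self.items:
                raise ValueError(f"model {n!r} items differ from {self.names[0]!r}")
            if m.meta.get("normalization") != "max" and m.vector().max() > 0:
                m = normalize_rdm(m)
            self._models[n] = m

    def __len__(self) -> int:
        return len(self.names)

    def __iter__(self):
        return iter(self.names)

    def __getitem__(self, name: str) -> RDM:
        return self._models[name]

    def matrix(self) -> np.ndarray:
        """(n_models, n_pairs) stack of RDM vectors in set order."""
        return np.stack([self._models[n].vector() for n in self.names])

    # -- serialization: directory of TSVs + manifest ----------------------
    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for n in self.names:
            self._models[n].to_tsv(directory / f"{n}.tsv")
        manifest = {"models": list(self.names), "items": list(self.items)}
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, directory: str | Path) -> "ModelSet":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        models = {n: RDM.from_tsv(directory / f"{n}.tsv")
                  for n in manifest["models"]}
        return cls(models)


def model_intercorrelation(models: ModelSet, method: str = "pearson") -> pd.DataFrame:
    """Model x model correlation matrix of the vectorized RDMs."""
    if len(models) < 2:
        raise ValueError("need at least 2 models")
    k = len(models)
    out = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            r = rdm_correlation(models[models.names[i]],
                                models[models.names[j]], method)
            out[i, j] = out[j, i] = r
    return pd.DataFrame(out, index=list(models.names), columns=list(models.names))


def vif(models: ModelSet) -> pd.Series:
    """Variance inflation factor 1 / (1 - R^2_i) per model.

    R^2_i comes from regressing model i's RDM vector on all other models
    (with intercept). Perfect collinearity is reported as an infinite
    VIF rather than raised.
    """
    x = models.matrix().T  # (n_pairs, n_models)
    n_pairs, k = x.shape
    if k < 2:
        raise ValueError("need at least 2 models for VIF")
    if n_pairs <= k:
        raise ValueError("need more condition pairs than models")
    out = {}
    for i, name in enumerate(models.names):
        y = x[:, i]
        others = np.delete(x, i, axis=1)
        design = np.column_stack([np.ones(n_pairs), others])
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ coef
        tss = np.sum((y - y.mean()) ** 2)
        if tss == 0:
            out[name] = np.inf
            continue
        r2 = 1.0 - resid @ resid / tss
        out[name] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")
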