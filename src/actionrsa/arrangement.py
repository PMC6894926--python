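"""Multi-arrangement behavior and inverse multidimensional scaling.

In the multi-arrangement task a participant drags item images inside a
circular arena so that on-screen distance expresses dissimilarity. The
first trial shows every item; each later trial shows an adaptively
chosen subset, concentrating measurement on the pairs with the weakest
evidence so far. This module represents sessions, turns trial layouts
into per-trial scaled distances, aggregates them into a subject RDM,
simulates arrangers against a known RDM, and quantifies inter-observer
reliability (leave-one-subject-out correlations with permutation
p-values) and per-item agreement (cosine distance between subjects'
RDM rows), including the keep/discard rule used for stimulus selection.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .rdm import (RDM, DegenerateRDMError, euclidean_rdm, normalize_rdm)

__all__ = ["Arena", "ArrangementTrial", "ArrangementSession", "EvidenceMatrix",
           "trial_distances", "aggregate_session", "select_next_subset",
           "simulate_arranger", "loso_reliability", "cosine_agreement",
           "select_consistent_items"]


@dataclass(frozen=True)
class Arena:
    radius: float = 300.0
    center: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("arena radius must be positive")


@dataclass
class ArrangementTrial:
    """One trial: an item subset and its 2-D arena coordinates."""

    items: tuple[str, ...]
    coords: np.ndarray  # (len(items), 2)

    def __post_init__(self):
        self.items = tuple(self.items)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.items), 2):
            raise ValueError("coords must be (n_items, 2)")


@dataclass
class ArrangementSession:
    subject: str
    task: str                       # semantic|body|scene|movement|object
    items: tuple[str, ...]          # the full fixed item list
    trials: list[ArrangementTrial]
    arena: Arena = field(default_factory=Arena)

    def __post_init__(self):
        self.items = tuple(self.items)
        if self.trials:
            first = self.trials[0]
            if set(first.items) != set(self.items):
                raise ValueError("trial 1 must contain every item")
            for t in self.trials:
                stray = set(t.items) - set(self.items)
                if stray:
                    raise ValueError(f"trial items not in item list: {stray}")

    # -- JSON round trip ---------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        payload = {
            "subject": self.subject, "task": self.task,
            "items": list(self.items),
            "arena": {"radius": self.arena.radius,
                      "center": list(self.arena.center)},
            "trials": [{"items": list(t.items),
                        "coords": t.coords.tolist()} for t in self.trials],
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "ArrangementSession":
        d = json.loads(Path(path).read_text())
        arena = Arena(d["arena"]["radius"], tuple(d["arena"]["center"]))
        trials = [ArrangementTrial(tuple(t["items"]), np.array(t["coords"]))
                  for t in d["trials"]]
        return cls(d["subject"], d["task"], tuple(d["items"]), trials, arena)


class EvidenceMatrix:
    """Accumulated per-pair evidence weights (symmetric, zero diagonal)."""

    def __init__(self, items: tuple[str, ...]):
        self.items = tuple(items)
        n = len(self.items)
        self.values = np.zeros((n, n))

    def add_trial(self, subset_idx: np.ndarray, weight: float) -> None:
        ix = np.asarray(subset_idx)
        self.values[np.ix_(ix, ix)] += weight
        np.fill_diagonal(self.values, 0.0)

    def min_pair_evidence(self) -> float:
        iu = np.triu_indices(len(self.items), k=1)
        return float(self.values[iu].min())


def trial_distances(trial: ArrangementTrial) -> RDM:
    """Screen distances of one trial, divided by the trial's maximum.

    The per-trial scaling removes how much of the arena the participant
    chose to use, so distances are comparable across trials with
    different subset sizes. Coincident (stacked) items are allowed.
    """
    if len(trial.items) < 2:
        raise ValueError("a trial needs at least 2 items")
    d = euclidean_rdm(trial.coords, trial.items)
    dmax = d.vector().max()
    if dmax == 0:
        raise DegenerateRDMError("all trial items are stacked at one point")
    out = d.copy(normalization="trial_max")
    out.values = d.values / dmax
    return out


def aggregate_session(session: ArrangementSession,
                      mode: str = "mean") -> RDM:
    """Subject RDM: per-pair mean of scaled trial distances, max-normalized.

    mode='mean' (default) averages per-trial max-scaled distances over
    the trials in which the pair co-occurred. mode='evidence_weighted'
    additionally aligns each trial to the running estimate by a
    least-squares scale factor and weights it by its evidence
    (an iterative refinement of the same aggregate).
    Any pair never co-placed is an error, which a valid trial 1 rules out.
    """
    items = session.items
    n = len(items)
    index = {it: i for i, it in enumerate(items)}
    sums = np.zeros((n, n))
    counts = np.zeros((n, n))
    trial_data = []
    for trial in session.trials:
        td = trial_distances(trial)
        ix = np.array([index[it] for it in td.items])
        trial_data.append((ix, td.values))
        sums[np.ix_(ix, ix)] += td.values
        counts[np.ix_(ix, ix)] += 1
    np.fill_diagonal(counts, 1)
    iu = np.triu_indices(n, k=1)
    missing = [(a, b) for a, b in zip(*iu) if counts[a, b] == 0]
    if missing:
        i, j = missing[0]
        raise ValueError(
            f"pair ({items[i]}, {items[j]}) never co-occurred in any trial"
        )
    est = sums / counts
    if mode == "evidence_weighted":
        # iteratively rescale each trial onto the pooled estimate
        for _ in range(10):
            wsum = np.zeros((n, n))
            wtot = np.zeros((n, n))
            for ix, vals in trial_data:
                ref = est[np.ix_(ix, ix)]
                denom = np.sum(vals * vals)
                scale = np.sum(vals * ref) / denom if denom > 0 else 1.0
                w = len(session.items) / len(ix)  # smaller subsets: more evidence
                wsum[np.ix_(ix, ix)] += w * scale * vals
                wtot[np.ix_(ix, ix)] += w
            np.fill_diagonal(wtot, 1)
            new = wsum / np.maximum(wtot, 1e-12)
            if np.allclose(new, est, atol=1e-10):
                est = new
                break
            est = new
    elif mode != "mean":
        raise ValueError(f"unknown aggregation mode {mode!r}")
    rdm = RDM(items, est, {"task": session.task, "subject": session.subject,
                           "aggregation": mode,
                           "pair_trial_counts": counts[iu].astype(int).tolist()})
    return normalize_rdm(rdm)


def select_next_subset(
    evidence: EvidenceMatrix,
    current_rdm_estimate: RDM | None = None,
    min_items: int = 3,
    max_items: int | None = None,
) -> tuple[str, ...]:
    """Adaptive 'lift the weakest' subset choice for the next trial.

    Seeds with the lowest-evidence pair (ties broken by item order),
    then repeatedly adds the item whose average evidence with the
    current subset is lowest. Growth continues while that average is
    strictly below the global mean pair evidence (the item still lifts
    weak pairs), up to ``max_items``, and always to at least
    ``min_items``. Deterministic given the evidence matrix.
    """
    if min_items < 3:
        raise ValueError("min_items must be >= 3")
    items = evidence.items
    n = len(items)
    max_items = max_items or max(min_items, n // 2)
    ev = evidence.values
    iu = np.triu_indices(n, k=1)
    pairs = list(zip(*iu))
    weakest = min(pairs, key=lambda p: (ev[p], p))
    subset = [weakest[0], weakest[1]]
    global_mean = float(ev[iu].mean())
    while len(subset) < max_items:
        rest = [i for i in range(n) if i not in subset]
        if not rest:
            break
        avg = [(float(ev[i, subset].mean()), i) for i in rest]
        best_avg, best = min(avg)
        if len(subset) >= min_items and best_avg >= global_mean:
            break
        subset.append(best)
    return tuple(items[i] for i in sorted(subset))


def simulate_arranger(
    true_rdm: RDM,
    noise_sd: float = 0.0,
    arena: Arena | None = None,
    time_budget_trials: int = 12,
    seed: int = 0,
    min_items: int = 3,
    max_items: int | None = None,
    subject: str = "sim01",
    task: str = "semantic",
) -> ArrangementSession:
    """Simulate a participant performing the multi-arrangement task.

    Each trial, the simulated subject 2-D-embeds (classical MDS) the
    noise-perturbed true sub-RDM of the trial's items and scales the
    layout to fill the arena. Trial 1 contains all items; later subsets
    come from :func:`select_next_subset` on the accumulated evidence.
    """
    from .characterize import classical_mds  # deferred: avoids import cycle

    arena = arena or Arena()
    rng = np.random.default_rng(seed)
    items = true_rdm.items
    n = len(items)
    index = {it: i for i, it in enumerate(items)}
    evidence = EvidenceMatrix(items)
    trials: list[ArrangementTrial] = []
    subset: tuple[str, ...] = items
    for _ in range(time_budget_trials):
        ix = np.array([index[it] for it in subset])
        sub = true_rdm.values[np.ix_(ix, ix)].copy()
        if noise_sd > 0:
            noise = rng.normal(0.0, noise_sd, size=sub.shape)
            noise = (noise + noise.T) / 2
            np.fill_diagonal(noise, 0.0)
            sub = np.clip(sub + noise, 0.0, None)
        sub_rdm = RDM(subset, sub)
        try:
            import warnings as _warnings
            with _warnings.catch_warnings():
                # noisy small sub-RDMs routinely embed in < 2 dims
                _warnings.simplefilter("ignore", RuntimeWarning)
                coords = classical_mds(sub_rdm, k=2).coords
        except DegenerateRDMError:
            coords = np.zeros((len(subset), 2))
        if coords.shape[1] < 2:
            coords = np.column_stack([coords,
                                      np.zeros((len(subset), 2 - coords.shape[1]))])
        radius = np.linalg.norm(coords, axis=1).max()
        if radius > 0:
            coords = coords * (arena.radius / radius)
        else:
            # degenerate embedding (noise swamped the geometry): the
            # simulated subject still spreads items around the arena
            ang = rng.uniform(0, 2 * np.pi, size=len(subset))
            rad = arena.radius * np.sqrt(rng.uniform(0, 1, size=len(subset)))
            coords = np.column_stack([rad * np.cos(ang), rad * np.sin(ang)])
        coords = coords + np.asarray(arena.center)
        trials.append(ArrangementTrial(subset, coords))
        evidence.add_trial(ix, weight=n / len(subset))
        subset = select_next_subset(evidence, None, min_items, max_items)
    return ArrangementSession(subject, task, items, trials, arena)


def loso_reliability(
    subject_rdms: list[RDM],
    n_perm: int = 10_000,
    q: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Leave-one-subject-out reliability of a cohort of RDMs.

    Each subject's RDM vector is Pearson-correlated with the mean RDM of
    the remaining subjects. One-sided p-values come from permuting the
    subject's item labels (joint row/column relabeling, ``n_perm``
    draws, add-one corrected) — a permutation null is used because RDM
    entries are not independent — followed by BH-FDR across subjects.
    """
    if len(subject_rdms) < 3:
        raise ValueError("need at least 3 subjects")
    items = subject_rdms[0].items
    for r in subject_rdms:
        if r.items != items:
            raise ValueError("subjects have mismatching item sets")
    from .inference import fdr_bh
    mats = np.stack([r.values for r in subject_rdms])
    n = len(items)
    iu = np.triu_indices(n, k=1)
    rng = np.random.default_rng(seed)
    rows = []
    for s, rdm in enumerate(subject_rdms):
        others = np.delete(mats, s, axis=0).mean(axis=0)
        ref = others[iu]
        own = mats[s]
        obs = np.corrcoef(own[iu], ref)[0, 1]
        exceed = 0
        for _ in range(n_perm):
            perm = rng.permutation(n)
            exceed += np.corrcoef(own[np.ix_(perm, perm)][iu], ref)[0, 1] >= obs
        p = (1.0 + exceed) / (1.0 + n_perm)
        rows.append({"subject": rdm.meta.get("subject", f"sub{s:02d}"),
                     "r": float(obs), "p": float(p)})
    df = pd.DataFrame(rows)
    reject, p_adj = fdr_bh(df["p"].to_numpy(), q)
    df["p_fdr"] = p_adj
    df["significant"] = reject
    df.attrs["mean_r"] = float(df["r"].mean())
    return df


def cosine_agreement(subject_rdms: list[RDM]) -> pd.Series:
    """Per-item mean cosine distance between subjects' RDM rows.

    For each item, its dissimilarity profile (RDM row) is compared
    between every pair of subjects with 1 - cosine similarity; the
    per-item score is the mean over all subject pairs. 0 means perfect
    agreement on where the item sits; 1 means orthogonal profiles.
    """
    if len(subject_rdms) < 2:
        raise ValueError("need at least 2 subjects")
    items = subject_rdms[0].items
    mats = np.stack([r.values for r in subject_rdms])
    norms = np.linalg.norm(mats, axis=2)
    if np.any(norms == 0):
        s, i = np.argwhere(norms == 0)[0]
        raise ValueError(f"zero dissimilarity row: subject {s}, item {items[i]!r}")
    unit = mats / norms[:, :, None]
    n_subj = len(subject_rdms)
    scores = np.zeros(len(items))
    n_pairs = 0
    for a in range(n_subj):
        for b in range(a + 1, n_subj):
            cos = np.sum(unit[a] * unit[b], axis=1)
            scores += 1.0 - cos
            n_pairs += 1
    return pd.Series(scores / n_pairs, index=list(items), name="cosine_distance")


def select_consistent_items(
    agreement_tables: dict[str, pd.Series],
    sd_rule: float = 1.0,
) -> pd.DataFrame:
    """Keep items whose agreement score is within mean + sd_rule * sd everywhere.

    ``agreement_tables`` maps a table name (task x stimulus set) to a
    per-item cosine-distance series over a common item set. An item is
    kept iff, in every table, its score does not exceed that table's
    mean + sd_rule * sd. The report carries each item's worst margin
    (score - threshold, most positive across tables; negative = safe).
    """
    names = list(agreement_tables)
    if not names:
        raise ValueError("no agreement tables given")
    items = list(agreement_tables[names[0]].index)
    for nm in names:
        if list(agreement_tables[nm].index) != items:
            raise ValueError(f"table {nm!r} covers different items")
    margins = pd.DataFrame(index=items)
    for nm in names:
        s = agreement_tables[nm]
        margins[nm] = s - (s.mean() + sd_rule * s.std(ddof=1))
    worst = margins.max(axis=1)
    keep = worst <= 0
    out = pd.DataFrame({"keep": keep, "worst_margin": worst})
    if not keep.any():
        import warnings
        warnings.warn("no item satisfies the consistency rule", RuntimeWarning)
    return out
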