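"""Rapid event-related fMRI design: trial sequences for the action study.

Each functional run presents 56 experimental trials (every one of the 28
actions twice, with two exemplars differing in actor and scene), 18 null
events, and 7 one-back catch trials (same action as the preceding trial
but a different exemplar; participants respond, and the trials are
discarded from analysis). Across runs 1-6 every action x exemplar
combination appears exactly once, and again across runs 7-12, so each
action is seen 24 times as an experimental trial over a session.

Exemplars factorize as 2 actors x 2 scenes x 3 camera perspectives. The
quasi-balancing rule pairs the two within-run exemplars of an action so
that if actor one performs it in scene A, actor two performs it in
scene B.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["DesignConfig", "TrialEvent", "generate_trial_sequence",
           "session_to_events_frame", "write_events_tsv", "read_events_tsv"]


class DesignError(RuntimeError):
    """Constraint satisfaction failed after bounded retries."""


@dataclass(frozen=True)
class DesignConfig:
    n_runs: int = 12
    n_actions: int = 28
    n_exemplars: int = 12          # 2 actors x 2 scenes x 3 perspectives
    trial_dur_s: float = 1.0       # image presentation
    fix_dur_s: float = 3.0         # fixation after each image
    null_dur_s: float = 4.0        # fixation-only null event
    n_null_per_run: int = 18
    n_catch_per_run: int = 7
    tr_s: float = 2.5
    volumes_per_run: int = 142
    start_fix_s: float = 15.0      # fixation at run start (and end)
    null_spacing: str = "unconstrained"  # or "min_gap:<k>" stimulus trials between nulls

    def __post_init__(self):
        for name in ("n_runs", "n_actions", "n_exemplars", "n_null_per_run",
                     "n_catch_per_run", "volumes_per_run"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_exemplars % 2:
            raise ValueError("n_exemplars must be even (two actors)")

    @property
    def trials_per_run(self) -> int:
        """Experimental trials per run: each action twice."""
        return 2 * self.n_actions

    @property
    def run_duration_s(self) -> float:
        n_events = self.trials_per_run + self.n_catch_per_run + self.n_null_per_run
        return 2 * self.start_fix_s + n_events * (self.trial_dur_s + self.fix_dur_s)


@dataclass(frozen=True)
class TrialEvent:
    onset: float
    duration: float
    trial_type: str           # 'exp' | 'catch' | 'null'
    action: int = -1          # -1 for null events
    exemplar: int = -1
    actor: int = -1
    scene: int = -1


def exemplar_factors(exemplar: int, n_exemplars: int = 12) -> tuple[int, int, int]:
    """(actor, scene, perspective) encoded in an exemplar index."""
    per_actor = n_exemplars // 2
    per_cell = per_actor // 2
    actor = exemplar // per_actor
    scene = (exemplar % per_actor) // per_cell
    perspective = exemplar % per_cell
    return actor, scene, perspective


def _pair_exemplars(rng: np.random.Generator, cfg: DesignConfig) -> list[tuple[int, int]]:
    """Split exemplars into actor/scene-complementary pairs, one pair per run.

    Pairs (actor0, scene s) with (actor1, scene 1-s) so each run's two
    exemplars of an action satisfy the quasi-balancing rule.
    """
    cells: dict[tuple[int, int], list[int]] = {}
    for e in range(cfg.n_exemplars):
        a, s, _ = exemplar_factors(e, cfg.n_exemplars)
        cells.setdefault((a, s), []).append(e)
    pairs = []
    for s in (0, 1):
        left = list(cells.get((0, s), []))
        right = list(cells.get((1, 1 - s), []))
        rng.shuffle(left)
        rng.shuffle(right)
        pairs.extend(zip(left, right))
    rng.shuffle(pairs)
    return pairs


def _order_run_trials(rng: np.random.Generator, actions: np.ndarray,
                      max_tries: int = 200) -> np.ndarray:
    """Permutation of trial indices with no action repeated consecutively."""
    for _ in range(max_tries):
        perm = rng.permutation(len(actions))
        if not np.any(actions[perm][1:] == actions[perm][:-1]):
            return perm
    raise DesignError("could not order run trials without action repeats")


def generate_trial_sequence(config: DesignConfig | None = None,
                            seed: int = 0) -> list[list[TrialEvent]]:
    """Generate a full session as a list of per-run ordered event lists.

    Pseudorandomization constraints: no action in two consecutive trials
    except at catch trials; within each half-session every action x
    exemplar combination once; catch actions drawn without replacement
    within each 4-run block.
    """
    cfg = config or DesignConfig()
    rng = np.random.default_rng(seed)
    n_half = cfg.n_runs // 2  # runs per balanced half-session

    # per-run exemplar pairs for every action, refreshed each half-session
    run_pairs: list[dict[int, tuple[int, int]]] = []
    for half in range(2):
        per_action = {a: _pair_exemplars(rng, cfg) for a in range(cfg.n_actions)}
        for r in range(n_half):
            run_pairs.append({a: per_action[a][r] for a in range(cfg.n_actions)})

    # catch actions: all actions once per 4-run block, 7 per run
    catch_plan: list[np.ndarray] = []
    block_runs = cfg.n_actions // cfg.n_catch_per_run
    for start in range(0, cfg.n_runs, block_runs):
        order = rng.permutation(cfg.n_actions)
        for k in range(min(block_runs, cfg.n_runs - start)):
            catch_plan.append(order[k * cfg.n_catch_per_run:(k + 1) * cfg.n_catch_per_run])

    session: list[list[TrialEvent]] = []
    for run in range(cfg.n_runs):
        pairs = run_pairs[run]
        actions = np.repeat(np.arange(cfg.n_actions), 2)
        exemplars = np.array([pairs[a][i] for a in range(cfg.n_actions) for i in (0, 1)])
        perm = _order_run_trials(rng, actions)
        actions, exemplars = actions[perm], exemplars[perm]

        # insert catch trials immediately after a trial of the same action
        events: list[tuple[str, int, int]] = [("exp", int(a), int(e))
                                              for a, e in zip(actions, exemplars)]
        for ca in catch_plan[run]:
            positions = [i for i, ev in enumerate(events)
                         if ev[0] == "exp" and ev[1] == ca]
            pos = int(rng.choice(positions))
            prev_ex = events[pos][2]
            others = [e for e in range(cfg.n_exemplars) if e != prev_ex]
            events.insert(pos + 1, ("catch", int(ca), int(rng.choice(others))))

        # interleave null events among the stimulus trials
        n_stim = len(events)
        slots = rng.choice(n_stim + 1, size=cfg.n_null_per_run, replace=True)
        if cfg.null_spacing.startswith("min_gap:"):
            gap = int(cfg.null_spacing.split(":")[1])
            for _ in range(500):
                slots = rng.choice(n_stim + 1, size=cfg.n_null_per_run, replace=False)
                if np.all(np.diff(np.sort(slots)) > gap):
                    break
            else:
                raise DesignError("could not satisfy null-event spacing")
        for slot in sorted(slots, reverse=True):
            events.insert(int(slot), ("null", -1, -1))

        onset = cfg.start_fix_s
        run_events: list[TrialEvent] = []
        for kind, a, e in events:
            if kind == "null":
                run_events.append(TrialEvent(onset, cfg.null_dur_s, "null"))
                onset += cfg.null_dur_s
            else:
                actor, scene, _ = exemplar_factors(e, cfg.n_exemplars)
                run_events.append(TrialEvent(onset, cfg.trial_dur_s, kind, a, e,
                                             actor, scene))
                onset += cfg.trial_dur_s + cfg.fix_dur_s
        if onset + cfg.start_fix_s > cfg.volumes_per_run * cfg.tr_s + 1e-9:
            raise DesignError("run events exceed the run duration")
        session.append(run_events)
    return session


def session_to_events_frame(session: list[list[TrialEvent]]) -> pd.DataFrame:
    """Flatten a session to a BIDS-style events table with a run column."""
    rows = []
    for run_idx, run in enumerate(session):
        for ev in run:
            rows.append({"run": run_idx + 1, **asdict(ev)})
    df = pd.DataFrame(rows)
    return df.rename(columns={"trial_dur_s": "duration"})


def write_events_tsv(session: list[list[TrialEvent]], path: str | Path) -> None:
    session_to_events_frame(session).to_csv(path, sep="\t", index=False)


def read_events_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"run", "onset", "duration", "trial_type", "action"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing events columns {sorted(missing)}")
    return df
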