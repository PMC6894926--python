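"""Hemodynamic model, design matrices, and fMRI time-series simulation.

The forward model is the standard linear one: each event type contributes
a boxcar at its onsets convolved with a canonical double-gamma HRF,
sampled at the TR; the vertex time series is the design matrix times the
vertex's betas plus AR(1) Gaussian noise. The same design-matrix builder
is used by the GLM estimator, so noiseless simulation followed by
estimation is an exact round trip.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter
from scipy.stats import gamma as gamma_dist

from .design import DesignConfig, TrialEvent

__all__ = ["HRFParams", "double_gamma_hrf", "condition_design_matrix",
           "simulate_timeseries"]


@dataclass(frozen=True)
class HRFParams:
    """Canonical two-gamma HRF: peak at ~6 s, undershoot at ~16 s, ratio 1/6."""
    peak_delay_s: float = 6.0
    undershoot_delay_s: float = 16.0
    undershoot_ratio: float = 1.0 / 6.0
    dispersion_s: float = 1.0
    duration_s: float = 32.0


def double_gamma_hrf(dt: float, params: HRFParams | None = None) -> np.ndarray:
    """Sampled HRF kernel, normalized to peak 1."""
    p = params or HRFParams()
    t = np.arange(0.0, p.duration_s + dt, dt)
    b = p.dispersion_s
    h = (gamma_dist.pdf(t, p.peak_delay_s / b, scale=b)
         - p.undershoot_ratio * gamma_dist.pdf(t, p.undershoot_delay_s / b, scale=b))
    peak = np.max(np.abs(h))
    if peak == 0:
        raise ValueError("degenerate HRF parameters")
    return h / peak


def condition_design_matrix(
    run_events: list[TrialEvent],
    config: DesignConfig,
    hrf_params: HRFParams | None = None,
    dt: float = 0.1,
    include_catch: bool = True,
) -> tuple[np.ndarray, list[str]]:
    """Convolved design matrix sampled at the TR grid.

    Columns: one per action condition (experimental trials only), then an
    optional pooled catch-trial regressor. The constant and any nuisance
    columns are appended by the GLM caller.
    """
    p = hrf_params or HRFParams()
    if p.duration_s >= config.volumes_per_run * config.tr_s:
        raise ValueError("HRF kernel longer than the run")
    n_vol = config.volumes_per_run
    run_len = n_vol * config.tr_s
    n_t = int(np.ceil(run_len / dt)) + 1
    kernel = double_gamma_hrf(dt, p)

    names = [f"action{a:02d}" for a in range(config.n_actions)]
    n_cols = config.n_actions + (1 if include_catch else 0)
    fine = np.zeros((n_t, n_cols))
    for ev in run_events:
        if ev.trial_type == "null":
            continue
        if ev.onset + ev.duration > run_len:
            raise ValueError(f"event at {ev.onset}s exceeds run duration")
        col = ev.action if ev.trial_type == "exp" else config.n_actions
        if ev.trial_type == "catch" and not include_catch:
            continue
        i0 = int(round(ev.onset / dt))
        i1 = int(round((ev.onset + ev.duration) / dt))
        fine[i0:max(i1, i0 + 1), col] = 1.0
    conv = np.apply_along_axis(lambda c: np.convolve(c, kernel)[:n_t], 0, fine)
    vol_idx = np.round(np.arange(n_vol) * config.tr_s / dt).astype(int)
    x = conv[vol_idx]
    if include_catch:
        names = names + ["catch"]
    return x, names


def _ar1_noise(rng: np.random.Generator, shape: tuple[int, int],
               sd: float, phi: float) -> np.ndarray:
    """AR(1) noise along axis 0 with stationary marginal sd."""
    innov_sd = sd * np.sqrt(max(1.0 - phi ** 2, 1e-12))
    eps = rng.normal(0.0, innov_sd, size=shape)
    return lfilter([1.0], [1.0, -phi], eps, axis=0)


def simulate_timeseries(
    betas_per_run: np.ndarray,
    trial_sequence: list[list[TrialEvent]],
    config: DesignConfig | None = None,
    hrf_params: HRFParams | None = None,
    noise_sd: float = 1.0,
    ar1_phi: float = 0.3,
    seed: int = 0,
) -> list[np.ndarray]:
    """Simulate per-run (volumes, vertices) series from planted betas.

    betas_per_run : (n_runs, n_actions, n_vertices)
        Amplitude of each action condition at each vertex, per run.
    Catch trials are driven by the per-vertex mean condition amplitude;
    the GLM's pooled catch regressor absorbs them, so condition-beta
    recovery is exact at zero noise.
    """
    cfg = config or DesignConfig()
    betas = np.asarray(betas_per_run, dtype=float)
    n_runs, n_cond, n_vert = betas.shape
    if n_runs != len(trial_sequence):
        raise ValueError("betas_per_run and trial_sequence run counts differ")
    if n_cond != cfg.n_actions:
        raise ValueError("betas_per_run condition count != n_actions")
    rng = np.random.default_rng(seed)
    runs = []
    for r, run_events in enumerate(trial_sequence):
        x, _ = condition_design_matrix(run_events, cfg, hrf_params)
        catch_amp = betas[r].mean(axis=0, keepdims=True)  # (1, n_vert)
        signal = x[:, :n_cond] @ betas[r] + x[:, n_cond:n_cond + 1] @ catch_amp
        noise = _ar1_noise(rng, signal.shape, noise_sd, ar1_phi) if noise_sd > 0 \
            else 0.0
        runs.append(signal + noise)
    return runs
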