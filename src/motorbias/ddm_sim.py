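"""Trial-level stochastic DDM simulator.

Euler random walk with increments N(mu*dt, sqrt(dt)) between the effective
bounds, used both as the independent Monte-Carlo oracle for the closed forms
in :mod:`motorbias.ddm_core` and as the generator for the error-RT contrast
analysis (test-minus-baseline RT change for correct and error trials by
motion direction).

Discretely monitored barriers are systematically harder to hit than the
continuous ones they stand for; by default the simulator applies the standard
continuity correction (each bound pulled inward by |zeta(1/2)|/sqrt(2*pi) *
sigma*sqrt(dt), Broadie-Glasserman-Kou) so that first-passage statistics at
the default 0.5 ms step agree with the continuous-time closed forms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import ddm_core
from .ddm_core import BASELINE, TEST, DDMParams

__all__ = ["SimTrial", "simulate_trial", "simulate_trials", "error_rt_contrast",
           "CONTINUITY_BETA"]

# |zeta(1/2)| / sqrt(2 pi): mean overshoot constant for Gaussian random walks
CONTINUITY_BETA = 0.5826  # Broadie, Glasserman & Kou (1997)

DEFAULT_STEP_MS = 0.5
MAX_DECISION_TIME_MS = 5000.0


@dataclass(frozen=True)
class SimTrial:
    """One simulated trial."""

    coherence: float
    phase: str
    choice: str  # left | right
    correct: bool
    decision_time: float  # ms
    rt: float  # ms, decision time + responding side's non-decision time
    flagged: bool = False  # hit the simulation time cap


def _barriers(params: DDMParams, phase: str, step_ms: float, continuity_correction: bool):
    a, b = ddm_core.effective_bounds(params, phase)
    if a <= 0 or b <= 0:
        raise ValueError("effective bounds must be positive")
    if continuity_correction:
        eps = CONTINUITY_BETA * np.sqrt(step_ms)
        if a - eps <= 0 or b - eps <= 0:
            raise ValueError("step too coarse for continuity correction at these bounds")
        a, b = a - eps, b - eps
    return a, b


def simulate_trials(
    params: DDMParams,
    coherence: float,
    phase: str,
    n: int,
    rng: np.random.Generator,
    step_ms: float = DEFAULT_STEP_MS,
    max_time_ms: float = MAX_DECISION_TIME_MS,
    continuity_correction: bool = True,
) -> pd.DataFrame:
    """Simulate ``n`` first-passage trials at one (coherence, phase) cell.

    Returns a DataFrame with columns coherence, phase, choice, correct,
    decision_time, rt, flagged.  Walks still alive at ``max_time_ms`` are
    capped there, assigned the side of the nearest bound, and flagged.
    """
    if step_ms <= 0:
        raise ValueError("step_ms must be positive")
    a, b = _barriers(params, phase, step_ms, continuity_correction)
    mu = ddm_core.drift(params, coherence, phase)

    x = np.zeros(n)
    dt_arr = np.full(n, np.nan)  # decision time, ms
    up = np.zeros(n, dtype=bool)
    alive = np.arange(n)
    t_elapsed = 0.0
    chunk = 256  # steps simulated per vectorized block
    sqdt = np.sqrt(step_ms)

    while alive.size and t_elapsed < max_time_ms:
        m = min(chunk, int(np.ceil((max_time_ms - t_elapsed) / step_ms)))
        inc = rng.normal(mu * step_ms, sqdt, size=(alive.size, m))
        path = x[alive, None] + np.cumsum(inc, axis=1)
        hit_up = path >= a
        hit_lo = path <= -b
        hit = hit_up | hit_lo
        any_hit = hit.any(axis=1)
        idx = hit.argmax(axis=1)
        done = alive[any_hit]
        di = idx[any_hit]
        dt_arr[done] = t_elapsed + (di + 1) * step_ms
        up[done] = hit_up[any_hit, di]
        keep = ~any_hit
        x[alive[keep]] = path[keep, -1]
        alive = alive[keep]
        t_elapsed += m * step_ms

    flagged = np.zeros(n, dtype=bool)
    if alive.size:  # runaway walks: cap and attribute to the nearest bound
        flagged[alive] = True
        dt_arr[alive] = max_time_ms
        up[alive] = (a - x[alive]) <= (b + x[alive])

    choice = np.where(up, "right", "left")
    t0 = np.where(up,
                  ddm_core.nondecision_time(params, phase, "right"),
                  ddm_core.nondecision_time(params, phase, "left"))
    correct = up if coherence > 0 else (~up if coherence < 0 else np.zeros(n, dtype=bool))
    return pd.DataFrame({
        "coherence": coherence,
        "phase": phase,
        "choice": choice,
        "correct": correct,
        "decision_time": dt_arr,
        "rt": dt_arr + t0,
        "flagged": flagged,
    })


def simulate_trial(
    params: DDMParams,
    coherence: float,
    phase: str,
    rng: np.random.Generator,
    step_ms: float = DEFAULT_STEP_MS,
    max_time_ms: float = MAX_DECISION_TIME_MS,
    continuity_correction: bool = True,
) -> SimTrial:
    """Simulate a single trial (see :func:`simulate_trials`)."""
    row = simulate_trials(params, coherence, phase, 1, rng, step_ms,
                          max_time_ms, continuity_correction).iloc[0]
    return SimTrial(coherence, phase, row["choice"], bool(row["correct"]),
                    float(row["decision_time"]), float(row["rt"]), bool(row["flagged"]))


def _cell_rng(seed: int, phase_idx: int, coh_idx: int) -> np.random.Generator:
    # keyed substream: same seed -> same cell stream regardless of call order
    return np.random.default_rng([seed, phase_idx, coh_idx])


def error_rt_contrast(
    params_baseline: DDMParams,
    params_test: DDMParams,
    coherences,
    n_per_cell: int = 10_000,
    seed: int = 0,
    step_ms: float = DEFAULT_STEP_MS,
) -> pd.DataFrame:
    """Test-minus-baseline RT change for correct and error trials per stimulus.

    For each signed coherence, simulates ``n_per_cell`` trials in the baseline
    phase (from ``params_baseline``, deltas inactive) and the test phase (from
    ``params_test``, deltas active), then tabulates the change in mean correct
    RT, mean error RT and correct rate.  Cells without error trials are
    flagged (NaN delta) rather than failing.  Deterministic given ``seed``:
    every (phase, coherence) cell draws from its own keyed substream.
    """
    rows = []
    cohs = list(coherences)
    for ci, coh in enumerate(cohs):
        if coh == 0:
            raise ValueError("error/correct split undefined at zero coherence")
        base = simulate_trials(params_baseline, coh, BASELINE, n_per_cell,
                               _cell_rng(seed, 0, ci), step_ms)
        test = simulate_trials(params_test, coh, TEST, n_per_cell,
                               _cell_rng(seed, 1, ci), step_ms)

        def cellmean(df, corr):
            sub = df.loc[df["correct"] == corr, "rt"]
            return (float(sub.mean()), len(sub)) if len(sub) else (np.nan, 0)

        rt_c_b, n_c_b = cellmean(base, True)
        rt_e_b, n_e_b = cellmean(base, False)
        rt_c_t, n_c_t = cellmean(test, True)
        rt_e_t, n_e_t = cellmean(test, False)
        rows.append({
            "coherence": coh,
            "direction": "right" if coh > 0 else "left",
            "n_per_cell": n_per_cell,
            "delta_rt_correct": rt_c_t - rt_c_b,
            "delta_rt_error": rt_e_t - rt_e_b,
            "delta_correct_rate": n_c_t / n_per_cell - n_c_b / n_per_cell,
            "n_error_baseline": n_e_b,
            "n_error_test": n_e_t,
            "flagged": (n_e_b == 0) or (n_e_t == 0),
        })
    return pd.DataFrame(rows)
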