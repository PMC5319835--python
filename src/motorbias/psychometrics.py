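"""Logistic psychometric analysis: PSE/JND, phase shifts, sliding-window decay.

P(rightward) is fitted by maximum-likelihood logistic regression on signed
coherence (in %).  PSE = -intercept/slope is the coherence at which both
responses are equally likely; JND = (x75 - x25)/2 = log(3)/slope measures
discrimination sensitivity.  Shifts are test-phase PSE minus baseline PSE
(negative = toward the resisted direction).  The sliding-window analysis
tracks how a vocally expressed bias decays with the number of trials since
the last manual (costly-response) trial.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

__all__ = [
    "PsychometricFit",
    "filter_rts",
    "align_by_resistance",
    "fit_psychometric",
    "pse_shift",
    "sliding_window_pse",
    "RT_MIN_MS",
    "RT_MAX_MS",
]

RT_MIN_MS = 100.0
RT_MAX_MS = 850.0

_JND_FACTOR = float(np.log(3.0))  # (x75 - x25)/2 = log(3)/slope


@dataclass(frozen=True)
class PsychometricFit:
    """Logistic fit of P(rightward) on signed coherence in %."""

    intercept: float  # log-odds at 0% coherence
    slope: float  # log-odds per % coherence
    pse: float  # % coherence
    jnd: float  # % coherence
    n_trials: int
    status: str = "ok"  # ok | separation | failed

    @property
    def valid(self) -> bool:
        return self.status == "ok" and np.isfinite(self.pse)


def filter_rts(trials: pd.DataFrame, rt_min: float = RT_MIN_MS,
               rt_max: float = RT_MAX_MS) -> pd.DataFrame:
    """Drop manual trials with RT outside [100, 850] ms; vocal trials pass through."""
    if trials.empty:
        return trials.copy()
    manual = trials["modality"] == "manual"
    keep = ~manual | ((trials["rt"] >= rt_min) & (trials["rt"] <= rt_max))
    return trials.loc[keep].reset_index(drop=True)


_FLIP = {"left": "right", "right": "left"}


def align_by_resistance(trials: pd.DataFrame, resisted_side: str) -> pd.DataFrame:
    """Express trials in the resisted-side-is-left convention.

    For a participant whose *right* hand carried the resistance, coherence
    signs and left/right labels (response and instructed direction) are
    mirrored so that negative coherence always denotes the resisted
    direction; left-resisted data pass through unchanged.  Applying the map
    twice is the identity.
    """
    if resisted_side == "left":
        return trials.copy()
    if resisted_side != "right":
        raise ValueError(f"unknown resisted side {resisted_side!r}")
    out = trials.copy()
    out["coherence"] = -out["coherence"].to_numpy(dtype=float) + 0.0  # avoid -0.0
    out["response"] = out["response"].map(lambda r: _FLIP.get(r, r))
    if "instructed_direction" in out.columns:
        out["instructed_direction"] = out["instructed_direction"].map(
            lambda r: _FLIP.get(r, r))
    if "resisted_side" in out.columns:
        out["resisted_side"] = "left"
    return out


def fit_psychometric(trials: pd.DataFrame) -> PsychometricFit:
    """Maximum-likelihood logistic fit of P(rightward) against coherence (%).

    Complete separation is flagged (``status='separation'``) and the PSE is
    still reported from the (diverging) fit with a warning status rather
    than raising.
    """
    x = trials["coherence"].to_numpy(dtype=float) * 100.0
    y = (trials["response"] == "right").to_numpy(dtype=float)
    n = len(trials)
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        return PsychometricFit(np.nan, np.nan, np.nan, np.nan, n, "failed")
    X = sm.add_constant(x)
    status = "ok"
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        b0, b1 = res.params
    except (PerfectSeparationError, PerfectSeparationWarning):
        status = "separation"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=25)
        b0, b1 = res.params
    except Exception:
        return PsychometricFit(np.nan, np.nan, np.nan, np.nan, n, "failed")
    if b1 == 0 or not np.isfinite(b1):
        return PsychometricFit(float(b0), float(b1), np.nan, np.nan, n, "failed")
    pse = -b0 / b1
    jnd = _JND_FACTOR / abs(b1)
    return PsychometricFit(float(b0), float(b1), float(pse), float(jnd), n, status)


def pse_shift(baseline_fit: PsychometricFit, test_fit: PsychometricFit) -> float:
    """Test PSE minus baseline PSE (% coherence); NaN if either fit is invalid."""
    if not (baseline_fit.valid and test_fit.valid):
        return float("nan")
    return test_fit.pse - baseline_fit.pse


def mean_pse_shift(table) -> float:
    """Mean per-participant PSE shift from a deposited-style summary table.

    ``table`` is a DataFrame or CSV path with one row per participant and a
    ``pse_shift`` column (% coherence), the format in which per-participant
    baseline-to-test shifts are archived alongside published figures.
    """
    df = table if isinstance(table, pd.DataFrame) else pd.read_csv(table)
    if "pse_shift" not in df.columns:
        raise ValueError("table needs a 'pse_shift' column")
    vals = df["pse_shift"].to_numpy(dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("no finite PSE shifts in table")
    return float(vals.mean())


def sliding_window_pse(vocal_trials: pd.DataFrame, window: int = 5) -> pd.DataFrame:
    """PSE shift per sliding window of trials-since-manual (vocal discrimination).

    Pools test-phase vocal trials whose position since the last manual trial
    falls in each overlapping ``window``-trial range (1-5, 2-6, ... for
    10-trial mini-blocks), fits a psychometric per window, and subtracts the
    baseline-phase vocal PSE.  Returns a frame with columns ``window``
    (1-based start), ``pse_shift``, ``n_trials``, ``status``.
    """
    voc = vocal_trials.loc[vocal_trials["modality"] == "vocal"]
    if voc.empty:
        raise ValueError("no vocal trials")
    tsm = voc["trials_since_manual"].to_numpy(dtype=float)
    mini_len = int(np.nanmax(tsm))
    if window > mini_len:
        raise ValueError("window exceeds the vocal mini-block length")
    base_fit = fit_psychometric(voc.loc[voc["phase"] == "baseline"])
    rows = []
    for start in range(1, mini_len - window + 2):
        in_win = (tsm >= start) & (tsm <= start + window - 1)
        sub = voc.loc[in_win & (voc["phase"] == "test").to_numpy()]
        f = fit_psychometric(sub)
        rows.append({
            "window": start,
            "pse_shift": pse_shift(base_fit, f),
            "n_trials": f.n_trials,
            "status": f.status,
        })
    return pd.DataFrame(rows)
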