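"""Signal detection analysis for the vocal yes/no motion-detection task.

Equal-variance Gaussian model: sensitivity d' = z(H) - z(F) and criterion
C = -(z(H) + z(F))/2, computed separately for leftward- and rightward-
instructed trials.  A positive criterion change means a more conservative
(yes-averse) observer.  The sliding-window analysis tracks the decay of the
cost-induced criterion asymmetry with trials since the last manual trial;
following the field's plotting convention the left-direction value is
subtracted from the right-direction value, so negative differences mean a
more conservative criterion for the (resisted) leftward motion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "DetectionCounts",
    "SDTResult",
    "counts_from_trials",
    "dprime_criterion",
    "phase_contrast",
    "sliding_window_bias",
]

DIRECTIONS = ("left", "right")


@dataclass(frozen=True)
class DetectionCounts:
    """Hit/miss/false-alarm/correct-rejection counts for one motion direction."""

    direction: str
    hits: int
    misses: int
    false_alarms: int
    correct_rejections: int

    def __post_init__(self) -> None:
        if min(self.hits, self.misses, self.false_alarms, self.correct_rejections) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n_signal(self) -> int:
        return self.hits + self.misses

    @property
    def n_noise(self) -> int:
        return self.false_alarms + self.correct_rejections


@dataclass(frozen=True)
class SDTResult:
    """Sensitivity and response bias of one observer/direction."""

    dprime: float
    criterion: float
    hit_rate: float
    fa_rate: float


def counts_from_trials(trials: pd.DataFrame, direction: str) -> DetectionCounts:
    """Tally detection outcomes for trials instructed toward ``direction``."""
    sub = trials.loc[(trials["task"] == "detection")
                     & (trials["instructed_direction"] == direction)]
    sig = sub["signal_present"].astype(bool)
    yes = sub["response"] == "yes"
    return DetectionCounts(
        direction=direction,
        hits=int((sig & yes).sum()),
        misses=int((sig & ~yes).sum()),
        false_alarms=int((~sig & yes).sum()),
        correct_rejections=int((~sig & ~yes).sum()),
    )


def dprime_criterion(counts: DetectionCounts,
                     correction_policy: str = "loglinear") -> SDTResult:
    """d' and criterion from detection counts.

    ``correction_policy='loglinear'`` adds 0.5 to every cell (and 1 to each
    trial total) whenever a hit or false-alarm rate would be 0 or 1, keeping
    the Gaussian quantiles finite; ``'none'`` applies no correction.
    """
    if counts.n_signal == 0 or counts.n_noise == 0:
        raise ValueError("need both signal and noise trials")
    h, f = counts.hits, counts.false_alarms
    ns, nn = counts.n_signal, counts.n_noise
    hr, fr = h / ns, f / nn
    if correction_policy == "loglinear":
        if hr in (0.0, 1.0) or fr in (0.0, 1.0):
            hr = (h + 0.5) / (ns + 1.0)
            fr = (f + 0.5) / (nn + 1.0)
    elif correction_policy != "none":
        raise ValueError(f"unknown correction policy {correction_policy!r}")
    zh, zf = norm.ppf(hr), norm.ppf(fr)
    return SDTResult(dprime=float(zh - zf), criterion=float(-(zh + zf) / 2.0),
                     hit_rate=float(hr), fa_rate=float(fr))


def phase_contrast(baseline: dict, test: dict) -> dict:
    """Per-direction (delta d', delta C) = test minus baseline.

    ``baseline`` and ``test`` map direction -> :class:`SDTResult` for both
    directions.  A positive delta C means a more conservative criterion in
    the test phase.
    """
    out = {}
    for d in DIRECTIONS:
        if d not in baseline or d not in test:
            raise ValueError(f"missing direction {d!r}")
        out[d] = (test[d].dprime - baseline[d].dprime,
                  test[d].criterion - baseline[d].criterion)
    return out


def sliding_window_bias(vocal_trials: pd.DataFrame, window: int = 3,
                        correction_policy: str = "loglinear") -> pd.DataFrame:
    """Right-minus-left criterion (and d') change per sliding window.

    For each overlapping ``window``-trial range of trials-since-manual
    (1-3, 2-4, ... for 7-trial mini-blocks) and each direction, d' and C are
    computed from the pooled test-phase trials and from the identically
    windowed baseline trials; their change (test - baseline) is differenced
    right minus left.  Negative ``dC_right_minus_left`` = more conservative
    for leftward motion.  Columns: window, dC_right_minus_left,
    ddprime_right_minus_left, per-direction deltas and trial counts.
    """
    voc = vocal_trials.loc[(vocal_trials["modality"] == "vocal")
                           & (vocal_trials["task"] == "detection")]
    if voc.empty:
        raise ValueError("no vocal detection trials")
    tsm = voc["trials_since_manual"].to_numpy(dtype=float)
    mini_len = int(np.nanmax(tsm))
    if window > mini_len:
        raise ValueError("window exceeds the vocal mini-block length")
    rows = []
    for start in range(1, mini_len - window + 2):
        in_win = (tsm >= start) & (tsm <= start + window - 1)
        sub = voc.loc[in_win]
        delta = {}
        n_win = {}
        for d in DIRECTIONS:
            try:
                base = dprime_criterion(
                    counts_from_trials(sub.loc[sub["phase"] == "baseline"], d),
                    correction_policy)
                test = dprime_criterion(
                    counts_from_trials(sub.loc[sub["phase"] == "test"], d),
                    correction_policy)
                delta[d] = (test.dprime - base.dprime, test.criterion - base.criterion)
            except ValueError:  # empty signal/noise class in a sparse window
                delta[d] = (np.nan, np.nan)
            n_win[d] = int((sub["instructed_direction"] == d).sum())
        rows.append({
            "window": start,
            "dC_right_minus_left": delta["right"][1] - delta["left"][1],
            "ddprime_right_minus_left": delta["right"][0] - delta["left"][0],
            "dC_left": delta["left"][1],
            "dC_right": delta["right"][1],
            "ddprime_left": delta["left"][0],
            "ddprime_right": delta["right"][0],
            "n_left": n_win["left"],
            "n_right": n_win["right"],
        })
    return pd.DataFrame(rows)
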