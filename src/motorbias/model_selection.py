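"""BIC model comparison with Schwarz weights and participant bootstrap.

The four DDM variants are compared on group-averaged choice/RT data:
BIC = -2 log L + n_params * log(n_obs), converted to Schwarz weights
w(i) = exp(-dBIC(i)/2) / sum_k exp(-dBIC(k)/2), with percentile confidence
intervals from resampling participants with replacement and refitting the
averaged resample.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import ddm_core
from .ddm_core import FitResult, get_variant

__all__ = [
    "bic",
    "bic_weights",
    "fit_group_average",
    "average_conditions",
    "bootstrap_comparison",
    "individual_delta_tests",
    "ModelComparison",
]

DEFAULT_VARIANTS = ("starting_point", "sensory_evidence", "full", "baseline")


def bic(logl: float, n_params: int, n_obs: int) -> float:
    """-2 log L + n_params * log(n_obs)."""
    if n_obs < 1:
        raise ValueError("n_obs must be >= 1")
    return -2.0 * logl + n_params * math.log(n_obs)


def bic_weights(bics: Sequence[float]) -> np.ndarray:
    """Schwarz weights; invariant to adding a constant to every BIC."""
    b = np.asarray(bics, dtype=float)
    if b.size == 0 or not np.isfinite(b).any():
        raise ValueError("need at least one finite BIC")
    delta = b - np.nanmin(b[np.isfinite(b)])
    w = np.exp(-0.5 * delta)
    w[~np.isfinite(b)] = 0.0
    return w / w.sum()


def average_conditions(datasets: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Average per-condition data across participants.

    Each dataset is a condition table (columns coherence, phase, n, n_right,
    mean_rt_correct, sd_rt_correct) on the same (phase, coherence) grid.
    Choice proportions and mean correct RTs are averaged unweighted across
    participants; the averaged cell keeps the summed trial counts so the
    binomial/Gaussian likelihood sees the group-level evidence.
    """
    if not datasets:
        raise ValueError("no datasets to average")
    key = ["phase", "coherence"]
    grids = [set(map(tuple, d[key].itertuples(index=False))) for d in datasets]
    if any(g != grids[0] for g in grids[1:]):
        raise ValueError("participants have mismatched condition grids")
    stacked = pd.concat(datasets, ignore_index=True)
    stacked["p_right"] = stacked["n_right"] / stacked["n"]
    stacked["n_correct"] = np.where(stacked["coherence"] > 0,
                                    stacked["n_right"], stacked["n"] - stacked["n_right"])

    def agg(sub: pd.DataFrame) -> pd.Series:
        n_tot = int(sub["n"].sum())
        p_bar = float(sub["p_right"].mean())
        rt = sub["mean_rt_correct"].to_numpy(dtype=float)
        ok = np.isfinite(rt)
        return pd.Series({
            "n": n_tot,
            "n_right": int(round(p_bar * n_tot)),
            "mean_rt_correct": float(rt[ok].mean()) if ok.any() else np.nan,
            "sd_rt_correct": float(sub.loc[ok, "sd_rt_correct"].mean()) if ok.any() else np.nan,
        })
    out = stacked.groupby(key, sort=True).apply(agg, include_groups=False).reset_index()
    out[["n", "n_right"]] = out[["n", "n_right"]].astype(int)
    return out


def fit_group_average(
    datasets: Sequence[pd.DataFrame],
    variant: str = "full",
    n_starts: int = 20,
    seed: int | None = 0,
    **fit_kwargs,
) -> FitResult:
    """Average the participants' condition tables, then fit one variant."""
    avg = average_conditions(datasets)
    return ddm_core.fit(avg, variant, n_starts=n_starts, seed=seed, **fit_kwargs)


@dataclass(frozen=True)
class ModelComparison:
    """Group-fit BICs/weights per variant with bootstrap percentile CIs."""

    variants: tuple[str, ...]
    bic: Mapping[str, float]
    weight: Mapping[str, float]
    bic_ci: Mapping[str, tuple[float, float]]
    weight_ci: Mapping[str, tuple[float, float]]
    n_boot: int
    seed: int | None
    group_fits: Mapping[str, FitResult] = field(default_factory=dict)

    @property
    def best(self) -> str:
        return min(self.variants, key=lambda v: self.bic[v])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for v in self.variants:
            rows.append({
                "variant": v,
                "bic": self.bic[v],
                "bic_lo": self.bic_ci[v][0],
                "bic_hi": self.bic_ci[v][1],
                "weight": self.weight[v],
                "weight_lo": self.weight_ci[v][0],
                "weight_hi": self.weight_ci[v][1],
            })
        return pd.DataFrame(rows)


def bootstrap_comparison(
    datasets: Sequence[pd.DataFrame],
    n_boot: int = 200,
    seed: int | None = 0,
    variants: Sequence[str] = DEFAULT_VARIANTS,
    n_starts: int = 20,
    boot_starts: int = 3,
) -> ModelComparison:
    """Fit every variant to the group average and bootstrap over participants.

    Each resample draws participants with replacement, averages, and refits
    each variant warm-started from the group-fit solution (plus
    ``boot_starts - 1`` jittered starts).  Deterministic given ``seed``.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if n_boot > 2000:
        warnings.warn(f"n_boot={n_boot} may take a long time", RuntimeWarning)
    rng = np.random.default_rng(seed)
    names = [get_variant(v).name for v in variants]

    group_fits = {v: fit_group_average(datasets, v, n_starts=n_starts, seed=seed)
                  for v in names}
    g_bic = {v: group_fits[v].bic for v in names}
    g_w = dict(zip(names, bic_weights([g_bic[v] for v in names])))

    # warm-start vectors for the bootstrap refits
    warm: dict[str, list[np.ndarray]] = {}
    for v in names:
        fr = group_fits[v]
        x = np.array([getattr(fr.params, nm) for nm in ddm_core._free_names(fr.variant)])
        warm[v] = [x]

    boot_bic = {v: np.empty(n_boot) for v in names}
    boot_w = {v: np.empty(n_boot) for v in names}
    n_part = len(datasets)
    for i in range(n_boot):
        idx = rng.integers(0, n_part, size=n_part)
        resample = [datasets[j] for j in idx]
        avg = average_conditions(resample)
        bics = []
        for v in names:
            starts = [warm[v][0]]
            for _ in range(boot_starts - 1):
                starts.append(warm[v][0] * (1.0 + 0.05 * rng.standard_normal(len(warm[v][0]))))
            fr = ddm_core.fit(avg, v, n_starts=len(starts), seed=None, x0_list=starts)
            boot_bic[v][i] = fr.bic
            bics.append(fr.bic)
        ws = bic_weights(bics)
        for v, w in zip(names, ws):
            boot_w[v][i] = w

    def ci(x: np.ndarray) -> tuple[float, float]:
        return (float(np.percentile(x, 2.5)), float(np.percentile(x, 97.5)))

    return ModelComparison(
        variants=tuple(names),
        bic=g_bic,
        weight=g_w,
        bic_ci={v: ci(boot_bic[v]) for v in names},
        weight_ci={v: ci(boot_w[v]) for v in names},
        n_boot=n_boot,
        seed=seed,
        group_fits=group_fits,
    )


def individual_delta_tests(fits: Sequence[FitResult]) -> dict:
    """Medians and Wilcoxon signed-rank tests of the full-model bias terms.

    Reports the median normalized starting-point shift sp/(A+B) and the
    median sensory-evidence shift dcoh across participants, each tested
    two-sided against zero.
    """
    if len(fits) < 5:
        raise ValueError("need at least 5 participants")
    nsp = np.array([ddm_core.normalized_sp(f) for f in fits])
    dcoh = np.array([f.params.dcoh for f in fits])

    def test(x: np.ndarray) -> float:
        if np.allclose(x, 0):
            return 1.0
        return float(stats.wilcoxon(x, alternative="two-sided").pvalue)

    return {
        "n": len(fits),
        "median_normalized_sp": float(np.median(nsp)),
        "p_normalized_sp": test(nsp),
        "median_dcoh": float(np.median(dcoh)),
        "p_dcoh": test(dcoh),
    }
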