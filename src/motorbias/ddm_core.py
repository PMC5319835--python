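"""Closed-form diffusion decision model (DDM) with asymmetric bounds and bias terms.

The accumulator collects momentary evidence drawn from N(mu, 1) per unit time
(ms) until it reaches the upper bound ``A`` (rightward decision) or the lower
bound ``-B`` (leftward decision).  Drift scales linearly with signed motion
coherence, ``mu = k * Coh`` with ``Coh`` a fraction in [-1, 1].  Two bias
mechanisms distinguish the test phase from the baseline phase:

* a starting-point shift ``sp`` (evidence units), equivalent to moving the
  bounds to ``A - sp`` and ``-B - sp`` while keeping their separation fixed —
  positive ``sp`` moves the start closer to the rightward bound;
* a sensory-evidence shift ``dcoh`` (percent-coherence points), an additive
  offset to the effective coherence entering the drift,
  ``mu = k * (Coh + dcoh/100)``.

Non-decision times are response-side specific (``t0_left``, ``t0_right``) and
may change additively between phases (``dt_left``, ``dt_right``; negative
values mean faster responses in the test phase, e.g. from motor practice).

Four nested model variants differ in which bias terms are free:

========================  ====================  ========
variant                   free bias terms       n params
========================  ====================  ========
``baseline``              none                  7
``starting_point``        sp                    8
``sensory_evidence``      dcoh                  8
``full``                  sp, dcoh              9
========================  ====================  ========

The model is fitted by maximum likelihood to per-condition choice proportions
(binomial) and mean correct-trial reaction times (Gaussian on the mean with
standard error sd/sqrt(n_correct)), the classic psychometric + chronometric
joint fit for this model class.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "DDMParams",
    "ModelVariant",
    "VARIANTS",
    "ConditionSummary",
    "FitResult",
    "effective_bounds",
    "drift",
    "p_right",
    "mean_decision_time",
    "predict_mean_rt_correct",
    "negative_log_likelihood",
    "fit",
    "mirror_params",
    "normalized_sp",
]

BASELINE = "baseline"
TEST = "test"
_PHASES = (BASELINE, TEST)

# order of the full 9-dim parameter vector used by the fitter
_PARAM_ORDER = ("k", "A", "B", "t0_left", "t0_right", "dt_left", "dt_right", "sp", "dcoh")

# optimizer search box per parameter (units: see DDMParams)
_DEFAULT_BOUNDS: Mapping[str, tuple[float, float]] = {
    "k": (0.01, 2.0),
    "A": (1.0, 40.0),
    "B": (1.0, 40.0),
    "t0_left": (50.0, 800.0),
    "t0_right": (50.0, 800.0),
    "dt_left": (-150.0, 150.0),
    "dt_right": (-150.0, 150.0),
    "sp": (-6.0, 6.0),
    "dcoh": (-20.0, 20.0),
}


@dataclass(frozen=True)
class DDMParams:
    """Parameters of the 9-parameter biased DDM family.

    Units: ``k`` in evidence/(ms * coherence fraction); ``A``, ``B``, ``sp``
    in evidence units (diffusion noise has unit variance per ms); non-decision
    times and their test-phase changes in ms; ``dcoh`` in percent-coherence
    points (divided by 100 internally).
    """

    k: float
    A: float
    B: float
    t0_left: float
    t0_right: float
    dt_left: float = 0.0
    dt_right: float = 0.0
    sp: float = 0.0
    dcoh: float = 0.0

    def validate(self) -> None:
        if self.A <= 0 or self.B <= 0:
            raise ValueError("bounds A and B must be positive")
        if self.t0_left < 0 or self.t0_right < 0:
            raise ValueError("non-decision times must be non-negative")
        if not (abs(self.sp) < min(self.A, self.B)):
            raise ValueError("|sp| must be smaller than min(A, B)")


@dataclass(frozen=True)
class ModelVariant:
    """One member of the nested model family: which bias terms are free."""

    name: str
    free_deltas: frozenset[str]

    @property
    def n_params(self) -> int:
        return 7 + len(self.free_deltas)


VARIANTS: Mapping[str, ModelVariant] = {
    "baseline": ModelVariant("baseline", frozenset()),
    "starting_point": ModelVariant("starting_point", frozenset({"sp"})),
    "sensory_evidence": ModelVariant("sensory_evidence", frozenset({"dcoh"})),
    "full": ModelVariant("full", frozenset({"sp", "dcoh"})),
}


def get_variant(variant: str | ModelVariant) -> ModelVariant:
    if isinstance(variant, ModelVariant):
        return variant
    try:
        return VARIANTS[variant]
    except KeyError:
        raise ValueError(f"unknown model variant {variant!r}") from None


@dataclass(frozen=True)
class ConditionSummary:
    """Per-condition aggregate consumed by the fitter.

    ``coherence`` is a non-zero signed fraction; correct trials are those whose
    response side matches the coherence sign.
    """

    coherence: float
    phase: str
    n: int
    n_right: int
    mean_rt_correct: float
    sd_rt_correct: float

    def __post_init__(self) -> None:
        if self.coherence == 0:
            raise ValueError("ConditionSummary requires non-zero coherence")
        if not 0 <= self.n_right <= self.n:
            raise ValueError("n_right must lie in [0, n]")
        if self.phase not in _PHASES:
            raise ValueError(f"unknown phase {self.phase!r}")

    @property
    def n_correct(self) -> int:
        return self.n_right if self.coherence > 0 else self.n - self.n_right


@dataclass(frozen=True)
class FitResult:
    """Outcome of one maximum-likelihood fit."""

    variant: ModelVariant
    params: DDMParams
    nll: float
    bic: float
    converged: bool
    n_obs: int
    n_starts: int = 0
    seed: int | None = None

    def to_dict(self) -> dict:
        d = {"variant": self.variant.name, "nll": self.nll, "bic": self.bic,
             "converged": self.converged, "n_obs": self.n_obs,
             "n_starts": self.n_starts, "seed": self.seed}
        d.update({name: getattr(self.params, name) for name in _PARAM_ORDER})
        return d


# ---------------------------------------------------------------------------
# closed forms


def effective_bounds(params: DDMParams, phase: str) -> tuple[float, float]:
    """Distances from the starting point to the right (a) and left (b) bound.

    In the test phase the starting-point shift moves the bounds to
    ``A - sp`` and ``-(B + sp)``; the baseline phase uses (A, B) unchanged.
    """
    if phase == BASELINE:
        return params.A, params.B
    if phase == TEST:
        return params.A - params.sp, params.B + params.sp
    raise ValueError(f"unknown phase {phase!r}")


def drift(params: DDMParams, coherence, phase: str):
    """Drift rate mu = k * Coh (baseline) or k * (Coh + dcoh/100) (test)."""
    coh = np.asarray(coherence, dtype=float)
    if phase == BASELINE:
        eff = coh
    elif phase == TEST:
        eff = coh + params.dcoh / 100.0
    else:
        raise ValueError(f"unknown phase {phase!r}")
    out = params.k * eff
    return float(out) if np.isscalar(coherence) else out


def _p_upper(mu, a: float, b: float):
    """P(absorb at upper bound) for drift mu, start 0, bounds (+a, -b).

    Stable rearrangement of (e^{2 mu b} - 1) / (e^{2 mu b} - e^{-2 mu a}):
    for mu > 0 multiply through by e^{-2 mu b}; for mu < 0 use the mirror
    identity p_up(mu, a, b) = 1 - p_up(-mu, b, a); near mu = 0 a Taylor
    ratio exact to O(mu^3).
    """
    m = np.asarray(mu, dtype=float)
    L = a + b
    small = np.abs(m) * L < 1e-4
    am = np.abs(m)

    def p_far(mm, dist):
        # probability of reaching the bound at distance `dist` against drift mm:
        # (e^{-2 mm dist} - e^{-2 mm L}) / (1 - e^{-2 mm L}); all terms decay,
        # so the value never cancels to zero
        return ((np.exp(-2.0 * mm * dist) - np.exp(-2.0 * mm * L))
                / -np.expm1(-2.0 * mm * L))

    with np.errstate(invalid="ignore", divide="ignore"):
        # drift toward upper: 1 - P(lower | distance b against drift); mirror else
        p = np.where(m >= 0, 1.0 - p_far(am, b), p_far(am, a))
    # series: (b + mu b^2 + 2/3 mu^2 b^3) / ((a+b) + mu(b^2-a^2) + 2/3 mu^2 (a^3+b^3))
    num = b + m * b**2 + (2.0 / 3.0) * m**2 * b**3
    den = L + m * (b**2 - a**2) + (2.0 / 3.0) * m**2 * (a**3 + b**3)
    return np.where(small, num / den, p)


def p_right(params: DDMParams, coherence, phase: str):
    """Probability of a rightward (upper-bound) decision.

    Continuous at mu = 0 with limit b/(a+b) for effective bounds (a, b).
    """
    a, b = effective_bounds(params, phase)
    if a <= 0 or b <= 0:
        raise ValueError("effective bounds must be positive (|sp| too large)")
    mu = np.atleast_1d(drift(params, coherence, phase))
    out = _p_upper(mu, a, b)
    return float(out[0]) if np.isscalar(coherence) else out


def _coth(x):
    return 1.0 / np.tanh(x)


def _t_upper(mu, a: float, b: float):
    """Mean decision time (ms) conditional on absorption at the upper bound.

    (a+b)/mu * coth(mu(a+b)) - b/mu * coth(mu*b); even in mu.  Near mu = 0
    the two 1/mu^2 singularities cancel; a series keeps the evaluation
    finite: ((a+b)^2 - b^2)/3 - mu^2 ((a+b)^4 - b^4)/45.
    """
    m = np.abs(np.asarray(mu, dtype=float))  # even function
    L = a + b
    small = m * L < 1e-3
    ms = np.where(small, 1.0, m)  # avoid divide-by-zero in the dead branch
    direct = (L / ms) * _coth(ms * L) - (b / ms) * _coth(ms * b)
    series = (L**2 - b**2) / 3.0 - m**2 * (L**4 - b**4) / 45.0
    return np.where(small, series, direct)


def mean_decision_time(params: DDMParams, coherence, phase: str, side: str):
    """Mean decision time (ms) conditional on the decision ``side``.

    ``side='right'`` conditions on upper-bound absorption, ``'left'`` on the
    lower bound.  Uses the mirror identity t_lower(mu, a, b) =
    t_upper(mu, b, a).
    """
    a, b = effective_bounds(params, phase)
    if a <= 0 or b <= 0:
        raise ValueError("effective bounds must be positive (|sp| too large)")
    mu = drift(params, coherence, phase)
    if side == "right":
        out = _t_upper(mu, a, b)
    elif side == "left":
        out = _t_upper(mu, b, a)
    else:
        raise ValueError(f"unknown side {side!r}")
    return float(out) if np.isscalar(coherence) else out


def nondecision_time(params: DDMParams, phase: str, side: str) -> float:
    """Side- and phase-specific non-decision time (ms)."""
    t0 = params.t0_left if side == "left" else params.t0_right
    if phase == TEST:
        t0 = t0 + (params.dt_left if side == "left" else params.dt_right)
    return t0


def predict_mean_rt_correct(params: DDMParams, coherence, phase: str):
    """Mean correct-trial RT: conditional decision time + that side's T0."""
    coh = np.atleast_1d(np.asarray(coherence, dtype=float))
    if np.any(coh == 0):
        raise ValueError("correct side undefined at zero coherence")
    t_r = mean_decision_time(params, coh, phase, "right") + nondecision_time(params, phase, "right")
    t_l = mean_decision_time(params, coh, phase, "left") + nondecision_time(params, phase, "left")
    out = np.where(coh > 0, t_r, t_l)
    return float(out[0]) if np.isscalar(coherence) else out


# ---------------------------------------------------------------------------
# likelihood and fitting


def _as_frame(conditions) -> pd.DataFrame:
    if isinstance(conditions, pd.DataFrame):
        df = conditions.copy()
    else:
        df = pd.DataFrame([c.to_dict() if hasattr(c, "to_dict") else vars(c) for c in conditions])
    required = {"coherence", "phase", "n", "n_right", "mean_rt_correct", "sd_rt_correct"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"condition table missing columns {sorted(missing)}")
    if (df["coherence"] == 0).any():
        raise ValueError("condition table must not contain zero coherence")
    return df


def _check_variant(params: DDMParams, variant: ModelVariant) -> None:
    if "sp" not in variant.free_deltas and params.sp != 0.0:
        raise ValueError(f"variant {variant.name!r} fixes sp = 0")
    if "dcoh" not in variant.free_deltas and params.dcoh != 0.0:
        raise ValueError(f"variant {variant.name!r} fixes dcoh = 0")


_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


def _prepare_data(df: pd.DataFrame) -> dict:
    """Precompute per-phase arrays (and likelihood constants) for fast NLL."""
    from scipy.special import gammaln

    prepared = {}
    for phase, sub in df.groupby("phase"):
        coh = sub["coherence"].to_numpy(dtype=float)
        n = sub["n"].to_numpy(dtype=float)
        n_r = sub["n_right"].to_numpy(dtype=float)
        n_corr = np.where(coh > 0, n_r, n - n_r)
        obs = sub["mean_rt_correct"].to_numpy(dtype=float)
        sd = sub["sd_rt_correct"].to_numpy(dtype=float)
        ok = (n_corr >= 2) & np.isfinite(obs) & np.isfinite(sd) & (sd > 0)
        se = np.where(ok, sd / np.sqrt(np.maximum(n_corr, 1.0)), 1.0)
        binom_const = float((gammaln(n + 1) - gammaln(n_r + 1) - gammaln(n - n_r + 1)).sum())
        rt_const = float((np.log(se[ok]) + _LOG_SQRT_2PI).sum())
        prepared[phase] = {
            "coh": coh, "n": n, "n_right": n_r, "is_right": coh > 0,
            "obs": obs, "se": se, "ok": ok,
            "const": -binom_const + rt_const,
        }
    return prepared


def _nll_prepared(params: DDMParams, prepared: dict) -> float:
    total = 0.0
    for phase, d in prepared.items():
        a, b = effective_bounds(params, phase)
        if a <= 1e-6 or b <= 1e-6:
            return np.inf
        mu = drift(params, d["coh"], phase)
        p = np.clip(_p_upper(mu, a, b), 1e-12, 1.0 - 1e-12)
        total -= float((d["n_right"] * np.log(p)
                        + (d["n"] - d["n_right"]) * np.log1p(-p)).sum())
        t_r = _t_upper(mu, a, b) + nondecision_time(params, phase, "right")
        t_l = _t_upper(mu, b, a) + nondecision_time(params, phase, "left")
        pred = np.where(d["is_right"], t_r, t_l)
        ok = d["ok"]
        z = (d["obs"][ok] - pred[ok]) / d["se"][ok]
        total += 0.5 * float((z * z).sum())
        total += d["const"]
    return total if np.isfinite(total) else np.inf


def negative_log_likelihood(params: DDMParams, variant: str | ModelVariant, conditions) -> float:
    """Joint NLL of choice proportions (binomial) and mean correct RTs (Gaussian).

    Per condition: a binomial term for the rightward-choice count given the
    closed-form choice probability, plus a Gaussian term for the mean correct
    RT around the model prediction with standard error sd/sqrt(n_correct).
    Conditions with fewer than two correct trials contribute no RT term.
    Invalid effective bounds return +inf rather than raising, so the
    optimizer can treat them as a penalty.
    """
    variant = get_variant(variant)
    _check_variant(params, variant)
    return _nll_prepared(params, _prepare_data(_as_frame(conditions)))


def count_data_points(conditions) -> int:
    """Fitted data points: one choice proportion + one mean RT per condition."""
    df = _as_frame(conditions)
    n_corr = np.where(df["coherence"] > 0, df["n_right"], df["n"] - df["n_right"])
    has_rt = (n_corr >= 2) & np.isfinite(df["mean_rt_correct"]) & (df["sd_rt_correct"] > 0)
    return int(len(df) + has_rt.sum())


def _vector_to_params(x: np.ndarray, variant: ModelVariant) -> DDMParams:
    kw = dict(zip(_PARAM_ORDER[:7], x[:7]))
    i = 7
    for name in ("sp", "dcoh"):
        if name in variant.free_deltas:
            kw[name] = x[i]
            i += 1
        else:
            kw[name] = 0.0
    return DDMParams(**kw)


def _free_names(variant: ModelVariant) -> list[str]:
    names = list(_PARAM_ORDER[:7])
    for name in ("sp", "dcoh"):
        if name in variant.free_deltas:
            names.append(name)
    return names


def _data_driven_start(df: pd.DataFrame, variant: ModelVariant) -> np.ndarray:
    """Crude moment-based initial guess; scattered starts cover the rest."""
    rt_min = float(np.nanmin(df["mean_rt_correct"])) if len(df) else 400.0
    t0 = max(100.0, rt_min - 80.0)
    x0 = {"k": 0.3, "A": 10.0, "B": 10.0, "t0_left": t0, "t0_right": t0,
          "dt_left": 0.0, "dt_right": 0.0, "sp": 0.0, "dcoh": 0.0}
    return np.array([x0[n] for n in _free_names(variant)])


def fit(
    conditions,
    variant: str | ModelVariant = "full",
    n_starts: int = 20,
    seed: int | None = 0,
    bounds: Mapping[str, tuple[float, float]] | None = None,
    x0_list: Sequence[Sequence[float]] | None = None,
    n_obs: int | None = None,
) -> FitResult:
    """Multi-start Nelder-Mead maximum-likelihood fit of one model variant.

    Starts are the moment-based guess plus ``n_starts - 1`` seed-controlled
    uniform draws within the search box (or explicit ``x0_list``).  Returns
    the best local optimum with its BIC; ``converged`` is False if every
    start failed to produce a finite optimum.
    """
    variant = get_variant(variant)
    df = _as_frame(conditions)
    names = _free_names(variant)
    box = dict(_DEFAULT_BOUNDS)
    if bounds:
        box.update(bounds)
    lo = np.array([box[n][0] for n in names])
    hi = np.array([box[n][1] for n in names])

    prepared = _prepare_data(df)

    def objective(x: np.ndarray) -> float:
        if np.any(x < lo) or np.any(x > hi):
            return np.inf
        try:
            return _nll_prepared(_vector_to_params(x, variant), prepared)
        except (ValueError, FloatingPointError):
            return np.inf

    rng = np.random.default_rng(seed)
    starts: list[np.ndarray] = []
    if x0_list is not None:
        starts.extend(np.asarray(x, dtype=float) for x in x0_list)
    else:
        starts.append(_data_driven_start(df, variant))
    while len(starts) < n_starts:
        starts.append(lo + rng.random(len(names)) * (hi - lo))

    best_x, best_f = None, np.inf
    for x0 in starts:
        x0 = np.clip(x0, lo, hi)
        if not np.isfinite(objective(x0)):
            continue
        res = optimize.minimize(objective, x0, method="Nelder-Mead",
                                options={"maxiter": 4000, "xatol": 1e-4, "fatol": 1e-6})
        if np.isfinite(res.fun) and res.fun < best_f:
            best_f, best_x = float(res.fun), res.x
    if best_x is not None:  # one polish pass from the incumbent
        res = optimize.minimize(objective, best_x, method="Nelder-Mead",
                                options={"maxiter": 4000, "xatol": 1e-5, "fatol": 1e-8})
        if np.isfinite(res.fun) and res.fun < best_f:
            best_f, best_x = float(res.fun), res.x

    n_pts = n_obs if n_obs is not None else count_data_points(df)
    if best_x is None:
        params = _vector_to_params(_data_driven_start(df, variant), variant)
        return FitResult(variant, params, np.inf, np.inf, False, n_pts, len(starts), seed)
    params = _vector_to_params(best_x, variant)
    bic = 2.0 * best_f + variant.n_params * math.log(n_pts)
    return FitResult(variant, params, best_f, bic, True, n_pts, len(starts), seed)


def mirror_params(params: DDMParams) -> DDMParams:
    """Left/right mirror image of a parameter set.

    Swaps the bounds and the side-specific non-decision terms and negates the
    bias terms; predictions at coherence -c under the mirror equal the
    opposite-side predictions at +c under the original.
    """
    return replace(
        params,
        A=params.B, B=params.A,
        t0_left=params.t0_right, t0_right=params.t0_left,
        dt_left=params.dt_right, dt_right=params.dt_left,
        sp=-params.sp, dcoh=-params.dcoh,
    )


def normalized_sp(fit_result: FitResult | DDMParams) -> float:
    """Starting-point shift normalized by the bound separation, sp/(A+B)."""
    p = fit_result.params if isinstance(fit_result, FitResult) else fit_result
    return p.sp / (p.A + p.B)
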