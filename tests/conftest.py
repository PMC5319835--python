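"""Shared fixtures: ground-truth parameter sets and simulated condition tables."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from motorbias import ddm_core, ddm_sim

# group-level parameter estimates used as generative ground truth throughout;
# sp follows the start-shift convention (positive = toward the rightward bound)
SP_ROW = ddm_core.DDMParams(k=0.29, A=11.76, B=12.02, t0_left=460.0, t0_right=459.0,
                            dt_left=-9.0, dt_right=-28.0, sp=-1.62, dcoh=0.0)
SE_ROW = ddm_core.DDMParams(k=0.29, A=11.59, B=12.20, t0_left=460.0, t0_right=458.0,
                            dt_left=-17.0, dt_right=-22.0, sp=0.0, dcoh=4.00)

COHERENCES = tuple(sorted(s * c for c in (0.032, 0.064, 0.128, 0.256, 0.512)
                          for s in (1, -1)))


def simulate_condition_table(params: ddm_core.DDMParams, n_per_cell: int,
                             seed: int, coherences=COHERENCES,
                             step_ms: float = 0.5) -> pd.DataFrame:
    """Condition summaries simulated from the trial-level DDM."""
    rng = np.random.default_rng(seed)
    rows = []
    for phase in (ddm_core.BASELINE, ddm_core.TEST):
        for coh in coherences:
            sim = ddm_sim.simulate_trials(params, coh, phase, n_per_cell, rng,
                                          step_ms=step_ms)
            corr = sim.loc[sim["correct"], "rt"]
            rows.append({
                "phase": phase, "coherence": coh, "n": n_per_cell,
                "n_right": int((sim["choice"] == "right").sum()),
                "mean_rt_correct": float(corr.mean()),
                "sd_rt_correct": float(corr.std(ddof=1)),
            })
    return pd.DataFrame(rows)


def exact_condition_table(params: ddm_core.DDMParams, n_per_cell: int = 1000,
                          coherences=COHERENCES, sd_rt: float = 60.0) -> pd.DataFrame:
    """Noise-free condition summaries placed exactly at the model predictions."""
    rows = []
    for phase in (ddm_core.BASELINE, ddm_core.TEST):
        p = ddm_core.p_right(params, np.array(coherences), phase)
        rt = ddm_core.predict_mean_rt_correct(params, np.array(coherences), phase)
        for coh, pi, rti in zip(coherences, p, rt):
            rows.append({
                "phase": phase, "coherence": coh, "n": n_per_cell,
                "n_right": int(round(pi * n_per_cell)),
                "mean_rt_correct": float(rti), "sd_rt_correct": sd_rt,
            })
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def sp_params() -> ddm_core.DDMParams:
    return SP_ROW


@pytest.fixture(scope="session")
def se_params() -> ddm_core.DDMParams:
    return SE_ROW


@pytest.fixture(scope="session")
def sp_sim_conditions() -> pd.DataFrame:
    """Moderate-size simulated dataset from the starting-point ground truth."""
    return simulate_condition_table(SP_ROW, n_per_cell=2000, seed=11)
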