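"""End-to-end orchestration: simulate -> filter/align -> psychophysics -> DDM -> comparison.

`run_full_analysis` reproduces the complete analysis chain on synthetic
cohorts: per-experiment PSE-shift tables, criterion-shift and window-decay
curves, condition aggregation, the four-variant DDM comparison with
participant bootstrap, individual full-model bias tests, and the error-RT
simulation contrast.  Every stage is a pure function of (inputs, seed); a
manifest records the configuration hash, seeds and package version.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps

from . import ddm_core, ddm_sim, model_selection, psychometrics, sdt, synthetic_data
from ._version import __version__
from .ddm_core import BASELINE, TEST
from .synthetic_data import ExperimentDesign, GenerativeParams

__all__ = ["RunConfig", "aggregate_conditions", "run_full_analysis",
           "participant_condition_tables", "manual_pse_table"]

log = logging.getLogger("motorbias")


@dataclass
class RunConfig:
    """Configuration of one full analysis run."""

    experiments: tuple[int, ...] = (1, 2, 3, 4)
    seed: int = 0
    out_dir: str = "motorbias_out"
    n_boot: int = 200
    n_starts: int = 20
    n_starts_individual: int = 6
    variants: tuple[str, ...] = model_selection.DEFAULT_VARIANTS
    trial_scale: float = 1.0  # scales blocks per phase (>= 1 block kept)
    participant_scale: float = 1.0
    error_rt_n_per_cell: int = 10_000
    step_ms: float = ddm_sim.DEFAULT_STEP_MS
    run_individual_fits: bool = True
    run_error_rt: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        for key in ("experiments", "variants"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _scaled_design(design: ExperimentDesign, cfg: RunConfig) -> ExperimentDesign:
    if cfg.trial_scale == 1.0 and cfg.participant_scale == 1.0:
        return design
    blocks = {ph: (max(1, round(nb * cfg.trial_scale)), per)
              for ph, (nb, per) in design.phase_blocks.items()}
    n = max(2, round(design.n_participants * cfg.participant_scale))
    sides = tuple(design.resisted_side_per_participant[i % design.n_participants]
                  for i in range(n))
    from dataclasses import replace
    return replace(design, phase_blocks=blocks, n_participants=n,
                   resisted_side_per_participant=sides)


def aggregate_conditions(trials: pd.DataFrame, drop_zero: bool = True) -> pd.DataFrame:
    """Per-(phase, coherence) aggregates for the DDM fitter.

    Input: RT-filtered, resistance-aligned manual discrimination trials of
    one participant.  Zero-coherence trials are excluded (no correct side);
    conditions whose correct-RT mean is undefined are kept with NaN RT and
    flagged.  Columns: phase, coherence, n, n_right, mean_rt_correct,
    sd_rt_correct, flagged.
    """
    man = trials.loc[(trials["modality"] == "manual")
                     & (trials["task"] == "discrimination")
                     & trials["phase"].isin([BASELINE, TEST])].copy()
    if drop_zero:
        man = man.loc[man["coherence"] != 0]
    man["is_right"] = man["response"] == "right"
    man["correct"] = np.sign(man["coherence"]) == np.where(man["is_right"], 1, -1)
    rows = []
    for (phase, coh), sub in man.groupby(["phase", "coherence"], sort=True):
        rts = sub.loc[sub["correct"], "rt"].to_numpy(dtype=float)
        rows.append({
            "phase": phase,
            "coherence": float(coh),
            "n": int(len(sub)),
            "n_right": int(sub["is_right"].sum()),
            "mean_rt_correct": float(rts.mean()) if len(rts) >= 1 else np.nan,
            "sd_rt_correct": float(rts.std(ddof=1)) if len(rts) >= 2 else np.nan,
            "flagged": len(rts) < 2,
        })
    return pd.DataFrame(rows)


def _aligned_manual(trials: pd.DataFrame) -> pd.DataFrame:
    """RT-filter and mirror right-resisted participants to the left convention."""
    parts = []
    for (_, side), sub in trials.groupby(["participant", "resisted_side"]):
        parts.append(psychometrics.align_by_resistance(sub, side))
    out = pd.concat(parts, ignore_index=True)
    return psychometrics.filter_rts(out)


def participant_condition_tables(trials: pd.DataFrame) -> dict[int, pd.DataFrame]:
    """Aligned, filtered per-participant condition tables keyed by participant id."""
    aligned = _aligned_manual(trials)
    return {int(pid): aggregate_conditions(sub)
            for pid, sub in aligned.groupby("participant")}


def manual_pse_table(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-participant manual psychometric fits and PSE shift (test - baseline)."""
    aligned = _aligned_manual(trials)
    man = aligned.loc[(aligned["modality"] == "manual")
                      & (aligned["task"] == "discrimination")]
    rows = []
    for pid, sub in man.groupby("participant"):
        fits = {ph: psychometrics.fit_psychometric(sub.loc[sub["phase"] == ph])
                for ph in (BASELINE, TEST)}
        rows.append({
            "participant": int(pid),
            "pse_baseline": fits[BASELINE].pse,
            "pse_test": fits[TEST].pse,
            "jnd_baseline": fits[BASELINE].jnd,
            "jnd_test": fits[TEST].jnd,
            "pse_shift": psychometrics.pse_shift(fits[BASELINE], fits[TEST]),
            "status": "ok" if fits[BASELINE].valid and fits[TEST].valid else "invalid",
        })
    return pd.DataFrame(rows)


def _shift_stats(shifts: np.ndarray) -> dict:
    """Descriptive replication aids (standard tests from scipy, not re-derived)."""
    shifts = shifts[np.isfinite(shifts)]
    out = {"n": int(shifts.size), "mean": float(np.mean(shifts)),
           "sem": float(sps.sem(shifts)) if shifts.size > 1 else float("nan")}
    if shifts.size > 1 and np.ptp(shifts) > 0:
        t = sps.ttest_1samp(shifts, 0.0)
        w = sps.wilcoxon(shifts)
        out.update(t_stat=float(t.statistic), t_p=float(t.pvalue),
                   wilcoxon_p=float(w.pvalue))
    return out


def _vocal_stage(exp_id: int, trials: pd.DataFrame) -> dict:
    """Vocal-task analyses: Exp 3 window PSE decay, Exp 4 criterion contrast."""
    out: dict = {}
    if exp_id == 3:
        curves = []
        for (pid, side), sub in trials.groupby(["participant", "resisted_side"]):
            aligned = psychometrics.align_by_resistance(sub, side)
            curve = psychometrics.sliding_window_pse(aligned, window=5)
            curve.insert(0, "participant", int(pid))
            curves.append(curve)
        table = pd.concat(curves, ignore_index=True)
        out["window_pse"] = table
        out["window_pse_mean"] = (table.groupby("window")["pse_shift"]
                                  .agg(["mean", "sem", "count"]).reset_index())
    elif exp_id == 4:
        contrasts, curves = [], []
        for pid, sub in trials.groupby("participant"):
            voc = sub.loc[sub["task"] == "detection"]
            res = {ph: {d: sdt.dprime_criterion(
                        sdt.counts_from_trials(voc.loc[voc["phase"] == ph], d))
                        for d in sdt.DIRECTIONS} for ph in (BASELINE, TEST)}
            pc = sdt.phase_contrast(res[BASELINE], res[TEST])
            contrasts.append({"participant": int(pid),
                              "dC_left": pc["left"][1], "dC_right": pc["right"][1],
                              "ddprime_left": pc["left"][0],
                              "ddprime_right": pc["right"][0]})
            curve = sdt.sliding_window_bias(voc, window=3)
            curve.insert(0, "participant", int(pid))
            curves.append(curve)
        out["criterion_contrast"] = pd.DataFrame(contrasts)
        table = pd.concat(curves, ignore_index=True)
        out["window_bias"] = table
        out["window_bias_mean"] = (table.groupby("window")["dC_right_minus_left"]
                                   .agg(["mean", "sem", "count"]).reset_index())
    return out


def run_full_analysis(config: RunConfig) -> dict:
    """Run the whole chain and write a report bundle under ``config.out_dir``.

    Returns a dict of in-memory results; on a stage failure the report marks
    the stage failed and keeps the upstream outputs.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__, "seed": config.seed,
        "config": asdict(config), "config_hash": config.config_hash(),
        "stages": {}, "exclusions": {},
    }
    results: dict = {"manifest": manifest}
    ddm_datasets: list[pd.DataFrame] = []
    pse_summaries = {}

    for exp_id in config.experiments:
        t0 = time.perf_counter()
        stage = f"experiment_{exp_id}"
        try:
            design = _scaled_design(ExperimentDesign.standard(exp_id), config)
            gen = GenerativeParams.for_experiment(exp_id)
            trials = synthetic_data.generate_experiment(
                design, gen, master_seed=config.seed + exp_id, step_ms=config.step_ms)
            synthetic_data.write_trials(trials, out_dir / f"exp{exp_id}_trials.csv")

            n_manual = int((trials["modality"] == "manual").sum())
            filtered = psychometrics.filter_rts(trials)
            manifest["exclusions"][stage] = {
                "rt_filter": n_manual - int((filtered["modality"] == "manual").sum()),
                "zero_coherence_ddm": int(((filtered["modality"] == "manual")
                                           & (filtered["coherence"] == 0)
                                           & filtered["phase"].isin([BASELINE, TEST])).sum()),
            }

            pse = manual_pse_table(trials)
            pse.to_csv(out_dir / f"exp{exp_id}_pse.csv", index=False)
            pse_summaries[exp_id] = _shift_stats(pse["pse_shift"].to_numpy())
            results[f"exp{exp_id}_pse"] = pse

            vocal = _vocal_stage(exp_id, trials)
            for name, obj in vocal.items():
                obj.to_csv(out_dir / f"exp{exp_id}_{name}.csv", index=False)
                results[f"exp{exp_id}_{name}"] = obj

            tables = participant_condition_tables(trials)
            ddm_datasets.extend(tables.values())
            manifest["stages"][stage] = {"status": "ok",
                                         "seconds": round(time.perf_counter() - t0, 2)}
        except Exception as exc:  # keep upstream outputs on partial failure
            log.exception("stage %s failed", stage)
            manifest["stages"][stage] = {"status": "failed", "error": repr(exc)}

    results["pse_shift_summary"] = pse_summaries
    with open(out_dir / "pse_shift_summary.json", "w") as fh:
        json.dump(pse_summaries, fh, indent=2)

    t0 = time.perf_counter()
    try:
        comparison = model_selection.bootstrap_comparison(
            ddm_datasets, n_boot=config.n_boot, seed=config.seed,
            variants=config.variants, n_starts=config.n_starts)
        comparison.to_frame().to_csv(out_dir / "model_comparison.csv", index=False)
        params_tbl = pd.DataFrame([f.to_dict() for f in comparison.group_fits.values()])
        params_tbl.to_csv(out_dir / "group_parameters.csv", index=False)
        results["comparison"] = comparison
        manifest["stages"]["model_comparison"] = {
            "status": "ok", "best": comparison.best,
            "seconds": round(time.perf_counter() - t0, 2)}
    except Exception as exc:
        log.exception("model comparison failed")
        manifest["stages"]["model_comparison"] = {"status": "failed", "error": repr(exc)}
        comparison = None

    if config.run_individual_fits:
        t0 = time.perf_counter()
        try:
            warm = None
            if comparison is not None and "full" in comparison.group_fits:
                fr = comparison.group_fits["full"]
                warm = [np.array([getattr(fr.params, nm)
                                  for nm in ddm_core._free_names(fr.variant)])]
            fits = []
            for i, dset in enumerate(ddm_datasets):
                starts = None
                if warm is not None:
                    rng = np.random.default_rng(config.seed + 1000 + i)
                    starts = [warm[0]] + [warm[0] * (1 + 0.05 * rng.standard_normal(len(warm[0])))
                                          for _ in range(config.n_starts_individual - 1)]
                fits.append(ddm_core.fit(dset, "full", seed=config.seed + 1000 + i,
                                         n_starts=config.n_starts_individual,
                                         x0_list=starts))
            results["individual_fits"] = fits
            if len(fits) >= 5:
                results["delta_tests"] = model_selection.individual_delta_tests(fits)
            else:
                results["delta_tests"] = {"n": len(fits),
                                          "note": "too few participants for signed-rank tests"}
            with open(out_dir / "individual_delta_tests.json", "w") as fh:
                json.dump(results["delta_tests"], fh, indent=2)
            manifest["stages"]["individual_fits"] = {
                "status": "ok", "seconds": round(time.perf_counter() - t0, 2)}
        except Exception as exc:
            log.exception("individual fits failed")
            manifest["stages"]["individual_fits"] = {"status": "failed", "error": repr(exc)}

    if config.run_error_rt and comparison is not None:
        t0 = time.perf_counter()
        try:
            cohs = [c * s for c in synthetic_data.STANDARD_COHERENCES for s in (1, -1)]
            tables = {}
            for variant in ("starting_point", "sensory_evidence"):
                if variant not in comparison.group_fits:
                    continue
                p = comparison.group_fits[variant].params
                tbl = ddm_sim.error_rt_contrast(p, p, sorted(cohs),
                                                n_per_cell=config.error_rt_n_per_cell,
                                                seed=config.seed,
                                                step_ms=config.step_ms)
                tbl.insert(0, "model", variant)
                tbl.to_csv(out_dir / f"error_rt_{variant}.csv", index=False)
                tables[variant] = tbl
            results["error_rt"] = tables
            manifest["stages"]["error_rt"] = {
                "status": "ok", "seconds": round(time.perf_counter() - t0, 2)}
        except Exception as exc:
            log.exception("error-RT simulation failed")
            manifest["stages"]["error_rt"] = {"status": "failed", "error": repr(exc)}

    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return results
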