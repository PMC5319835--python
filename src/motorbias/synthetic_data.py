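"""Synthetic motor-cost experiments: trial tables with the structure the analysis assumes.

Emulates four random-dot-motion experiments in which a viscous resistance on
one hand (the "motor cost") ramps up during an induction phase:

1. manual left/right discrimination, baseline / induction / test phases;
2. as 1, but the induction movements are instructed (no visual judgement);
3. manual discrimination interleaved with *vocal* discrimination in 10+10
   mini-blocks; resistance side counterbalanced across participants;
4. manual discrimination interleaved with vocal yes/no *detection* in 11+7
   mini-blocks.

Manual choices and RTs come from the biased DDM (:mod:`motorbias.ddm_sim`)
with the bias terms active only in the test phase.  Vocal discrimination
responses are Bernoulli draws from a logistic psychometric whose PSE is
offset, and detection responses come from an equal-variance signal-detection
model whose criterion for the resisted direction is offset; both offsets
decay exponentially with the number of trials since the last manual trial.
The viscous-resistance schedule (coefficient vs. number of resisted-hand
movements) is modelled explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from . import ddm_core, ddm_sim
from .ddm_core import BASELINE, TEST, DDMParams

__all__ = [
    "RESISTANCE_BASE",
    "RESISTANCE_INCREMENT",
    "RESISTANCE_CEILING",
    "resistance_schedule",
    "resistive_force",
    "ExperimentDesign",
    "GenerativeParams",
    "TrialRecord",
    "generate_manual_trials",
    "generate_vocal_trials",
    "generate_experiment",
    "write_trials",
    "read_trials",
    "TRIAL_COLUMNS",
]

# viscous resistance schedule (Ns/cm): f = -alpha * v
RESISTANCE_BASE = 0.10
RESISTANCE_INCREMENT = 0.0008
RESISTANCE_CEILING = 0.18

STANDARD_COHERENCES = (0.032, 0.064, 0.128, 0.256, 0.512)


def resistance_schedule(n_left_moves, base: float = RESISTANCE_BASE,
                        increment: float = RESISTANCE_INCREMENT,
                        ceiling: float = RESISTANCE_CEILING):
    """Viscosity coefficient (Ns/cm) after ``n_left_moves`` resisted-hand moves.

    Starts at 0.10, grows by 0.0008 per movement, saturates at 0.18.
    """
    n = np.asarray(n_left_moves)
    if np.any(n < 0):
        raise ValueError("number of movements must be non-negative")
    out = np.minimum(base + increment * n, ceiling)
    return float(out) if np.isscalar(n_left_moves) else out


def resistive_force(alpha: float, velocity) -> np.ndarray:
    """Velocity-dependent resistive force [fx, fy] = -alpha [vx, vy] (N)."""
    if alpha < 0:
        raise ValueError("viscosity coefficient must be non-negative")
    return -alpha * np.asarray(velocity, dtype=float)


@dataclass(frozen=True)
class ExperimentDesign:
    """Layout of one experiment: phases, blocks, coherences, mini-blocks."""

    experiment_id: int
    n_participants: int
    coherence_levels: tuple[float, ...]  # signed fractions, includes 0 if used
    phase_blocks: dict  # phase -> (n_blocks, trials_per_block)
    miniblock_layout: tuple[int, int] | None = None  # (manual, vocal) per mini-block
    vocal_task: str | None = None  # discrimination | detection
    resisted_side_per_participant: tuple[str, ...] = ()
    induction_instructed: bool = False  # Exp 2: arrow-following movements

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        levels = set(self.coherence_levels)
        nonzero = {c for c in levels if c != 0}
        if {-c for c in nonzero} != nonzero:
            raise ValueError("coherence levels must be symmetric about 0")
        if len(self.resisted_side_per_participant) != self.n_participants:
            raise ValueError("resisted side must be given per participant")
        if any(s not in ("left", "right") for s in self.resisted_side_per_participant):
            raise ValueError("resisted side must be 'left' or 'right'")
        if self.miniblock_layout is not None and self.vocal_task is None:
            raise ValueError("mini-block designs need a vocal task")

    @classmethod
    def standard(cls, experiment_id: int, n_participants: int | None = None) -> "ExperimentDesign":
        """The four canonical designs (analysed sample sizes 10/9/14/12)."""
        pm = [c * s for c in STANDARD_COHERENCES for s in (+1, -1)]
        if experiment_id == 1:
            n = n_participants or 10
            return cls(1, n, tuple(sorted(pm + [0.0])),
                       {"baseline": (5, 66), "induction": (15, 66), "test": (5, 66)},
                       resisted_side_per_participant=("left",) * n)
        if experiment_id == 2:
            n = n_participants or 9
            return cls(2, n, tuple(sorted(pm + [0.0])),
                       {"baseline": (5, 66), "induction": (15, 66), "test": (5, 66)},
                       resisted_side_per_participant=("left",) * n,
                       induction_instructed=True)
        if experiment_id == 3:
            n = n_participants or 14
            sides = tuple("left" if i < (n + 1) // 2 else "right" for i in range(n))
            return cls(3, n, tuple(sorted(pm)),
                       {"baseline": (4, 80), "induction": (14, 60), "test": (4, 80)},
                       miniblock_layout=(10, 10), vocal_task="discrimination",
                       resisted_side_per_participant=sides)
        if experiment_id == 4:
            n = n_participants or 12
            return cls(4, n, tuple(sorted(pm + [0.0])),
                       {"baseline": (6, 72), "induction": (13, 66), "test": (6, 72)},
                       miniblock_layout=(11, 7), vocal_task="detection",
                       resisted_side_per_participant=("left",) * n)
        raise ValueError("experiment_id must be 1-4")


@dataclass(frozen=True)
class GenerativeParams:
    """Ground-truth parameters behind a synthetic experiment.

    ``ddm`` holds the baseline DDM parameters together with the test-phase
    bias terms (sp, dcoh) and non-decision changes, all inactive in the
    baseline phase.  Vocal biases are the offset at the first vocal trial
    after a manual run, decaying as exp(-decay * trials_since_manual-1).
    """

    ddm: DDMParams = field(default_factory=lambda: DDMParams(
        k=0.29, A=11.76, B=12.02, t0_left=460.0, t0_right=459.0,
        dt_left=-9.0, dt_right=-28.0, sp=1.62, dcoh=0.0))
    vocal_bias_magnitude: float = -3.5  # PSE shift (% coh) or criterion shift
    vocal_bias_decay: float = 0.05  # per vocal trial since last manual trial
    vocal_slope: float = 0.12  # logistic slope per % coherence (discrimination)
    lapse_rate: float = 0.02
    detection_dprime: float = 1.349  # ~75% correct at a neutral criterion
    detection_criterion: float = 0.0
    detection_coherence: float = 0.064  # near-threshold magnitude, bookkeeping only

    def __post_init__(self) -> None:
        if not 0 <= self.lapse_rate <= 0.1:
            raise ValueError("lapse_rate must be in [0, 0.1]")
        if self.vocal_bias_decay < 0:
            raise ValueError("decay rate must be non-negative")
        if self.detection_dprime < 0:
            raise ValueError("baseline d' must be non-negative")

    @classmethod
    def for_experiment(cls, experiment_id: int) -> "GenerativeParams":
        """Defaults per experiment; Exp 4 uses a criterion bias that decays."""
        if experiment_id == 4:
            return cls(vocal_bias_magnitude=0.4, vocal_bias_decay=0.35)
        return cls()


@dataclass(frozen=True)
class TrialRecord:
    """One behavioural trial row (see ``TRIAL_COLUMNS`` for the CSV schema)."""

    participant: int
    phase: str  # baseline | induction | test
    modality: str  # manual | vocal
    task: str  # discrimination | detection | instructed
    coherence: float  # signed fraction; 0 for noise-only detection trials
    response: str  # left | right | yes | no
    instructed_direction: str = "none"
    signal_present: bool | None = None  # detection only
    rt: float | None = None  # ms, manual only
    trials_since_manual: int | None = None  # vocal only
    block: int = 0
    miniblock: int = 0
    pos: int = 0  # position within the (mini-)block, 1-based

    def __post_init__(self) -> None:
        if (self.rt is not None) != (self.modality == "manual"):
            raise ValueError("rt must be present iff modality is manual")
        if (self.signal_present is not None) != (self.task == "detection"):
            raise ValueError("signal_present defined iff task is detection")


TRIAL_COLUMNS = [
    "experiment", "participant", "phase", "block", "miniblock", "pos",
    "modality", "task", "coherence", "instructed_direction", "signal_present",
    "response", "rt", "trials_since_manual", "resistance_coeff", "resisted_side",
]


def _phase_for_ddm(phase: str) -> str:
    # the bias terms are active only in the test phase; the induction phase is
    # generated from the baseline parameter set
    return TEST if phase == TEST else BASELINE


def _participant_ddm(gen: GenerativeParams, resisted_side: str) -> DDMParams:
    """Ground-truth DDM for one participant, mirrored if the right hand is resisted."""
    return gen.ddm if resisted_side == "left" else ddm_core.mirror_params(gen.ddm)


def _balanced_coherences(levels: Sequence[float], n_trials: int,
                         rng: np.random.Generator) -> np.ndarray:
    reps = int(np.ceil(n_trials / len(levels)))
    seq = np.tile(np.asarray(levels, dtype=float), reps)[:n_trials]
    rng.shuffle(seq)
    return seq


def _manual_layout(design: ExperimentDesign, phase: str) -> tuple[int, int, int]:
    """(n_blocks, miniblocks_per_block, manual_trials_per_miniblock)."""
    n_blocks, per_block = design.phase_blocks[phase]
    if design.miniblock_layout is None or phase == "induction":
        return n_blocks, 1, per_block
    man, voc = design.miniblock_layout
    n_mini = per_block // (man + voc)
    return n_blocks, n_mini, man


def generate_manual_trials(
    design: ExperimentDesign,
    gen: GenerativeParams,
    participant: int,
    phase: str,
    rng: np.random.Generator,
    step_ms: float = ddm_sim.DEFAULT_STEP_MS,
) -> list[TrialRecord]:
    """Manual discrimination trials for one participant and phase.

    Choices and RTs are first-passage draws from the participant's DDM
    (bias terms active in the test phase only); RT = decision time + the
    responding side's non-decision time.
    """
    if phase not in design.phase_blocks:
        raise ValueError(f"unknown phase {phase!r}")
    side = design.resisted_side_per_participant[participant]
    params = _participant_ddm(gen, side)
    ddm_phase = _phase_for_ddm(phase)

    if design.induction_instructed and phase == "induction":
        return _instructed_trials(design, params, participant, phase, rng, step_ms)

    n_blocks, n_mini, man = _manual_layout(design, phase)
    records: list[TrialRecord] = []
    # draw the coherence sequence first, then simulate grouped by coherence
    layout = [(b, mb, p) for b in range(1, n_blocks + 1)
              for mb in range(1, n_mini + 1) for p in range(1, man + 1)]
    cohs = _balanced_coherences(design.coherence_levels, len(layout), rng)
    sims: dict[float, pd.DataFrame] = {}
    for c in np.unique(cohs):
        n_c = int((cohs == c).sum())
        sims[c] = ddm_sim.simulate_trials(params, float(c), ddm_phase, n_c, rng,
                                          step_ms=step_ms)
    cursor = {c: 0 for c in sims}
    for (b, mb, p), c in zip(layout, cohs):
        row = sims[c].iloc[cursor[c]]
        cursor[c] += 1
        records.append(TrialRecord(
            participant=participant, phase=phase, modality="manual",
            task="discrimination", coherence=float(c), response=row["choice"],
            rt=float(row["rt"]), block=b, miniblock=mb, pos=p))
    return records


def _instructed_trials(design, params, participant, phase, rng, step_ms) -> list[TrialRecord]:
    """Arrow-instructed movements (Exp 2 induction): no visual judgement."""
    n_blocks, per_block = design.phase_blocks[phase]
    records = []
    for b in range(1, n_blocks + 1):
        dirs = _balanced_coherences((-1.0, 1.0), per_block, rng)
        for c in (-1.0, 1.0):
            n_c = int((dirs == c).sum())
            sim = ddm_sim.simulate_trials(params, c, _phase_for_ddm(phase), n_c, rng,
                                          step_ms=step_ms)
            dirs_idx = np.flatnonzero(dirs == c)
            for i, p in enumerate(dirs_idx):
                side = "right" if c > 0 else "left"
                records.append(TrialRecord(
                    participant=participant, phase=phase, modality="manual",
                    task="instructed", coherence=c, response=side,
                    instructed_direction=side, rt=float(sim["rt"].iloc[i]),
                    block=b, miniblock=1, pos=int(p) + 1))
    records.sort(key=lambda r: (r.block, r.pos))
    return records


def _vocal_bias(gen: GenerativeParams, phase: str, tsm: np.ndarray) -> np.ndarray:
    """Bias offset per trial: magnitude * exp(-decay * (tsm - 1)) in test, 0 else."""
    if phase != TEST:
        return np.zeros_like(tsm, dtype=float)
    return gen.vocal_bias_magnitude * np.exp(-gen.vocal_bias_decay * (tsm - 1.0))


def generate_vocal_trials(
    design: ExperimentDesign,
    gen: GenerativeParams,
    participant: int,
    phase: str,
    rng: np.random.Generator,
) -> list[TrialRecord]:
    """Vocal trials for one participant and phase (discrimination or detection).

    Discrimination: P(right) is a logistic in coherence (%) whose PSE equals
    the decaying bias offset.  Detection: yes/no responses from an
    equal-variance SDT model; the criterion for the resisted direction
    carries the decaying offset.  A lapse rate mixes in uniform guessing.
    """
    if design.vocal_task is None:
        raise ValueError("design has no vocal task")
    if phase == "induction":
        return []
    side = design.resisted_side_per_participant[participant]
    man, voc = design.miniblock_layout
    n_blocks, per_block = design.phase_blocks[phase]
    n_mini = per_block // (man + voc)

    blocks = np.repeat(np.arange(1, n_blocks + 1), n_mini * voc)
    minis = np.tile(np.repeat(np.arange(1, n_mini + 1), voc), n_blocks)
    tsm = np.tile(np.arange(1, voc + 1), n_blocks * n_mini)
    n_total = tsm.size
    lapse = rng.random(n_total) < gen.lapse_rate
    guess = rng.random(n_total) < 0.5

    records: list[TrialRecord] = []
    if design.vocal_task == "discrimination":
        levels = [c for c in design.coherence_levels if c != 0]
        cohs = _balanced_coherences(levels, n_total, rng)
        pse = _vocal_bias(gen, phase, tsm)
        if side == "right":
            pse = -pse  # bias mirrored for right-hand resistance
        p_right = expit(gen.vocal_slope * (cohs * 100.0 - pse))
        is_right = np.where(lapse, guess, rng.random(n_total) < p_right)
        for i in range(n_total):
            records.append(TrialRecord(
                participant=participant, phase=phase, modality="vocal",
                task="discrimination", coherence=float(cohs[i]),
                response="right" if is_right[i] else "left",
                trials_since_manual=int(tsm[i]),
                block=int(blocks[i]), miniblock=int(minis[i]), pos=int(tsm[i])))
    elif design.vocal_task == "detection":
        instructed = np.where(rng.random(n_total) < 0.5, "left", "right")
        signal = rng.random(n_total) < 0.5
        crit = np.full(n_total, gen.detection_criterion, dtype=float)
        crit += np.where(instructed == side, _vocal_bias(gen, phase, tsm), 0.0)
        d = gen.detection_dprime
        p_yes = np.where(signal, norm.cdf(d / 2.0 - crit), norm.cdf(-d / 2.0 - crit))
        say_yes = np.where(lapse, guess, rng.random(n_total) < p_yes)
        sign = np.where(instructed == "right", 1.0, -1.0)
        coh = np.where(signal, sign * gen.detection_coherence, 0.0)
        for i in range(n_total):
            records.append(TrialRecord(
                participant=participant, phase=phase, modality="vocal",
                task="detection", coherence=float(coh[i]),
                response="yes" if say_yes[i] else "no",
                instructed_direction=str(instructed[i]),
                signal_present=bool(signal[i]), trials_since_manual=int(tsm[i]),
                block=int(blocks[i]), miniblock=int(minis[i]), pos=int(tsm[i])))
    else:
        raise ValueError(f"unknown vocal task {design.vocal_task!r}")
    return records


def _records_to_frame(records: list[TrialRecord], design: ExperimentDesign,
                      participant: int) -> pd.DataFrame:
    side = design.resisted_side_per_participant[participant]
    df = pd.DataFrame([{
        "experiment": design.experiment_id,
        "participant": r.participant,
        "phase": r.phase,
        "block": r.block,
        "miniblock": r.miniblock,
        "pos": r.pos,
        "modality": r.modality,
        "task": r.task,
        "coherence": r.coherence,
        "instructed_direction": r.instructed_direction,
        "signal_present": r.signal_present,
        "response": r.response,
        "rt": r.rt,
        "trials_since_manual": r.trials_since_manual,
        "resisted_side": side,
    } for r in records])
    return df


_PHASE_ORDER = {"baseline": 0, "induction": 1, "test": 2}


def _attach_resistance(df: pd.DataFrame, resisted_side: str) -> pd.DataFrame:
    """Per-trial viscosity coefficient from the movement count of the resisted hand."""
    df = df.copy()
    coeff = np.full(len(df), RESISTANCE_BASE)
    ind = df["phase"] == "induction"
    moves = ((df["modality"] == "manual") & (df["response"] == resisted_side) & ind)
    # coefficient in force *before* each movement: cumulative count of prior moves
    prior = moves.cumsum().shift(fill_value=0)[ind].to_numpy()
    coeff[ind.to_numpy()] = resistance_schedule(prior)
    n_total = int(moves.sum())
    coeff[(df["phase"] == "test").to_numpy()] = resistance_schedule(n_total)
    df["resistance_coeff"] = coeff
    return df


def generate_experiment(
    design: ExperimentDesign,
    gen: GenerativeParams | None = None,
    master_seed: int = 0,
    step_ms: float = ddm_sim.DEFAULT_STEP_MS,
) -> pd.DataFrame:
    """Full synthetic experiment: all participants, phases and modalities.

    One master seed spawns an independent substream per participant, so any
    participant's data can be regenerated in isolation.  Mini-block designs
    interleave manual and vocal runs within each block in the order performed.
    """
    if gen is None:
        gen = GenerativeParams.for_experiment(design.experiment_id)
    ss = np.random.SeedSequence(master_seed)
    children = ss.spawn(design.n_participants)
    frames = []
    for pid in range(design.n_participants):
        rng = np.random.default_rng(children[pid])
        records: list[TrialRecord] = []
        for phase in ("baseline", "induction", "test"):
            records.extend(generate_manual_trials(design, gen, pid, phase, rng, step_ms))
            if design.miniblock_layout is not None:
                records.extend(generate_vocal_trials(design, gen, pid, phase, rng))
        df = _records_to_frame(records, design, pid)
        df["_ph"] = df["phase"].map(_PHASE_ORDER)
        df["_mod"] = (df["modality"] == "vocal").astype(int)  # manual first in a mini-block
        df = (df.sort_values(["_ph", "block", "miniblock", "_mod", "pos"], kind="stable")
                .drop(columns=["_ph", "_mod"]).reset_index(drop=True))
        df = _attach_resistance(df, design.resisted_side_per_participant[pid])
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    return out[TRIAL_COLUMNS]


def write_trials(df: pd.DataFrame, path) -> None:
    """Write a trial table as CSV (tidy, one row per trial)."""
    df.to_csv(path, index=False, float_format="%.6g")


def read_trials(path) -> pd.DataFrame:
    """Read a trial table written by :func:`write_trials`."""
    df = pd.read_csv(path)
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trial table missing columns {sorted(missing)}")
    return df
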