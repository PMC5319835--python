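"""Synthetic-experiment generator: resistance model, designs, trial statistics."""

import io
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from motorbias import ddm_core as dc, synthetic_data as sy


class TestResistance:
    @pytest.mark.parametrize("n_moves,expected", [
        (0, 0.10),      # starting coefficient
        (50, 0.14),     # 0.10 + 50 * 0.0008
        (100, 0.18),    # exactly at the ceiling
        (500, 0.18),    # held at the ceiling thereafter
    ])
    def test_schedule_values(self, n_moves, expected):
        assert sy.resistance_schedule(n_moves) == pytest.approx(expected)

    def test_schedule_monotone_and_bounded(self):
        traj = sy.resistance_schedule(np.arange(0, 1200))
        assert np.all(np.diff(traj) >= 0)
        assert traj.min() == 0.10 and traj.max() == 0.18

    def test_schedule_rejects_negative(self):
        with pytest.raises(ValueError):
            sy.resistance_schedule(-1)

    @pytest.mark.parametrize("alpha,v,expected", [
        (0.10, (40.0, 0.0), (-4.0, 0.0)),
        (0.18, (0.0, 0.0), (0.0, 0.0)),
        (0.18, (40.0, 30.0), (-7.2, -5.4)),
    ])
    def test_resistive_force(self, alpha, v, expected):
        np.testing.assert_allclose(sy.resistive_force(alpha, v), expected)

    def test_resistive_force_antiparallel(self):
        v = np.array([12.0, -5.0])
        f = sy.resistive_force(0.13, v)
        assert np.dot(f, v) < 0
        assert f[0] * v[1] - f[1] * v[0] == pytest.approx(0.0)


class TestDesigns:
    def test_standard_designs_validate(self):
        for i in (1, 2, 3, 4):
            d = sy.ExperimentDesign.standard(i)
            nz = sorted(abs(c) for c in d.coherence_levels if c != 0)
            assert set(nz) == {0.032, 0.064, 0.128, 0.256, 0.512}

    def test_zero_coherence_membership(self):
        # the interleaved discrimination experiment uses no 0% trials
        assert 0.0 not in sy.ExperimentDesign.standard(3).coherence_levels
        for i in (1, 2, 4):
            assert 0.0 in sy.ExperimentDesign.standard(i).coherence_levels

    def test_miniblock_layouts(self):
        assert sy.ExperimentDesign.standard(3).miniblock_layout == (10, 10)
        assert sy.ExperimentDesign.standard(4).miniblock_layout == (11, 7)

    def test_asymmetric_levels_rejected(self):
        with pytest.raises(ValueError):
            sy.ExperimentDesign(1, 1, (0.1, -0.2), {"baseline": (1, 10)},
                                resisted_side_per_participant=("left",))

    def test_lapse_and_decay_validation(self):
        with pytest.raises(ValueError):
            sy.GenerativeParams(lapse_rate=0.5)
        with pytest.raises(ValueError):
            sy.GenerativeParams(vocal_bias_decay=-1.0)


def tiny_design(exp=3, n=2, blocks=1):
    d = sy.ExperimentDesign.standard(exp, n)
    phase_blocks = {ph: (min(blocks, nb) if ph != "induction" else 1, per)
                    for ph, (nb, per) in d.phase_blocks.items()}
    return replace(d, phase_blocks=phase_blocks)


class TestGeneration:
    def test_deterministic_byte_identical_output(self):
        d = tiny_design()
        t1 = sy.generate_experiment(d, master_seed=3)
        t2 = sy.generate_experiment(d, master_seed=3)
        b1, b2 = io.StringIO(), io.StringIO()
        sy.write_trials(t1, b1)
        sy.write_trials(t2, b2)
        assert b1.getvalue() == b2.getvalue()

    def test_miniblock_alternation(self):
        tr = sy.generate_experiment(tiny_design(3, 1), master_seed=0)
        blk = tr[(tr.phase == "baseline") & (tr.block == 1)]
        seq = "".join("M" if m == "manual" else "V" for m in blk["modality"])
        assert seq == ("M" * 10 + "V" * 10) * 4

    def test_exp4_miniblock_layout(self):
        tr = sy.generate_experiment(tiny_design(4, 1), master_seed=0)
        blk = tr[(tr.phase == "test") & (tr.block == 1)]
        seq = "".join("M" if m == "manual" else "V" for m in blk["modality"])
        assert seq == ("M" * 11 + "V" * 7) * 4

    def test_full_induction_reaches_ceiling(self):
        # 15 blocks x 66 trials with ~half leftward responses crosses 100 moves
        d = replace(sy.ExperimentDesign.standard(1, 1),
                    phase_blocks={"baseline": (1, 66), "induction": (15, 66),
                                  "test": (1, 66)})
        tr = sy.generate_experiment(d, master_seed=1)
        ind = tr[tr.phase == "induction"]
        assert ind["resistance_coeff"].iloc[0] == pytest.approx(0.10)
        assert ind["resistance_coeff"].max() == pytest.approx(0.18)
        assert np.all(np.diff(ind["resistance_coeff"]) >= 0)
        assert (tr.loc[tr.phase == "test", "resistance_coeff"] == 0.18).all()
        assert (tr.loc[tr.phase == "baseline", "resistance_coeff"] == 0.10).all()

    def test_manual_rt_exceeds_nondecision_time(self):
        gen = sy.GenerativeParams()
        tr = sy.generate_experiment(tiny_design(1, 1), gen, master_seed=2)
        man = tr[(tr.modality == "manual") & tr.phase.isin(["baseline", "test"])]
        for (phase, resp), sub in man.groupby(["phase", "response"]):
            t0 = dc.nondecision_time(gen.ddm, "test" if phase == "test" else "baseline",
                                     resp)
            assert (sub["rt"] > t0).all()

    def test_manual_choice_proportions_match_closed_form(self):
        # unbiased symmetric model at 0 coherence: P(right) = 1/2
        gen = sy.GenerativeParams(ddm=dc.DDMParams(
            k=0.3, A=8.0, B=8.0, t0_left=300.0, t0_right=300.0))
        d = replace(sy.ExperimentDesign.standard(1, 1),
                    coherence_levels=(0.0,),
                    phase_blocks={"baseline": (1, 4000), "induction": (1, 10),
                                  "test": (1, 10)})
        recs = sy.generate_manual_trials(d, gen, 0, "baseline",
                                         np.random.default_rng(0))
        p_hat = np.mean([r.response == "right" for r in recs])
        assert p_hat == pytest.approx(0.5, abs=3 * 0.5 / np.sqrt(4000))

    def test_manual_biased_choice_proportions_match_closed_form(self):
        # test phase with a start shift: P(right) follows the closed form
        gen = sy.GenerativeParams()
        d = replace(sy.ExperimentDesign.standard(1, 1),
                    coherence_levels=(0.0,),
                    phase_blocks={"baseline": (1, 10), "induction": (1, 10),
                                  "test": (1, 4000)})
        recs = sy.generate_manual_trials(d, gen, 0, "test", np.random.default_rng(1))
        p_hat = np.mean([r.response == "right" for r in recs])
        p_th = dc.p_right(gen.ddm, 0.0, "test")
        assert p_th > 0.5  # bias away from the costly (left) response
        assert p_hat == pytest.approx(p_th, abs=3 * np.sqrt(p_th * (1 - p_th) / 4000))

    def test_unknown_phase_rejected(self):
        d = tiny_design(1, 1)
        with pytest.raises(ValueError):
            sy.generate_manual_trials(d, sy.GenerativeParams(), 0, "warmup",
                                      np.random.default_rng(0))


class TestVocalGeneration:
    def test_null_generator_has_no_phase_effect(self):
        gen = sy.GenerativeParams(vocal_bias_magnitude=0.0, vocal_bias_decay=0.0,
                                  lapse_rate=0.0)
        d = replace(sy.ExperimentDesign.standard(3, 1),
                    phase_blocks={"baseline": (25, 80), "induction": (1, 60),
                                  "test": (25, 80)})
        rng = np.random.default_rng(0)
        base = sy.generate_vocal_trials(d, gen, 0, "baseline", rng)
        test = sy.generate_vocal_trials(d, gen, 0, "test", rng)
        from motorbias import psychometrics as ps
        df = sy._records_to_frame(base + test, d, 0)
        f_b = ps.fit_psychometric(df[df.phase == "baseline"])
        f_t = ps.fit_psychometric(df[df.phase == "test"])
        assert ps.pse_shift(f_b, f_t) == pytest.approx(0.0, abs=1.0)

    def test_constant_bias_recovered_by_psychometric_fit(self):
        gen = sy.GenerativeParams(vocal_bias_magnitude=-3.0, vocal_bias_decay=0.0,
                                  lapse_rate=0.0)
        d = replace(sy.ExperimentDesign.standard(3, 1),
                    phase_blocks={"baseline": (40, 80), "induction": (1, 60),
                                  "test": (40, 80)})
        rng = np.random.default_rng(4)
        recs = sy.generate_vocal_trials(d, gen, 0, "test", rng)
        from motorbias import psychometrics as ps
        f = ps.fit_psychometric(sy._records_to_frame(recs, d, 0))
        assert f.pse == pytest.approx(-3.0, abs=0.8)

    def test_detection_false_alarm_rate_matches_sdt_model(self):
        gen = sy.GenerativeParams(vocal_bias_magnitude=0.0, lapse_rate=0.0,
                                  detection_dprime=1.6, detection_criterion=0.0)
        d = replace(sy.ExperimentDesign.standard(4, 1),
                    phase_blocks={"baseline": (150, 72), "induction": (1, 66),
                                  "test": (1, 72)})
        recs = sy.generate_vocal_trials(d, gen, 0, "baseline",
                                        np.random.default_rng(8))
        df = sy._records_to_frame(recs, d, 0)
        noise = df[~df.signal_present.astype(bool)]
        fa = (noise.response == "yes").mean()
        expected = norm.cdf(-1.6 / 2.0)
        assert fa == pytest.approx(expected, abs=3 * np.sqrt(expected * (1 - expected)
                                                             / len(noise)))

    def test_vocal_bias_vanishes_far_from_manual_trials(self):
        gen = sy.GenerativeParams.for_experiment(4)
        tsm = np.array([1.0, 4.0, 7.0, 50.0])
        bias = sy._vocal_bias(gen, "test", tsm)
        assert abs(bias[0]) == pytest.approx(gen.vocal_bias_magnitude, abs=1e-12)
        assert abs(bias[1]) < abs(bias[0])
        assert abs(bias[3]) < 1e-7
        assert np.all(sy._vocal_bias(gen, "baseline", tsm) == 0.0)


class TestRoundTrip:
    def test_csv_round_trip(self, tmp_path):
        tr = sy.generate_experiment(tiny_design(4, 1), master_seed=6)
        path = tmp_path / "trials.csv"
        sy.write_trials(tr, path)
        back = sy.read_trials(path)
        assert len(back) == len(tr)
        assert list(back.columns) == sy.TRIAL_COLUMNS
        pd.testing.assert_series_equal(back["response"], tr["response"])

    def test_read_rejects_missing_columns(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame({"a": [1]}).to_csv(path, index=False)
        with pytest.raises(ValueError):
            sy.read_trials(path)
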