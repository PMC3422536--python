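"""Tests of the trial-by-trial session simulator and block schedules."""

import numpy as np
import pandas as pd
import pytest

from sdtsim import (
    BlockConfig,
    ObserverParams,
    SessionConfig,
    StimulusSet,
    TRIAL_COLUMNS,
    run_adaptive_track,
    run_constant_block,
    run_limits_block,
    run_session,
    session_pcmax,
    session_rates,
)


def _session(params, level=47.35, rng=None, **kwargs):
    stim = StimulusSet("limits", (level,), noise_level=48.0)
    cfg = SessionConfig(stimuli=stim, **kwargs)
    return run_session(cfg, params, rng or np.random.default_rng(0))


class TestRunSession:
    def test_columns_and_quota_conservation(self, f2_limits, rng):
        params, _ = f2_limits
        df = _session(params, rng=rng)
        assert list(df.columns) == TRIAL_COLUMNS
        main = df[~df["is_correction"]]
        assert (main["trial_type"] == "signal").sum() == 50
        assert (main["trial_type"] == "nosignal").sum() == 50
        # hits + misses account for every scheduled signal trial
        sig = main[main["trial_type"] == "signal"]
        assert (sig["outcome"].isin(["hit", "miss"])).all()
        nos = main[main["trial_type"] == "nosignal"]
        assert (nos["outcome"].isin(["false_alarm", "correct_rejection"])).all()

    def test_correction_trial_bookkeeping(self, f2_limits, rng):
        params, _ = f2_limits
        df = _session(params, level=42.0, rng=rng)
        rows = df.to_dict(orient="records")
        for prev, cur in zip(rows, rows[1:]):
            if prev["outcome"] in ("miss", "false_alarm"):
                # every error is followed by a correction trial repeating
                # the identical stimulus
                assert cur["is_correction"]
                assert cur["trial_type"] == prev["trial_type"]
                if prev["trial_type"] == "signal":
                    assert cur["level"] == prev["level"]
            else:
                assert not cur["is_correction"]

    def test_no_signal_trial_after_false_alarm(self, f2_limits, rng):
        params, _ = f2_limits
        df = _session(params, level=42.0, rng=rng)
        rows = df.to_dict(orient="records")
        for prev, cur in zip(rows, rows[1:]):
            if prev["outcome"] == "false_alarm":
                assert cur["trial_type"] == "nosignal"

    def test_corrections_absent_when_disabled(self, f2_limits, rng):
        params, _ = f2_limits
        df = _session(params, level=42.0, rng=rng, use_correction_trials=False)
        assert not df["is_correction"].any()
        assert len(df) == 100

    def test_seed_determinism(self, f2_limits):
        params, _ = f2_limits
        a = _session(params, rng=np.random.default_rng(42))
        b = _session(params, rng=np.random.default_rng(42))
        pd.testing.assert_frame_equal(a, b)

    def test_criterion_shift_rule_traceable(self, f2_limits):
        # reconstructed criterion: c_base + s1*sign(r_{i-1}) + s2*sign(r_{i-2})
        params, _ = f2_limits
        df = _session(params, level=52.0, rng=np.random.default_rng(3))
        c_base = 0.5 * (params.reference_level + 52.0) + params.criterion_bias
        signs = np.where(df["response"].to_numpy() == "yes", 1, -1)
        s1 = np.concatenate([[0], signs[:-1]])
        s2 = np.concatenate([[0, 0], signs[:-2]])
        expect = c_base + params.trial_shift_1 * s1 + params.trial_shift_2 * s2
        np.testing.assert_allclose(df["criterion_used"].to_numpy(), expect,
                                   atol=1e-10)

    def test_history_argument_shifts_first_criterion(self, f2_limits):
        params, _ = f2_limits
        stim = StimulusSet("limits", (52.0,))
        cfg = SessionConfig(stimuli=stim)
        df = run_session(cfg, params, np.random.default_rng(5), history=(1, 1))
        c_base = 0.5 * (params.reference_level + 52.0) + params.criterion_bias
        assert df.loc[0, "criterion_used"] == pytest.approx(
            c_base + params.trial_shift_1 + params.trial_shift_2
        )

    def test_pure_guessing_observer_near_half(self):
        params = ObserverParams(internal_sd=9.2, reference_level=37.35,
                                guess_rate=1.0)
        rng = np.random.default_rng(7)
        stim = StimulusSet("limits", (72.0,))
        dfs = [run_session(SessionConfig(stimuli=stim, session_id=f"s{k}",
                                         use_correction_trials=False),
                           params, rng) for k in range(20)]
        t = pd.concat(dfs)
        p_yes = (t["response"] == "yes").mean()
        # 2000 fair-coin trials: 5 sigma of 0.5 is ~0.056
        assert abs(p_yes - 0.5) < 0.056

    def test_degenerate_observer_hits_safety_cap(self):
        # a near-noiseless observer below its reference never answers yes:
        # correction trials repeat forever and trip the cap
        params = ObserverParams(internal_sd=1e-9, reference_level=37.35)
        stim = StimulusSet("limits", (30.0,))
        cfg = SessionConfig(stimuli=stim, use_correction_trials=True)
        with pytest.raises(RuntimeError, match="safety cap"):
            run_session(cfg, params, np.random.default_rng(0))

    def test_centre_reward_flagged(self, f2_limits):
        params, _ = f2_limits
        df = _session(params, rng=np.random.default_rng(1),
                      centre_reward_prob=0.3)
        assert df["centre_reward"].any()
        rates_all = session_rates(df)
        # flagged trials are excluded from the rates
        assert rates_all.n_signal < (df["trial_type"] == "signal").sum()


class TestSessionRates:
    def test_rates_exclude_corrections(self, f2_limits, rng):
        params, _ = f2_limits
        df = _session(params, level=42.0, rng=rng)
        r = session_rates(df)
        assert r.n_signal == 50 and r.n_nosignal == 50
        main = df[~df["is_correction"]]
        sig = main[main["trial_type"] == "signal"]
        assert r.hit_rate == pytest.approx((sig["response"] == "yes").mean())

    def test_pcmax_matches_manual_pipeline(self, f2_limits, rng):
        from sdtsim import dprime, pcmax
        params, _ = f2_limits
        df = _session(params, rng=rng)
        assert session_pcmax(df) == pytest.approx(pcmax(dprime(session_rates(df))))


class TestLimitsBlock:
    def test_staircase_rule_audit(self, f2_limits):
        params, noise = f2_limits
        block = BlockConfig(method="limits", start_level=72.0, noise_level=noise)
        sim = run_limits_block(block, params, np.random.default_rng(2024))
        levels = [lv[0] for lv in sim.session_levels]
        # level moves only by 0 (repeat), -10 (fast phase) or -5 (fine phase)
        steps = {round(b - a, 6) for a, b in zip(levels, levels[1:])}
        assert steps <= {0.0, -10.0, -5.0}
        # once the -5 phase starts, no -10 step occurs
        if -5.0 in [round(b - a, 6) for a, b in zip(levels, levels[1:])]:
            seq = [round(b - a, 6) for a, b in zip(levels, levels[1:])]
            assert -10.0 not in seq[seq.index(-5.0):]
        # fine-phase levels are tested at least twice
        fine = [lvl for lvl in set(levels) if levels.count(lvl) >= 2]
        assert levels.count(levels[0]) >= 2  # the start anchor
        assert len(fine) >= 2
        # the tested levels bracket the analytic 71% point
        from scipy.stats import norm
        analytic = params.reference_level + 2 * params.internal_sd * norm.ppf(0.71)
        assert min(levels) < analytic < max(levels)

    def test_separable_limit_stops_at_reference(self):
        # sigma -> 0: performance is perfect above the reference and chance
        # at/below it, so the staircase stops within one fine step below ref
        params = ObserverParams(internal_sd=1e-6, reference_level=37.35)
        block = BlockConfig(method="limits", start_level=77.35,
                            use_correction_trials=False)
        sim = run_limits_block(block, params, np.random.default_rng(0))
        last = sim.session_levels[-1][0]
        assert last <= params.reference_level
        assert last > params.reference_level - 10.0

    def test_runaway_guard(self):
        # steps large enough to overshoot far below the reference must
        # abort rather than keep descending
        params = ObserverParams(internal_sd=1e-6, reference_level=37.35)
        block = BlockConfig(method="limits", start_level=120.0,
                            big_step=50.0, small_step=50.0,
                            use_correction_trials=False, runaway_db=40.0)
        with pytest.raises(RuntimeError, match="runaway"):
            run_limits_block(block, params, np.random.default_rng(0))


class TestConstantBlock:
    def test_levels_interleaved_within_sessions(self, rng):
        from sdtsim import get_preset
        params, noise = get_preset("F2", "constant")
        block = BlockConfig(method="constant", start_level=67.0,
                            noise_level=noise,
                            level_set=(42.0, 47.0, 52.0, 57.0, 67.0))
        sim = run_constant_block(block, params, 3, rng)
        assert len(sim.sessions) == 3
        for df in sim.sessions:
            sig = df[(df["trial_type"] == "signal") & ~df["is_correction"]]
            assert len(sig) == 50
            assert set(sig["level"].unique()) <= set(block.level_set)
            assert sig["level"].nunique() >= 2  # interleaving

    def test_warns_without_easy_level(self, rng):
        params = ObserverParams(internal_sd=9.2, reference_level=37.35)
        block = BlockConfig(method="constant", start_level=45.0,
                            level_set=(38.0, 40.0, 42.0, 44.0))
        with pytest.warns(UserWarning, match="easily detectable"):
            run_constant_block(block, params, 1, rng)

    def test_requires_level_set(self, rng, simple_params):
        block = BlockConfig(method="constant", start_level=45.0)
        with pytest.raises(ValueError, match="level_set"):
            run_constant_block(block, simple_params, 1, rng)


class TestAdaptiveTrack:
    def test_rule_audit(self, f2_limits):
        params, noise = f2_limits
        block = BlockConfig(method="adaptive", start_level=72.0,
                            noise_level=noise)
        track, threshold = run_adaptive_track(block, params,
                                              np.random.default_rng(31))
        lv = track["track_level"].to_numpy()
        steps = {round(abs(d), 6) for d in np.diff(lv) if d != 0.0}
        assert steps <= {block.initial_step, block.main_step, block.final_step}
        # phase order: once a 2 dB move happens no 6 or 4 dB move follows
        moves = [round(abs(d), 6) for d in np.diff(lv) if d != 0.0]
        if block.final_step in moves:
            k = moves.index(block.final_step)
            assert set(moves[k:]) <= {block.final_step}
        # plausible threshold: between the reference and the start level
        assert params.reference_level - 6.0 < threshold < 72.0

    def test_separable_limit_converges_to_reference(self):
        # sigma -> 0 observer: the track must oscillate at the reference,
        # so the reversal-mean threshold lies within one final step of it
        params = ObserverParams(internal_sd=1e-6, reference_level=37.0)
        block = BlockConfig(method="adaptive", start_level=73.0)
        _, threshold = run_adaptive_track(block, params,
                                          np.random.default_rng(8))
        assert abs(threshold - 37.0) <= 2.0 * block.final_step

    def test_method_mismatch_raises(self, simple_params, rng):
        block = BlockConfig(method="limits", start_level=70.0)
        with pytest.raises(ValueError):
            run_adaptive_track(block, simple_params, rng)
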