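"""Trial-by-trial simulation of yes/no detection sessions.

This is the synthetic-data generator for the whole pipeline.  A session is
a sequence of signal and no-signal trials (equally likely, 50 + 50 by
default, mirroring the minimum trial counts used in testing).  On every
trial the observer compares an internal value against a criterion

    c_i = c_opt + criterion_bias + s1 * sign(r_{i-1}) + s2 * sign(r_{i-2})

where ``c_opt`` is the reward-optimal criterion for the session's stimulus
set, ``sign(yes) = +1`` and ``sign(no) = -1``, and the history shifts
update on *every* response — including correction trials and guesses.
With probability ``guess_rate`` the response is a fair coin instead.

An error (miss or false alarm) is followed by identical *correction
trials* — same trial type and level — until a correct response is given,
when correction trials are enabled.  Correction trials do not count toward
the session's scheduled trial quota.  A small probability of a
centre-spout reward can flag trials for exclusion from analysis.

Three data-collection methods are provided on top of single sessions:

* :func:`run_limits_block` — Method of Limits: one level per session,
  stepped down across sessions (-10 dB, then -5 dB every other session)
  until percent correct falls below 71%.
* :func:`run_constant_block` — Method of Constant Stimuli: a preset group
  of 4-6 levels interleaved within every session.
* :func:`run_adaptive_track` — within-session transformed up/down
  staircase (6 dB 1-up/5-down, then 4 dB 1-up/2-down, then 2 dB after a
  set number of reversals), threshold from final-phase reversal levels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sdt_core import ObserverParams, RatePair, StimulusSet, dprime, optimal_criterion, pcmax

__all__ = [
    "SessionConfig",
    "BlockConfig",
    "TRIAL_COLUMNS",
    "run_session",
    "run_limits_block",
    "run_constant_block",
    "run_adaptive_track",
    "session_rates",
    "session_pcmax",
]

#: column order of a trial log; one row per trial
TRIAL_COLUMNS = [
    "session_id",
    "trial_index",
    "trial_type",
    "level",
    "is_correction",
    "internal_value",
    "criterion_used",
    "response",
    "outcome",
    "rewarded",
    "centre_reward",
]

_OUTCOME = {
    ("signal", True): "hit",
    ("signal", False): "miss",
    ("nosignal", True): "false_alarm",
    ("nosignal", False): "correct_rejection",
}


@dataclass(frozen=True)
class SessionConfig:
    """Stimulus schedule and bookkeeping options for one session."""

    stimuli: StimulusSet
    n_signal_trials: int = 50
    n_nosignal_trials: int = 50
    use_correction_trials: bool = True
    centre_reward_prob: float = 0.0
    session_id: str = "s0"

    def __post_init__(self) -> None:
        if self.n_signal_trials <= 0 or self.n_nosignal_trials <= 0:
            raise ValueError("trial counts must be positive")
        if not 0.0 <= self.centre_reward_prob <= 1.0:
            raise ValueError("centre_reward_prob must lie in [0, 1]")


@dataclass(frozen=True)
class BlockConfig:
    """Across-session schedule for one contiguous block of sessions."""

    method: str
    start_level: float
    noise_level: float = 0.0
    level_set: tuple[float, ...] | None = None  # constant-stimuli level group
    n_signal_trials: int = 50
    n_nosignal_trials: int = 50
    use_correction_trials: bool = True
    centre_reward_prob: float = 0.0
    # Method-of-Limits staircase rules
    high_pc: float = 0.90
    mid_pc: float = 0.85
    stop_pc: float = 0.71
    big_step: float = 10.0
    small_step: float = 5.0
    variation_trigger: float = 0.10
    # adaptive-track rules
    initial_step: float = 6.0
    main_step: float = 4.0
    final_step: float = 2.0
    reversal_switch: int = 5  # reversals in the 4 dB phase before the 2 dB phase
    final_reversals: int = 8  # reversals averaged for the threshold
    runaway_db: float = 60.0  # abort if the level falls this far below reference

    def __post_init__(self) -> None:
        if self.method not in ("limits", "constant", "adaptive"):
            raise ValueError(f"unknown method {self.method!r}")
        for step in (self.big_step, self.small_step, self.initial_step,
                     self.main_step, self.final_step):
            if step <= 0:
                raise ValueError("step sizes must be positive")
        for pc in (self.high_pc, self.mid_pc, self.stop_pc):
            if not 0.5 < pc < 1.0:
                raise ValueError("staircase P(c)max thresholds must lie in (0.5, 1)")


class _ChunkSampler:
    """Pre-drawn random variates consumed one at a time (loop speed)."""

    def __init__(self, rng: np.random.Generator, chunk: int = 1024):
        self._rng = rng
        self._chunk = chunk
        self._z = rng.standard_normal(chunk)
        self._u = rng.random(chunk)
        self._iz = 0
        self._iu = 0

    def normal(self) -> float:
        if self._iz == self._chunk:
            self._z = self._rng.standard_normal(self._chunk)
            self._iz = 0
        v = self._z[self._iz]
        self._iz += 1
        return v

    def uniform(self) -> float:
        if self._iu == self._chunk:
            self._u = self._rng.random(self._chunk)
            self._iu = 0
        v = self._u[self._iu]
        self._iu += 1
        return v


def run_session(
    config: SessionConfig,
    params: ObserverParams,
    rng: np.random.Generator,
    history: tuple[int, ...] = (),
) -> pd.DataFrame:
    """Simulate one session and return its trial log.

    ``history`` carries the response signs (+1 yes, -1 no) of up to the
    two trials preceding the session, most recent last; it defaults to an
    empty history (no criterion shift at the start).
    """
    stim = config.stimuli
    c_opt = optimal_criterion(stim, params)
    c_base = c_opt + params.criterion_bias
    sd = params.internal_sd
    ref = params.reference_level
    g = params.guess_rate
    s1, s2 = params.trial_shift_1, params.trial_shift_2
    p_centre = config.centre_reward_prob

    # exact quotas, randomly interleaved
    schedule = np.concatenate([
        np.ones(config.n_signal_trials, dtype=bool),
        np.zeros(config.n_nosignal_trials, dtype=bool),
    ])
    rng.shuffle(schedule)
    if stim.method == "constant":
        level_of = rng.choice(stim.signal_levels, size=config.n_signal_trials)
    else:
        level_of = np.full(config.n_signal_trials, stim.signal_levels[0])

    h1 = history[-1] if len(history) >= 1 else 0
    h2 = history[-2] if len(history) >= 2 else 0

    draws = _ChunkSampler(rng)
    max_trials = 100 * (config.n_signal_trials + config.n_nosignal_trials)

    rows: list[tuple] = []
    pending: tuple[str, float] | None = None  # correction stimulus
    i_sched = 0
    i_sig = 0
    t = 0
    while pending is not None or i_sched < len(schedule):
        if t >= max_trials:
            raise RuntimeError(
                "session exceeded the correction-trial safety cap; "
                "observer parameters are degenerate"
            )
        if pending is not None:
            trial_type, level = pending
            is_corr = True
        else:
            if schedule[i_sched]:
                trial_type = "signal"
                level = float(level_of[i_sig])
                i_sig += 1
            else:
                trial_type, level = "nosignal", np.nan
            i_sched += 1
            is_corr = False

        criterion = c_base + s1 * h1 + s2 * h2
        mean = level if trial_type == "signal" else ref
        internal = mean + sd * draws.normal()
        if g > 0.0 and draws.uniform() < g:
            yes = draws.uniform() < 0.5
        else:
            yes = internal > criterion
        outcome = _OUTCOME[(trial_type, yes)]
        correct = outcome in ("hit", "correct_rejection")
        centre = p_centre > 0.0 and draws.uniform() < p_centre

        rows.append((
            config.session_id, t, trial_type, level, is_corr,
            internal, criterion, "yes" if yes else "no",
            outcome, correct, centre,
        ))

        pending = None if correct or not config.use_correction_trials \
            else (trial_type, level)
        h2 = h1
        h1 = 1 if yes else -1
        t += 1

    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def _analysis_mask(trials: pd.DataFrame) -> pd.Series:
    """Trials that enter rate calculations (no corrections, no centre rewards)."""
    return ~trials["is_correction"] & ~trials["centre_reward"]


def session_rates(trials: pd.DataFrame) -> RatePair:
    """Hit/false-alarm rates of a trial log, excluding correction and
    centre-reward trials."""
    t = trials[_analysis_mask(trials)]
    sig = t[t["trial_type"] == "signal"]
    nosig = t[t["trial_type"] == "nosignal"]
    n_s, n_n = len(sig), len(nosig)
    if n_s == 0 or n_n == 0:
        raise ValueError("need at least one signal and one no-signal trial")
    return RatePair(
        hit_rate=float((sig["response"] == "yes").mean()),
        fa_rate=float((nosig["response"] == "yes").mean()),
        n_signal=n_s,
        n_nosignal=n_n,
    )


def session_pcmax(trials: pd.DataFrame) -> float:
    """P(c)max of a trial log via d' with 1/(2N) clipping."""
    return pcmax(dprime(session_rates(trials)))


@dataclass
class SimulatedBlock:
    """Sessions of one contiguous block, with the level(s) tested per session."""

    method: str
    sessions: list[pd.DataFrame] = field(default_factory=list)
    session_levels: list[tuple[float, ...]] = field(default_factory=list)

    def all_trials(self) -> pd.DataFrame:
        return pd.concat(self.sessions, ignore_index=True)


def run_limits_block(
    block: BlockConfig, params: ObserverParams, rng: np.random.Generator
) -> SimulatedBlock:
    """Simulate a Method-of-Limits block: the across-session staircase.

    Two sessions are run at the start level (a third if their P(c)max
    values differ by more than the variation trigger), then the level
    drops by ``big_step`` each session until per-session P(c)max falls
    below ``mid_pc``, then by ``small_step`` every other session — with
    the same third-session rule — until the level's pooled P(c)max falls
    below ``stop_pc``.
    """
    if block.method != "limits":
        raise ValueError("run_limits_block requires a limits block")
    out = SimulatedBlock(method="limits")
    level = float(block.start_level)
    sess_counter = 0

    def _run_at(lvl: float) -> pd.DataFrame:
        nonlocal sess_counter
        stim = StimulusSet("limits", (lvl,), noise_level=block.noise_level)
        cfg = SessionConfig(
            stimuli=stim,
            n_signal_trials=block.n_signal_trials,
            n_nosignal_trials=block.n_nosignal_trials,
            use_correction_trials=block.use_correction_trials,
            centre_reward_prob=block.centre_reward_prob,
            session_id=f"s{sess_counter:03d}",
        )
        sess_counter += 1
        df = run_session(cfg, params, rng)
        out.sessions.append(df)
        out.session_levels.append((lvl,))
        return df

    def _pair_at(lvl: float) -> float:
        """Two (or three) sessions at one level; pooled P(c)max."""
        d1, d2 = _run_at(lvl), _run_at(lvl)
        if abs(session_pcmax(d1) - session_pcmax(d2)) > block.variation_trigger:
            _run_at(lvl)
            pooled = pd.concat(out.sessions[-3:], ignore_index=True)
        else:
            pooled = pd.concat([d1, d2], ignore_index=True)
        return session_pcmax(pooled)

    def _check_runaway(lvl: float) -> None:
        if lvl < params.reference_level - block.runaway_db:
            raise RuntimeError(
                f"staircase runaway: level {lvl} dB SPL fell more than "
                f"{block.runaway_db} dB below the reference level"
            )

    _pair_at(level)  # top of the block: suprathreshold anchor
    # fast descent, one session per level
    while True:
        level -= block.big_step
        _check_runaway(level)
        if session_pcmax(_run_at(level)) < block.mid_pc:
            break
    # fine descent, two sessions per level
    while True:
        level -= block.small_step
        _check_runaway(level)
        if _pair_at(level) < block.stop_pc:
            break
    return out


def run_constant_block(
    block: BlockConfig,
    params: ObserverParams,
    n_sessions: int,
    rng: np.random.Generator,
) -> SimulatedBlock:
    """Simulate a Method-of-Constant-Stimuli block of ``n_sessions``."""
    if block.method != "constant":
        raise ValueError("run_constant_block requires a constant block")
    if not block.level_set:
        raise ValueError("a constant block requires a level_set")
    stim = StimulusSet("constant", tuple(block.level_set),
                       noise_level=block.noise_level)
    # at least one level should be easily detectable (suprathreshold anchor)
    c = optimal_criterion(stim, params)
    best = max(
        pcmax((lvl - params.reference_level) / params.internal_sd)
        for lvl in stim.signal_levels
    )
    if best < 0.9:
        warnings.warn(
            "no easily detectable level in the constant-stimuli set "
            f"(best attainable P(c)max {best:.2f} at criterion {c:.1f})",
            stacklevel=2,
        )
    out = SimulatedBlock(method="constant")
    for k in range(n_sessions):
        cfg = SessionConfig(
            stimuli=stim,
            n_signal_trials=block.n_signal_trials,
            n_nosignal_trials=block.n_nosignal_trials,
            use_correction_trials=block.use_correction_trials,
            centre_reward_prob=block.centre_reward_prob,
            session_id=f"s{k:03d}",
        )
        out.sessions.append(run_session(cfg, params, rng))
        out.session_levels.append(stim.signal_levels)
    return out


def run_adaptive_track(
    block: BlockConfig,
    params: ObserverParams,
    rng: np.random.Generator,
    max_trials: int = 10_000,
) -> tuple[pd.DataFrame, float]:
    """Simulate one adaptive (transformed up/down) track.

    Phase 1 holds the level high, dropping ``initial_step`` after five
    consecutive correct responses, and ends at the first error.  Phase 2
    applies a 1-up/2-down rule at ``main_step``; after ``reversal_switch``
    reversals the step shrinks to ``final_step`` (phase 3).  The track
    stops after ``final_reversals`` reversals in phase 3 and the threshold
    is the mean of those reversal levels.  Correction trials are not used
    during adaptive tracking.
    """
    if block.method != "adaptive":
        raise ValueError("run_adaptive_track requires an adaptive block")
    ref = params.reference_level
    sd = params.internal_sd
    g = params.guess_rate
    s1, s2 = params.trial_shift_1, params.trial_shift_2
    draws = _ChunkSampler(rng)

    level = float(block.start_level)
    phase = 1
    correct_run = 0
    direction = 0  # last level move: -1 down, +1 up
    reversals_mid = 0
    final_levels: list[float] = []
    h1 = h2 = 0
    rows: list[tuple] = []

    for t in range(max_trials):
        trial_type = "signal" if draws.uniform() < 0.5 else "nosignal"
        criterion = 0.5 * (ref + level) + params.criterion_bias + s1 * h1 + s2 * h2
        mean = level if trial_type == "signal" else ref
        internal = mean + sd * draws.normal()
        if g > 0.0 and draws.uniform() < g:
            yes = draws.uniform() < 0.5
        else:
            yes = internal > criterion
        outcome = _OUTCOME[(trial_type, yes)]
        correct = outcome in ("hit", "correct_rejection")
        rows.append((
            "track", t, trial_type,
            level if trial_type == "signal" else np.nan,
            False, internal, criterion, "yes" if yes else "no",
            outcome, correct, False, level,
        ))
        h2, h1 = h1, (1 if yes else -1)

        move = 0
        if phase == 1:
            if correct:
                correct_run += 1
                if correct_run == 5:
                    move, correct_run = -1, 0
            else:
                # first error ends the initial phase; the 1-up/2-down rule
                # takes over from this trial onward
                phase = 2
                correct_run = 0
                move = +1
        else:
            if correct:
                correct_run += 1
                if correct_run == 2:
                    move, correct_run = -1, 0
            else:
                move, correct_run = +1, 0

        if move != 0:
            if direction != 0 and move != direction and phase >= 2:
                if phase == 2:
                    reversals_mid += 1
                    if reversals_mid >= block.reversal_switch:
                        phase = 3
                else:
                    final_levels.append(level)
                    if len(final_levels) >= block.final_reversals:
                        break
            direction = move
            step = {1: block.initial_step, 2: block.main_step,
                    3: block.final_step}[phase]
            level += move * step
            if level < ref - block.runaway_db:
                raise RuntimeError("adaptive track runaway below reference level")
    else:
        raise RuntimeError("adaptive track did not finish within max_trials")

    track = pd.DataFrame(rows, columns=TRIAL_COLUMNS + ["track_level"])
    return track, float(np.mean(final_levels))
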