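"""Psychometric functions from trial logs.

Turns trial logs into per-level hit/false-alarm rates, d' and P(c)max,
fits a logistic psychometric function and reads off the detection
threshold at the 71% P(c)max criterion, and computes simulation-based
confidence bands.

Rate aggregation follows the two data-collection methods:

* Method of Limits — hit and false-alarm rates are pooled over runs of
  consecutive sessions at the same level (two or more sessions, and at
  least 50 signal and 50 no-signal trials, by default).
* Method of Constant Stimuli — hits are computed per level; the matching
  false-alarm rate is computed from a without-replacement random sample
  of the pooled no-signal trials, sized to that level's signal-trial
  count, so both rates rest on similar trial numbers.

Correction trials and centre-reward trials never enter any rate.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .sdt_core import ObserverParams, RatePair, StimulusSet, dprime, pcmax
from .simulate import SessionConfig, run_session, session_pcmax, session_rates

__all__ = [
    "LogisticFit",
    "PsychometricResult",
    "aggregate_rates",
    "fit_logistic",
    "threshold_at",
    "confidence_bands",
    "analyze_trials",
    "expected_pcmax",
    "staircase_levels",
    "limits_threshold_experiment",
]


@dataclass(frozen=True)
class LogisticFit:
    """Parameters of P(level) = 0.5 + 0.5 / (1 + exp(-(level - midpoint)/slope)).

    The floor and ceiling are fixed at 0.5 and 1.0: chance and perfect
    performance for P(c)max; lapses live in the observer's guess rate,
    not in the psychometric function.
    """

    midpoint: float
    slope: float
    low_confidence: bool = False

    def __post_init__(self) -> None:
        if not self.slope > 0:
            raise ValueError("slope must be positive")

    def __call__(self, level: np.ndarray | float) -> np.ndarray | float:
        return _logistic(level, self.midpoint, self.slope)


@dataclass
class PsychometricResult:
    """Per-level rates, P(c)max values, logistic fit and threshold."""

    levels: list[float]
    snr: list[float]
    rates: list[RatePair]
    pcmax_values: list[float]
    fit: LogisticFit | None
    threshold: float | None
    ci_bands: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        return {
            "levels": self.levels,
            "snr": self.snr,
            "hit_rate": [r.hit_rate for r in self.rates],
            "fa_rate": [r.fa_rate for r in self.rates],
            "n_signal": [r.n_signal for r in self.rates],
            "n_nosignal": [r.n_nosignal for r in self.rates],
            "pcmax": self.pcmax_values,
            "logistic": None if self.fit is None else {
                "midpoint": self.fit.midpoint,
                "slope": self.fit.slope,
                "low_confidence": self.fit.low_confidence,
            },
            "threshold": self.threshold,
        }


def _valid(trials: pd.DataFrame) -> pd.DataFrame:
    return trials[~trials["is_correction"] & ~trials["centre_reward"]]


def _counts(sub: pd.DataFrame) -> tuple[int, int]:
    return int((sub["response"] == "yes").sum()), int(len(sub))


def aggregate_rates(
    trials: pd.DataFrame,
    method: str,
    rng: np.random.Generator | None = None,
    min_sessions: int = 2,
    min_trials: int = 50,
) -> dict[float, RatePair]:
    """Per-level hit/false-alarm rates from a (multi-session) trial log.

    ``trials`` is a concatenated log whose ``session_id`` values appear in
    session order.  Levels failing the pooling requirements are omitted
    with a warning.  ``rng`` is required for the constant-stimuli
    matched false-alarm sampling.
    """
    t = _valid(trials)
    if method == "limits":
        return _aggregate_limits(t, min_sessions, min_trials)
    if method == "constant":
        if rng is None:
            raise ValueError("constant-stimuli aggregation needs an rng "
                             "for matched false-alarm sampling")
        return _aggregate_constant(t, rng, min_trials)
    raise ValueError(f"unknown method {method!r}")


def _aggregate_limits(
    t: pd.DataFrame, min_sessions: int, min_trials: int
) -> dict[float, RatePair]:
    # session order = order of first appearance in the log
    session_ids = t["session_id"].drop_duplicates().tolist()
    sess_level: list[tuple[str, float]] = []
    for sid in session_ids:
        lv = t.loc[(t["session_id"] == sid) & (t["trial_type"] == "signal"), "level"]
        levels = lv.dropna().unique()
        if len(levels) != 1:
            raise ValueError(f"limits session {sid!r} has {len(levels)} levels")
        sess_level.append((sid, float(levels[0])))

    # maximal runs of consecutive sessions at one level
    runs: list[tuple[float, list[str]]] = []
    for sid, lvl in sess_level:
        if runs and runs[-1][0] == lvl:
            runs[-1][1].append(sid)
        else:
            runs.append((lvl, [sid]))

    pooled: dict[float, list[str]] = {}
    for lvl, sids in runs:
        if len(sids) < min_sessions:
            warnings.warn(
                f"level {lvl} dB SPL: only {len(sids)} consecutive session(s), "
                "omitted", stacklevel=3,
            )
            continue
        pooled.setdefault(lvl, []).extend(sids)

    out: dict[float, RatePair] = {}
    for lvl in sorted(pooled, reverse=True):
        sub = t[t["session_id"].isin(pooled[lvl])]
        sig = sub[sub["trial_type"] == "signal"]
        nos = sub[sub["trial_type"] == "nosignal"]
        if len(sig) < min_trials or len(nos) < min_trials:
            warnings.warn(
                f"level {lvl} dB SPL: {len(sig)} signal / {len(nos)} no-signal "
                f"trials < {min_trials}, omitted", stacklevel=3,
            )
            continue
        ys, ns = _counts(sig)
        yn, nn = _counts(nos)
        out[lvl] = RatePair(ys / ns, yn / nn, n_signal=ns, n_nosignal=nn)
    return dict(sorted(out.items()))


def _aggregate_constant(
    t: pd.DataFrame, rng: np.random.Generator, min_trials: int
) -> dict[float, RatePair]:
    sig = t[t["trial_type"] == "signal"]
    nos = t[t["trial_type"] == "nosignal"]
    nos_yes = (nos["response"] == "yes").to_numpy()
    out: dict[float, RatePair] = {}
    for lvl in sorted(sig["level"].dropna().unique()):
        s = sig[sig["level"] == lvl]
        n_s = len(s)
        if n_s < min_trials:
            warnings.warn(
                f"level {lvl} dB SPL: {n_s} signal trials < {min_trials}, omitted",
                stacklevel=3,
            )
            continue
        if n_s > len(nos_yes):
            warnings.warn(
                f"level {lvl} dB SPL: not enough no-signal trials "
                f"({len(nos_yes)}) to match {n_s} signal trials, omitted",
                stacklevel=3,
            )
            continue
        # matched false-alarm sample, without replacement, one draw per level
        idx = rng.choice(len(nos_yes), size=n_s, replace=False)
        fa_sample = nos_yes[idx]
        ys, _ = _counts(s)
        out[float(lvl)] = RatePair(
            ys / n_s, float(fa_sample.mean()), n_signal=n_s, n_nosignal=n_s
        )
    return out


def _logistic(x, m, s):
    return 0.5 + 0.5 / (1.0 + np.exp(-(np.asarray(x, dtype=float) - m) / s))


def fit_logistic(
    levels: np.ndarray | list[float],
    pcmax_values: np.ndarray | list[float],
    criterion: float = 0.71,
) -> LogisticFit:
    """Least-squares logistic fit to P(c)max as a function of level.

    Fewer than three levels, or a level set that does not span the
    threshold criterion, yields a fit flagged ``low_confidence``.  A flat
    profile (no slope information) is rejected.
    """
    x = np.asarray(levels, dtype=float)
    y = np.asarray(pcmax_values, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("need at least two (level, pcmax) points")
    if np.ptp(y) < 1e-3:
        raise ValueError("pcmax values carry no slope information; fit rejected")

    order = np.argsort(x)
    x, y = x[order], y[order]
    # initial midpoint: level where the profile crosses (roughly) 0.75
    m0 = float(np.interp(0.75, np.clip(y, 0.5 + 1e-6, 1.0 - 1e-6), x))
    s0 = max(np.ptp(x) / 5.0, 1e-2)
    try:
        popt, _ = curve_fit(
            _logistic, x, y, p0=[m0, s0],
            bounds=([-np.inf, 1e-8], [np.inf, np.inf]), maxfev=10_000,
        )
    except RuntimeError as err:  # pragma: no cover - rare non-convergence
        raise RuntimeError(f"logistic fit did not converge: {err}") from err
    low_conf = x.size < 3 or not (y.min() <= criterion <= y.max())
    return LogisticFit(midpoint=float(popt[0]), slope=float(popt[1]),
                       low_confidence=bool(low_conf))


def threshold_at(fit: LogisticFit, criterion: float = 0.71) -> float:
    """Level at which the fitted logistic reaches ``criterion``.

    Inverts the fixed-asymptote logistic:
    ``threshold = midpoint + slope * ln((criterion - 0.5)/(1 - criterion))``.
    """
    if not 0.5 < criterion < 1.0:
        raise ValueError(f"criterion must lie in (0.5, 1), got {criterion}")
    return float(fit.midpoint + fit.slope * math.log((criterion - 0.5) / (1.0 - criterion)))


def analyze_trials(
    trials: pd.DataFrame,
    method: str,
    noise_level: float = 0.0,
    rng: np.random.Generator | None = None,
    criterion: float = 0.71,
    min_sessions: int = 2,
    min_trials: int = 50,
) -> PsychometricResult:
    """Full psychometric analysis of a trial log: rates, P(c)max per
    level, logistic fit and the threshold at ``criterion``."""
    rates = aggregate_rates(trials, method, rng=rng,
                            min_sessions=min_sessions, min_trials=min_trials)
    levels = list(rates)
    pc = [pcmax(dprime(rates[lvl])) for lvl in levels]
    fit = None
    thr = None
    if len(levels) >= 2 and np.ptp(pc) >= 1e-3:
        fit = fit_logistic(levels, pc, criterion=criterion)
        thr = threshold_at(fit, criterion)
    return PsychometricResult(
        levels=levels,
        snr=[lvl - noise_level for lvl in levels],
        rates=[rates[lvl] for lvl in levels],
        pcmax_values=pc,
        fit=fit,
        threshold=thr,
    )


def confidence_bands(
    levels: list[float],
    params: ObserverParams,
    rng: np.random.Generator,
    n_sessions: int = 200,
    method: str = "limits",
    noise_level: float = 0.0,
    n_signal: int = 50,
    n_nosignal: int = 50,
    use_correction_trials: bool = True,
    q: tuple[float, float] = (2.5, 97.5),
) -> pd.DataFrame:
    """Empirical percentile bands of P(c)max, hit and false-alarm rates.

    Simulates ``n_sessions`` sessions per level and returns a table with
    the median and the ``q`` percentiles of each quantity per level.
    ``method`` only labels the output here; each level is simulated as a
    single-level session so a per-level false-alarm rate exists.
    """
    records = []
    for lvl in levels:
        stim = StimulusSet("limits", (lvl,), noise_level=noise_level)
        pc_vals, hits, fas = [], [], []
        for k in range(n_sessions):
            cfg = SessionConfig(
                stimuli=stim, n_signal_trials=n_signal,
                n_nosignal_trials=n_nosignal,
                use_correction_trials=use_correction_trials,
                session_id=f"cb{k}",
            )
            df = run_session(cfg, params, rng)
            r = session_rates(df)
            hits.append(r.hit_rate)
            fas.append(r.fa_rate)
            pc_vals.append(pcmax(dprime(r)))
        for name, vals in (("pcmax", pc_vals), ("hit_rate", hits), ("fa_rate", fas)):
            lo, hi = np.percentile(vals, q)
            records.append({
                "level": lvl, "snr": lvl - noise_level, "quantity": name,
                "median": float(np.median(vals)), "lo": float(lo), "hi": float(hi),
                "method": method,
            })
    return pd.DataFrame.from_records(records)


def expected_pcmax(level: float, params: ObserverParams) -> float:
    """Noise-free P(c)max of the observer at one level (Method of Limits).

    Uses the analytic hit/false-alarm probabilities at the session
    criterion (midpoint plus bias), including the guess rate; history
    shifts average out and are ignored here.
    """
    from .sdt_core import expected_rates
    c = 0.5 * (params.reference_level + level) + params.criterion_bias
    r = expected_rates(c, level, params)
    return pcmax(dprime(r))


def staircase_levels(
    params: ObserverParams,
    start_level: float,
    high_pc: float = 0.90,
    mid_pc: float = 0.85,
    stop_pc: float = 0.71,
    big_step: float = 10.0,
    small_step: float = 5.0,
    max_levels: int = 20,
) -> list[float]:
    """Levels the Method-of-Limits schedule tests for a given observer.

    Applies the across-session staircase rule to the observer's *expected*
    P(c)max: hold the start level, drop ``big_step`` per level while
    performance stays at or above ``mid_pc``, then ``small_step`` per
    level until it falls below ``stop_pc``.  This is the deterministic
    trace of the staircase — the level grid a replicated threshold
    experiment should test.
    """
    levels = [float(start_level)]
    level = float(start_level)
    if expected_pcmax(level, params) <= high_pc:
        warnings.warn("start level is not clearly suprathreshold", stacklevel=2)
    while len(levels) < max_levels:
        level -= big_step
        levels.append(level)
        if expected_pcmax(level, params) < mid_pc:
            break
    while len(levels) < max_levels:
        if expected_pcmax(level, params) < stop_pc:
            break
        level -= small_step
        levels.append(level)
    return levels


def limits_threshold_experiment(
    params: ObserverParams,
    levels: list[float],
    rng: np.random.Generator,
    n_blocks: int = 800,
    noise_level: float = 0.0,
    n_signal: int = 50,
    n_nosignal: int = 50,
    use_correction_trials: bool = True,
    criterion: float = 0.71,
) -> np.ndarray:
    """Replicate Method-of-Limits threshold estimation on a fixed level grid.

    Each replicate block runs one 50+50-trial session at every level,
    computes per-level P(c)max (d' with 1/(2N) clipping) and fits the
    logistic psychometric function; the threshold is read off at the
    ``criterion`` P(c)max.  Returns the array of per-block thresholds
    (replicates whose logistic fit is degenerate are dropped, which for
    a level grid spanning the threshold is rare).

    This is the protocol used to ask whether trial-by-trial criterion
    shifts move the average detection threshold: run it once with the
    fitted parameters and once with ``params.without_shifts()``.
    """
    thresholds = []
    for b in range(n_blocks):
        pc = []
        for lvl in levels:
            stim = StimulusSet("limits", (lvl,), noise_level=noise_level)
            cfg = SessionConfig(
                stimuli=stim, n_signal_trials=n_signal,
                n_nosignal_trials=n_nosignal,
                use_correction_trials=use_correction_trials,
                session_id=f"b{b}",
            )
            pc.append(session_pcmax(run_session(cfg, params, rng)))
        try:
            fit = fit_logistic(levels, pc, criterion=criterion)
        except (ValueError, RuntimeError):
            continue
        thresholds.append(threshold_at(fit, criterion))
    return np.asarray(thresholds)
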