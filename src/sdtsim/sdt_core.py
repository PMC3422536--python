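"""Closed-form primitives of the equal-variance Gaussian SDT observer.

The observer lives entirely on a decibel scale.  Each trial evokes an
internal representation: for a signal trial it is the tone level (dB SPL)
plus zero-mean Gaussian internal noise; for a no-signal trial it is a
*reference level* — the tone level that would be indistinguishable from
no tone at all — plus the same noise.  The observer answers "yes" when the
internal value exceeds a decision criterion (also in dB SPL).

This module provides the analytic side of the model: expected hit and
false-alarm probabilities for a given criterion, the reward-optimal
criterion (the point where P(false alarm) = P(miss)), the sensitivity
index d' and the unbiased percent-correct P(c)max.  Sampling and full
session simulation live in :mod:`sdtsim.simulate`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm

__all__ = [
    "ObserverParams",
    "StimulusSet",
    "RatePair",
    "sample_internal_value",
    "expected_rates",
    "optimal_criterion",
    "dprime",
    "pcmax",
]

Method = Literal["limits", "constant", "adaptive"]
TrialType = Literal["signal", "nosignal"]


@dataclass(frozen=True)
class ObserverParams:
    """Parameter set of the SDT observer.

    Parameters
    ----------
    internal_sd:
        Standard deviation of the internal noise, dB.  Must be positive.
    reference_level:
        Signal level (dB SPL) indistinguishable from a no-signal trial;
        the mean of the no-signal internal distribution.
    criterion_bias:
        Fixed block-level offset (dB) of the decision criterion away from
        the reward-optimal point.  Positive = more conservative.
    guess_rate:
        Probability of an attentional lapse on a trial, in which case the
        response is a fair coin regardless of the internal value.
    trial_shift_1, trial_shift_2:
        Criterion shifts (dB) contingent on the responses one and two
        trials back: added after a "yes", subtracted after a "no".
    """

    internal_sd: float
    reference_level: float
    criterion_bias: float = 0.0
    guess_rate: float = 0.0
    trial_shift_1: float = 0.0
    trial_shift_2: float = 0.0

    def __post_init__(self) -> None:
        if not self.internal_sd > 0:
            raise ValueError(f"internal_sd must be positive, got {self.internal_sd}")
        if not 0.0 <= self.guess_rate <= 1.0:
            raise ValueError(f"guess_rate must lie in [0, 1], got {self.guess_rate}")
        if self.trial_shift_1 < 0 or self.trial_shift_2 < 0:
            raise ValueError("trial shifts must be non-negative")

    def without_shifts(self) -> "ObserverParams":
        """Copy of the parameters with both history shifts zeroed."""
        return replace(self, trial_shift_1=0.0, trial_shift_2=0.0)


@dataclass(frozen=True)
class StimulusSet:
    """Stimulus schedule for one session.

    ``limits`` sessions present a single tone level; ``constant`` sessions
    interleave a preset group of 4–6 levels; ``adaptive`` sessions start
    from a single level that the staircase then moves.  The SNR of a level
    is ``level − noise_level`` in dB.
    """

    method: Method
    signal_levels: tuple[float, ...]
    noise_level: float = 0.0
    # bounds on how many levels a constant-stimuli session may carry
    constant_min_levels: int = field(default=4, repr=False)
    constant_max_levels: int = field(default=6, repr=False)

    def __post_init__(self) -> None:
        levels = tuple(float(x) for x in self.signal_levels)
        object.__setattr__(self, "signal_levels", levels)
        if len(levels) == 0:
            raise ValueError("at least one signal level is required")
        if self.method in ("limits", "adaptive") and len(levels) != 1:
            raise ValueError(f"{self.method} sessions carry exactly one signal level")
        if self.method == "constant" and not (
            self.constant_min_levels <= len(levels) <= self.constant_max_levels
        ):
            raise ValueError(
                "constant-stimuli sessions carry "
                f"{self.constant_min_levels}-{self.constant_max_levels} levels, "
                f"got {len(levels)}"
            )

    @property
    def snr(self) -> tuple[float, ...]:
        return tuple(lvl - self.noise_level for lvl in self.signal_levels)

    def with_levels(self, levels: Sequence[float]) -> "StimulusSet":
        return replace(self, signal_levels=tuple(levels))


@dataclass
class RatePair:
    """Hit and false-alarm rates with (optional) trial counts."""

    hit_rate: float
    fa_rate: float
    n_signal: int | None = None
    n_nosignal: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.hit_rate <= 1.0 and 0.0 <= self.fa_rate <= 1.0):
            raise ValueError("rates must lie in [0, 1]")
        for n in (self.n_signal, self.n_nosignal):
            if n is not None and n < 0:
                raise ValueError("counts must be non-negative")


def sample_internal_value(
    trial_type: TrialType,
    level: float | None,
    params: ObserverParams,
    rng: np.random.Generator,
    size: int | None = None,
) -> float | np.ndarray:
    """Draw internal representation values for one trial type.

    Signal trials return ``level + N(0, internal_sd)``; no-signal trials
    return ``reference_level + N(0, internal_sd)``.
    """
    if trial_type == "signal":
        if level is None:
            raise ValueError("a signal trial requires a level")
        mean = float(level)
    elif trial_type == "nosignal":
        mean = params.reference_level
    else:
        raise ValueError(f"unknown trial type {trial_type!r}")
    draw = rng.normal(mean, params.internal_sd, size=size)
    return float(draw) if size is None else draw


def expected_rates(
    criterion: float, level: float, params: ObserverParams
) -> RatePair:
    """Analytic hit/false-alarm probabilities for a fixed criterion.

    Without guessing, ``P(hit) = 1 − Φ((c − level)/σ)`` and
    ``P(fa) = 1 − Φ((c − reference)/σ)``.  A guess rate ``g`` mixes each
    probability with a fair coin: ``(1 − g)·p + g/2``.
    """
    sd = params.internal_sd
    p_hit = norm.sf((criterion - level) / sd)
    p_fa = norm.sf((criterion - params.reference_level) / sd)
    g = params.guess_rate
    if g:
        p_hit = (1.0 - g) * p_hit + 0.5 * g
        p_fa = (1.0 - g) * p_fa + 0.5 * g
    return RatePair(hit_rate=float(p_hit), fa_rate=float(p_fa))


def _miss_minus_fa(c: float, levels: Sequence[float], ref: float, sd: float) -> float:
    # P(miss) − P(fa) at criterion c; strictly increasing in c.
    p_miss = float(np.mean(norm.cdf((c - np.asarray(levels)) / sd)))
    p_fa = norm.sf((c - ref) / sd)
    return p_miss - p_fa


def optimal_criterion(
    stimuli: StimulusSet, params: ObserverParams, tol: float = 1e-12
) -> float:
    """Criterion at which P(false alarm) equals P(miss).

    For a single signal level the equal-variance geometry puts the optimum
    exactly midway between the no-signal and signal means.  For a
    constant-stimuli session the signal distribution is the equal-weight
    mixture of the per-level Gaussians, and the optimum — found by root
    bracketing — sits below the midpoint of the reference and the mean
    level (the mixture's lower flank is heavier than a single Gaussian's).
    """
    levels = stimuli.signal_levels
    ref = params.reference_level
    sd = params.internal_sd
    if len(levels) == 1:
        return 0.5 * (ref + levels[0])
    lo = min(ref, min(levels)) - 10.0 * sd
    hi = max(levels) + 10.0 * sd
    f_lo = _miss_minus_fa(lo, levels, ref, sd)
    f_hi = _miss_minus_fa(hi, levels, ref, sd)
    if not (f_lo < 0 < f_hi):  # pragma: no cover - cannot occur for finite params
        raise RuntimeError(
            f"failed to bracket the optimal criterion on [{lo}, {hi}]"
        )
    return float(brentq(_miss_minus_fa, lo, hi, args=(levels, ref, sd), xtol=tol))


def dprime(rates: RatePair) -> float:
    """Sensitivity index d' = z(H) − z(FA).

    Rates of exactly 0 or 1 are clipped to ``1/(2N)`` and ``1 − 1/(2N)``
    using the corresponding trial count, keeping d' finite; if a rate is
    degenerate and its count is unknown the value is undefined and an
    error is raised.
    """
    h, fa = rates.hit_rate, rates.fa_rate
    if h in (0.0, 1.0):
        if not rates.n_signal:
            raise ValueError("hit rate of 0/1 needs n_signal for clipping")
        eps = 1.0 / (2.0 * rates.n_signal)
        h = eps if h == 0.0 else 1.0 - eps
    if fa in (0.0, 1.0):
        if not rates.n_nosignal:
            raise ValueError("false-alarm rate of 0/1 needs n_nosignal for clipping")
        eps = 1.0 / (2.0 * rates.n_nosignal)
        fa = eps if fa == 0.0 else 1.0 - eps
    return float(norm.ppf(h) - norm.ppf(fa))


def pcmax(dprime_value: float) -> float:
    """Percent correct of an unbiased observer at a given d': Φ(d'/2)."""
    return float(norm.cdf(dprime_value / 2.0))
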