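"""Reward earned under a static decision criterion.

A deterministic reading of the equal-variance SDT model: the signal and
no-signal Gaussians are bisected by a fixed criterion ``c`` and the
expected proportion of rewarded trials (1 = every trial correct) is

    reward(c) = 0.5 * mean_j[1 - Phi((c - L_j)/sigma)] + 0.5 * Phi((c - ref)/sigma)

with P(yes) = 0.5 * mean_j[1 - Phi((c - L_j)/sigma)] + 0.5 * [1 - Phi((c - ref)/sigma)],
signal levels L_j weighted equally and signal / no-signal trials equally
likely.  For a single level the symmetry of the two Gaussians puts the
reward maximum exactly at the midpoint criterion, where P(yes) = 0.5 —
at *any* SNR.  For a multi-level (constant-stimuli) set the optimum is
slightly conservative: P(yes) at the argmax falls below 0.5.

The gradient of reward with respect to P(yes) says how strongly the
operating point is pulled back to the optimum; it shrinks near the
optimum and is shallower at low SNR, where criterion setting is
correspondingly harder.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import norm

from .sdt_core import ObserverParams, StimulusSet

__all__ = ["RewardCurve", "reward_curve", "argmax_reward", "gradient_at",
           "aligned_gradient"]


@dataclass
class RewardCurve:
    stimuli: StimulusSet
    params: ObserverParams
    criterion_grid: np.ndarray
    p_yes: np.ndarray  # strictly decreasing in criterion
    reward: np.ndarray
    gradient: np.ndarray  # d(reward)/d(p_yes), by central differences


def _p_yes_signal(c, levels, sd):
    return np.mean([norm.sf((c - lvl) / sd) for lvl in levels], axis=0)


def _p_yes(c, levels, ref, sd):
    return 0.5 * _p_yes_signal(c, levels, sd) + 0.5 * norm.sf((c - ref) / sd)


def _reward(c, levels, ref, sd):
    return 0.5 * _p_yes_signal(c, levels, sd) + 0.5 * norm.cdf((c - ref) / sd)


def default_grid(stimuli: StimulusSet, params: ObserverParams,
                 step: float = 0.05) -> np.ndarray:
    lo = params.reference_level - 4.0 * params.internal_sd
    hi = max(stimuli.signal_levels) + 4.0 * params.internal_sd
    return np.arange(lo, hi + step, step)


def reward_curve(
    stimuli: StimulusSet,
    params: ObserverParams,
    grid: np.ndarray | None = None,
) -> RewardCurve:
    """Sweep a static criterion and tabulate P(yes), reward and gradient."""
    if grid is None:
        grid = default_grid(stimuli, params)
    grid = np.asarray(grid, dtype=float)
    levels = stimuli.signal_levels
    ref, sd = params.reference_level, params.internal_sd
    p_yes = _p_yes(grid, levels, ref, sd)
    reward = _reward(grid, levels, ref, sd)
    if p_yes.max() < 0.99 or p_yes.min() > 0.01:
        warnings.warn(
            "criterion grid does not span P(yes) in (0.01, 0.99); "
            "extend the grid", stacklevel=2,
        )
    gradient = np.gradient(reward, p_yes)
    return RewardCurve(stimuli=stimuli, params=params, criterion_grid=grid,
                       p_yes=p_yes, reward=reward, gradient=gradient)


def argmax_reward(curve: RewardCurve) -> tuple[float, float]:
    """Criterion and P(yes) at the reward maximum.

    The grid argmax seeds a bounded scalar minimisation of the analytic
    reward function, so the returned criterion is accurate well beyond
    the grid spacing (for a single level it matches the closed-form
    midpoint to better than 1e-6 dB).
    """
    stim, par = curve.stimuli, curve.params
    levels, ref, sd = stim.signal_levels, par.reference_level, par.internal_sd
    g = curve.criterion_grid
    i = int(np.argmax(curve.reward))
    lo = g[max(i - 2, 0)]
    hi = g[min(i + 2, len(g) - 1)]
    res = minimize_scalar(
        lambda c: -_reward(c, levels, ref, sd),
        bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-10},
    )
    c_star = float(res.x)
    return c_star, float(_p_yes(c_star, levels, ref, sd))


def gradient_at(curve: RewardCurve, p_yes: float) -> float:
    """Gradient d(reward)/d(P(yes)) interpolated at a given P(yes)."""
    # p_yes decreases along the grid; np.interp needs ascending x
    x = curve.p_yes[::-1]
    y = curve.gradient[::-1]
    if not (x[0] <= p_yes <= x[-1]):
        raise ValueError(f"p_yes {p_yes} outside the tabulated range "
                         f"[{x[0]:.4f}, {x[-1]:.4f}]")
    return float(np.interp(p_yes, x, y))


def aligned_gradient(curve: RewardCurve) -> tuple[np.ndarray, np.ndarray]:
    """Gradient re-centred so P(yes) = 0 at the curve's reward argmax
    (the zero-gradient point), for overlaying curves across SNRs."""
    _, p_star = argmax_reward(curve)
    return curve.p_yes - p_star, curve.gradient
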