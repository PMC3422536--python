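"""Staged fitting of the SDT observer to hit/false-alarm data.

The observer parameters are fitted to per-level hit and false-alarm rates
by minimising the mean squared error between observed rates and rates
averaged over repeated simulated sessions, in three supervised stages:

1. ``fit_stage1`` — internal s.d., reference level and one criterion bias
   per block are optimised (coarse grid over s.d. and reference, then a
   Nelder–Mead polish) while the history shifts and guess rate are held
   at fixed starting values (2 dB, 1.5 dB, 1%).
2. ``fit_stage2_guess`` — the guess rate is chosen from a preset grid.
3. ``fit_stage3_shifts`` — the two history-shift parameters are chosen
   from a grid; because they barely move hit/false-alarm rates, their
   objective is the sequential-dependency tree (squared error of the
   after-hit and after-correct-rejection conditional P(yes) values).

Every candidate evaluation re-seeds the simulator from the same sub-seed
(common random numbers), which makes the loss deterministic in the
parameters and the staged search reproducible.

``evaluate_fit`` scores a fitted model by correlating observed per-level
P(c)max / hit / false-alarm values against the simulated means
(``exp_sim``), and by the model-against-itself protocol (``sim_sim``):
repeatedly draw one block-sized set of sessions from the simulation pool
and correlate it with the mean of the remainder — an upper bound on the
attainable correlation given the protocol's trial counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .sdt_core import ObserverParams, RatePair, StimulusSet, dprime, pcmax
from .simulate import SessionConfig, run_session, session_rates

__all__ = [
    "BlockDesign",
    "FitResult",
    "mse_loss",
    "simulate_rates",
    "observed_from_rates",
    "fit_stage1",
    "fit_stage2_guess",
    "fit_stage3_shifts",
    "evaluate_fit",
]

#: sentinel level for block-wide (level-free) false-alarm entries
ALL_LEVELS = "all"


@dataclass(frozen=True)
class BlockDesign:
    """Stimulus conditions of one observed block, for forward simulation."""

    block_id: str
    method: str  # "limits" or "constant"
    levels: tuple[float, ...]
    noise_level: float = 0.0
    n_signal: int = 50
    n_nosignal: int = 50
    use_correction_trials: bool = True

    def __post_init__(self) -> None:
        if self.method not in ("limits", "constant"):
            raise ValueError("fitting designs are limits or constant blocks")


@dataclass
class FitResult:
    params: ObserverParams
    bias_by_block: dict[str, float]
    loss: float
    r2: dict[str, dict[str, float]] = field(default_factory=dict)
    n_sim_sessions: int = 0

    def to_dict(self) -> dict:
        p = self.params
        return {
            "internal_sd": p.internal_sd,
            "reference_level": p.reference_level,
            "guess_rate": p.guess_rate,
            "trial_shift_1": p.trial_shift_1,
            "trial_shift_2": p.trial_shift_2,
            "bias_by_block": self.bias_by_block,
            "loss": self.loss,
            "r2": self.r2,
            "n_sim_sessions": self.n_sim_sessions,
        }


def observed_from_rates(
    rates_by_block: dict[str, dict[float, RatePair]],
    method: str,
) -> pd.DataFrame:
    """Shape per-level rates into the (block, level, quantity, rate) table
    the loss operates on.

    Method of Limits keeps a false-alarm entry per level (false alarms
    rise as the session level falls); Constant Stimuli keeps one pooled
    false-alarm entry per block, since its no-signal trials carry no SNR.
    """
    rows = []
    for block, by_level in rates_by_block.items():
        fa_vals = []
        for lvl, rp in by_level.items():
            rows.append({"block": block, "level": lvl, "quantity": "hit",
                         "rate": rp.hit_rate})
            if method == "limits":
                rows.append({"block": block, "level": lvl, "quantity": "fa",
                             "rate": rp.fa_rate})
            else:
                fa_vals.append(rp.fa_rate)
        if method == "constant" and fa_vals:
            rows.append({"block": block, "level": ALL_LEVELS, "quantity": "fa",
                         "rate": float(np.mean(fa_vals))})
    return pd.DataFrame(rows)


def mse_loss(observed: pd.DataFrame, simulated: pd.DataFrame) -> float:
    """Mean squared error over all matched hit and false-alarm entries."""
    merged = observed.merge(
        simulated, on=["block", "level", "quantity"],
        suffixes=("_obs", "_sim"), how="inner",
    )
    if merged.empty:
        raise ValueError("observed and simulated tables share no entries")
    return float(np.mean((merged["rate_obs"] - merged["rate_sim"]) ** 2))


def _sessions_for(
    design: BlockDesign, level: float | None, params: ObserverParams,
    n_sim: int, rng: np.random.Generator,
) -> list[pd.DataFrame]:
    if design.method == "limits":
        stim = StimulusSet("limits", (float(level),), noise_level=design.noise_level)
    else:
        stim = StimulusSet("constant", design.levels, noise_level=design.noise_level)
    cfg = SessionConfig(
        stimuli=stim, n_signal_trials=design.n_signal,
        n_nosignal_trials=design.n_nosignal,
        use_correction_trials=design.use_correction_trials,
    )
    return [run_session(cfg, params, rng) for _ in range(n_sim)]


def simulate_rates(
    params: ObserverParams,
    bias_by_block: dict[str, float],
    designs: Sequence[BlockDesign],
    n_sim: int,
    seed: int,
) -> pd.DataFrame:
    """Average hit/false-alarm rates over ``n_sim`` simulated sessions per
    condition, in the same table shape as :func:`observed_from_rates`."""
    rng = np.random.default_rng(seed)
    rows = []
    for design in designs:
        p = replace(params, criterion_bias=bias_by_block[design.block_id])
        if design.method == "limits":
            for lvl in design.levels:
                rs = [session_rates(df)
                      for df in _sessions_for(design, lvl, p, n_sim, rng)]
                rows.append({"block": design.block_id, "level": lvl,
                             "quantity": "hit",
                             "rate": float(np.mean([r.hit_rate for r in rs]))})
                rows.append({"block": design.block_id, "level": lvl,
                             "quantity": "fa",
                             "rate": float(np.mean([r.fa_rate for r in rs]))})
        else:
            dfs = _sessions_for(design, None, p, n_sim, rng)
            pool = pd.concat(dfs, ignore_index=True)
            valid = pool[~pool["is_correction"] & ~pool["centre_reward"]]
            sig = valid[valid["trial_type"] == "signal"]
            for lvl in design.levels:
                s = sig[sig["level"] == lvl]
                rows.append({"block": design.block_id, "level": lvl,
                             "quantity": "hit",
                             "rate": float((s["response"] == "yes").mean())})
            nos = valid[valid["trial_type"] == "nosignal"]
            rows.append({"block": design.block_id, "level": ALL_LEVELS,
                         "quantity": "fa",
                         "rate": float((nos["response"] == "yes").mean())})
    return pd.DataFrame(rows)


_STAGE1_FIXED = {"trial_shift_1": 2.0, "trial_shift_2": 1.5, "guess_rate": 0.01}


def fit_stage1(
    observed: pd.DataFrame,
    designs: Sequence[BlockDesign],
    init: dict | None = None,
    sigma_grid: Sequence[float] | None = None,
    ref_grid: Sequence[float] | None = None,
    bias_init: float = 2.0,
    n_sim: int = 100,
    seed: int = 0,
    maxfev: int = 200,
) -> FitResult:
    """Stage 1: fit internal s.d., reference level and per-block bias.

    A coarse (sigma, reference) grid map at a fixed starting bias seeds a
    Nelder–Mead polish over the full (sigma, reference, biases) vector.
    The history shifts and guess rate stay at their stage-1 values.
    """
    fixed = dict(_STAGE1_FIXED)
    if init:
        fixed.update(init)
    blocks = [d.block_id for d in designs]
    all_levels = [lvl for d in designs for lvl in d.levels]
    if sigma_grid is None:
        sigma_grid = np.linspace(5.0, 15.0, 5)
    if ref_grid is None:
        span = max(all_levels) - min(all_levels)
        ref_grid = np.linspace(min(all_levels) - 0.5 * span,
                               max(all_levels) - 0.5 * span, 6)

    def make_params(sd: float, ref: float) -> ObserverParams:
        return ObserverParams(
            internal_sd=sd, reference_level=ref, criterion_bias=0.0,
            guess_rate=fixed["guess_rate"],
            trial_shift_1=fixed["trial_shift_1"],
            trial_shift_2=fixed["trial_shift_2"],
        )

    def loss_at(theta: np.ndarray) -> float:
        sd, ref = theta[0], theta[1]
        if sd < 0.5:  # keep the search in the valid domain
            return 1e3 + (0.5 - sd) ** 2
        biases = dict(zip(blocks, theta[2:]))
        sim = simulate_rates(make_params(sd, ref), biases, designs, n_sim, seed)
        return mse_loss(observed, sim)

    # coarse map
    best = None
    for sd in sigma_grid:
        for ref in ref_grid:
            theta = np.array([sd, ref] + [bias_init] * len(blocks))
            val = loss_at(theta)
            if best is None or val < best[1]:
                best = (theta, val)
    assert best is not None

    res = minimize(
        loss_at, best[0], method="Nelder-Mead",
        options={"fatol": 1e-5, "xatol": 1e-3, "maxfev": maxfev},
    )
    theta = res.x if res.fun <= best[1] else best[0]
    final_loss = float(min(res.fun, best[1]))
    params = make_params(float(theta[0]), float(theta[1]))
    return FitResult(
        params=params,
        bias_by_block={b: float(v) for b, v in zip(blocks, theta[2:])},
        loss=final_loss,
        n_sim_sessions=n_sim,
    )


DEFAULT_GUESS_GRID = (0.0, 0.01, 0.013, 0.02, 0.05, 0.1)


def fit_stage2_guess(
    observed: pd.DataFrame,
    designs: Sequence[BlockDesign],
    stage1: FitResult,
    grid: Sequence[float] = DEFAULT_GUESS_GRID,
    n_sim: int = 100,
    seed: int = 0,
) -> FitResult:
    """Stage 2: pick the guess rate from a preset grid by simulation loss.

    Stage-1 parameters are never modified; only the guess rate moves.
    """
    best_g, best_loss = stage1.params.guess_rate, np.inf
    for g in grid:
        cand = replace(stage1.params, guess_rate=float(g))
        sim = simulate_rates(cand, stage1.bias_by_block, designs, n_sim, seed)
        val = mse_loss(observed, sim)
        if val < best_loss:
            best_g, best_loss = float(g), val
    return FitResult(
        params=replace(stage1.params, guess_rate=best_g),
        bias_by_block=dict(stage1.bias_by_block),
        loss=float(best_loss),
        n_sim_sessions=n_sim,
    )


def _dependency_targets(tree) -> dict[tuple, float]:
    out = {}
    for (trial_type, level, path), node in tree.nodes.items():
        if path in (("hit",), ("correct_rejection",)):
            out[(trial_type, level, path)] = node.p_yes
    return out


def fit_stage3_shifts(
    observed_tree,
    designs: Sequence[BlockDesign],
    stage2: FitResult,
    grid: Sequence[float] | None = None,
    n_sim: int = 20,
    seed: int = 0,
) -> FitResult:
    """Stage 3: pick the two history shifts from a grid.

    The shifts barely move hit/false-alarm rates, so the objective is the
    dependency tree: squared error of the after-hit and after-correct-
    rejection conditional P(yes) values against the observed tree.
    Earlier-stage parameters are never modified.
    """
    from .dependencies import build_dependency_tree

    if grid is None:
        grid = np.arange(0.0, 5.5, 0.5)
    target = _dependency_targets(observed_tree)
    if not target:
        raise ValueError("observed tree has no after-hit / after-CR nodes")

    def tree_loss(s1: float, s2: float) -> float:
        cand = replace(stage2.params, trial_shift_1=s1, trial_shift_2=s2)
        rng = np.random.default_rng(seed)
        dfs = []
        for design in designs:
            p = replace(cand, criterion_bias=stage2.bias_by_block[design.block_id])
            if design.method == "limits":
                for lvl in design.levels:
                    dfs.extend(_sessions_for(design, lvl, p, n_sim, rng))
            else:
                dfs.extend(_sessions_for(design, None, p, n_sim, rng))
        for k, df in enumerate(dfs):
            df["session_id"] = f"sim{k:04d}"
        sim_tree = build_dependency_tree(pd.concat(dfs, ignore_index=True), depth=1)
        err, n = 0.0, 0
        for key, obs_p in target.items():
            node = sim_tree.nodes.get(key)
            if node is not None:
                err += (obs_p - node.p_yes) ** 2
                n += 1
        return err / n if n else np.inf

    best = None
    for s1 in grid:
        for s2 in grid:
            val = tree_loss(float(s1), float(s2))
            if best is None or val < best[2]:
                best = (float(s1), float(s2), val)
    assert best is not None
    return FitResult(
        params=replace(stage2.params, trial_shift_1=best[0], trial_shift_2=best[1]),
        bias_by_block=dict(stage2.bias_by_block),
        loss=stage2.loss,
        n_sim_sessions=n_sim,
    )


def _session_values(df: pd.DataFrame, level: float | None) -> tuple[float, float, float]:
    r = session_rates(df)
    return pcmax(dprime(r)), r.hit_rate, r.fa_rate


def evaluate_fit(
    observed_by_block: dict[str, dict[float, RatePair]],
    designs: Sequence[BlockDesign],
    result: FitResult,
    rng: np.random.Generator,
    n_sim: dict[str, int] | None = None,
    n_draws: int = 100,
    sessions_per_level: int = 2,
) -> FitResult:
    """Score a fit by the exp–sim and sim–sim correlation protocol.

    Populates ``result.r2`` (same object, returned for convenience) with
    squared Pearson correlations for P(c)max, hit rate and — for the
    Method of Limits only — false-alarm rate.
    """
    if n_sim is None:
        n_sim = {"limits": 200, "constant": 1000}
    quantities = ("pcmax", "hits", "fa")
    exp_acc: dict[str, list[float]] = {q: [] for q in quantities}
    sim_acc: dict[str, list[float]] = {q: [] for q in quantities}

    for design in designs:
        skip_fa = design.method == "constant"
        p = replace(result.params,
                    criterion_bias=result.bias_by_block[design.block_id])
        pool_n = n_sim[design.method]
        # pool[level] -> (pcmax, hit, fa) per simulated session
        pool: dict[float, np.ndarray] = {}
        for lvl in design.levels:
            if design.method == "limits":
                dfs = _sessions_for(design, lvl, p, pool_n, rng)
                vals = [_session_values(df, lvl) for df in dfs]
            else:
                # constant: simulate the whole level set, slice out the level
                dfs = pool.get("_dfs")  # type: ignore[assignment]
                if dfs is None:
                    dfs = _sessions_for(design, None, p, pool_n, rng)
                    pool["_dfs"] = dfs  # type: ignore[index]
                vals = []
                for df in dfs:
                    valid = df[~df["is_correction"] & ~df["centre_reward"]]
                    sig = valid[(valid["trial_type"] == "signal")
                                & (valid["level"] == lvl)]
                    nos = valid[valid["trial_type"] == "nosignal"]
                    if len(sig) == 0:
                        continue
                    rp = RatePair(
                        float((sig["response"] == "yes").mean()),
                        float((nos["response"] == "yes").mean()),
                        n_signal=len(sig), n_nosignal=len(nos),
                    )
                    vals.append((pcmax(dprime(rp)), rp.hit_rate, rp.fa_rate))
            pool[lvl] = np.asarray(vals)
        pool.pop("_dfs", None)

        levels = [lvl for lvl in design.levels if lvl in observed_by_block[design.block_id]]
        model_mean = {lvl: pool[lvl].mean(axis=0) for lvl in levels}

        # exp-sim: observed per-level values vs simulated means
        obs = observed_by_block[design.block_id]
        obs_vals = {
            "pcmax": [pcmax(dprime(obs[lvl])) for lvl in levels],
            "hits": [obs[lvl].hit_rate for lvl in levels],
            "fa": [obs[lvl].fa_rate for lvl in levels],
        }
        sim_vals = {q: [model_mean[lvl][k] for lvl in levels]
                    for k, q in enumerate(("pcmax", "hits", "fa"))}
        for q in quantities:
            if q == "fa" and skip_fa:
                continue
            exp_acc[q].append(_r2(obs_vals[q], sim_vals[q]))

        # sim-sim: one block-sized draw vs the mean of the remainder
        for _ in range(n_draws):
            drawn, rest = {}, {}
            for lvl in levels:
                idx = rng.choice(len(pool[lvl]),
                                 size=min(sessions_per_level, len(pool[lvl])),
                                 replace=False)
                mask = np.zeros(len(pool[lvl]), dtype=bool)
                mask[idx] = True
                drawn[lvl] = pool[lvl][mask].mean(axis=0)
                rest[lvl] = pool[lvl][~mask].mean(axis=0)
            for k, q in enumerate(("pcmax", "hits", "fa")):
                if q == "fa" and skip_fa:
                    continue
                sim_acc[q].append(_r2([drawn[lvl][k] for lvl in levels],
                                      [rest[lvl][k] for lvl in levels]))

    result.r2 = {
        "exp_sim": {q: float(np.mean(v)) for q, v in exp_acc.items() if v},
        "sim_sim": {q: float(np.mean(v)) for q, v in sim_acc.items() if v},
    }
    return result


def _r2(x, y) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)
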