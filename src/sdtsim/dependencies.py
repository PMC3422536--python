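"""Sequential (choice-history) dependency analysis of trial logs.

Estimates the probability of a "yes" response on the current trial
conditioned on the outcome of the previous trial (hit, miss, correct
rejection or false alarm) and, at depth 2, the trial before that —
separately for signal and no-signal trials and, where meaningful, per
signal level.  Probabilities are computed per session and then averaged
(unweighted) across sessions, with pooled counts kept alongside for the
chi-squared tests.

Because an error triggers correction trials that repeat the same
stimulus, a signal trial can never directly follow a false alarm when
correction trials are in use, so that conditional probability does not
exist.  Centre-reward trials are excluded throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DependencyNode",
    "DependencyTree",
    "build_dependency_tree",
    "test_dependencies",
    "dependency_slope",
    "differences_table",
]

#: pooled-level key for nodes not tied to a single signal level
POOLED = None

OUTCOMES = ("hit", "miss", "correct_rejection", "false_alarm")


@dataclass
class DependencyNode:
    """Conditional P(yes) for one (trial type, level, outcome path) cell.

    ``path`` holds the conditioning outcomes going backwards: ``path[0]``
    is the outcome on trial i-1, ``path[1]`` (depth 2) on trial i-2.  An
    empty path is the unconditional node.
    """

    trial_type: str
    level: float | None
    path: tuple[str, ...]
    p_yes: float  # unweighted mean of per-session probabilities
    per_session: list[float]
    n_yes: int  # pooled counts across sessions
    n: int

    @property
    def n_sessions(self) -> int:
        return len(self.per_session)

    @property
    def pooled_p_yes(self) -> float:
        return self.n_yes / self.n if self.n else float("nan")


@dataclass
class ComparisonResult:
    """Chi-squared comparison of two conditioning paths' yes/no counts."""

    trial_type: str
    level: float | None
    path_a: tuple[str, ...]
    path_b: tuple[str, ...]
    chi2: float
    p_raw: float
    p_adj: float | None = None
    min_expected: float = float("nan")

    @property
    def low_counts(self) -> bool:
        return self.min_expected < 5


@dataclass
class DependencyTree:
    nodes: dict[tuple[str, float | None, tuple[str, ...]], DependencyNode] \
        = field(default_factory=dict)
    tests: list[ComparisonResult] = field(default_factory=list)
    depth: int = 1

    def get(self, trial_type: str, level: float | None,
            path: tuple[str, ...] = ()) -> DependencyNode | None:
        return self.nodes.get((trial_type, level, tuple(path)))

    def to_dict(self) -> dict:
        return {
            "depth": self.depth,
            "nodes": [
                {
                    "trial_type": n.trial_type, "level": n.level,
                    "path": list(n.path), "p_yes": n.p_yes,
                    "pooled_p_yes": n.pooled_p_yes,
                    "n_yes": n.n_yes, "n": n.n,
                    "n_sessions": n.n_sessions,
                }
                for n in self.nodes.values()
            ],
            "tests": [
                {
                    "trial_type": t.trial_type, "level": t.level,
                    "path_a": list(t.path_a), "path_b": list(t.path_b),
                    "chi2": t.chi2, "p_raw": t.p_raw, "p_adj": t.p_adj,
                    "min_expected": t.min_expected,
                }
                for t in self.tests
            ],
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def _annotate(trials: pd.DataFrame, depth: int) -> pd.DataFrame:
    """Add previous-outcome columns (within session); drop centre rewards."""
    t = trials[~trials["centre_reward"]].copy()
    g = t.groupby("session_id", sort=False)
    t["prev1"] = g["outcome"].shift(1)
    if depth == 2:
        t["prev2"] = g["outcome"].shift(2)
    return t


def _session_level_key(t: pd.DataFrame, group_by_level: bool) -> pd.Series:
    """Level key per trial: a signal trial's own level; for no-signal
    trials, the session's level when the session tests a single level
    (Method of Limits), otherwise pooled."""
    if not group_by_level:
        return pd.Series(POOLED, index=t.index, dtype=object)
    key = t["level"].astype(object).copy()
    per_sess = t[t["trial_type"] == "signal"].groupby("session_id")["level"].apply(
        lambda v: tuple(v.dropna().unique())
    )
    single = {sid: float(lvls[0]) for sid, lvls in per_sess.items() if len(lvls) == 1}
    nos = t["trial_type"] == "nosignal"
    key[nos] = t.loc[nos, "session_id"].map(lambda s: single.get(s, POOLED))
    return key


def build_dependency_tree(
    trials: pd.DataFrame,
    depth: int = 1,
    group_by_level: bool = True,
) -> DependencyTree:
    """Estimate conditional P(yes) keyed by previous-trial outcomes.

    Current trials include correction trials (responses after a miss or a
    false alarm are of interest precisely because they sit on correction
    trials); conditioning uses the immediately preceding trial within the
    same session.  Session probabilities are averaged unweighted across
    sessions having at least one qualifying trial; empty cells yield no
    node rather than a 0/0 probability.
    """
    if depth not in (1, 2):
        raise ValueError("depth must be 1 or 2")
    if trials.empty:
        raise ValueError("empty trial log")
    t = _annotate(trials, depth)
    t["level_key"] = _session_level_key(t, group_by_level)
    t["yes"] = (t["response"] == "yes").astype(int)

    tree = DependencyTree(depth=depth)
    paths: list[tuple[str, ...]] = [()]
    paths += [(o,) for o in OUTCOMES]
    if depth == 2:
        paths += [(o1, o2) for o1 in OUTCOMES for o2 in OUTCOMES]

    for trial_type in ("signal", "nosignal"):
        for level in _levels_for(t, trial_type, group_by_level):
            base = t[(t["trial_type"] == trial_type)
                     & (t["level_key"].apply(lambda v: v == level))]
            for path in paths:
                sub = base
                if len(path) >= 1:
                    sub = sub[sub["prev1"] == path[0]]
                if len(path) == 2:
                    sub = sub[sub["prev2"] == path[1]]
                if sub.empty:
                    continue
                per_sess = sub.groupby("session_id")["yes"].mean()
                node = DependencyNode(
                    trial_type=trial_type, level=level, path=path,
                    p_yes=float(per_sess.mean()),
                    per_session=per_sess.tolist(),
                    n_yes=int(sub["yes"].sum()), n=int(len(sub)),
                )
                tree.nodes[(trial_type, level, path)] = node
    return tree


def _levels_for(t: pd.DataFrame, trial_type: str, group_by_level: bool):
    if not group_by_level:
        return [POOLED]
    keys = t.loc[t["trial_type"] == trial_type, "level_key"]
    levels = sorted({k for k in keys if k is not None})
    if keys.isin([POOLED]).any() or not levels:
        levels = levels + [POOLED]
    return levels


def _chi2_yes_no(a: DependencyNode, b: DependencyNode,
                 correction: bool = False) -> tuple[float, float, float]:
    table = np.array([
        [a.n_yes, a.n - a.n_yes],
        [b.n_yes, b.n - b.n_yes],
    ])
    if (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
        return 0.0, 1.0, 0.0
    res = chi2_contingency(table, correction=correction)
    return float(res.statistic), float(res.pvalue), float(res.expected_freq.min())


def test_dependencies(
    tree: DependencyTree,
    alpha: float = 0.05,
    correction: bool = False,
) -> DependencyTree:
    """Chi-squared tests of after-hit vs after-correct-rejection cells.

    For every (trial type, level) the depth-1 comparison tests the yes/no
    counts after a hit against those after a correct rejection; at depth 2
    the i-2 outcome (hit vs CR) is tested within each i-1 branch.
    Holm–Bonferroni adjustment is applied within each family, one family
    per trial type (the per-panel convention).  Results are stored on the
    returned tree (same object, mutated).
    """
    comparisons: list[ComparisonResult] = []
    for trial_type in ("signal", "nosignal"):
        fam: list[ComparisonResult] = []
        cells = sorted(
            {lvl for (tt, lvl, _p) in tree.nodes if tt == trial_type},
            key=lambda v: (v is None, v),
        )
        for level in cells:
            pairs = [(("hit",), ("correct_rejection",))]
            if tree.depth == 2:
                for branch in ("hit", "correct_rejection"):
                    pairs.append(((branch, "hit"), (branch, "correct_rejection")))
            for pa, pb in pairs:
                a, b = tree.get(trial_type, level, pa), tree.get(trial_type, level, pb)
                if a is None or b is None:
                    continue
                chi2, p, min_exp = _chi2_yes_no(a, b, correction=correction)
                fam.append(ComparisonResult(
                    trial_type=trial_type, level=level, path_a=pa, path_b=pb,
                    chi2=chi2, p_raw=p, min_expected=min_exp,
                ))
        if fam:
            _, p_adj, _, _ = multipletests([c.p_raw for c in fam],
                                           alpha=alpha, method="holm")
            for c, pa in zip(fam, p_adj):
                c.p_adj = float(pa)
        comparisons.extend(fam)
    tree.tests = comparisons
    return tree


def dependency_slope(
    tree: DependencyTree, noise_level: float = 0.0
) -> tuple[float, float]:
    """OLS slope (per dB SNR) and F statistic of the after-CR minus
    after-hit P(yes) difference across all per-level points."""
    xs, ys = [], []
    for (trial_type, level, _p) in list(tree.nodes):
        if level is None:
            continue
        a = tree.get(trial_type, level, ("correct_rejection",))
        b = tree.get(trial_type, level, ("hit",))
        if a is None or b is None:
            continue
        xs.append(level - noise_level)
        ys.append(a.p_yes - b.p_yes)
    # a node key appears once per path; deduplicate (trial_type, level)
    pts = sorted(set(zip(xs, ys)))
    if len(pts) < 3:
        raise ValueError("need at least three (SNR, difference) points")
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    from scipy.stats import linregress
    res = linregress(x, y)
    f_stat = float((res.slope / res.stderr) ** 2) if res.stderr > 0 else float("inf")
    return float(res.slope), f_stat


def differences_table(tree: DependencyTree, noise_level: float = 0.0) -> pd.DataFrame:
    """Per-SNR after-CR minus after-hit differences (summary export)."""
    rows = []
    seen = set()
    for (trial_type, level, _p) in list(tree.nodes):
        if (trial_type, level) in seen:
            continue
        seen.add((trial_type, level))
        a = tree.get(trial_type, level, ("correct_rejection",))
        b = tree.get(trial_type, level, ("hit",))
        if a is None or b is None:
            continue
        rows.append({
            "trial_type": trial_type,
            "level": level,
            "snr": None if level is None else level - noise_level,
            "p_yes_after_cr": a.p_yes,
            "p_yes_after_hit": b.p_yes,
            "difference": a.p_yes - b.p_yes,
            "n_after_cr": a.n,
            "n_after_hit": b.n,
        })
    return pd.DataFrame(rows)
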