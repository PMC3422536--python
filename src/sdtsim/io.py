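"""Serialisation: trial logs, configuration files and parameter presets.

Trial logs travel as flat CSV tables (one row per trial, fixed header,
RFC-4180, '.' decimal, dB values at 4 decimal places) or as JSON-lines.
Configs are YAML or JSON mappings.  The ``table1`` preset materialises
the published fitted observer parameters for the five ferrets (two
masker levels for F1) under both the Method of Limits and the Method of
Constant Stimuli, together with each condition's masker noise level.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .sdt_core import ObserverParams, StimulusSet
from .simulate import TRIAL_COLUMNS, BlockConfig, SessionConfig

__all__ = [
    "write_trials",
    "read_trials",
    "write_trials_jsonl",
    "read_trials_jsonl",
    "save_config",
    "load_config",
    "params_to_dict",
    "params_from_dict",
    "TABLE1",
    "get_preset",
    "parse_preset",
    "preset_method_differences",
]

_DB_COLUMNS = ("level", "internal_value", "criterion_used")
_BOOL_COLUMNS = ("is_correction", "rewarded", "centre_reward")


def write_trials(trials: pd.DataFrame, path: str | Path) -> None:
    """Write a trial log as CSV (dB values at 4 decimal places)."""
    df = trials.loc[:, [c for c in TRIAL_COLUMNS if c in trials.columns]]
    df.to_csv(path, index=False, float_format="%.4f", lineterminator="\n")


def read_trials(path: str | Path) -> pd.DataFrame:
    """Read a CSV trial log, with row-level diagnostics on malformed input."""
    df = pd.read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing trial-log columns {missing}")
    for col in _BOOL_COLUMNS:
        if df[col].dtype != bool:
            mapped = df[col].map({"True": True, "False": False, True: True,
                                  False: False})
            bad = df.index[mapped.isna()]
            if len(bad):
                raise ValueError(
                    f"{path}: non-boolean {col!r} at rows {list(bad[:5])}"
                )
            df[col] = mapped.astype(bool)
    bad_resp = df.index[~df["response"].isin(["yes", "no"])]
    if len(bad_resp):
        raise ValueError(f"{path}: invalid response at rows {list(bad_resp[:5])}")
    return df


def write_trials_jsonl(trials: pd.DataFrame, path: str | Path) -> None:
    df = trials.copy()
    for col in _DB_COLUMNS:
        df[col] = df[col].round(4)
    with open(path, "w", encoding="utf-8") as fh:
        for rec in df.to_dict(orient="records"):
            if isinstance(rec.get("level"), float) and np.isnan(rec["level"]):
                rec["level"] = None
            fh.write(json.dumps(rec) + "\n")


def read_trials_jsonl(path: str | Path) -> pd.DataFrame:
    rows = []
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line:
                continue
            try:
                rows.append(json.loads(line))
            except json.JSONDecodeError as err:
                raise ValueError(f"{path}: malformed JSON at line {i + 1}: {err}")
    df = pd.DataFrame(rows, columns=TRIAL_COLUMNS)
    df["level"] = df["level"].astype(float)
    return df


def save_config(config: dict, path: str | Path) -> None:
    path = Path(path)
    text = (json.dumps(config, indent=1) if path.suffix == ".json"
            else yaml.safe_dump(config, sort_keys=False))
    path.write_text(text, encoding="utf-8")


def load_config(path: str | Path) -> dict:
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    return json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)


def params_to_dict(params: ObserverParams) -> dict:
    return asdict(params)


def params_from_dict(d: dict) -> ObserverParams:
    return ObserverParams(**d)


def stimulus_from_dict(d: dict) -> StimulusSet:
    return StimulusSet(method=d["method"],
                       signal_levels=tuple(d["signal_levels"]),
                       noise_level=d.get("noise_level", 0.0))


def session_config_from_dict(d: dict) -> SessionConfig:
    d = dict(d)
    d["stimuli"] = stimulus_from_dict(d["stimuli"])
    return SessionConfig(**d)


def block_config_from_dict(d: dict) -> BlockConfig:
    d = dict(d)
    if d.get("level_set") is not None:
        d["level_set"] = tuple(d["level_set"])
    return BlockConfig(**d)


# ---------------------------------------------------------------------------
# Published fitted observer parameters per ferret and data-collection method
# (internal s.d. dB, mean block criterion bias dB, guess rate, reference
# level dB SPL, trial shifts dB), plus each condition's masker level.
# ---------------------------------------------------------------------------

def _row(sd, bias, guess, ref, s1, s2, noise):
    return {
        "internal_sd": sd, "criterion_bias": bias, "guess_rate": guess,
        "reference_level": ref, "trial_shift_1": s1, "trial_shift_2": s2,
        "noise_level": noise,
    }


TABLE1: dict[tuple[str, str], dict] = {
    # Method of Limits
    ("F1_35", "limits"): _row(10.54, 1.80, 0.010, 12.54, 2.0, 1.0, 35.0),
    ("F1_55", "limits"): _row(11.83, 1.48, 0.010, 31.55, 2.0, 1.0, 55.0),
    ("F2", "limits"): _row(9.20, 3.78, 0.010, 37.35, 2.0, 1.5, 48.0),
    ("F3", "limits"): _row(11.29, 1.03, 0.050, 39.46, 2.5, 2.0, 48.0),
    ("F4", "limits"): _row(11.00, 1.05, 0.050, 29.86, 2.0, 1.5, 48.0),
    ("F5", "limits"): _row(7.24, 1.85, 0.013, 30.30, 2.0, 1.0, 48.0),
    # Method of Constant Stimuli
    ("F1_35", "constant"): _row(11.00, 2.98, 0.010, 12.00, 2.5, 1.0, 35.0),
    ("F1_55", "constant"): _row(11.80, 3.40, 0.010, 32.76, 3.0, 2.5, 55.0),
    ("F2", "constant"): _row(8.07, 3.62, 0.010, 37.39, 2.0, 1.5, 48.0),
    ("F3", "constant"): _row(11.86, 4.19, 0.020, 40.51, 3.5, 3.0, 48.0),
    ("F4", "constant"): _row(10.50, 3.20, 0.010, 35.14, 2.0, 1.5, 48.0),
    ("F5", "constant"): _row(11.09, 2.24, 0.020, 26.29, 2.0, 1.5, 48.0),
}


def get_preset(ferret: str, method: str) -> tuple[ObserverParams, float]:
    """Observer parameters and masker noise level for one fitted model."""
    key = (ferret, method)
    if key not in TABLE1:
        raise KeyError(
            f"no preset for {ferret!r}/{method!r}; available: "
            f"{sorted(set(f for f, _ in TABLE1))} x "
            f"{sorted(set(m for _, m in TABLE1))}"
        )
    row = TABLE1[key]
    params = ObserverParams(
        internal_sd=row["internal_sd"],
        reference_level=row["reference_level"],
        criterion_bias=row["criterion_bias"],
        guess_rate=row["guess_rate"],
        trial_shift_1=row["trial_shift_1"],
        trial_shift_2=row["trial_shift_2"],
    )
    return params, row["noise_level"]


def parse_preset(spec: str) -> tuple[ObserverParams, float]:
    """Parse a ``table1:<ferret>:<method>`` preset specifier."""
    parts = spec.split(":")
    if len(parts) != 3 or parts[0] != "table1":
        raise ValueError(f"preset must look like table1:<ferret>:<method>, got {spec!r}")
    return get_preset(parts[1], parts[2])


def preset_method_differences() -> dict[str, float]:
    """Mean (Constant Stimuli − Limits) parameter difference across the six
    fitted models (same ferret and masker level paired across methods)."""
    keys = sorted({f for f, _ in TABLE1})
    out: dict[str, float] = {}
    for name in ("internal_sd", "reference_level", "trial_shift_1", "trial_shift_2"):
        diffs = [TABLE1[(f, "constant")][name] - TABLE1[(f, "limits")][name]
                 for f in keys]
        out[name] = float(np.mean(diffs))
    return out
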