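# sdtsim

Simulation and analysis of yes/no tone-in-noise detection behaviour with an
equal-variance signal-detection-theory (SDT) observer, built for animal
(ferret) psychoacoustics. The package generates realistic trial-by-trial
session logs under three data-collection methods, estimates psychometric
functions and detection thresholds, quantifies trial-history (choice-history)
dependencies, fits the observer model back to behavioural rates in supervised
stages, and evaluates reward-maximisation accounts of criterion setting.

## The model

The observer lives on a decibel scale. A signal trial at tone level `L`
evokes an internal value `L + ε`, a no-signal trial evokes `ref + ε`, with
`ε ~ N(0, σ²)`; `ref` is the *reference level*, the tone level
indistinguishable from silence. The observer answers "yes" when the internal
value exceeds a decision criterion that moves trial by trial:

```
c_i = c_opt + b + s1·sign(r_{i-1}) + s2·sign(r_{i-2})
```

where `c_opt` is the reward-optimal criterion for the session's stimulus set
(the midpoint of the two means for a single level; the `P(fa) = P(miss)`
root for a multi-level set), `b` a fixed block-level bias, and `s1`, `s2`
criterion shifts contingent on the previous responses (`sign(yes) = +1`,
`sign(no) = −1`). With probability `g` (the guess rate) a response is a fair
coin instead. Errors trigger *correction trials* — identical stimulus
repeats until the response is correct — which are excluded from all rates.

Sensitivity is summarised as `d′ = z(H) − z(FA)` with `1/(2N)` clipping of
degenerate rates, and as `P(c)max = Φ(d′/2)`. Thresholds are read off
logistic fits `P(L) = 0.5 + 0.5/(1 + exp(−(L − m)/s))` at the 71% `P(c)max`
criterion.

## Worked example

```python
import numpy as np
from sdtsim import (get_preset, BlockConfig, run_limits_block,
                    analyze_trials, build_dependency_tree, test_dependencies)

params, noise = get_preset("F2", "limits")   # σ=9.2, ref=37.35, bias=3.78,
                                             # g=0.01, shifts 2/1.5, masker 48
rng = np.random.default_rng(11)

# one Method-of-Limits block: descending across-session staircase
block = BlockConfig(method="limits", start_level=72.0, noise_level=noise)
sim = run_limits_block(block, params, rng)
trials = sim.all_trials()

res = analyze_trials(trials, "limits", noise_level=noise)
print(res.levels)        # e.g. [47.0, 52.0, 72.0]
print(res.threshold)     # 71% P(c)max threshold, ~46-49 dB SPL

tree = test_dependencies(build_dependency_tree(trials, depth=1))
node = tree.get("signal", 47.0, ("correct_rejection",))
print(node.p_yes)        # P(yes | previous trial was a correct rejection)
```

The same pipeline is available from the command line:

```bash
sdtsim simulate limits --preset table1:F2:limits --seed 11 --out run/
sdtsim analyze psychometric --log run/trials.csv --method limits \
       --noise-level 48 --seed 1 --out run/psy.json
sdtsim analyze dependency --log run/trials.csv --out run/dep.json
sdtsim reward --preset table1:F2:limits --out run/reward/
```

Every stochastic command records its seed and fully resolved configuration
in a `manifest.json`, so runs are reproducible bit for bit.

## Package layout

| module | contents |
| --- | --- |
| `sdtsim.sdt_core` | observer/stimulus types, analytic rates, optimal criterion, d′, P(c)max |
| `sdtsim.simulate` | trial-by-trial session generator; limits / constant-stimuli / adaptive schedules |
| `sdtsim.psychometrics` | rate aggregation, logistic fits, thresholds, confidence bands |
| `sdtsim.dependencies` | conditional P(yes) trees, Holm-corrected chi-squared tests |
| `sdtsim.fitting` | staged model fitting (σ/ref/bias → guess rate → history shifts), r² protocol |
| `sdtsim.reward` | deterministic reward-vs-criterion curves, argmax, gradients |
| `sdtsim.io`, `sdtsim.cli` | CSV/JSONL/YAML serialisation, parameter presets, CLI |

See `docs/methods.md` for modelling assumptions, parameter conventions and
numerical choices.

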