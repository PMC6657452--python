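# catqol

Simulation and evaluation toolkit for **adaptive quality-of-life (QoL)
assessment with individualized feedback**. It answers questions of the
form: if a patient-reported outcome measure is delivered as a
computerized adaptive test (CAT) instead of a fixed-length form, and its
scores are fed back graphically or with tailored text, how short does
the assessment get, and how do user-experience ratings move? The
package is aimed at psychometricians and health-outcomes researchers
who want a tested, seeded sandbox for that design.

## What is inside

* **Rasch partial credit model (PCM) core** — for an item with ordered
  categories `0..m` and step thresholds `b_j`,
  `P(X=k|θ) ∝ exp(Σ_{j≤k}(θ−b_j))`; maximum-likelihood trait estimation
  with `SE = 1/√ΣI_i(θ̂)`, bounded to θ ∈ [−4, 4].
* **Adaptive engine** — maximum-information item selection, stop at
  `SE < 0.45` (configurable), norm-referenced scoring
  `score = clip(50 + (100/6)·z, 0, 100)` with `z = (θ−μ_norm)/σ_norm`.
* **Fixed-form scoring** — BREF-style: reverse-keyed recoding, domain
  means, linear 0–100 transform, 20% missing-data tolerance.
* **Feedback generator** — per-domain 0–100 bars and band-tailored text
  (lower / average / higher than the population mean ±5 points).
* **Ordinal psychometrics** — Cliff's delta
  `δ = (#{x>y} − #{x<y})/(n_x n_y)` with Cliff's consistent-variance CI;
  exact (pooled n ≤ 20) and tie-corrected asymptotic Wilcoxon rank-sum;
  polytomous Loevinger H with greedy AISP; Cronbach's α; the
  P<.005 significant / P<.05 suggestive evidence convention.
* **Synthetic generators** — item banks, PCM respondents, and six-arm
  acceptability surveys whose *population* Cliff deltas are calibrated
  exactly (quadrature + convolution + root finding), so parameter
  recovery can be tested against known truth.
* **Study pipeline** — six conditions ({fixed, CAT} × {no feedback,
  graphical, graphical+text}), attention-check filtering, all comparison
  tables, and the CAT item-reduction summary, deterministic per seed.

## Worked example

```python
import numpy as np
from catqol import (SynthConfig, generate_acceptability, compare_groups,
                    loevinger_h, cronbach_alpha)
from catqol.psych import SURVEY_ITEMS

records = generate_acceptability(SynthConfig(), seed=11)
kept = [r for r in records if not r.attention_failed]

gt   = np.array([r.total for r in kept if r.condition.endswith("graphical_text")])
none = np.array([r.total for r in kept if r.condition.endswith("_none")])
res = compare_groups(gt, none)
X = np.array([r.items for r in kept])
```

The same analysis, with printing, is `examples/04_effect_sizes.py`;
it outputs:

```
enrolled 1454, analyzed 1389 after the attention check
graphical+text vs no feedback (0-16 totals): delta +0.25 [+0.18, +0.32], P=2.3e-11 (significant)
scale H = 0.44 (medium); item H: interesting 0.44, information 0.44, share 0.44, recommend 0.42
Cronbach alpha = 0.75 over 4 items
```

1454 simulated respondents enroll; 65 endorsed the attention check and
are dropped. The pooled contrast of the two graphical+text arms against
the two no-feedback arms estimates Cliff's δ = +0.25 — within sampling
error of the generator's calibrated population value of 0.22 — and is
significant under the P<.005 convention. The four acceptability items
form a single medium-strength Mokken scale (H = 0.44) with adequate
internal consistency (α = 0.75).

The `examples/` directory has one short script per capability
(adaptive session walk-through, fixed-form scoring, feedback rendering,
effect sizes, full study). A thin CLI mirrors the pipeline:

```bash
catqol synth --seed 7 --outdir data/          # bank.csv, responses.csv, acceptability.csv
catqol simulate-cat --bank data/bank.csv --n 500 --se-stop 0.45 --seed 7 --out sessions.jsonl
catqol run --seed 7 --out report.json         # full six-arm study
catqol analyze --acceptability data/acceptability.csv --out effects.csv
```

## Documentation

`docs/methods.md` describes the models, defaults, calibration
machinery, numerical choices, and what the synthetic data do and do not
emulate.
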