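"""Ordinal effect sizes and scale psychometrics on a synthetic survey.

Generates the six-arm acceptability survey (population Cliff deltas
calibrated exactly by the generator), then estimates from the sample:
Cliff's delta with CI and a rank-sum P for the headline pooled contrast,
plus Loevinger's H and Cronbach's alpha for the 4-item scale.
"""

import numpy as np

from catqol import (
    SynthConfig,
    compare_groups,
    cronbach_alpha,
    generate_acceptability,
    loevinger_h,
)
from catqol.psych import SURVEY_ITEMS

records = generate_acceptability(SynthConfig(), seed=11)
kept = [r for r in records if not r.attention_failed]
print(f"enrolled {len(records)}, analyzed {len(kept)} after the attention check")

gt = [r.total for r in kept if r.condition.endswith("graphical_text")]
none = [r.total for r in kept if r.condition.endswith("_none")]
res = compare_groups(np.array(gt), np.array(none))
print(
    f"graphical+text vs no feedback (0-16 totals): delta {res.delta:+.2f} "
    f"[{res.ci_low:+.2f}, {res.ci_high:+.2f}], P={res.p_value:.2g} ({res.verdict.value})"
)

X = np.array([r.items for r in kept])
mokken = loevinger_h(X, item_labels=list(SURVEY_ITEMS))
alpha = cronbach_alpha(X)
print(f"scale H = {mokken.scale_h:.2f} ({mokken.classification}); item H: "
      + ", ".join(f"{k} {v:.2f}" for k, v in mokken.item_h.items()))
print(f"Cronbach alpha = {alpha.alpha:.2f} over {alpha.n_items} items")
# The generator's pooled population delta is 0.22; the sample estimate
# lands within sampling error of that.  H above .3 for every item and a
# single selected scale indicate the four items form one scalable
# acceptability dimension.
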