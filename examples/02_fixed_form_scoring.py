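"""Scoring a fixed-length questionnaire.

A 24-item form (6 items x 4 domains, 5 response categories, one
negatively worded item per domain) is scored per domain: reversed items
are recoded, the domain mean of non-missing items is rescaled to 0-100,
and a domain with more than 20% of its items missing stays missing.
"""

import numpy as np
import pandas as pd

from catqol import default_fixed_form, score_fixed_form

form = default_fixed_form()

# two hand-written respondents: resp_a mid-range with a missing answer,
# resp_b reporting the best possible quality of life (top category on the
# positively worded items, bottom category on the negatively worded ones)
rows = {it.item_id: ([3, 1] if it.reversed else [3, 5]) for it in form.items}
rows["bref_phys_2"] = [np.nan, 5]
responses = pd.DataFrame(rows, index=["resp_a", "resp_b"])

scores = score_fixed_form(form, responses)
print(scores.pivot(index="respondent_id", columns="domain_id", values="score_0_100"))
# resp_b sits at the 100 anchor in every domain once the negatively
# worded items are recoded.  resp_a answered 3 ("neither") throughout,
# which lands at 50 -- recoding maps the scale midpoint to itself.  The
# missing item is simply left out of its domain mean (1 of 6 missing is
# under the 20% tolerance).
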