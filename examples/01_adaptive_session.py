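"""One adaptive assessment session, step by step.

Builds a synthetic 25-item partial-credit bank for the physical domain,
simulates a respondent with a known trait, and walks the adaptive loop:
pick the most informative item, record the response, re-estimate, stop
once the standard error drops below 0.45 logits.
"""

import numpy as np

from catqol import BankSpec, CatConfig, generate_bank, run_cat, theta_to_domain_score
from catqol.irt import pcm_category_probs

rng = np.random.default_rng(7)
true_theta = 0.8  # the respondent's actual quality of life, in logits

bank = generate_bank(BankSpec(), seed=1)
config = CatConfig(se_stop=0.45, norms={"physical": (0.0, 1.0)})


def responder(item):
    p = pcm_category_probs(item, true_theta)
    return int(rng.choice(len(p), p=p))


session = run_cat(bank, responder, config, "physical")

print(f"true theta = {true_theta}")
for (item_id, category), est in zip(session.administered, session.trajectory):
    print(
        f"  {item_id}: answered {category}  ->  "
        f"theta {est.theta:+.2f} (SE {est.se:.3f})"
    )
print(f"stopped: {session.stopped_reason.value} after {session.n_items} items")

score = theta_to_domain_score(session.final, config, "physical")
print(f"domain score: {score.score_0_100:.1f} / 100 (z = {score.z:+.2f})")
# The trajectory shows the SE shrinking with each answer; the final line
# maps the trait estimate onto the 0 (worst) .. 100 (best) reporting scale
# where 50 is the reference-population mean.
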