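"""Tailored feedback for one respondent's domain scores.

Scores are banded against reference means (within +/-5 points counts as
"average"); the graphical condition yields 0-100 bars only, while the
graphical+text condition adds a message per domain that states the
numeric score and what it suggests.
"""

from catqol import DomainScore, render_feedback
from catqol.feedback import bundle_to_json

NORMS = {"physical": 68.0, "psychological": 59.0, "social": 57.0, "environment": 72.0}

scores = [
    DomainScore("physical", z=0.0, score_0_100=68.0, source="cat"),
    DomainScore("psychological", z=-1.98, score_0_100=26.0, source="cat"),
    DomainScore("social", z=0.1, score_0_100=57.0, source="cat"),
    DomainScore("environment", z=0.66, score_0_100=83.0, source="cat"),
]

bars_only = render_feedback(scores, "graphical")
print("graphical bars:", bars_only.bars)

full = render_feedback(scores, "graphical_text", norms=NORMS)
for domain, band, message in full.texts:
    print(f"\n[{domain} | {band.value}]\n  {message}")

print("\nserialized:", bundle_to_json(full)[:120], "...")
# The psychological score of 26 sits far below the reference mean of 59,
# so its message uses the lower-band wording; physical and social are
# within 5 points of their norms and read as "about average".
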