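"""The whole pipeline in one call.

Runs a scaled-down six-arm study -- synthetic surveys, attention filter,
adaptive and fixed-length scoring, feedback, effect sizes, scalability,
viewing times and the CAT item-count reduction -- and prints the report.
For the full-scale run (1454 enrolled) drop the size overrides; it takes
a few seconds longer.
"""

from catqol import BankSpec, StudyConfig, SynthConfig, report_to_text, run_study

config = StudyConfig(
    synth=SynthConfig(
        n_respondents=420,
        condition_sizes={
            "fixed_none": 65,
            "fixed_graphical": 65,
            "fixed_graphical_text": 65,
            "cat_none": 65,
            "cat_graphical": 65,
            "cat_graphical_text": 65,
        },
    ),
    max_cat_respondents=40,
)

report = run_study(config, seed=9)
print(report_to_text(report))
print("CAT detail:", report["cat_summary"])
# At this reduced n the per-arm confidence intervals are wide; the
# full-size run separates the graphical+text arms from the control at
# the P<.005 threshold and reproduces a ~25% item reduction.
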