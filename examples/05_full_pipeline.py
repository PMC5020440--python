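"""The whole pipeline in one call, plus the equivalent shell commands.

Simulates a default cohort, runs group construction, eligibility
filtering, ranking, the 4x4 model grid, collinearity diagnostics and the
four eta scans, and prints the rendered report.

Shell equivalent:

    ranknorms run-all --seed 42 --out-dir out/
    ranknorms simulate --seed 42 --out survey.csv
    ranknorms report --in survey.csv --out-dir out/
"""

import ranknorms as rn

report = rn.run_pipeline(rn.CohortConfig(seed=42))
print(rn.render_report_text(report))
print("JSON payload keys:", sorted(report.to_dict().keys()))
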