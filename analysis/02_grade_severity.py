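"""Grade recurrence severity from imaging volume and NIHSS.

Applies the three-level grading (imaging volume bands, NIHSS bands, worse
grade wins on mismatch) and the moderate/severe-vs-mild binary recoding to
the simulated cohort, and reports the grade distribution.
"""

from pathlib import Path

import pandas as pd

from strokerecur.grading import grade_cohort

outdir = Path(__file__).resolve().parents[1] / "results"
df = pd.read_csv(outdir / "cohort.csv")
graded = df.copy()
graded[["recurrence_grade", "recurrence_binary_graded"]] = grade_cohort(
    df.rename(columns={"recurrence_binary": "_sim_outcome"}),
    nihss_col="recurrence_nihss",
)[["recurrence_grade", "recurrence_binary"]]
graded.to_csv(outdir / "cohort_graded.csv", index=False)

counts = graded["recurrence_grade"].value_counts().sort_index()
labels = {0: "mild", 1: "moderate", 2: "severe"}
print("severity distribution (grading applied to imaging volume + NIHSS):")
for level, n in counts.items():
    print(f"  {labels[level]:>8}: {n} ({n / len(graded):.1%})")
print(f"binary event rate (moderate+severe): {graded['recurrence_binary_graded'].mean():.3f}")
print("(downstream analyses use the model-simulated outcome in cohort.csv)")
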