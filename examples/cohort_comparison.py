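"""Real-vs-fake comparison on a simulated cohort.

Simulates a reduced cohort (40 subjects x 4 emotions x 2 conditions;
24-s recordings with a 15-s analysis window), runs the complete
pipeline and prints the collapsed per-emotion summaries, a slice of the
per-AU comparison grid, the factor regression on average movement, and
the HRV contrast.  With the default effect structure, mean movement is
higher in real expressions for every emotion, while the vibration
frequency is higher in fake expressions of contentment and sadness.
"""

import warnings

from micromotion import CohortSpec, analyze_cohort, factor_regression, generate_cohort
from micromotion.config import PipelineConfig

warnings.filterwarnings("ignore")

spec = CohortSpec(n_subjects=40, duration_s=24.0, window_s=15.0, seed=3)
out = analyze_cohort(generate_cohort(spec), PipelineConfig(window_s=15.0))

print("== collapsed per-emotion comparisons (pooled over AUs and sections) ==")
cols = ["emotion", "feature", "mean_real", "mean_fake", "direction", "stars"]
print(out["collapsed"][cols].round(3).to_string(index=False))

print("\n== per-AU grid, happiness / mean_delta / t+0.5 ==")
cells = out["cells"]
sel = cells[
    (cells.emotion == "happiness")
    & (cells.feature == "mean_delta")
    & (cells.section == "t+0.5")
]
print(sel[["au", "side", "t_stat", "p_value", "stars", "direction"]].round(4).to_string(index=False))

print("\n== factor regression of mean movement (happiness) ==")
reg = factor_regression(out["features"], "happiness")
print(f"R^2 = {reg.r_squared:.3f} on {reg.nobs} rows; factor p-values:")
for factor, p in reg.factor_pvalues.items():
    print(f"  {factor:13s} p = {p:.3g}")

print("\n== HRV real-vs-fake contrast ==")
print(
    out["hrv_cells"][["feature", "mean_real", "mean_fake", "direction", "stars"]]
    .round(1)
    .to_string(index=False)
)
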