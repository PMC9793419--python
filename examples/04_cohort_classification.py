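"""Classify cohorts of embryos and compare conditions.

Simulates a membrane-localized and a uniform cohort, runs the full
quantification (detect -> decompose -> profile -> classify) on each embryo,
and reports per-condition localized proportions plus a Welch two-sample
t-test on the bin-1 enrichment frequencies.
"""

import pandas as pd

from memfish import LocalizationModel
from memfish.pipeline import RunConfig, SimulationConfig, run_quantify, run_report, run_simulate

frames = []
for mode, seed in [("membrane", 11), ("uniform", 12)]:
    config = RunConfig(
        simulation=SimulationConfig(
            stage=2, shape=(24, 128, 128), n_molecules=600, n_embryos=4,
            model=LocalizationModel(mode=mode), seed=seed,
        ),
        condition=mode,
    )
    manifest = run_simulate(config, f"example_output/cohort_{mode}")
    inputs = [
        (f"{mode}_{e['embryo_id']}", e["files"]["stack"], e["files"]["labels"])
        for e in manifest["embryos"]
    ]
    df, _ = run_quantify(config, inputs)
    frames.append(df)

records = pd.concat(frames, ignore_index=True)
summary, comparisons = run_report(records, out_dir="example_output/report")

print(records[["embryo_id", "total_molecules", "bin1_frequency", "localization"]]
      .to_string(index=False))
print("\ncondition summary:")
print(summary.to_string(index=False))
print("\nWelch comparison of bin-1 frequencies:")
print(comparisons[["group_a", "group_b", "t", "df", "p", "stars"]].to_string(index=False))
print(
    "\nA bin-1 frequency near 1 means the outermost 10% of the cell holds no\n"
    "more mRNA than chance; the membrane cohort sits several-fold above it."
)
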