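"""Run the full analysis chain on the synthetic cohort.

simulate -> bandpass/decimate -> iAPF & individual theta band -> wPLI ->
median-threshold graphs -> efficiency/small-world metrics -> RM-ANOVA.
The run directory (with HDF5 connectivity store) lands in scratch/; the
text tables are copied to results/.
"""

import shutil
from pathlib import Path

import pandas as pd

from thetanet.pipeline import RunConfig, run_all, summarize

ROOT = Path(__file__).resolve().parents[1]

config = RunConfig(
    out_dir=str(ROOT / "scratch" / "pipeline_run"),
    n_subjects=4,
    tests=("T1", "T4"),
    trials_per_scenario=2,
    epoch_duration=40.0,
    rest_duration=60.0,
    sample_rate=250.0,
    n_surrogates=100,
    seed=2024,
)

run_dir = run_all(config)
report = summarize(run_dir)
print(report.read_text())

out = ROOT / "results"
out.mkdir(exist_ok=True)
for name in ["metrics.csv", "iapf.csv", "report.txt"]:
    shutil.copy(run_dir / name, out / name)
for f in run_dir.glob("stats_*.csv"):
    shutil.copy(f, out / f.name)

iapf = pd.read_csv(run_dir / "iapf.csv")
err = (iapf["iapf"] - iapf["alpha_true"]).abs()
print(f"iAPF recovery: max |error| = {err.max():.3f} Hz "
      f"(mean {err.mean():.3f} Hz) across {len(iapf)} sessions")
print(f"text tables -> {out}")
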