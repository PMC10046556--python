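"""Generate the synthetic study cohort and export it as EDF.

Builds a scaled-down cohort following the study protocol (4 scenarios of
increasing difficulty per test session, multiple trials per scenario,
eyes-closed rest before and after each session) with the default
condition effects: coupling density rising with difficulty in the first
session and falling with difficulty in the post-schema sessions.

EDF files are written under scratch/ (they are bulky and regenerable);
the tidy label table goes to results/.
"""

from pathlib import Path

from thetanet.synthdata import OscillatorSpec, StudyDesign, generate_study, \
    write_study_edf

ROOT = Path(__file__).resolve().parents[1]

design = StudyDesign(
    n_subjects=4,
    tests=("T1", "T4"),          # first and last test session
    trials_per_scenario=2,
    rest_duration=60.0,
)
base = OscillatorSpec(sample_rate=250.0, duration=40.0, seed=2024)

study = generate_study(design, base)
print(f"cohort: {design.n_subjects} subjects, "
      f"{len(study.tasks)} task recordings, {len(study.rests)} rest recordings")
print("per-session trial counts:")
print(study.labels.groupby(["subject", "test"]).size().to_string())
print("subject alpha peaks:",
      {s: round(a, 2) for s, a in study.subject_alpha.items()})

edf_dir = ROOT / "scratch" / "cohort_edf"
table = write_study_edf(study, edf_dir)
out = ROOT / "results"
out.mkdir(exist_ok=True)
table.to_csv(out / "cohort_labels.csv", index=False)
print(f"wrote {len(table)} EDF files to {edf_dir}")
print(f"label table -> {out / 'cohort_labels.csv'}")
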