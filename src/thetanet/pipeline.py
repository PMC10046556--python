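"""End-to-end orchestration: simulate -> preprocess -> wPLI -> graphs -> stats.

``run_all`` executes the whole chain for one configuration and writes a
self-contained run directory:

    run_dir/
      manifest.json        config + package version (regenerates the run)
      run.log              per-stage counts (segments dropped, degenerate
                           units, unreachable pairs)
      edf/                 optional EDF export of the synthetic cohort
      connectivity.h5      /connectivity/<subject>/<test>/<scenario>
      iapf.csv             per subject x test: iAPF and theta band
      metrics.csv          tidy (subject, test, scenario, metric, channel, value)
      stats_<metric>.csv   RM-ANOVA tables per network metric

``summarize`` renders a human-readable report (condition table, ANOVA
summary, scalp scatter of per-channel local efficiency).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import h5py
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .connectivity import analytic_signals, connectivity_matrix
from .netmetrics import binarize, compute_metrics, median_threshold
from .preprocess import (
    bandpass_and_decimate,
    estimate_iapf_cog,
    segment_by_events,
    session_iapf,
)
from .stats import results_to_frame, rm_anova_2way
from .synthdata import (
    SCENARIOS,
    TESTS,
    CellEffect,
    OscillatorSpec,
    StudyDesign,
    default_effect_map,
    generate_study,
    write_study_edf,
)

logger = logging.getLogger(__name__)

NETWORK_METRICS = ("E_global", "E_local_mean", "sigma")


@dataclass
class RunConfig:
    """Everything needed to regenerate a run, serializable to YAML."""

    out_dir: str = "run"
    # synthetic cohort
    n_subjects: int = 10
    tests: Sequence[str] = TESTS
    scenarios: Sequence[str] = SCENARIOS
    trials_per_scenario: int = 4
    epoch_duration: float = 60.0
    rest_duration: float = 120.0
    sample_rate: float = 1000.0
    effect_densities: Mapping[str, Mapping[str, float]] | None = None
    seed: int = 0
    write_edf: bool = False
    # preprocessing
    band: tuple[float, float] = (0.5, 48.0)
    target_rate: float = 250.0
    min_segment_s: float = 30.0
    alpha_window: tuple[float, float] = (7.5, 12.5)
    # connectivity & graphs
    aggregate: str = "pool"
    threshold_scope: str = "subject-test"
    n_surrogates: int = 100
    # statistics
    alpha: float = 0.05
    exclude_scenarios: Sequence[str] = ("L3",)

    def __post_init__(self) -> None:
        self.tests = tuple(self.tests)
        self.scenarios = tuple(self.scenarios)
        self.band = tuple(self.band)
        self.alpha_window = tuple(self.alpha_window)
        self.exclude_scenarios = tuple(self.exclude_scenarios)
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.threshold_scope not in ("subject-test", "global"):
            raise ValueError(f"unknown threshold_scope {self.threshold_scope!r}")
        if self.aggregate not in ("pool", "mean"):
            raise ValueError(f"unknown aggregate {self.aggregate!r}")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["tests"] = list(self.tests)
        d["scenarios"] = list(self.scenarios)
        d["band"] = list(self.band)
        d["alpha_window"] = list(self.alpha_window)
        d["exclude_scenarios"] = list(self.exclude_scenarios)
        return d

    def effect_map(self) -> dict[tuple[str, str], CellEffect]:
        if self.effect_densities is None:
            return default_effect_map(self.tests, self.scenarios)
        return {
            (t, s): CellEffect(density=float(self.effect_densities[t][s]))
            for t in self.tests
            for s in self.scenarios
        }


def _setup_run_logger(run_dir: Path) -> logging.Handler:
    handler = logging.FileHandler(run_dir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("thetanet")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    return handler


def run_all(config: RunConfig) -> Path:
    """Execute every stage for one configuration; returns the run directory."""
    run_dir = Path(config.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    handler = _setup_run_logger(run_dir)
    try:
        return _run_all_inner(config, run_dir)
    finally:
        logging.getLogger("thetanet").removeHandler(handler)
        handler.close()


def _run_all_inner(config: RunConfig, run_dir: Path) -> Path:
    stage = "simulate"
    try:
        design = StudyDesign(
            n_subjects=config.n_subjects,
            tests=config.tests,
            scenarios=config.scenarios,
            trials_per_scenario=config.trials_per_scenario,
            effect_map=config.effect_map(),
            rest_duration=config.rest_duration,
        )
        base = OscillatorSpec(
            sample_rate=config.sample_rate,
            duration=config.epoch_duration,
            seed=config.seed,
        )
        study = generate_study(design, base)
        logger.info("simulate: %d task recordings, %d rest recordings",
                    len(study.tasks), len(study.rests))
        if config.write_edf:
            write_study_edf(study, run_dir / "edf")

        stage = "preprocess"
        iapf_rows = []
        theta_bands: dict[tuple[str, str], tuple[float, float]] = {}
        for si in range(config.n_subjects):
            subject = f"S{si + 1:02d}"
            for test in config.tests:
                profiles = []
                for phase in ("pre", "post"):
                    rest = bandpass_and_decimate(
                        study.rests[(subject, test, phase)],
                        band=config.band, target_rate=config.target_rate,
                    )
                    profiles.append(estimate_iapf_cog(rest, config.alpha_window))
                iapf = session_iapf(*profiles)
                lo, hi = (4.0, 0.8 * iapf)
                theta_bands[(subject, test)] = (lo, hi)
                iapf_rows.append({
                    "subject": subject, "test": test, "iapf": iapf,
                    "theta_low": lo, "theta_high": hi,
                    "alpha_true": study.subject_alpha[subject],
                })
        pd.DataFrame(iapf_rows).to_csv(run_dir / "iapf.csv", index=False)

        segments: dict[tuple[str, str, str], list] = {}
        kept = dropped = 0
        for (subject, test, scen, trial), rec in study.tasks.items():
            pre = bandpass_and_decimate(
                rec, band=config.band, target_rate=config.target_rate
            )
            segs = segment_by_events(pre, min_duration_s=config.min_segment_s)
            dropped += len(pre.events) - len(segs)
            kept += len(segs)
            segments.setdefault((subject, test, scen), []).extend(segs)
        logger.info("preprocess: %d segments kept, %d dropped", kept, dropped)

        stage = "connectivity"
        labels = study.tasks[next(iter(study.tasks))].channel_labels
        matrices = []
        for (subject, test, scen), segs in segments.items():
            if not segs:
                raise ValueError(f"no usable segments for {(subject, test, scen)}")
            band = theta_bands[(subject, test)]
            analytic = [analytic_signals(s, band) for s in segs]
            matrices.append(
                connectivity_matrix(
                    analytic, labels, band,
                    condition=(subject, test, scen),
                    aggregate=config.aggregate,
                )
            )
        with h5py.File(run_dir / "connectivity.h5", "w") as h5:
            for m in matrices:
                s, t, l = m.condition
                ds = h5.create_dataset(f"connectivity/{s}/{t}/{l}", data=m.values)
                ds.attrs["band"] = m.band
                ds.attrs["n_samples_used"] = m.n_samples_used
                ds.attrs["channel_labels"] = list(m.channel_labels)

        stage = "graph"
        thresholds = median_threshold(matrices, scope=config.threshold_scope)
        metric_rows = []
        for ci, m in enumerate(matrices):
            subject, test, scen = m.condition
            key = (subject, test) if config.threshold_scope == "subject-test" else ("all",)
            g = binarize(m, thresholds[key])
            gm = compute_metrics(
                g, n_surrogates=config.n_surrogates,
                seed=np.random.SeedSequence(entropy=config.seed, spawn_key=(5000, ci)),
            )
            base_row = {"subject": subject, "test": test, "scenario": scen}
            scalars = {
                "L": gm.L, "E_global": gm.E_global, "E_local_mean": gm.E_local_mean,
                "C": gm.C, "gamma": gm.gamma, "lambda": gm.lam, "sigma": gm.sigma,
                "density": g.density, "unreachable_pairs": gm.unreachable_pairs,
            }
            for name, value in scalars.items():
                if value is None:
                    continue
                metric_rows.append(
                    {**base_row, "metric": name, "channel": "global", "value": value}
                )
            for ch, value in zip(labels, gm.E_local_per_node):
                metric_rows.append(
                    {**base_row, "metric": "E_local", "channel": ch, "value": value}
                )
        metrics = pd.DataFrame(metric_rows)
        metrics.to_csv(run_dir / "metrics.csv", index=False, float_format="%.10g")

        stage = "stats"
        analyzed = metrics[~metrics["scenario"].isin(config.exclude_scenarios)]
        for metric in NETWORK_METRICS:
            sub = analyzed[
                (analyzed["metric"] == metric) & (analyzed["channel"] == "global")
            ]
            if sub.empty or sub["scenario"].nunique() < 2 or sub["test"].nunique() < 2:
                logger.info("stats: skipping %s (insufficient factor levels)", metric)
                continue
            table = results_to_frame(rm_anova_2way(sub))
            table.insert(0, "metric", metric)
            table.to_csv(run_dir / f"stats_{metric}.csv", index=False,
                         float_format="%.10g")

        manifest = {
            "package": "thetanet",
            "version": __version__,
            "config": config.to_dict(),
        }
        (run_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return run_dir
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc


def _montage_positions(labels: Sequence[str]) -> dict[str, tuple[float, float]]:
    """2-D scalp positions for the montage from mne's 10–20 template."""
    import mne

    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            montage = mne.channels.make_standard_montage("standard_1020")
        except Exception:  # template renamed in newer mne
            montage = mne.channels.make_standard_montage("colin27_1020")
    pos3d = montage.get_positions()["ch_pos"]
    return {lb: (float(pos3d[lb][0]), float(pos3d[lb][1])) for lb in labels}


def summarize(run_dir: str | Path) -> Path:
    """Write report.txt and a scalp map of mean local efficiency.

    Raises with the list of missing artifacts if the run is incomplete.
    """
    run_dir = Path(run_dir)
    required = ["manifest.json", "metrics.csv"]
    missing = [f for f in required if not (run_dir / f).exists()]
    if missing:
        raise FileNotFoundError(f"incomplete run; missing artifacts: {missing}")
    metrics = pd.read_csv(run_dir / "metrics.csv")

    lines = ["# Run summary", ""]
    glob = metrics[metrics["channel"] == "global"]
    table = (
        glob[glob["metric"].isin(NETWORK_METRICS)]
        .groupby(["test", "scenario", "metric"])["value"]
        .mean()
        .unstack("metric")
    )
    lines.append("Mean network metrics per condition (across subjects):")
    lines.append(table.to_string(float_format=lambda v: f"{v:.4f}"))
    lines.append("")

    for f in sorted(run_dir.glob("stats_*.csv")):
        lines.append(f"ANOVA ({f.stem.removeprefix('stats_')}):")
        lines.append(pd.read_csv(f).to_string(index=False))
        lines.append("")

    # scalp scatter of per-channel local efficiency
    eloc = metrics[metrics["metric"] == "E_local"]
    fig_path = None
    if not eloc.empty:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        per_ch = eloc.groupby("channel")["value"].mean()
        try:
            pos = _montage_positions(per_ch.index)
        except KeyError:
            pos = None
            logger.warning("summarize: montage positions unavailable for labels")
        if pos is not None:
            fig, ax = plt.subplots(figsize=(5, 5))
            xs = [pos[ch][0] for ch in per_ch.index]
            ys = [pos[ch][1] for ch in per_ch.index]
            sc = ax.scatter(xs, ys, c=per_ch.values, s=200, cmap="viridis")
            for ch, x, y in zip(per_ch.index, xs, ys):
                ax.annotate(ch, (x, y), fontsize=6, ha="center", va="center")
            ax.set_aspect("equal")
            ax.axis("off")
            ax.set_title("Mean local efficiency per channel")
            fig.colorbar(sc, ax=ax, shrink=0.7)
            fig_path = run_dir / "scalp_elocal.png"
            fig.savefig(fig_path, dpi=120)
            plt.close(fig)
            lines.append(f"Scalp map: {fig_path.name} ({len(per_ch)} channels)")

    report = run_dir / "report.txt"
    report.write_text("\n".join(lines))
    return report
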