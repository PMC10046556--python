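"""Synthetic EEG-like cohorts with known phase-coupling ground truth.

Real task EEG for this kind of workload study is rarely public, so every
downstream stage is validated against signals whose coupling structure
is known exactly.  Task epochs come from a stochastic phase-oscillator
(Kuramoto-style) model: channel i carries a narrowband oscillation whose
phase is pulled toward (neighbor phase + prescribed lag) with a strength
proportional to the coupling matrix, plus phase-diffusion noise.  The
prescribed pairwise lags are exactly the quantity the weighted Phase Lag
Index estimates, so the generator provides a recoverable target for the
whole pipeline.  Volume conduction — the classic sensor-space confound —
is modeled as instantaneous linear mixing of the channel signals, which
wPLI is built to reject; this yields the key negative-control tests.

Rest epochs are spectrally synthesized 1/f-background noise with a
Gaussian alpha bump at a controllable peak frequency, so the individual
alpha peak frequency estimator has a known target.

Whole studies follow the 4-test x 4-scenario x 4-trial protocol: an
``effect_map`` assigns each (test, scenario) cell a coupling density and
strength, and all randomness flows from a single top-level seed through
per-recording derived seeds, so any single trial can be regenerated in
isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .preprocess import MONTAGE_24, Event, Recording

TESTS = ("T1", "T2", "T3", "T4")
SCENARIOS = ("L0", "L1", "L2", "L3")


@dataclass
class OscillatorSpec:
    """Parameters of one coupled-phase-oscillator recording.

    Parameters
    ----------
    n_channels, sample_rate, duration
        Geometry of the output array (duration in seconds).
    carrier_band
        (low, high) in Hz; each channel's natural frequency is drawn
        uniformly from this band.  Defaults to the canonical theta range.
    coupling
        Symmetric matrix in [0, 1] with zero diagonal; 0 means
        independent channels.  ``None`` -> all zeros.
    phase_lags
        Antisymmetric matrix of target phase differences in radians:
        channel i is pulled toward ``phase(j) + phase_lags[i, j]``.
        ``None`` -> all zeros.
    alpha_peak
        Peak frequency (Hz) of the alpha bump for rest generation.
    noise_sd
        SD of additive white measurement noise, in signal units.
    phase_noise
        Phase diffusion coefficient in rad/sqrt(s).
    mixing
        Square zero-lag leakage matrix applied to the clean channel
        signals (volume-conduction model).  ``None`` -> identity.
    amplitude
        Oscillation amplitude in microvolt-like units.
    coupling_gain
        Rad/s of phase pull at coupling 1.  The default (together with
        the default phase noise) puts the network in a partial-synchrony
        regime — coupled pairs reach moderate phase consistency without
        the whole network collapsing into one phase-locked cluster, the
        regime in which sensor-level wPLI contrasts are observable.
        Raise it well above the worst-case natural-frequency detuning
        (2 * pi * carrier bandwidth) to force full pairwise locking.
    seed
        Seed for all randomness of this recording.
    """

    n_channels: int = 24
    sample_rate: float = 1000.0
    duration: float = 60.0
    carrier_band: tuple[float, float] = (4.0, 8.0)
    coupling: np.ndarray | None = None
    phase_lags: np.ndarray | None = None
    alpha_peak: float = 10.0
    noise_sd: float = 10.0
    phase_noise: float = 2.5
    mixing: np.ndarray | None = None
    amplitude: float = 50.0
    coupling_gain: float = 6.0
    alpha_bump_rel: float = 4.0
    one_over_f_slope: float = 1.0
    alpha_bump_width: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        n = self.n_channels
        if self.coupling is None:
            self.coupling = np.zeros((n, n))
        if self.phase_lags is None:
            self.phase_lags = np.zeros((n, n))
        if self.mixing is None:
            self.mixing = np.eye(n)
        self.coupling = np.asarray(self.coupling, dtype=float)
        self.phase_lags = np.asarray(self.phase_lags, dtype=float)
        self.mixing = np.asarray(self.mixing, dtype=float)
        for name, m in (("coupling", self.coupling),
                        ("phase_lags", self.phase_lags),
                        ("mixing", self.mixing)):
            if m.shape != (n, n):
                raise ValueError(f"{name} must be {n}x{n}, got {m.shape}")
        if not np.allclose(self.coupling, self.coupling.T):
            raise ValueError("coupling must be symmetric")
        if np.any(np.diag(self.coupling) != 0):
            raise ValueError("coupling diagonal must be zero")
        if self.coupling.min() < 0 or self.coupling.max() > 1:
            raise ValueError("coupling entries must lie in [0, 1]")
        if not np.allclose(self.phase_lags, -self.phase_lags.T):
            raise ValueError("phase_lags must be antisymmetric")
        lo, hi = self.carrier_band
        if not 0 < lo < hi:
            raise ValueError(f"invalid carrier_band {self.carrier_band}")
        if self.duration * self.sample_rate < 2 * self.sample_rate / lo:
            raise ValueError("duration must cover at least 2 carrier periods")


def generate_task_epoch(spec: OscillatorSpec) -> Recording:
    """One task epoch from the coupled phase-oscillator model.

    Euler–Maruyama integration of

        d theta_i = [ omega_i + g * sum_j K_ij sin(theta_j + lag_ij - theta_i) ] dt
                    + phase_noise * dW_i

    followed by ``x = mixing @ (amplitude * cos(theta)) + measurement noise``.
    With symmetric coupling the pair (i, j) locks at a stable phase
    difference ``theta_i - theta_j = lag_ij``.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_channels
    n_samples = int(round(spec.duration * spec.sample_rate))
    dt = 1.0 / spec.sample_rate

    omega = 2 * np.pi * rng.uniform(*spec.carrier_band, size=n)
    theta = np.empty((n, n_samples))
    theta[:, 0] = rng.uniform(0, 2 * np.pi, size=n)

    ii, jj = np.nonzero(spec.coupling)  # both directions present (symmetric)
    k_pair = spec.coupling_gain * spec.coupling[ii, jj]
    lag_pair = spec.phase_lags[ii, jj]
    dw = spec.phase_noise * np.sqrt(dt) * rng.standard_normal((n, n_samples - 1))

    cur = theta[:, 0].copy()
    for t in range(1, n_samples):
        if ii.size:
            pull = k_pair * np.sin(cur[jj] + lag_pair - cur[ii])
            drift = omega + np.bincount(ii, weights=pull, minlength=n)
        else:
            drift = omega
        cur = cur + drift * dt + dw[:, t - 1]
        theta[:, t] = cur

    x = spec.amplitude * np.cos(theta)
    x = spec.mixing @ x
    if spec.noise_sd > 0:
        x = x + spec.noise_sd * rng.standard_normal(x.shape)
    return Recording(
        data=x,
        sample_rate=spec.sample_rate,
        channel_labels=_labels(n),
        events=[Event("task", 0, n_samples)],
    )


def generate_rest(spec: OscillatorSpec) -> Recording:
    """Eyes-closed-like rest: 1/f spectral background plus an alpha bump.

    Channels are synthesized independently in the frequency domain with
    amplitude ``sqrt(P_bg + P_alpha)`` and random phases, where
    ``P_bg ~ 1/f^slope`` inside the acquisition band and ``P_alpha`` is a
    Gaussian bump of width ``alpha_bump_width`` centered at
    ``alpha_peak`` whose height is ``alpha_bump_rel`` times the local
    background.  Each channel is scaled to ``amplitude`` RMS, then
    measurement noise is added.
    """
    nyquist = spec.sample_rate / 2
    if not 0 < spec.alpha_peak < nyquist:
        raise ValueError(
            f"alpha_peak {spec.alpha_peak} Hz outside (0, {nyquist}) Hz"
        )
    rng = np.random.default_rng(spec.seed)
    n_samples = int(round(spec.duration * spec.sample_rate))
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / spec.sample_rate)

    p_bg = np.zeros_like(freqs)
    in_band = (freqs >= 0.5) & (freqs <= 48.0)
    p_bg[in_band] = freqs[in_band] ** (-spec.one_over_f_slope)
    bg_at_peak = spec.alpha_peak ** (-spec.one_over_f_slope)
    p_alpha = (
        spec.alpha_bump_rel
        * bg_at_peak
        * np.exp(-((freqs - spec.alpha_peak) ** 2) / (2 * spec.alpha_bump_width**2))
    )
    amp = np.sqrt(p_bg + p_alpha)

    shape = (spec.n_channels, freqs.size)
    spectrum = amp * (rng.standard_normal(shape) + 1j * rng.standard_normal(shape))
    x = np.fft.irfft(spectrum, n=n_samples, axis=1)
    rms = x.std(axis=1, keepdims=True)
    x = spec.amplitude * x / np.where(rms > 0, rms, 1.0)
    if spec.noise_sd > 0:
        x = x + spec.noise_sd * rng.standard_normal(x.shape)
    return Recording(
        data=x,
        sample_rate=spec.sample_rate,
        channel_labels=_labels(spec.n_channels),
        events=[Event("rest", 0, n_samples)],
    )


def _labels(n: int) -> list[str]:
    if n == len(MONTAGE_24):
        return list(MONTAGE_24)
    return [f"ch{i}" for i in range(n)]


@dataclass(frozen=True)
class CellEffect:
    """Coupling structure of one (test, scenario) cell of the design."""

    density: float  # fraction of channel pairs coupled, in [0, 1]
    strength: float = 0.8  # coupling value assigned to coupled pairs

    def __post_init__(self) -> None:
        if not 0 <= self.density <= 1:
            raise ValueError("density must be in [0, 1]")
        if not 0 <= self.strength <= 1:
            raise ValueError("strength must be in [0, 1]")


def default_effect_map(
    tests: Sequence[str] = TESTS, scenarios: Sequence[str] = SCENARIOS
) -> dict[tuple[str, str], CellEffect]:
    """Condition effects emulating the study's qualitative findings.

    Early training (T1): coupling density rises with task difficulty.
    Transitional session (T2): no consistent trend.  Post-schema sessions
    (T3, T4): density falls monotonically with difficulty, the pattern
    that should be recovered as decreasing network efficiency.
    """
    profiles = {
        "T1": {"L0": 0.30, "L1": 0.38, "L2": 0.46, "L3": 0.50},
        "T2": {"L0": 0.35, "L1": 0.35, "L2": 0.35, "L3": 0.35},
        "T3": {"L0": 0.50, "L1": 0.35, "L2": 0.25, "L3": 0.20},
        "T4": {"L0": 0.50, "L1": 0.35, "L2": 0.25, "L3": 0.20},
    }
    out: dict[tuple[str, str], CellEffect] = {}
    for t in tests:
        for s in scenarios:
            density = profiles.get(t, profiles["T2"]).get(s, 0.35)
            out[(t, s)] = CellEffect(density=density)
    return out


@dataclass
class StudyDesign:
    """A multi-subject, multi-session workload study layout.

    The default is the full protocol: 4 test sessions (T1–T4), 4 task
    scenarios per session in increasing difficulty (L0–L3), 4 trials per
    scenario — 16 task trials per session — plus eyes-closed rest before
    and after each session.
    """

    n_subjects: int = 10
    tests: Sequence[str] = TESTS
    scenarios: Sequence[str] = SCENARIOS
    trials_per_scenario: int = 4
    effect_map: Mapping[tuple[str, str], CellEffect] | None = None
    rest_duration: float = 120.0

    def __post_init__(self) -> None:
        self.tests = tuple(self.tests)
        self.scenarios = tuple(self.scenarios)
        if self.effect_map is None:
            self.effect_map = default_effect_map(self.tests, self.scenarios)
        missing = [
            (t, s)
            for t in self.tests
            for s in self.scenarios
            if (t, s) not in self.effect_map
        ]
        if missing:
            raise ValueError(f"effect_map missing cells: {missing}")


@dataclass
class StudyData:
    """All recordings of one synthetic study plus the tidy label table."""

    tasks: dict[tuple[str, str, str, int], Recording]
    rests: dict[tuple[str, str, str], Recording]  # (subject, test, pre|post)
    labels: pd.DataFrame  # columns: subject, test, scenario, trial
    subject_alpha: dict[str, float]
    coupling_truth: dict[tuple[str, str, str], np.ndarray]
    design: StudyDesign
    base_spec: OscillatorSpec


def _derived_seed(root: int, *path: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=root, spawn_key=tuple(path))


def _cell_coupling(
    n: int, effect: CellEffect, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Random coupling topology at the cell's density, with detectable lags."""
    iu = np.triu_indices(n, k=1)
    n_pairs = iu[0].size
    n_edges = int(round(effect.density * n_pairs))
    pick = rng.choice(n_pairs, size=n_edges, replace=False)
    coupling = np.zeros((n, n))
    coupling[iu[0][pick], iu[1][pick]] = effect.strength
    coupling = coupling + coupling.T
    # lags away from 0 and pi so the imaginary cross-spectrum is substantial
    mag = rng.uniform(np.pi / 4, 3 * np.pi / 4, size=n_pairs)
    sign = rng.choice((-1.0, 1.0), size=n_pairs)
    lags = np.zeros((n, n))
    lags[iu] = mag * sign
    lags = lags - lags.T
    return coupling, lags


def generate_study(
    design: StudyDesign, base_spec: OscillatorSpec | None = None
) -> StudyData:
    """Generate every recording of a study design.

    Each (subject, test, scenario) cell gets one coupling topology drawn
    at the density/strength prescribed by the design's ``effect_map``;
    the cell's trials share that ground truth but have independent noise.
    Per-subject alpha peaks are drawn around 10 Hz and used for the pre-
    and post-session rest recordings.  Every recording's seed is derived
    from ``base_spec.seed`` and its (subject, test, scenario, trial)
    indices, so any single recording is regenerable in isolation.
    """
    base = base_spec if base_spec is not None else OscillatorSpec()
    root = base.seed
    n = base.n_channels
    tasks: dict[tuple[str, str, str, int], Recording] = {}
    rests: dict[tuple[str, str, str], Recording] = {}
    truth: dict[tuple[str, str, str], np.ndarray] = {}
    alpha: dict[str, float] = {}
    rows = []
    for si in range(design.n_subjects):
        subject = f"S{si + 1:02d}"
        subj_rng = np.random.default_rng(_derived_seed(root, si, 900))
        alpha[subject] = float(np.clip(subj_rng.normal(10.0, 0.75), 8.0, 12.0))
        for ti, test in enumerate(design.tests):
            for phase_idx, phase in enumerate(("pre", "post")):
                rest_spec = replace(
                    base,
                    alpha_peak=alpha[subject],
                    duration=design.rest_duration,
                    seed=_derived_seed(root, si, ti, 800 + phase_idx),
                )
                rests[(subject, test, phase)] = generate_rest(rest_spec)
            for li, scen in enumerate(design.scenarios):
                cell_rng = np.random.default_rng(_derived_seed(root, si, ti, li, 700))
                coupling, lags = _cell_coupling(
                    n, design.effect_map[(test, scen)], cell_rng
                )
                truth[(subject, test, scen)] = coupling
                for tr in range(design.trials_per_scenario):
                    spec = replace(
                        base,
                        coupling=coupling,
                        phase_lags=lags,
                        seed=_derived_seed(root, si, ti, li, tr),
                    )
                    rec = generate_task_epoch(spec)
                    rec.events = [Event(scen, 0, rec.n_samples)]
                    tasks[(subject, test, scen, tr)] = rec
                    rows.append(
                        {"subject": subject, "test": test,
                         "scenario": scen, "trial": tr}
                    )
    labels = pd.DataFrame(rows, columns=["subject", "test", "scenario", "trial"])
    return StudyData(
        tasks=tasks,
        rests=rests,
        labels=labels,
        subject_alpha=alpha,
        coupling_truth=truth,
        design=design,
        base_spec=base,
    )


def write_study_edf(study: StudyData, out_dir) -> pd.DataFrame:
    """Write one EDF file per recording plus a labels.csv manifest.

    Returns the label table extended with a ``file`` column; rest
    recordings appear with scenario ``rest-pre`` / ``rest-post`` and
    trial -1.
    """
    from pathlib import Path

    from .edfio_min import write_edf

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for (subject, test, scen, tr), rec in study.tasks.items():
        fname = f"{subject}_{test}_{scen}_trial{tr}.edf"
        write_edf(out / fname, rec)
        rows.append({"subject": subject, "test": test, "scenario": scen,
                     "trial": tr, "file": fname})
    for (subject, test, phase), rec in study.rests.items():
        fname = f"{subject}_{test}_rest-{phase}.edf"
        write_edf(out / fname, rec)
        rows.append({"subject": subject, "test": test,
                     "scenario": f"rest-{phase}", "trial": -1, "file": fname})
    table = pd.DataFrame(rows)
    table.to_csv(out / "labels.csv", index=False)
    return table
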