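"""Weighted Phase Lag Index (wPLI) connectivity in the individual theta band.

The wPLI of two signals with analytic representations ``zx``, ``zy`` and
per-sample cross-spectrum ``S_t = zx_t * conj(zy_t)`` is

    wPLI = | sum_t |Im S_t| sgn(Im S_t) |  /  sum_t |Im S_t|

i.e. the magnitude of the imaginary cross-spectral mass, normalized by the
total imaginary mass.  Consistent phase leads (or lags) give 1; phase
differences that are symmetric around zero (or exactly zero, as produced
by instantaneous volume conduction) give 0.  When the denominator is zero
— no imaginary cross-spectral mass at all — the value is defined as 0,
since purely zero-lag coupling is exactly what the index discounts.

Cross-spectra are realized per sample via the Hilbert analytic signal of
the band-limited data, matching the sum over samples in the definition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .preprocess import Recording

#: seconds trimmed from each end after filtering + Hilbert, to keep
#: filter and Hilbert edge transients out of the phase statistics.
EDGE_TRIM_S = 1.0

#: relative floor under which the imaginary cross-spectral mass counts
#: as zero (the zero-lag convention), measured against the total
#: cross-spectral magnitude
_REL_ZERO = 1e-12


@dataclass
class ConnectivityMatrix:
    """Symmetric wPLI matrix for one (subject, test, scenario) condition."""

    values: np.ndarray
    channel_labels: Sequence[str]
    band: tuple[float, float]
    n_samples_used: int
    condition: tuple[str, str, str] | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("values must be a square matrix")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("wPLI matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("diagonal must be zero")
        if v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise ValueError("wPLI values must lie in [0, 1]")
        self.values = np.clip(v, 0.0, 1.0)
        self.channel_labels = list(self.channel_labels)
        if len(self.channel_labels) != v.shape[0]:
            raise ValueError("one label per channel required")

    def upper_triangle(self) -> np.ndarray:
        """Off-diagonal upper-triangle values as a flat vector."""
        iu = np.triu_indices(self.values.shape[0], k=1)
        return self.values[iu]


def analytic_signals(
    segment: Recording,
    band: tuple[float, float],
    order: int = 4,
    edge_trim_s: float = EDGE_TRIM_S,
) -> np.ndarray:
    """Band-limit a segment and return its analytic signal, edges trimmed.

    Zero-phase Butterworth bandpass to ``band``, Hilbert transform per
    channel, then ``edge_trim_s`` seconds dropped from each end.  Raises
    if fewer than 2 s survive the trim.
    """
    fs = segment.sample_rate
    trim = int(round(edge_trim_s * fs))
    remaining = segment.n_samples - 2 * trim
    if remaining < 2 * fs:
        raise ValueError(
            f"segment of {segment.duration:.1f} s leaves {remaining / fs:.1f} s "
            "after edge trimming; need >= 2 s"
        )
    sos = sps.butter(order, band, btype="bandpass", fs=fs, output="sos")
    filtered = sps.sosfiltfilt(sos, segment.data, axis=1)
    z = sps.hilbert(filtered, axis=1)
    return z[:, trim : segment.n_samples - trim] if trim else z


def wpli(zx: np.ndarray, zy: np.ndarray) -> float:
    """wPLI between two analytic signals (equal length, >= 2 samples)."""
    zx = np.asarray(zx)
    zy = np.asarray(zy)
    if zx.shape != zy.shape:
        raise ValueError("series must have equal length")
    if zx.size < 2:
        raise ValueError("need at least 2 samples")
    s = zx * np.conj(zy)
    im = s.imag
    denom = np.abs(im).sum()
    # zero-lag convention with a relative floor: float rounding leaves
    # ~1e-16 imaginary residue on exactly-real cross-spectra
    if denom <= _REL_ZERO * np.abs(s).sum():
        return 0.0
    return float(abs(im.sum()) / denom)


def _pair_sums(z: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    # per-pair sums of Im S, |Im S| and |S| over samples, all pairs at once
    s = z[:, None, :] * np.conj(z[None, :, :])
    im = s.imag
    return im.sum(axis=2), np.abs(im).sum(axis=2), np.abs(s).sum(axis=2)


def connectivity_matrix(
    segments: Sequence[np.ndarray],
    channel_labels: Sequence[str],
    band: tuple[float, float],
    condition: tuple[str, str, str] | None = None,
    aggregate: str = "pool",
) -> ConnectivityMatrix:
    """wPLI matrix for one condition from one or more analytic segments.

    With ``aggregate='pool'`` (default) the per-sample numerator and
    denominator terms are pooled across all segments before the ratio is
    taken — equivalent to concatenating the segments and robust to
    unequal lengths.  ``aggregate='mean'`` instead averages per-segment
    wPLI matrices (each segment weighted equally).
    """
    if len(segments) == 0:
        cond = condition if condition is not None else "<unlabelled>"
        raise ValueError(f"no segments for condition {cond}")
    if aggregate not in ("pool", "mean"):
        raise ValueError(f"unknown aggregate mode {aggregate!r}")
    n_ch = len(channel_labels)
    n_used = 0
    if aggregate == "pool":
        num = np.zeros((n_ch, n_ch))
        den = np.zeros((n_ch, n_ch))
        mass = np.zeros((n_ch, n_ch))
        for z in segments:
            if z.shape[0] != n_ch:
                raise ValueError("segment channel count does not match labels")
            s_num, s_den, s_mass = _pair_sums(z)
            num += s_num
            den += s_den
            mass += s_mass
            n_used += z.shape[1]
        ok = den > _REL_ZERO * mass
        values = np.where(ok, np.abs(num) / np.where(ok, den, 1.0), 0.0)
    else:
        acc = np.zeros((n_ch, n_ch))
        for z in segments:
            s_num, s_den, s_mass = _pair_sums(z)
            ok = s_den > _REL_ZERO * s_mass
            acc += np.where(ok, np.abs(s_num) / np.where(ok, s_den, 1.0), 0.0)
            n_used += z.shape[1]
        values = acc / len(segments)
    np.fill_diagonal(values, 0.0)
    values = 0.5 * (values + values.T)  # exact symmetry against float noise
    return ConnectivityMatrix(
        values=values,
        channel_labels=channel_labels,
        band=band,
        n_samples_used=n_used,
        condition=condition,
    )
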