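"""Deterministic quantification of single-channel anesthesia EEG.

Implements the standard depth-of-anesthesia descriptors used throughout the
package: zero-phase Butterworth band-pass filtering, burst suppression ratio
(BSR), spectral edge frequency (SEF95) from a short-time Fourier transform,
Welch power spectral density with absolute/relative band powers, and the
normalized 10-bin emergence-trajectory decomposition.

All operations are pure functions of the input signal: identical input gives
bit-identical output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

logger = logging.getLogger(__name__)

#: Canonical band partition (Hz), tiling the 1-48 Hz filtered support.
DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (12.0, 30.0),
    "gamma": (30.0, 48.0),
}

PHASES = ("baseline", "maintenance", "emergence")


class InputError(ValueError):
    """Raised when an operation's preconditions on its input are violated."""


class ConfigurationError(ValueError):
    """Raised when a configuration value is invalid."""


@dataclass
class EEGRecording:
    """A single-channel EEG trace in microvolts with phase annotations.

    Parameters
    ----------
    samples : array of amplitudes in uV.
    sample_rate : sampling frequency in Hz (1000 Hz in the reference setup).
    phase_intervals : mapping of phase name to a half-open ``(start, end)``
        interval in seconds, time origin at the start of the recording.
    animal_id : identifier of the recorded animal.
    """

    samples: np.ndarray
    sample_rate: float = 1000.0
    phase_intervals: dict[str, tuple[float, float]] = field(default_factory=dict)
    animal_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise InputError("EEG samples must be one-dimensional")
        if self.sample_rate <= 0:
            raise InputError("sample_rate must be positive")
        dur = self.duration
        for name, (a, b) in self.phase_intervals.items():
            if not (0 <= a < b <= dur + 1e-9):
                raise InputError(
                    f"phase interval {name!r}=({a}, {b}) outside [0, {dur:.3f})"
                )

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return len(self.samples) / self.sample_rate

    def slice_phase(self, phase: str) -> "EEGRecording":
        """Return the sub-recording covered by a named phase interval."""
        if phase not in self.phase_intervals:
            raise InputError(f"phase {phase!r} not annotated for {self.animal_id!r}")
        a, b = self.phase_intervals[phase]
        i0 = int(round(a * self.sample_rate))
        i1 = int(round(b * self.sample_rate))
        return EEGRecording(
            samples=self.samples[i0:i1],
            sample_rate=self.sample_rate,
            phase_intervals={},
            animal_id=self.animal_id,
        )


@dataclass
class SpectralProfile:
    """Welch spectrum with band summaries for one signal segment."""

    freqs: np.ndarray
    psd: np.ndarray
    band_powers: dict[str, float] = field(default_factory=dict)
    band_ratios: dict[str, float] = field(default_factory=dict)
    sef95: np.ndarray | None = None
    bsr: float | None = None


@dataclass
class EmergenceTrajectory:
    """Ten-bin decomposition of the emergence interval (10% ... 100% arousal)."""

    arousal_grid: np.ndarray
    segments: list[EEGRecording]
    per_bin_spectra: list[SpectralProfile]
    bin_duration: float
    segment_duration: float


# ---------------------------------------------------------------------------
# filtering


def bandpass(
    rec: EEGRecording, low: float = 1.0, high: float = 48.0, order: int = 4,
    mode: str = "zero-phase",
) -> EEGRecording:
    """Band-pass filter a recording with an ``order``-th Butterworth design.

    ``mode='zero-phase'`` applies the filter forward and backward
    (``sosfiltfilt``), doubling the effective order but leaving phase intact;
    ``mode='single-pass'`` applies it once causally.
    """
    nyq = rec.sample_rate / 2.0
    if not (0 < low < high < nyq):
        raise InputError(f"band ({low}, {high}) must satisfy 0 < low < high < {nyq}")
    sos = sps.butter(order, [low, high], btype="bandpass", fs=rec.sample_rate,
                     output="sos")
    if mode == "zero-phase":
        # sosfiltfilt needs > 3 * padlen samples
        padlen = 3 * (2 * sos.shape[0] + 1)
        if len(rec.samples) <= 3 * padlen:
            raise InputError(
                f"signal of {len(rec.samples)} samples too short for zero-phase "
                f"filtering (needs > {3 * padlen})"
            )
        y = sps.sosfiltfilt(sos, rec.samples)
    elif mode == "single-pass":
        y = sps.sosfilt(sos, rec.samples)
    else:
        raise ConfigurationError(f"unknown filter mode {mode!r}")
    return replace(rec, samples=y)


# ---------------------------------------------------------------------------
# burst suppression


def suppression_mask(
    samples: np.ndarray, sample_rate: float, threshold: float = 5.0,
    min_dur: float = 0.5,
) -> np.ndarray:
    """Boolean mask of samples belonging to valid suppression runs.

    A suppression run is a maximal stretch of consecutive samples with
    ``|x| <= threshold`` lasting at least ``min_dur`` seconds. Runs touching
    the signal boundary are truncated there (never extended).
    """
    flat = np.abs(samples) <= threshold
    if not flat.any():
        return np.zeros_like(flat)
    min_len = int(np.ceil(min_dur * sample_rate))
    padded = np.concatenate(([False], flat, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = edges[0::2], edges[1::2]
    keep = (ends - starts) >= min_len
    mask = np.zeros_like(flat)
    for s, e in zip(starts[keep], ends[keep]):
        mask[s:e] = True
    return mask


def burst_suppression_ratio(
    rec: EEGRecording, threshold: float = 5.0, min_dur: float = 0.5,
) -> float:
    """Percent of recording time spent in suppression (|x| <= ±5 uV, >= 0.5 s).

    Returns ``100 * suppressed_samples / total_samples``.
    """
    if threshold <= 0 or min_dur <= 0:
        raise InputError("threshold and min_dur must be positive")
    x = rec.samples
    if len(x) == 0:
        raise InputError("empty signal")
    mask = suppression_mask(x, rec.sample_rate, threshold, min_dur)
    return 100.0 * float(mask.sum()) / len(x)


# ---------------------------------------------------------------------------
# spectral edge frequency


def spectral_edge_frequency(
    rec: EEGRecording, quantile: float = 0.95,
    window_s: float = 1.0, overlap: float = 0.75,
) -> np.ndarray:
    """Per-slice spectral edge frequency from a short-time Fourier transform.

    Spectrograms use a ``window_s`` Hamming window with fractional ``overlap``;
    for each time slice the cumulative spectral power is integrated from low to
    high frequency and the first frequency at which it reaches ``quantile`` of
    the slice total is the edge. All-zero slices yield NaN (edge undefined).
    """
    if not (0 < quantile <= 1):
        raise InputError("quantile must be in (0, 1]")
    nperseg = int(round(window_s * rec.sample_rate))
    if len(rec.samples) < nperseg:
        raise InputError("signal shorter than one STFT window")
    noverlap = int(round(overlap * nperseg))
    freqs, _, sxx = sps.spectrogram(
        rec.samples, fs=rec.sample_rate, window="hamming",
        nperseg=nperseg, noverlap=noverlap, detrend=False, mode="psd",
    )
    cum = np.cumsum(sxx, axis=0)
    totals = cum[-1]  # total from the cumulative sum itself so that the
    # threshold is always reached at the top bin, even at quantile = 1
    edges = np.full(sxx.shape[1], np.nan)
    ok = totals > 0
    if ok.any():
        idx = np.argmax(cum[:, ok] >= quantile * totals[ok], axis=0)
        edges[ok] = freqs[idx]
    return edges


# ---------------------------------------------------------------------------
# Welch PSD and band powers


def welch_psd(
    rec: EEGRecording, window_s: float = 2.0, overlap: float = 0.5,
) -> SpectralProfile:
    """Welch power spectral density (2 s Hann window, 50% overlap, uV^2/Hz).

    With the 2 s default window the frequency grid has 0.5 Hz resolution, and
    integrating the density over frequency approximates the signal variance.
    """
    nperseg = int(round(window_s * rec.sample_rate))
    if len(rec.samples) < nperseg:
        raise InputError(
            f"signal of {len(rec.samples)} samples shorter than one "
            f"{window_s} s window"
        )
    freqs, psd = sps.welch(
        rec.samples, fs=rec.sample_rate, window="hann",
        nperseg=nperseg, noverlap=int(round(overlap * nperseg)),
        detrend="constant", scaling="density",
    )
    return SpectralProfile(freqs=freqs, psd=psd)


def band_powers(
    profile: SpectralProfile, bands: dict[str, tuple[float, float]] | None = None,
) -> SpectralProfile:
    """Populate absolute band powers and relative band ratios on a profile.

    Bands must be non-overlapping and tile their support without gaps; power
    is accumulated on half-open frequency intervals [low, high) so the band
    powers are exactly additive and the ratios sum to 1.
    """
    bands = dict(DEFAULT_BANDS) if bands is None else dict(bands)
    ordered = sorted(bands.items(), key=lambda kv: kv[1][0])
    for (_, (a1, b1)), (_, (a2, _)) in zip(ordered, ordered[1:]):
        if b1 != a2:
            raise ConfigurationError(
                f"bands must tile the support contiguously; gap or overlap at "
                f"{b1} vs {a2} Hz"
            )
    lo, hi = ordered[0][1][0], ordered[-1][1][1]
    if hi > profile.freqs[-1] + 1e-9:
        raise ConfigurationError(
            f"band edge {hi} Hz beyond analyzed support {profile.freqs[-1]} Hz"
        )
    df = profile.freqs[1] - profile.freqs[0]
    powers: dict[str, float] = {}
    for name, (a, b) in ordered:
        sel = (profile.freqs >= a) & (profile.freqs < b)
        powers[name] = float(profile.psd[sel].sum() * df)
    total = sum(powers.values())
    ratios = {k: (v / total if total > 0 else np.nan) for k, v in powers.items()}
    profile.band_powers = powers
    profile.band_ratios = ratios
    return profile


# ---------------------------------------------------------------------------
# emergence binning


def emergence_bins(
    rec: EEGRecording, n_bins: int = 10, segment_s: float = 15.0,
    placement: str = "center",
) -> EmergenceTrajectory:
    """Split the emergence interval into ``n_bins`` equal bins of arousal.

    The interval from anesthetic cessation to recovery of the righting reflex
    is normalized to a 0-100% arousal axis and divided into ``n_bins`` equal
    bins (10%, 20%, ..., 100%). One fixed ``segment_s`` segment is extracted
    per bin — centered within the bin by default (``placement`` may also be
    ``'first'`` or ``'last'``) — and a Welch spectrum with band summaries is
    computed for each segment.
    """
    if "emergence" not in rec.phase_intervals:
        raise InputError(f"no emergence interval annotated for {rec.animal_id!r}")
    a, b = rec.phase_intervals["emergence"]
    needed = n_bins * segment_s
    if (b - a) + 1e-9 < needed:
        raise InputError(
            f"emergence interval of {b - a:.1f} s is {needed - (b - a):.1f} s "
            f"short of the {needed:.0f} s required for {n_bins} x {segment_s} s bins"
        )
    bin_dur = (b - a) / n_bins
    fs = rec.sample_rate
    seg_len = int(round(segment_s * fs))
    segments: list[EEGRecording] = []
    spectra: list[SpectralProfile] = []
    for i in range(n_bins):
        t0 = a + i * bin_dur
        if placement == "center":
            s0 = t0 + (bin_dur - segment_s) / 2.0
        elif placement == "first":
            s0 = t0
        elif placement == "last":
            s0 = t0 + bin_dur - segment_s
        else:
            raise ConfigurationError(f"unknown segment placement {placement!r}")
        i0 = int(round(s0 * fs))
        seg = EEGRecording(
            samples=rec.samples[i0:i0 + seg_len], sample_rate=fs,
            animal_id=rec.animal_id,
        )
        segments.append(seg)
        spectra.append(band_powers(welch_psd(seg)))
    return EmergenceTrajectory(
        arousal_grid=np.linspace(100.0 / n_bins, 100.0, n_bins),
        segments=segments,
        per_bin_spectra=spectra,
        bin_duration=bin_dur,
        segment_duration=segment_s,
    )


def trajectory_heatmap(
    traj: EmergenceTrajectory, reference_power: float = 1.0,
    vmin: float = -20.0, vmax: float = 20.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-bin spectra in dB relative to ``reference_power``, clipped to a
    fixed global scale (default -20 ... +20 dB, no per-animal normalization).

    Returns ``(freqs, arousal_grid, matrix)`` with matrix shape
    (n_freqs, n_bins).
    """
    freqs = traj.per_bin_spectra[0].freqs
    mat = np.stack([p.psd for p in traj.per_bin_spectra], axis=1)
    with np.errstate(divide="ignore"):
        db = 10.0 * np.log10(mat / reference_power)
    return freqs, traj.arousal_grid, np.clip(db, vmin, vmax)
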