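"""The 33-feature emergence-EEG descriptor.

Emergence-phase EEG is cut into non-overlapping 2 s epochs; 33 handcrafted
time- and frequency-domain features are computed per epoch and averaged
across epochs into one ordered feature vector per animal. The catalog covers
statistical descriptors, difference/complexity measures, Hjorth parameters,
entropy measures and band-limited power, including the six headline features
(arithmetic mean, log energy entropy, log root sum of sequential variation,
Hjorth complexity, alpha- and beta-band power).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as spstats

from .eegsignal import (
    DEFAULT_BANDS,
    EEGRecording,
    InputError,
    SpectralProfile,
    band_powers,
    welch_psd,
)

logger = logging.getLogger(__name__)

EPOCH_SECONDS = 2.0
LOG_GUARD = 1e-12  # floor inside log transforms for zero samples

#: Frozen canonical order of the 33-feature catalog.
FEATURE_NAMES: tuple[str, ...] = (
    "arithmetic_mean",
    "median",
    "standard_deviation",
    "variance",
    "skewness",
    "kurtosis",
    "minimum",
    "maximum",
    "range",
    "root_mean_square",
    "mean_energy",
    "mean_curve_length",
    "mean_teager_energy",
    "zero_crossing_rate",
    "first_difference_mean",
    "normalized_first_difference",
    "second_difference_mean",
    "normalized_second_difference",
    "hjorth_activity",
    "hjorth_mobility",
    "hjorth_complexity",
    "log_energy_entropy",
    "shannon_entropy",
    "spectral_entropy",
    "log_rssv",
    "delta_power",
    "theta_power",
    "alpha_power",
    "beta_power",
    "gamma_power",
    "relative_alpha_power",
    "relative_beta_power",
    "relative_delta_power",
)

HEADLINE_FEATURES: tuple[str, ...] = (
    "arithmetic_mean",
    "log_energy_entropy",
    "log_rssv",
    "hjorth_complexity",
    "alpha_power",
    "beta_power",
)


@dataclass
class EpochMatrix:
    """Non-overlapping 2 s epochs of one phase of one animal's recording."""

    epochs: np.ndarray  # (n_epochs, epoch_len)
    sample_rate: float
    animal_id: str = ""
    source_phase: str = ""

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]


@dataclass
class FeatureVector:
    """Ordered 33-feature descriptor averaged over an animal's epochs."""

    names: tuple[str, ...]
    values: np.ndarray
    animal_id: str = ""
    n_epochs_averaged: int = 0

    def to_dict(self) -> dict[str, float]:
        return {n: float(v) for n, v in zip(self.names, self.values)}


# ---------------------------------------------------------------------------
# segmentation


def segment_epochs(
    rec: EEGRecording, phase: str | None = None,
    epoch_s: float = EPOCH_SECONDS,
) -> EpochMatrix:
    """Cut a phase of a recording into consecutive non-overlapping epochs.

    A trailing remainder shorter than one epoch is discarded (logged).
    """
    sub = rec.slice_phase(phase) if phase else rec
    epoch_len = int(round(epoch_s * rec.sample_rate))
    n = len(sub.samples) // epoch_len
    if n == 0:
        raise InputError(
            f"interval of {len(sub.samples) / rec.sample_rate:.2f} s shorter "
            f"than one {epoch_s} s epoch"
        )
    rem = len(sub.samples) - n * epoch_len
    if rem:
        logger.debug("discarding %.3f s trailing remainder (%s)",
                     rem / rec.sample_rate, rec.animal_id)
    mat = sub.samples[: n * epoch_len].reshape(n, epoch_len)
    return EpochMatrix(epochs=mat, sample_rate=rec.sample_rate,
                       animal_id=rec.animal_id, source_phase=phase or "")


# ---------------------------------------------------------------------------
# individual features


def hjorth_parameters(epoch: np.ndarray) -> tuple[float, float, float]:
    """Hjorth activity, mobility and complexity of one epoch.

    activity = var(x); mobility = sqrt(var(dx)/var(x));
    complexity = mobility(dx)/mobility(x), with d the first difference.
    A zero-variance epoch has activity 0 and undefined (NaN) mobility and
    complexity — never 0 or infinity.
    """
    x = np.asarray(epoch, dtype=float)
    if x.size < 3:
        raise InputError("Hjorth parameters need at least 3 samples")
    v0 = float(np.var(x))
    if v0 == 0.0:
        return 0.0, float("nan"), float("nan")
    d1 = np.diff(x)
    d2 = np.diff(d1)
    v1, v2 = float(np.var(d1)), float(np.var(d2))
    mobility = np.sqrt(v1 / v0)
    if v1 == 0.0:
        return v0, mobility, float("nan")
    complexity = np.sqrt(v2 / v1) / mobility
    return v0, float(mobility), float(complexity)


def log_energy_entropy(epoch: np.ndarray) -> float:
    """Sum over samples of log(x_i^2 + eps), eps = 1e-12.

    Additive over concatenation; zero for a unit-amplitude epoch.
    """
    x = np.asarray(epoch, dtype=float)
    if x.size == 0:
        raise InputError("empty epoch")
    return float(np.sum(np.log(x * x + LOG_GUARD)))


def log_rssv(epoch: np.ndarray) -> float:
    """log(sqrt(sum of squared successive differences) + eps), eps = 1e-12."""
    x = np.asarray(epoch, dtype=float)
    if x.size < 2:
        raise InputError("log RSSV needs at least 2 samples")
    return float(np.log(np.sqrt(np.sum(np.diff(x) ** 2)) + LOG_GUARD))


def shannon_entropy(epoch: np.ndarray, n_bins: int = 16) -> float:
    """Shannon entropy (nats) of a 16-bin amplitude histogram of the epoch."""
    counts, _ = np.histogram(epoch, bins=n_bins)
    p = counts / counts.sum()
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def spectral_entropy(profile: SpectralProfile) -> float:
    """Shannon entropy (nats) of the Welch PSD normalized to a distribution."""
    p = profile.psd[profile.psd > 0]
    total = p.sum()
    if total == 0:
        return float("nan")
    q = p / total
    return float(-(q * np.log(q)).sum())


def zero_crossing_rate(epoch: np.ndarray) -> float:
    """Fraction of successive sample pairs with a strict sign change."""
    s = np.sign(epoch)
    # treat exact zeros as belonging to the previous sign
    for i in range(1, s.size):
        if s[i] == 0:
            s[i] = s[i - 1]
    return float(np.mean(s[1:] * s[:-1] < 0))


def _epoch_features(
    epoch: np.ndarray, sample_rate: float,
    bands: dict[str, tuple[float, float]],
) -> dict[str, float]:
    x = np.asarray(epoch, dtype=float)
    d1 = np.diff(x)
    d2 = np.diff(x, n=2)
    sd = float(np.std(x))
    act, mob, comp = hjorth_parameters(x)
    prof = band_powers(
        welch_psd(EEGRecording(x, sample_rate)), bands=bands
    )
    fd_mean = float(np.mean(np.abs(d1)))
    sd_mean = float(np.mean(np.abs(d2)))
    feats = {
        "arithmetic_mean": float(np.mean(x)),
        "median": float(np.median(x)),
        "standard_deviation": sd,
        "variance": float(np.var(x)),
        "skewness": float(spstats.skew(x)) if sd > 0 else float("nan"),
        "kurtosis": float(spstats.kurtosis(x)) if sd > 0 else float("nan"),
        "minimum": float(np.min(x)),
        "maximum": float(np.max(x)),
        "range": float(np.ptp(x)),
        "root_mean_square": float(np.sqrt(np.mean(x * x))),
        "mean_energy": float(np.mean(x * x)),
        "mean_curve_length": float(np.sum(np.abs(d1))),
        "mean_teager_energy": float(np.mean(x[1:-1] ** 2 - x[:-2] * x[2:])),
        "zero_crossing_rate": zero_crossing_rate(x),
        "first_difference_mean": fd_mean,
        "normalized_first_difference": fd_mean / sd if sd > 0 else float("nan"),
        "second_difference_mean": sd_mean,
        "normalized_second_difference": sd_mean / sd if sd > 0 else float("nan"),
        "hjorth_activity": act,
        "hjorth_mobility": mob,
        "hjorth_complexity": comp,
        "log_energy_entropy": log_energy_entropy(x),
        "shannon_entropy": shannon_entropy(x),
        "spectral_entropy": spectral_entropy(prof),
        "log_rssv": log_rssv(x),
        "delta_power": prof.band_powers["delta"],
        "theta_power": prof.band_powers["theta"],
        "alpha_power": prof.band_powers["alpha"],
        "beta_power": prof.band_powers["beta"],
        "gamma_power": prof.band_powers["gamma"],
        "relative_alpha_power": prof.band_ratios["alpha"],
        "relative_beta_power": prof.band_ratios["beta"],
        "relative_delta_power": prof.band_ratios["delta"],
    }
    return feats


def feature_vector(
    epochs: EpochMatrix, bands: dict[str, tuple[float, float]] | None = None,
) -> FeatureVector:
    """Compute the 33-feature catalog per epoch and average across epochs.

    Missing per-epoch values (e.g. undefined Hjorth complexity on a flat
    epoch) are excluded from that feature's average, with the exclusion count
    logged.
    """
    if epochs.n_epochs < 1:
        raise InputError("need at least one epoch")
    bands = dict(DEFAULT_BANDS) if bands is None else bands
    table = np.full((epochs.n_epochs, len(FEATURE_NAMES)), np.nan)
    for i in range(epochs.n_epochs):
        f = _epoch_features(epochs.epochs[i], epochs.sample_rate, bands)
        table[i] = [f[name] for name in FEATURE_NAMES]
    n_missing = int(np.isnan(table).sum())
    if n_missing:
        logger.info("excluding %d missing per-epoch values from averages",
                    n_missing)
    with np.errstate(invalid="ignore"):
        values = np.nanmean(table, axis=0)
    return FeatureVector(names=FEATURE_NAMES, values=values,
                         animal_id=epochs.animal_id,
                         n_epochs_averaged=epochs.n_epochs)


def trajectory_features(
    traj, feature_names: tuple[str, ...] | list[str] = HEADLINE_FEATURES,
):
    """Per-bin feature table over an emergence trajectory.

    Each of the ten 15 s bin segments is cut into 2 s epochs internally and
    the selected features averaged per bin, yielding a 10 x |subset| table.
    Returns a pandas DataFrame indexed by arousal percentage.
    """
    import pandas as pd

    unknown = set(feature_names) - set(FEATURE_NAMES)
    if unknown:
        raise InputError(f"unknown feature name(s): {sorted(unknown)}")
    rows = []
    for seg in traj.segments:
        em = segment_epochs(seg)
        fv = feature_vector(em)
        d = fv.to_dict()
        rows.append({name: d[name] for name in feature_names})
    return pd.DataFrame(rows, index=np.asarray(traj.arousal_grid),
                        columns=list(feature_names))


def cohort_feature_table(recordings: dict[str, EEGRecording], phase: str = "emergence"):
    """Per-animal 33-feature table (animals x features) for one phase."""
    import pandas as pd

    rows, ids = [], []
    for animal_id, rec in recordings.items():
        fv = feature_vector(segment_epochs(rec, phase))
        rows.append(fv.values)
        ids.append(animal_id)
    return pd.DataFrame(rows, index=ids, columns=list(FEATURE_NAMES))
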