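"""Reproducible synthetic surgical cohorts: behavior tables + EEG + truth.

The generator emulates the statistical structure the analysis assumes: a
four-group design (young-sham, aged-sham, young-surgery, aged-surgery) with
16 correlated standardized behavioral fractions, a two-component
preserved/vulnerable mixture inside the aged-surgery group (about 1:2), and
EEG whose maintenance phase is delta-dominant with burst-suppression
episodes and whose emergence phase ramps from a maintenance-like to an
awake-like spectrum — more slowly in the alpha/beta bands, and with more
retained delta, for the vulnerable phenotype.

Everything is deterministic for a fixed (config, seed) pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .behavior import FRACTION_NAMES, GROUPS, BehavioralMatrix
from .eegsignal import DEFAULT_BANDS, PHASES, EEGRecording

PHENOTYPES = ("preserved", "vulnerable")

#: Relative band-power weights (delta, theta, alpha, beta, gamma) per state.
AWAKE_WEIGHTS = {"delta": 0.15, "theta": 0.20, "alpha": 0.25,
                 "beta": 0.25, "gamma": 0.15}
MAINTENANCE_WEIGHTS = {"delta": 0.70, "theta": 0.15, "alpha": 0.07,
                       "beta": 0.05, "gamma": 0.03}
#: Emergence endpoint for the vulnerable phenotype: persistent delta, blunted
#: alpha/beta recovery.
VULNERABLE_AWAKE_WEIGHTS = {"delta": 0.28, "theta": 0.21, "alpha": 0.18,
                            "beta": 0.18, "gamma": 0.15}

#: Fractions carrying the vulnerability effect (standardized mean shifts):
#: longer latencies, fewer entries, less freezing, more hyperactivity.
DEFAULT_BEHAVIOR_EFFECT: dict[str, float] = {
    "escape_latency_d1": 1.75,
    "escape_latency_d2": 1.75,
    "escape_latency_d3": 1.75,
    "escape_latency_d4": 1.75,
    "delta_latency_d1_d2": 1.75,
    "first_entry_session": 1.75,
    "total_successful_entries": -1.75,
    "freezing_time": -1.75,
}


class ConfigError(ValueError):
    """Raised when a synthetic-cohort configuration field is invalid."""


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic cohort.

    Defaults mirror the reference design: group sizes 8/8/8/30 with
    two-thirds of the aged-surgery animals vulnerable (a 20:10 split),
    maintenance-phase suppression occupying 30% of the time, and emergence
    lasting 180 s (preserved) vs 300 s (vulnerable, prolonged emergence).
    """

    n_per_group: dict[str, int] = field(default_factory=lambda: {
        "young-sham": 8, "aged-sham": 8, "young-surgery": 8,
        "aged-surgery": 30})
    vulnerable_fraction: float = 2.0 / 3.0
    behavior_effect: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BEHAVIOR_EFFECT))
    behavior_noise_sd: float = 1.0
    band_weights: dict[str, dict[str, float]] = field(default_factory=lambda: {
        "baseline": dict(AWAKE_WEIGHTS),
        "maintenance": dict(MAINTENANCE_WEIGHTS),
        "emergence_end_preserved": dict(AWAKE_WEIGHTS),
        "emergence_end_vulnerable": dict(VULNERABLE_AWAKE_WEIGHTS),
    })
    suppression_fraction: float = 0.3
    emergence_duration_s: dict[str, float] = field(default_factory=lambda: {
        "preserved": 180.0, "vulnerable": 300.0})
    baseline_duration_s: float = 60.0
    maintenance_duration_s: float = 300.0
    awake_rms_uv: float = 20.0
    vulnerable_emergence_rms_uv: float = 22.0
    suppression_rms_uv: float = 0.5
    ramp: str = "linear"  # or "sigmoid"
    #: Per-animal biological variability: log-SD of multiplicative jitter on
    #: band weights (shared across phases, renormalized) and on target RMS.
    band_jitter_logsd: float = 0.35
    rms_jitter_logsd: float = 0.15
    sample_rate: float = 1000.0
    seed: int = 0
    fraction_names: tuple[str, ...] = FRACTION_NAMES
    correlation: float = 0.15  # within-assay-block equicorrelation

    def validate(self) -> "SyntheticConfig":
        for g, n in self.n_per_group.items():
            if g not in GROUPS:
                raise ConfigError(f"n_per_group: unknown group {g!r}")
            if n <= 0:
                raise ConfigError(f"n_per_group[{g!r}] must be > 0, got {n}")
        if not 0 <= self.vulnerable_fraction <= 1:
            raise ConfigError("vulnerable_fraction must lie in [0, 1]")
        if not 0 <= self.suppression_fraction <= 1:
            raise ConfigError("suppression_fraction must lie in [0, 1]")
        if self.behavior_noise_sd <= 0:
            raise ConfigError("behavior_noise_sd must be positive")
        top = max(b for _, b in DEFAULT_BANDS.values())
        if self.sample_rate <= 2 * top:
            raise ConfigError(
                f"sample_rate must exceed twice the highest band edge ({top} Hz)")
        for phase, w in self.band_weights.items():
            vals = np.array(list(w.values()), dtype=float)
            if (vals < 0).any():
                raise ConfigError(f"band_weights[{phase!r}] must be nonnegative")
            if abs(vals.sum() - 1.0) > 1e-9:
                raise ConfigError(f"band_weights[{phase!r}] must sum to 1")
        unknown = set(self.behavior_effect) - set(self.fraction_names)
        if unknown:
            raise ConfigError(f"behavior_effect names unknown: {sorted(unknown)}")
        if self.ramp not in ("linear", "sigmoid"):
            raise ConfigError(f"ramp must be 'linear' or 'sigmoid', got {self.ramp!r}")
        return self


@dataclass
class SyntheticCohort:
    """A generated cohort: behavior table, recordings, planted truth."""

    behavioral_table: BehavioralMatrix
    recordings: dict[str, EEGRecording]
    truth_labels: dict[str, str]
    config_used: SyntheticConfig


# ---------------------------------------------------------------------------
# behavior


#: Assay blocks sharing a latent factor (within-block correlation).
_ASSAY_BLOCKS = (
    ("escape_latency_d1", "escape_latency_d2", "escape_latency_d3",
     "escape_latency_d4", "delta_latency_d1_d2", "first_entry_session",
     "total_successful_entries"),
    ("target_quadrant_time", "target_hole_latency", "target_visits"),
    ("freezing_time", "freezing_bouts"),
    ("high_active_time", "movement_time", "oft_distance", "oft_center_time"),
)


def _planted_counts(config: SyntheticConfig) -> tuple[int, int]:
    n_aged = config.n_per_group["aged-surgery"]
    n_vuln = int(round(config.vulnerable_fraction * n_aged))
    return n_vuln, n_aged - n_vuln


def plant_truth(config: SyntheticConfig) -> tuple[list[str], list[str], list[str]]:
    """Deterministic animal ids, group labels and phenotype truth.

    ``round(vulnerable_fraction * n)`` aged-surgery animals are planted
    vulnerable, at positions drawn (deterministically from the config seed)
    uniformly within the group — which animals are vulnerable carries no
    information in their ids. All other animals (shams and young-surgery)
    are preserved.
    """
    ids, groups, truth = [], [], []
    n_vuln, _ = _planted_counts(config)
    n_aged = config.n_per_group.get("aged-surgery", 0)
    placement_rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, 0xA5]))
    vuln_pos = set(placement_rng.permutation(n_aged)[:n_vuln].tolist())
    for g in GROUPS:
        for i in range(config.n_per_group.get(g, 0)):
            ids.append(f"{g}-{i + 1:02d}")
            groups.append(g)
            if g == "aged-surgery" and i in vuln_pos:
                truth.append("vulnerable")
            else:
                truth.append("preserved")
    return ids, groups, truth


def gen_behavioral_table(config: SyntheticConfig) -> BehavioralMatrix:
    """Generate the animals x 16 standardized-fraction table.

    All animals draw correlated Gaussian noise (within-assay-block
    equicorrelation ``config.correlation``) around a zero mean in
    standardized units; vulnerable aged-surgery animals additionally receive
    the ``behavior_effect`` mean shift. The preserved aged-surgery component
    shares the young-surgery mean (zero).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    ids, groups, truth = plant_truth(config)
    n = len(ids)
    d = len(config.fraction_names)
    rho = config.correlation
    col_of = {name: j for j, name in enumerate(config.fraction_names)}
    X = np.empty((n, d))
    # block-equicorrelated noise via shared latent factor per assay block
    for i in range(n):
        row = np.empty(d)
        assigned = np.zeros(d, dtype=bool)
        for block in _ASSAY_BLOCKS:
            cols = [col_of[c] for c in block if c in col_of]
            if not cols:
                continue
            latent = rng.standard_normal()
            eps = rng.standard_normal(len(cols))
            row[cols] = np.sqrt(rho) * latent + np.sqrt(1 - rho) * eps
            assigned[cols] = True
        row[~assigned] = rng.standard_normal((~assigned).sum())
        X[i] = row * config.behavior_noise_sd
    for i, t in enumerate(truth):
        if t == "vulnerable":
            for name, shift in config.behavior_effect.items():
                X[i, col_of[name]] += shift
    return BehavioralMatrix(animal_ids=ids, group=groups, X=X,
                            columns=config.fraction_names, standardized=True)


# ---------------------------------------------------------------------------
# EEG


def _band_noise(rng: np.random.Generator, n: int, fs: float,
                band: tuple[float, float]) -> np.ndarray:
    """Unit-variance band-limited Gaussian noise."""
    x = rng.standard_normal(n)
    sos = sps.butter(4, band, btype="bandpass", fs=fs, output="sos")
    y = sps.sosfiltfilt(sos, x)
    sd = y.std()
    return y / sd if sd > 0 else y


def _weight_path(config: SyntheticConfig, phase: str, phenotype: str,
                 n: int) -> dict[str, np.ndarray]:
    """Per-sample band weights across the requested interval."""
    bw = config.band_weights
    if phase == "baseline":
        return {b: np.full(n, w) for b, w in bw["baseline"].items()}
    if phase == "maintenance":
        return {b: np.full(n, w) for b, w in bw["maintenance"].items()}
    # emergence: ramp maintenance -> phenotype-dependent awake target
    start = bw["maintenance"]
    end = bw[f"emergence_end_{phenotype}"]
    t = np.linspace(0.0, 1.0, n)
    if config.ramp == "sigmoid":
        t = 1.0 / (1.0 + np.exp(-8.0 * (t - 0.5)))
    path = {}
    for b in start:
        r = t ** 2 if (phenotype == "vulnerable" and b in ("alpha", "beta")) else t
        path[b] = start[b] + r * (end[b] - start[b])
    return path


def gen_eeg(config: SyntheticConfig, phase: str, phenotype: str,
            duration_s: float, seed: int) -> EEGRecording:
    """Synthesize one phase of one animal's EEG in microvolts.

    The signal is a weighted sum of unit-variance band-limited noise
    components, mixed with sqrt-power weights so each band's share of total
    power tracks its weight, then scaled to the target RMS. Maintenance
    signals interleave near-flat suppression episodes totalling
    ``suppression_fraction`` of the duration; emergence signals ramp the
    weights from maintenance-like to awake-like over the interval.
    """
    config.validate()
    if phase not in PHASES:
        raise ConfigError(f"unknown phase {phase!r}")
    if phenotype not in PHENOTYPES:
        raise ConfigError(f"unknown phenotype {phenotype!r}")
    if duration_s <= 0:
        raise ConfigError("duration_s must be positive")
    fs = config.sample_rate
    n = int(round(duration_s * fs))
    rng = np.random.default_rng(seed)
    weights = _weight_path(config, phase, phenotype, n)
    x = np.zeros(n)
    for band_name, w in weights.items():
        comp = _band_noise(rng, n, fs, DEFAULT_BANDS[band_name])
        x += np.sqrt(w) * comp
    sd = x.std()
    if sd > 0:
        x /= sd
    rms = config.awake_rms_uv
    if phase == "emergence" and phenotype == "vulnerable":
        rms = config.vulnerable_emergence_rms_uv
    x *= rms
    if phase == "maintenance" and config.suppression_fraction > 0:
        x = _apply_suppression(x, fs, config, rng)
    return EEGRecording(samples=x, sample_rate=fs,
                        phase_intervals={phase: (0.0, duration_s)})


def _apply_suppression(x: np.ndarray, fs: float, config: SyntheticConfig,
                       rng: np.random.Generator) -> np.ndarray:
    """Replace evenly spaced episodes with low-amplitude noise.

    Episodes of ~3 s nominal length are placed at regular intervals and
    replaced by Gaussian noise of ``suppression_rms_uv`` RMS (well inside
    the ±5 uV criterion), totalling ``suppression_fraction`` of the samples.
    """
    n = len(x)
    frac = config.suppression_fraction
    total = int(round(frac * n))
    if total >= n:
        return rng.standard_normal(n) * config.suppression_rms_uv
    nominal = int(3.0 * fs)
    n_ep = max(1, int(round(total / nominal)))
    ep_len = total // n_ep
    lengths = [ep_len] * n_ep
    lengths[-1] += total - ep_len * n_ep
    gap = (n - total) // (n_ep + 1)
    out = x.copy()
    pos = gap
    for L in lengths:
        out[pos:pos + L] = rng.standard_normal(L) * config.suppression_rms_uv
        pos += L + gap
    return out


def _jittered_config(config: SyntheticConfig, seed: int) -> SyntheticConfig:
    """Per-animal trait variability: one multiplicative jitter per band,
    applied to every phase's weights (renormalized), plus an RMS jitter."""
    from dataclasses import replace

    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x1F]))
    bands = list(DEFAULT_BANDS)
    mult = {b: float(np.exp(config.band_jitter_logsd * rng.standard_normal()))
            for b in bands}
    bw = {}
    for phase, w in config.band_weights.items():
        jw = {b: w[b] * mult[b] for b in w}
        s = sum(jw.values())
        bw[phase] = {b: v / s for b, v in jw.items()}
    rms_mult = float(np.exp(config.rms_jitter_logsd * rng.standard_normal()))
    return replace(
        config, band_weights=bw,
        awake_rms_uv=config.awake_rms_uv * rms_mult,
        vulnerable_emergence_rms_uv=config.vulnerable_emergence_rms_uv * rms_mult,
    )


def gen_recording(config: SyntheticConfig, animal_id: str, phenotype: str,
                  seed: int, phases: tuple[str, ...] = PHASES) -> EEGRecording:
    """Concatenate the requested phases into one annotated recording.

    Each animal carries its own spectral traits (jittered band weights and
    amplitude) so that cohort-level feature distributions overlap between
    phenotypes instead of separating on any single averaged descriptor.
    """
    config = _jittered_config(config, seed)
    seq = np.random.SeedSequence(seed)
    phase_seeds = {p: int(s.generate_state(1)[0] % (2 ** 31))
                   for p, s in zip(PHASES, seq.spawn(len(PHASES)))}
    durations = {
        "baseline": config.baseline_duration_s,
        "maintenance": config.maintenance_duration_s,
        "emergence": config.emergence_duration_s[phenotype],
    }
    chunks, intervals, t0 = [], {}, 0.0
    for p in phases:
        rec = gen_eeg(config, p, phenotype, durations[p], phase_seeds[p])
        chunks.append(rec.samples)
        intervals[p] = (t0, t0 + durations[p])
        t0 += durations[p]
    return EEGRecording(samples=np.concatenate(chunks),
                        sample_rate=config.sample_rate,
                        phase_intervals=intervals, animal_id=animal_id)


def gen_cohort(config: SyntheticConfig,
               phases: tuple[str, ...] = PHASES,
               recording_groups: tuple[str, ...] = ("young-surgery",
                                                    "aged-surgery"),
               ) -> SyntheticCohort:
    """Generate a full consistent cohort.

    Behavioral rows and truth labels cover all four groups; EEG recordings
    are generated for the surgical animals (the groups that underwent
    anesthesia), each containing the requested phases. Young-surgery animals
    are always planted preserved.
    """
    config.validate()
    table = gen_behavioral_table(config)
    ids, groups, truth = plant_truth(config)
    truth_map = dict(zip(ids, truth))
    recordings: dict[str, EEGRecording] = {}
    master = np.random.SeedSequence(config.seed)
    spawned = master.spawn(len(ids))
    for aid, g, child in zip(ids, groups, spawned):
        if g not in recording_groups:
            continue
        rec_seed = int(child.generate_state(1)[0] % (2 ** 31))
        recordings[aid] = gen_recording(config, aid, truth_map[aid],
                                        rec_seed, phases=phases)
    return SyntheticCohort(behavioral_table=table, recordings=recordings,
                           truth_labels=truth_map, config_used=config)
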